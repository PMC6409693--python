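"""Ant colony search engines for epistatic interaction detection.

Two modes share one engine.  ``aco`` is the standard ant colony: each of M
ants picks a K-locus set with probability proportional to
``tau_k^alpha * eta_k^beta``, every set is scored by the chi-square fitness,
the iteration's best set is recorded as a candidate, and each visited locus
receives the visiting ant's chi-square as pheromone deposit on top of
evaporation: ``tau_k <- (1 - rho) tau_k + sum(deposits)``.

``ieaco`` adds an entropy-driven switch: when the pheromone-distribution
entropy stops changing (|dH| <= theta between adjacent iterations) the
selection rule gains a negative-feedback factor ``w_k = mu - tau_k`` raised
to gamma, boosting loci the colony has neglected and restoring exploration.

After the final iteration the distinct recorded candidates whose p-values
clear the Bonferroni-corrected threshold ``significance / C(L, K)`` are
reported, ranked by chi-square descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .association import FitnessValue, bonferroni_threshold, score_sets
from .entropy import EntropyHistory, Strategy, choose_strategy, pheromone_entropy
from .simulator import GenotypeDataset

__all__ = [
    "ConfigurationError",
    "InvalidStateError",
    "SamplingError",
    "SearchConfig",
    "PheromoneState",
    "SearchResult",
    "selection_probs_positive",
    "selection_probs_negative",
    "negative_feedback_weights",
    "sample_snp_set",
    "update_pheromones",
    "run_search",
]

#: floor applied to negative-feedback weights once tau_k >= mu
W_FLOOR = 1e-6


class ConfigurationError(ValueError):
    """The search configuration violates a constraint."""


class InvalidStateError(ValueError):
    """Pheromone or heuristic state is outside its valid domain."""


class SamplingError(ValueError):
    """Too few selectable loci for the requested set size."""


@dataclass(frozen=True)
class SearchConfig:
    """All parameters of a search run.

    ``n_ants`` and ``n_iterations`` default to ``None`` and are resolved
    from the dataset size L at run time: 500 ants for L <= 500 and 200
    otherwise, with ``0.2 * L`` iterations.  The remaining defaults are the
    standard operating point of the algorithm: alpha = beta = 1, rho = 0.05,
    tau0 = 100, eta = 1, and for ieaco mu = 300, gamma = 1, theta = 0.001.
    """

    mode: str = "ieaco"
    n_ants: int | None = None
    n_iterations: int | None = None
    set_size: int = 2
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    rho: float = 0.05
    tau0: float = 100.0
    eta: float | Sequence[float] = 1.0
    mu: float = 300.0
    theta: float = 0.001
    significance: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("aco", "ieaco"):
            raise ConfigurationError(f"mode must be 'aco' or 'ieaco', got {self.mode!r}")
        if self.n_ants is not None and self.n_ants < 1:
            raise ConfigurationError("n_ants must be >= 1")
        if self.n_iterations is not None and self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.set_size < 1:
            raise ConfigurationError("set_size must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigurationError("rho must lie in [0, 1)")
        if self.tau0 <= 0:
            raise ConfigurationError("tau0 must be positive")
        if self.mode == "ieaco" and self.mu <= self.tau0:
            raise ConfigurationError("mu must exceed tau0")
        if not (0.0 < self.significance < 1.0):
            raise ConfigurationError("significance must lie in (0, 1)")

    def resolved(self, n_snps: int) -> "SearchConfig":
        """Fill dataset-size-dependent defaults for a given locus count."""
        n_ants = self.n_ants if self.n_ants is not None else (500 if n_snps <= 500 else 200)
        n_iterations = (
            self.n_iterations
            if self.n_iterations is not None
            else max(1, round(0.2 * n_snps))
        )
        return replace(self, n_ants=n_ants, n_iterations=n_iterations)


@dataclass
class PheromoneState:
    """Per-locus pheromone vector at a given iteration."""

    tau: np.ndarray
    iteration: int = 0


@dataclass
class SearchResult:
    """Outcome of a search run.

    ``per_iteration_best`` holds the iteration-best (snp_set, fitness) pairs
    in iteration order; ``reported`` the distinct candidates whose p-values
    clear the Bonferroni threshold, ranked by chi-square descending.
    ``entropy_history`` is populated in ieaco mode only.
    """

    per_iteration_best: list[tuple[tuple[int, ...], FitnessValue]]
    reported: list[tuple[tuple[int, ...], FitnessValue]]
    strategies: list[Strategy]
    entropy_history: EntropyHistory | None
    config: SearchConfig
    pheromones: np.ndarray | None = None

    @property
    def top_hit(self) -> tuple[int, ...] | None:
        return self.reported[0][0] if self.reported else None


def _as_positive_vector(x, n: int, label: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim == 0:
        v = np.full(n, float(v))
    if v.shape != (n,):
        raise InvalidStateError(f"{label} must be a scalar or length-{n} vector")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise InvalidStateError(f"{label} values must be positive and finite")
    return v


def selection_probs_positive(tau, eta, alpha: float = 1.0, beta: float = 1.0) -> np.ndarray:
    """Positive-feedback selection probabilities p_k ~ tau_k^alpha eta_k^beta."""
    tau = np.asarray(tau, dtype=float)
    eta = _as_positive_vector(eta, tau.shape[0], "eta")
    if np.any(tau <= 0):
        raise InvalidStateError("pheromone values must be positive")
    weights = tau**alpha * eta**beta
    return weights / weights.sum()


def negative_feedback_weights(tau, mu: float, floor: float = W_FLOOR) -> np.ndarray:
    """Negative-feedback pheromones ``w_k = mu - tau_k``, floored at ``floor``.

    ``mu`` is the upper bound of negative-feedback pheromone on the worst
    loci: an empty locus (tau = 0) receives the full bound while loci whose
    pheromone meets or exceeds mu are clamped to a small positive floor so
    the selection rule stays well defined.
    """
    if mu <= 0:
        raise InvalidStateError("mu must be positive")
    tau = np.asarray(tau, dtype=float)
    return np.maximum(mu - tau, floor)


def selection_probs_negative(
    tau, eta, w, alpha: float = 1.0, beta: float = 1.0, gamma: float = 1.0
) -> np.ndarray:
    """Negative-feedback probabilities p_k ~ tau_k^alpha eta_k^beta w_k^gamma.

    With gamma = 0 this reduces exactly to the positive-feedback rule.
    """
    tau = np.asarray(tau, dtype=float)
    eta = _as_positive_vector(eta, tau.shape[0], "eta")
    w = _as_positive_vector(w, tau.shape[0], "w")
    if np.any(tau <= 0):
        raise InvalidStateError("pheromone values must be positive")
    weights = tau**alpha * eta**beta * w**gamma
    return weights / weights.sum()


def _sample_sets(probs: np.ndarray, k: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m SNP sets of k distinct loci by sequential sampling.

    Each within-set draw conditions on the loci already chosen, which is
    realised by rejection (redraw on collision) -- exactly equivalent to
    renormalising the remaining probabilities after each pick.  Rows are
    returned sorted ascending.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise SamplingError("selection probabilities must be nonnegative with positive sum")
    if int(np.count_nonzero(p)) < k:
        raise SamplingError(f"only {np.count_nonzero(p)} selectable loci for set size {k}")
    cdf = np.cumsum(p)
    total = cdf[-1]
    last = len(p) - 1
    picks = np.empty((m, k), dtype=np.int64)
    for j in range(k):
        idx = np.minimum(np.searchsorted(cdf, rng.random(m) * total, side="right"), last)
        if j:
            dup = (idx[:, None] == picks[:, :j]).any(axis=1)
            while dup.any():
                n_dup = int(dup.sum())
                idx[dup] = np.minimum(
                    np.searchsorted(cdf, rng.random(n_dup) * total, side="right"), last
                )
                dup = (idx[:, None] == picks[:, :j]).any(axis=1)
        picks[:, j] = idx
    picks.sort(axis=1)
    return picks


def sample_snp_set(probs, k: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Draw one set of k distinct loci from a selection-probability vector."""
    return tuple(_sample_sets(np.asarray(probs, dtype=float), k, 1, rng)[0].tolist())


def update_pheromones(
    state: PheromoneState, ant_sets, fitness, rho: float
) -> PheromoneState:
    """Evaporate and deposit: tau_k <- (1 - rho) tau_k + sum of visiting chi2.

    Every ant deposits its set's chi-square on each locus of its set;
    deposits sum across ants, and unvisited loci only evaporate.
    """
    fitness = np.asarray(fitness, dtype=float)
    if np.any(fitness < 0):
        raise InvalidStateError("chi-square deposits must be nonnegative")
    sets = np.atleast_2d(np.asarray(ant_sets, dtype=np.int64))
    if sets.shape[0] != fitness.shape[0]:
        raise InvalidStateError("one fitness value per ant set is required")
    deposit = np.zeros_like(state.tau, dtype=float)
    np.add.at(deposit, sets.ravel(), np.repeat(fitness, sets.shape[1]))
    return PheromoneState(tau=(1.0 - rho) * state.tau + deposit, iteration=state.iteration + 1)


def run_search(dataset: GenotypeDataset, config: SearchConfig) -> SearchResult:
    """Run the full ant colony search on a dataset.

    Each iteration: (ieaco only) pick the strategy from the entropy change,
    sample one K-set per ant, score all sets, record the iteration best
    (ties broken toward the lexicographically smallest set), then update
    pheromones.  Finally the distinct candidates passing the Bonferroni
    threshold are reported ranked by chi-square.  A fixed seed gives an
    identical result.
    """
    n_snps = dataset.n_snps
    cfg = config.resolved(n_snps)
    k = cfg.set_size
    if k > n_snps:
        raise ConfigurationError(f"set_size {k} exceeds locus count {n_snps}")
    rng = np.random.default_rng(cfg.seed)
    eta = _as_positive_vector(cfg.eta, n_snps, "eta")
    state = PheromoneState(tau=np.full(n_snps, float(cfg.tau0)), iteration=0)
    ieaco = cfg.mode == "ieaco"
    history = EntropyHistory(theta=cfg.theta) if ieaco else None
    if ieaco:
        history.values.append(pheromone_entropy(state.tau))

    strategies: list[Strategy] = []
    per_iteration_best: list[tuple[tuple[int, ...], FitnessValue]] = []
    for _ in range(cfg.n_iterations):
        if ieaco:
            h = history.values
            strategy = (
                Strategy.POSITIVE
                if len(h) < 2
                else choose_strategy(h[-1], h[-2], cfg.theta)
            )
        else:
            strategy = Strategy.POSITIVE
        if strategy is Strategy.POSITIVE:
            probs = selection_probs_positive(state.tau, eta, cfg.alpha, cfg.beta)
        else:
            w = negative_feedback_weights(state.tau, cfg.mu)
            probs = selection_probs_negative(state.tau, eta, w, cfg.alpha, cfg.beta, cfg.gamma)
        strategies.append(strategy)

        sets = _sample_sets(probs, k, cfg.n_ants, rng)
        chi2, dof, p = score_sets(dataset, sets)
        best_chi2 = chi2.max()
        tied = np.flatnonzero(chi2 == best_chi2)
        best_idx = min(tied, key=lambda i: tuple(sets[i]))
        best_set = tuple(int(x) for x in sets[best_idx])
        per_iteration_best.append(
            (best_set, FitnessValue(float(chi2[best_idx]), int(dof[best_idx]), float(p[best_idx])))
        )
        state = update_pheromones(state, sets, chi2, cfg.rho)
        if ieaco:
            history.values.append(pheromone_entropy(state.tau))

    # merge duplicate candidates keeping the highest chi-square
    pool: dict[tuple[int, ...], FitnessValue] = {}
    for snp_set, fit in per_iteration_best:
        prev = pool.get(snp_set)
        if prev is None or fit.chi2 > prev.chi2:
            pool[snp_set] = fit
    threshold = bonferroni_threshold(cfg.significance, n_snps, k)
    reported = [(s, f) for s, f in pool.items() if f.p_value < threshold]
    reported.sort(key=lambda item: (-item[1].chi2, item[0]))
    return SearchResult(
        per_iteration_best=per_iteration_best,
        reported=reported,
        strategies=strategies,
        entropy_history=history,
        config=cfg,
        pheromones=state.tau,
    )
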