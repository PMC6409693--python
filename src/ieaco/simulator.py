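"""Two-locus penetrance-model simulator for case-control genotype data.

A :class:`PenetranceModel` specifies minor-allele frequencies (MAFs) for two
interacting loci together with a 3x3 table of penetrances -- the probability
of disease for each joint genotype.  Genotypes are coded by the copy number
of the minor allele (0 = homozygous major, 1 = heterozygous, 2 = homozygous
minor).  Table rows are indexed by the B-locus genotype (BB, Bb, bb) and
columns by the A-locus genotype (AA, Aa, aa).

Datasets are sampled with a fixed number of cases and controls.  The two
embedded loci are drawn jointly from the penetrance table inverted by Bayes'
rule conditional on disease status; all background loci are drawn
independently under Hardy-Weinberg equilibrium with MAFs identical in cases
and controls, so only the embedded pair carries association signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidParameterError",
    "DegenerateModelError",
    "PenetranceModel",
    "GenotypeDataset",
    "hwe_genotype_freqs",
    "model_prevalence",
    "conditional_genotype_dist",
    "simulate_dataset",
    "simulate_multi_dataset",
]

#: status code for affected individuals
CASE = 1
#: status code for unaffected individuals
CONTROL = 2


class InvalidParameterError(ValueError):
    """A model or sampling parameter is outside its valid range."""


class DegenerateModelError(ValueError):
    """The penetrance model cannot produce the requested status group."""


@dataclass(frozen=True)
class PenetranceModel:
    """A two-locus disease model: MAFs plus a 3x3 penetrance table.

    Parameters
    ----------
    name
        Text label for the model.
    maf_a, maf_b
        Minor-allele frequencies of locus A and locus B, each in (0, 0.5].
    table
        3x3 penetrance matrix, rows indexed by B-locus genotype (BB, Bb, bb),
        columns by A-locus genotype (AA, Aa, aa); entries in [0, 1].
    declared_prevalence
        Optional population prevalence as stated by the model's source.  It
        is metadata only: sampling always uses the prevalence implied by the
        table under Hardy-Weinberg genotype frequencies
        (:func:`model_prevalence`), which for some published "no marginal
        effect" models differs from the declared value.
    """

    name: str
    maf_a: float
    maf_b: float
    table: np.ndarray
    declared_prevalence: float | None = None

    def __post_init__(self) -> None:
        for label, maf in (("maf_a", self.maf_a), ("maf_b", self.maf_b)):
            if not (0.0 < maf <= 0.5):
                raise InvalidParameterError(
                    f"{label}={maf!r} must lie in (0, 0.5]"
                )
        table = np.asarray(self.table, dtype=float)
        if table.shape != (3, 3):
            raise InvalidParameterError(
                f"penetrance table must be 3x3, got shape {table.shape}"
            )
        if np.any(table < 0.0) or np.any(table > 1.0):
            raise InvalidParameterError("penetrance values must lie in [0, 1]")
        if not np.any(table > 0.0):
            raise InvalidParameterError(
                "penetrance table is uniformly zero; no cases can be sampled"
            )
        object.__setattr__(self, "table", table)
        table.setflags(write=False)


@dataclass
class GenotypeDataset:
    """Case-control genotype matrix with optional embedded ground truth.

    ``genotypes`` is an S x L matrix with entries in {0, 1, 2} (minor-allele
    copy number); ``status`` holds 1 for cases and 2 for controls.  ``truth``
    lists the locus-index sets of any embedded interactions (0-based).
    """

    genotypes: np.ndarray
    status: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    truth: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.status = np.asarray(self.status)
        if self.genotypes.ndim != 2:
            raise InvalidParameterError("genotypes must be a 2-D matrix")
        if self.status.shape != (self.genotypes.shape[0],):
            raise InvalidParameterError("status length must match sample count")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise InvalidParameterError("genotype entries must be 0, 1 or 2")
        if not np.isin(self.status, (CASE, CONTROL)).all():
            raise InvalidParameterError("status entries must be 1 (case) or 2 (control)")
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(self.genotypes.shape[1])]
        if len(self.snp_ids) != self.genotypes.shape[1]:
            raise InvalidParameterError("snp_ids length must match locus count")
        for s in self.truth:
            if any(not (0 <= i < self.n_snps) for i in s):
                raise InvalidParameterError(f"truth indices {s} out of range")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.status == CASE))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.status == CONTROL))


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies for a biallelic locus.

    Returns the probabilities of carrying 0, 1 or 2 copies of the minor
    allele: ``((1-q)^2, 2q(1-q), q^2)`` at minor-allele frequency ``q``.
    """
    if not (0.0 < maf <= 0.5):
        raise InvalidParameterError(f"maf={maf!r} must lie in (0, 0.5]")
    q = float(maf)
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q])


def _joint_genotype_freqs(model: PenetranceModel) -> np.ndarray:
    """3x3 matrix of P(B genotype h, A genotype g) under HWE independence."""
    return np.outer(hwe_genotype_freqs(model.maf_b), hwe_genotype_freqs(model.maf_a))


def model_prevalence(model: PenetranceModel) -> float:
    """Population prevalence implied by the penetrance table under HWE.

    The genotype-frequency-weighted mean of the table:
    ``sum_{g,h} f_A(g) f_B(h) table[h][g]``.
    """
    return float(np.sum(_joint_genotype_freqs(model) * model.table))


def conditional_genotype_dist(model: PenetranceModel, status: int) -> np.ndarray:
    """Joint genotype distribution at the interacting pair given status.

    Bayes inversion of the penetrance table.  For cases,
    ``P(g, h | case) = f_A(g) f_B(h) table[h][g] / prevalence``; for controls
    the complement ``1 - table[h][g]`` is used with ``1 - prevalence``.

    Returns a 3x3 array (rows = B genotype, cols = A genotype) summing to 1.
    """
    if status not in (CASE, CONTROL):
        raise InvalidParameterError(f"status must be {CASE} (case) or {CONTROL} (control)")
    joint = _joint_genotype_freqs(model)
    if status == CASE:
        unnorm = joint * model.table  # normaliser = prevalence
    else:
        unnorm = joint * (1.0 - model.table)  # normaliser = 1 - prevalence
    mass = unnorm.sum()
    if mass <= 0.0:
        label = "cases" if status == CASE else "controls"
        raise DegenerateModelError(
            f"model prevalence is {'0' if status == CASE else '1'}; cannot sample {label}"
        )
    return unnorm / mass


def _sample_pair_genotypes(
    model: PenetranceModel, status: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n joint genotypes (A-locus, B-locus) conditional on status."""
    dist = conditional_genotype_dist(model, status)
    cells = rng.choice(9, size=n, p=dist.ravel())
    # ravel order: h (B genotype) major, g (A genotype) minor
    return cells % 3, cells // 3


def simulate_dataset(
    model: PenetranceModel,
    n_snps: int,
    n_cases: int,
    n_controls: int,
    pair_positions: tuple[int, int] | None = None,
    background_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
) -> GenotypeDataset:
    """Simulate a case-control dataset with one embedded epistatic pair.

    Cases come first in the returned matrix, then controls.  The two loci in
    ``pair_positions`` (chosen at random when ``None``) are drawn jointly from
    the model's status-conditional genotype distribution; all other loci are
    independent HWE noise with per-locus MAFs drawn uniformly from
    ``background_maf_range``.  A fixed ``seed`` reproduces the dataset
    bit-identically.
    """
    if n_snps < 2:
        raise InvalidParameterError("n_snps must be at least 2")
    if n_cases < 0 or n_controls < 0 or n_cases + n_controls == 0:
        raise InvalidParameterError("need a positive number of samples")
    rng = np.random.default_rng(seed)
    if pair_positions is None:
        pair_positions = tuple(sorted(rng.choice(n_snps, size=2, replace=False).tolist()))
    dataset = simulate_multi_dataset(
        [model],
        n_snps,
        n_cases,
        n_controls,
        [tuple(pair_positions)],
        background_maf_range=background_maf_range,
        rng=rng,
    )
    return dataset


def simulate_multi_dataset(
    models: list[PenetranceModel],
    n_snps: int,
    n_cases: int,
    n_controls: int,
    pair_positions: list[tuple[int, int]],
    background_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeDataset:
    """Simulate a dataset with several embedded pairs, one model per pair.

    Each pair is sampled independently from its own model's conditional
    distribution given the individual's status; pairs must not share loci.
    """
    if len(models) != len(pair_positions):
        raise InvalidParameterError("need one model per embedded pair")
    flat: list[int] = []
    for pair in pair_positions:
        a, b = pair
        if a == b or not (0 <= a < n_snps) or not (0 <= b < n_snps):
            raise InvalidParameterError(f"invalid pair positions {pair!r}")
        flat.extend(pair)
    if len(set(flat)) != len(flat):
        raise InvalidParameterError("embedded pairs must not share loci")
    lo, hi = background_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidParameterError(
            f"background_maf_range {background_maf_range!r} must satisfy 0 < lo <= hi <= 0.5"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    n_total = n_cases + n_controls
    status = np.concatenate(
        [np.full(n_cases, CASE, dtype=np.int8), np.full(n_controls, CONTROL, dtype=np.int8)]
    )
    genotypes = np.empty((n_total, n_snps), dtype=np.int8)

    embedded = set(flat)
    background = np.array([j for j in range(n_snps) if j not in embedded])
    if background.size:
        mafs = rng.uniform(lo, hi, size=background.size)
        # binomial(2, q) reproduces HWE genotype frequencies exactly
        genotypes[:, background] = rng.binomial(2, mafs, size=(n_total, background.size))

    for model, (pos_a, pos_b) in zip(models, pair_positions):
        g_case, h_case = _sample_pair_genotypes(model, CASE, n_cases, rng)
        g_ctrl, h_ctrl = _sample_pair_genotypes(model, CONTROL, n_controls, rng)
        genotypes[:n_cases, pos_a] = g_case
        genotypes[:n_cases, pos_b] = h_case
        genotypes[n_cases:, pos_a] = g_ctrl
        genotypes[n_cases:, pos_b] = h_ctrl

    truth = [tuple(sorted(p)) for p in pair_positions]
    return GenotypeDataset(genotypes=genotypes, status=status, truth=truth)
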