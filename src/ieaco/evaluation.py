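"""Detection power, recall/precision and top-N evaluation of search runs.

Detection power is the fraction of datasets on which the top-ranked
reported interaction equals the single embedded truth pair.  Recall and
precision follow the information-retrieval definitions: a true positive is
a truth set recovered anywhere in its dataset's report list (set equality,
order-insensitive); partial overlaps count as misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .search import SearchConfig, SearchResult, run_search
from .simulator import PenetranceModel, simulate_dataset

__all__ = [
    "EvaluationReport",
    "detection_power",
    "recall_precision",
    "top_n_breakdown",
    "evaluate_batch",
    "run_power_experiment",
    "analytic_pair_power",
]


@dataclass
class EvaluationReport:
    """Batch metrics over a collection of datasets."""

    power: float | None
    recall: float
    precision: float
    tp: int
    fp: int
    fn: int
    per_dataset: list[dict] = field(default_factory=list)


def _reported_sets(result) -> list[frozenset]:
    """Accept a SearchResult or a plain sequence of index sets."""
    if isinstance(result, SearchResult):
        return [frozenset(s) for s, _ in result.reported]
    return [frozenset(s) for s in result]


def detection_power(results: Sequence, truths: Sequence[Iterable[int]]) -> float:
    """Fraction of datasets whose top-ranked report equals the embedded truth.

    ``truths`` holds one ground-truth locus set per dataset.
    """
    if len(results) == 0:
        raise ValueError("no results to evaluate")
    if len(results) != len(truths):
        raise ValueError("results and truths must have equal length")
    successes = 0
    for result, truth in zip(results, truths):
        truth = frozenset(truth)
        if not truth:
            raise ValueError("each truth set must be nonempty")
        reported = _reported_sets(result)
        if reported and reported[0] == truth:
            successes += 1
    return successes / len(results)


def recall_precision(
    reported: Sequence[Sequence[Iterable[int]]],
    truths: Sequence[Sequence[Iterable[int]]],
) -> tuple[float, float]:
    """(recall, precision) over per-dataset report lists.

    TP counts truth sets recovered anywhere in their dataset's report list;
    FN the truths missed; FP the reports matching no truth of their dataset.
    Precision is 0 by convention when nothing is reported at all.
    """
    if len(reported) != len(truths):
        raise ValueError("reported and truths must have equal length")
    tp = fp = fn = 0
    for rep_sets, truth_sets in zip(reported, truths):
        rep = [frozenset(s) for s in _reported_sets(rep_sets)]
        tru = {frozenset(s) for s in truth_sets}
        if not tru:
            raise ValueError("each dataset needs at least one truth set")
        hits = {s for s in rep if s in tru}
        tp += len(tru & hits)
        fn += len(tru - hits)
        fp += sum(1 for s in rep if s not in tru)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return recall, precision


def top_n_breakdown(
    result, truth: Sequence[Iterable[int]], n: int
) -> tuple[float, float, float]:
    """(TP, FP, undetected) fractions among the top-n reported interactions.

    TP fraction = matched truths in the top n divided by n; FP fraction =
    unmatched reports divided by n; undetected fraction = truths absent from
    the top n divided by the number of truths.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    top = _reported_sets(result)[:n]
    tru = {frozenset(s) for s in truth}
    matched = {s for s in top if s in tru}
    tp_frac = len(matched) / n
    fp_frac = sum(1 for s in top if s not in tru) / n
    undetected = len(tru - matched) / len(tru)
    return tp_frac, fp_frac, undetected


def evaluate_batch(results: Sequence, truths: Sequence[Sequence[Iterable[int]]]) -> EvaluationReport:
    """Power plus recall/precision over a batch of per-dataset results.

    Power is only defined when every dataset embeds exactly one truth set;
    it is ``None`` otherwise.
    """
    if len(results) != len(truths):
        raise ValueError("results and truths must have equal length")
    single_truth = all(len(t) == 1 for t in truths)
    per_dataset = []
    tp = fp = fn = 0
    successes = 0
    for i, (result, truth_sets) in enumerate(zip(results, truths)):
        rep = _reported_sets(result)
        tru = {frozenset(s) for s in truth_sets}
        hits = {s for s in rep if s in tru}
        tp += len(hits)
        fn += len(tru - hits)
        fp += sum(1 for s in rep if s not in tru)
        success = bool(rep) and len(tru) == 1 and rep[0] == next(iter(tru))
        successes += success
        per_dataset.append(
            {
                "dataset": i,
                "reported": [tuple(sorted(s)) for s in rep],
                "truth": [tuple(sorted(s)) for s in tru],
                "success": success,
            }
        )
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    power = successes / len(results) if single_truth and results else None
    return EvaluationReport(
        power=power, recall=recall, precision=precision, tp=tp, fp=fp, fn=fn,
        per_dataset=per_dataset,
    )


def analytic_pair_power(
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    n_snps: int,
    significance: float = 0.05,
) -> float:
    """Detection-power ceiling for a model's embedded pair.

    Probability that the embedded pair's chi-square clears the
    Bonferroni-corrected threshold ``significance / C(n_snps, 2)``, from
    the noncentral chi-square approximation: the noncentrality is

        lambda = sum_c [n1 (p1c - pbar_c)^2 + n2 (p2c - pbar_c)^2] / pbar_c

    over the 9 joint-genotype cells, with p1/p2 the case/control
    conditional distributions and pbar their count-weighted mixture.  This
    bounds the top-hit power of *any* search strategy, since an unreported
    pair (p-value above the threshold) can never be a top hit.
    """
    from scipy import stats

    from .association import bonferroni_threshold
    from .simulator import CASE, CONTROL, conditional_genotype_dist

    p1 = conditional_genotype_dist(model, CASE).ravel()
    p2 = conditional_genotype_dist(model, CONTROL).ravel()
    pbar = (n_cases * p1 + n_controls * p2) / (n_cases + n_controls)
    live = pbar > 0
    lam = float(
        np.sum(
            (n_cases * (p1[live] - pbar[live]) ** 2 + n_controls * (p2[live] - pbar[live]) ** 2)
            / pbar[live]
        )
    )
    dof = int(live.sum()) - 1
    critical = stats.chi2.isf(bonferroni_threshold(significance, n_snps, 2), dof)
    return float(stats.ncx2.sf(critical, dof, lam))


def run_power_experiment(
    model: PenetranceModel,
    n_datasets: int = 30,
    n_snps: int = 500,
    n_cases: int = 1000,
    n_controls: int = 1000,
    config: SearchConfig | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Simulate ``n_datasets`` datasets from one model and measure power.

    Each dataset embeds the model's pair at random positions and is searched
    with ``config`` (default: ieaco at the standard operating point).  The
    master ``seed`` derives independent sub-seeds (below 2^31) for every
    simulation and search.
    """
    if config is None:
        config = SearchConfig()
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31, size=(n_datasets, 2))
    results = []
    truths = []
    for d in range(n_datasets):
        dataset = simulate_dataset(
            model, n_snps=n_snps, n_cases=n_cases, n_controls=n_controls,
            seed=int(sub_seeds[d, 0]),
        )
        from dataclasses import replace

        result = run_search(dataset, replace(config, seed=int(sub_seeds[d, 1])))
        results.append(result)
        truths.append(dataset.truth)
    return evaluate_batch(results, truths)
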