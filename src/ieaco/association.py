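"""Chi-square association scoring of SNP sets against disease status.

The fitness of a K-SNP set is Pearson's chi-square statistic on the
2 x 3^K contingency table of status (case/control) against the joint
genotype of the set.  The raw statistic -- not the p-value -- is what the
ant colony deposits as pheromone; p-values are used only for the final
Bonferroni-corrected report.

Degrees of freedom: joint genotype columns with zero total are dropped
before computing dof, so dof = (number of observed genotype combinations
- 1).  No continuity correction and no minimum expected-count rule are
applied; the statistic is the plain sum of (O - E)^2 / E over cells with
positive expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulator import CASE, GenotypeDataset

__all__ = [
    "InvalidSNPSetError",
    "UndefinedTestError",
    "ContingencyTable",
    "FitnessValue",
    "contingency_table",
    "chi2_fitness",
    "score_sets",
    "bonferroni_threshold",
]


class InvalidSNPSetError(ValueError):
    """The SNP set has duplicate or out-of-range locus indices."""


class UndefinedTestError(ValueError):
    """The contingency table cannot support a chi-square test."""


@dataclass(frozen=True)
class FitnessValue:
    """Chi-square statistic with its degrees of freedom and p-value."""

    chi2: float
    dof: int
    p_value: float


@dataclass
class ContingencyTable:
    """2 x 3^K status-by-genotype count table for a K-SNP set.

    Row 0 counts cases, row 1 controls.  Columns enumerate joint genotypes
    in base-3 positional order with the first locus most significant.
    """

    counts: np.ndarray
    snp_set: tuple[int, ...]


def contingency_table(dataset: GenotypeDataset, snp_set) -> ContingencyTable:
    """Tabulate case/control counts over the joint genotypes of a SNP set."""
    snp_set = tuple(int(i) for i in snp_set)
    k = len(snp_set)
    if k < 1:
        raise InvalidSNPSetError("SNP set must contain at least one locus")
    if len(set(snp_set)) != k:
        raise InvalidSNPSetError(f"duplicate locus indices in {snp_set}")
    if any(not (0 <= i < dataset.n_snps) for i in snp_set):
        raise InvalidSNPSetError(f"locus indices {snp_set} out of range [0, {dataset.n_snps})")
    n_cells = 3**k
    powers = 3 ** np.arange(k - 1, -1, -1)
    codes = dataset.genotypes[:, list(snp_set)].astype(np.int64) @ powers
    case = dataset.status == CASE
    counts = np.stack(
        [
            np.bincount(codes[case], minlength=n_cells),
            np.bincount(codes[~case], minlength=n_cells),
        ]
    )
    return ContingencyTable(counts=counts, snp_set=snp_set)


def _pearson(counts: np.ndarray) -> FitnessValue:
    """Pearson chi-square on one 2 x C table (zero-total columns dropped)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    row_tot = counts.sum(axis=1)
    if total <= 0 or np.any(row_tot <= 0):
        raise UndefinedTestError("both status rows must contain individuals")
    col_tot = counts.sum(axis=0)
    expected = np.outer(row_tot, col_tot) / total
    mask = expected > 0
    chi2 = float((np.square(counts - expected)[mask] / expected[mask]).sum())
    dof = int(np.count_nonzero(col_tot) - 1)
    if dof < 1 or chi2 == 0.0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(chi2, dof))
    return FitnessValue(chi2=chi2, dof=max(dof, 0), p_value=p)


def chi2_fitness(table: ContingencyTable) -> FitnessValue:
    """Chi-square fitness of a tabulated SNP set.

    Raises
    ------
    UndefinedTestError
        If the table is empty or one status row has zero total.
    """
    return _pearson(table.counts)


def score_sets(dataset: GenotypeDataset, sets) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised chi-square fitness for many SNP sets at once.

    ``sets`` is an (M, K) array of locus indices (distinct within a row).
    Returns arrays ``(chi2, dof, p_value)`` of length M, identical cell by
    cell to :func:`chi2_fitness` applied to each row's contingency table.
    """
    sets = np.atleast_2d(np.asarray(sets, dtype=np.int64))
    m, k = sets.shape
    n_cells = 3**k
    powers = 3 ** np.arange(k - 1, -1, -1)
    codes = (dataset.genotypes[:, sets].astype(np.int32) * powers).sum(axis=2)
    case = dataset.status == CASE
    offsets = np.arange(m, dtype=np.int64) * n_cells
    case_counts = np.bincount(
        (codes[case] + offsets).ravel(), minlength=m * n_cells
    ).reshape(m, n_cells)
    ctrl_counts = np.bincount(
        (codes[~case] + offsets).ravel(), minlength=m * n_cells
    ).reshape(m, n_cells)

    observed = np.stack([case_counts, ctrl_counts], axis=1).astype(float)
    total = observed[0].sum()
    if total <= 0:
        raise UndefinedTestError("dataset is empty")
    row_tot = observed.sum(axis=2)
    if np.any(row_tot <= 0):
        raise UndefinedTestError("both status rows must contain individuals")
    col_tot = observed.sum(axis=1)
    expected = row_tot[:, :, None] * col_tot[:, None, :] / total
    safe = np.where(expected > 0, expected, 1.0)
    chi2 = (np.square(observed - expected) / safe * (expected > 0)).sum(axis=(1, 2))
    dof = (col_tot > 0).sum(axis=1) - 1
    p = np.ones(m)
    valid = (dof >= 1) & (chi2 > 0)
    p[valid] = stats.chi2.sf(chi2[valid], dof[valid])
    return chi2, dof.astype(np.int64), p


def bonferroni_threshold(alpha: float, n_snps: int, k: int) -> float:
    """Bonferroni-corrected significance level: alpha / C(n_snps, k)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha={alpha!r} must lie in (0, 1)")
    if k < 1 or n_snps < k:
        raise ValueError("need n_snps >= k >= 1")
    return alpha / math.comb(n_snps, k)
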