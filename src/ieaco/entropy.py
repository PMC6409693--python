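"""Entropy-based control of the ant path-selection strategy.

The Shannon entropy (base 2) of the normalised pheromone distribution
measures how spread out the colony's attention is: it is maximal,
``log2(L)``, when every locus holds equal pheromone and falls as pheromone
concentrates on a few loci.  When the entropy change between two adjacent
iterations drops to the switch threshold theta or below, the search is
deemed to be converging and the negative-feedback selection rule takes
over to push ants back toward neglected loci.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UndefinedEntropyError",
    "Strategy",
    "EntropyHistory",
    "pheromone_entropy",
    "choose_strategy",
]


class UndefinedEntropyError(ValueError):
    """Entropy of an all-zero pheromone vector is undefined."""


class Strategy(str, enum.Enum):
    """Active path-selection rule."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass
class EntropyHistory:
    """Entropy trace of a search run.

    ``values[0]`` is the entropy of the initial (uniform) pheromones;
    ``values[i]`` is the entropy after iteration i's pheromone update.
    """

    theta: float
    values: list[float] = field(default_factory=list)


def pheromone_entropy(pheromones) -> float:
    """Shannon entropy (bits) of the normalised pheromone distribution.

    ``H = -sum_k p_k log2 p_k`` with ``p_k = tau_k / sum_j tau_j``; zero
    shares contribute nothing.  Scale-invariant in the pheromone vector.
    """
    tau = np.asarray(pheromones, dtype=float)
    if np.any(tau < 0):
        raise UndefinedEntropyError("pheromone values must be nonnegative")
    total = tau.sum()
    if total <= 0:
        raise UndefinedEntropyError("all-zero pheromone vector has no entropy")
    p = tau / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def choose_strategy(h_curr: float, h_prev: float | None, theta: float) -> Strategy:
    """Pick the selection strategy from the adjacent-iteration entropy change.

    Positive feedback (the standard rule) stays active while
    ``|h_curr - h_prev| > theta``; once the change is *not greater than*
    theta the negative-feedback rule is used.  With no previous entropy
    (the first iteration) the positive strategy is the default.

    ``theta`` is normally >= 0; a negative theta (which keeps the positive
    strategy permanently active) is accepted for diagnostics.
    """
    if h_prev is None:
        return Strategy.POSITIVE
    return Strategy.POSITIVE if abs(h_curr - h_prev) > theta else Strategy.NEGATIVE
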