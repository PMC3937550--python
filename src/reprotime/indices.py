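"""Model-free data reduction: per-cell mean responses and aggregate ratios.

A subject's 45 trials reduce to a 3 x 3 table of arithmetic means (valence x
encoded duration); the aggregate ratio index of an emotional valence is the
mean over durations of the ratio of its cell means to the neutral cell
means.  Under the null (no valence effect) the index has expectation 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .estimation import Trial

__all__ = ["CellMeans", "RatioIndices", "DURATIONS", "cell_means", "aggregate_ratio", "ratio_indices"]

logger = logging.getLogger(__name__)

#: duration index mapping: i = 1, 2, 3 <-> s = 2, 4, 6 s
DURATIONS = (2.0, 4.0, 6.0)
VALENCES = ("P", "N", "E")
_TRIALS_PER_CELL = 5


@dataclass(frozen=True)
class CellMeans:
    """Mean response and trial count per (valence, duration) cell."""

    r_bar: Mapping[str, tuple[float, ...]]  # valence -> means for s = 2, 4, 6
    n: Mapping[str, tuple[int, ...]]


@dataclass(frozen=True)
class RatioIndices:
    a_N: float
    a_P: float


def cell_means(trials: Sequence[Trial], durations: Sequence[float] = DURATIONS) -> CellMeans:
    """Arithmetic mean response per (valence, duration) cell of one subject."""
    r_bar: dict[str, tuple[float, ...]] = {}
    n: dict[str, tuple[int, ...]] = {}
    for v in VALENCES:
        means, counts = [], []
        for s in durations:
            rs = [t.r for t in trials if t.valence == v and t.s == s]
            counts.append(len(rs))
            if rs:
                if len(rs) < _TRIALS_PER_CELL:
                    logger.warning(
                        "cell (%s, s=%g) has %d trials (expected %d); averaging what is present",
                        v, s, len(rs), _TRIALS_PER_CELL,
                    )
                means.append(float(np.mean(rs)))
            else:
                means.append(float("nan"))
        r_bar[v] = tuple(means)
        n[v] = tuple(counts)
    return CellMeans(r_bar=r_bar, n=n)


def aggregate_ratio(cm: CellMeans, v: str) -> float:
    """Mean over durations of the v-to-neutral ratio of cell means."""
    if v not in ("P", "N"):
        raise ValueError(f"aggregate ratio defined for valences P and N, got {v!r}")
    rv = np.asarray(cm.r_bar[v], dtype=float)
    re = np.asarray(cm.r_bar["E"], dtype=float)
    if np.any(~np.isfinite(rv)) or np.any(~np.isfinite(re)):
        raise ValueError(f"empty cell encountered for valence {v!r} or E")
    return float(np.mean(rv / re))


def ratio_indices(trials: Sequence[Trial]) -> RatioIndices:
    """Both aggregate ratio indices of one subject."""
    cm = cell_means(trials)
    return RatioIndices(a_N=aggregate_ratio(cm, "N"), a_P=aggregate_ratio(cm, "P"))
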