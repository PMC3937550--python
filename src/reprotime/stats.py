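"""Statistical battery: t-tests, repeated-measures ANOVA with
Greenhouse-Geisser correction, Pearson correlation and fixed-bandwidth
Gaussian kernel density estimation.

All tests are two-sided.  The sphericity correction is applied
unconditionally (no Mauchly gate); the correction factor epsilon is computed
from the eigenvalues of the double-centered covariance of the within-subject
condition scores and lies in ``[1/(k-1), 1]`` for a k-level effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AnovaEffect",
    "AnovaResult",
    "KDEstimate",
    "one_sample_t",
    "paired_t",
    "pearson",
    "rm_anova_gg",
    "gaussian_kde",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        if self.df <= 0:
            raise ValueError(f"df must be > 0, got {self.df}")


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    epsilon: float
    df1_corr: float
    df2_corr: float
    p_uncorrected: float
    p_gg: float


@dataclass(frozen=True)
class AnovaResult:
    effects: Mapping[str, AnovaEffect] = field(default_factory=dict)


@dataclass(frozen=True)
class KDEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def one_sample_t(values: Sequence[float], mu0: float) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate input: zero variance")
    t = (float(np.mean(x)) - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p_value=p, method="one-sample t")


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test (one-sample t on the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(x - y, 0.0)
    return TestResult(statistic=res.statistic, df=res.df, p_value=res.p_value,
                      method="paired t")


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided t-based p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("degenerate input: zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    df = x.size - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=r, df=df, p_value=p, method="pearson r")


def _gg_epsilon(scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by ``contrasts``.

    ``scores``: subjects x conditions matrix; ``contrasts``: conditions x d
    orthonormal basis of the effect subspace.  epsilon =
    (sum lambda)^2 / (d * sum lambda^2) for the eigenvalues lambda of the
    projected covariance, clipped to [1/d, 1].
    """
    cov = np.cov(scores, rowvar=False)
    m = contrasts.T @ cov @ contrasts
    lam = np.linalg.eigvalsh(m)
    lam = np.clip(lam, 0.0, None)
    d = contrasts.shape[1]
    denom = d * float(np.sum(lam**2))
    if denom == 0.0:
        return 1.0
    eps = float(np.sum(lam)) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis orthogonal to the unit vector (Helmert)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= math.sqrt(j * (j + 1))
    return h


def rm_anova_gg(table: np.ndarray) -> AnovaResult:
    """Within-subject ANOVA with unconditional Greenhouse-Geisser correction.

    ``table`` is either ``(subjects, levels)`` for a one-way design or
    ``(subjects, a_levels, b_levels)`` for a fully-crossed two-way design.
    Effects are named ``"A"``, ``"B"`` and ``"AxB"`` (just ``"A"`` for
    one-way).  Missing cells are not supported.
    """
    y = np.asarray(table, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("table contains missing or non-finite cells")
    if y.ndim == 2:
        y = y[:, :, None]
    if y.ndim != 3:
        raise ValueError("table must be 2-D (one-way) or 3-D (two-way)")
    n, a, b = y.shape
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means
    m_a = y.mean(axis=(0, 2))          # factor-A level means
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)              # n x a
    m_sb = y.mean(axis=1)              # n x b
    m_ab = y.mean(axis=0)              # a x b

    effects: dict[str, AnovaEffect] = {}

    def add_effect(name, ss_eff, ss_err, df1, df2, scores, contrasts):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err
        eps = _gg_epsilon(scores, contrasts)
        p_unc = float(sps.f.sf(f, df1, df2))
        p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
        effects[name] = AnovaEffect(
            name=name, F=float(f), df1=df1, df2=df2, epsilon=eps,
            df1_corr=eps * df1, df2_corr=eps * df2,
            p_uncorrected=p_unc, p_gg=p_gg,
        )

    ca = _orthonormal_contrasts(a)
    ss_a = n * b * float(np.sum((m_a - gm) ** 2))
    ss_sa = b * float(np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2))
    add_effect("A", ss_a, ss_sa, a - 1, (a - 1) * (n - 1), m_sa, ca)

    if b > 1:
        cb = _orthonormal_contrasts(b)
        ss_b = n * a * float(np.sum((m_b - gm) ** 2))
        ss_sb = a * float(np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2))
        add_effect("B", ss_b, ss_sb, b - 1, (b - 1) * (n - 1), m_sb, cb)

        ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2))
        resid = (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - gm
        )
        ss_sab = float(np.sum(resid**2))
        cab = np.kron(ca, cb)  # (a*b) x (a-1)(b-1), orthonormal
        scores_ab = y.reshape(n, a * b)
        add_effect("AxB", ss_ab, ss_sab, (a - 1) * (b - 1),
                   (a - 1) * (b - 1) * (n - 1), scores_ab, cab)

    return AnovaResult(effects=effects)


def gaussian_kde(
    values: Sequence[float],
    bandwidth: float,
    grid: Sequence[float] | None = None,
    grid_points: int = 512,
) -> KDEstimate:
    """Fixed-bandwidth Gaussian kernel density estimate.

    ``density(g) = (1/n) * sum_j phi((g - x_j) / bw) / bw`` with the standard
    normal density phi.  When ``grid`` is omitted, a uniform grid extending
    8 bandwidths beyond the data range is used (its trapezoidal integral is
    1 to within 1e-3).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    if not (np.isfinite(bandwidth) and bandwidth > 0):
        raise ValueError(f"bandwidth must be finite and > 0, got {bandwidth}")
    if grid is None:
        lo = x.min() - 8.0 * bandwidth
        hi = x.max() + 8.0 * bandwidth
        grid = np.linspace(lo, hi, grid_points)
    g = np.asarray(grid, dtype=float)
    z = (g[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bandwidth * math.sqrt(2.0 * math.pi))
    return KDEstimate(grid=g, density=density, bandwidth=float(bandwidth))
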