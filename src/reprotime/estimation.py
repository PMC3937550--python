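"""Per-subject parameter estimation and subject screening.

Three-step procedure: (1) fit the leak rate ``kappa`` to all of a subject's
trials with the inflow ratio formally fixed at 1; (2) holding that ``kappa``,
fit ``eta`` separately per valence condition; (3) form the ratios
``eta_P/eta_E`` and ``eta_N/eta_E``.  Screening removes subjects whose fits
land on the ``kappa = 0`` boundary (systematic over-reproducers, which the
model cannot represent), non-responders (flat response-vs-duration slope) and
extreme ``kappa`` outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .model import krf_vec, krf_inverse_eta, ReproductionSetting

__all__ = [
    "Trial",
    "KappaFit",
    "EtaFit",
    "EtaRatios",
    "ScreeningReport",
    "KAPPA_MAX",
    "ETA_MAX",
    "fit_kappa",
    "fit_eta",
    "eta_ratios",
    "screen_subjects",
]

KAPPA_MAX = 0.5
ETA_MAX = 10.0
_GRID_POINTS = 200
_DEFAULT_W = 2.0

VALENCES = ("P", "N", "E")


@dataclass(frozen=True)
class Trial:
    """One reproduction trial."""

    s: float
    w: float
    r: float
    valence: str = "E"
    subject_id: str = ""


@dataclass(frozen=True)
class KappaFit:
    kappa_hat: float
    sse: float
    n_trials: int
    at_lower_bound: bool


@dataclass(frozen=True)
class EtaFit:
    eta_hat: Mapping[str, float]
    sse: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EtaRatios:
    eta_pe: float
    eta_ne: float


@dataclass(frozen=True)
class ScreeningReport:
    subject_id: str
    excluded: bool
    reason: str  # over_reproducer_boundary | non_responder | kappa_outlier | none


def _trial_arrays(trials: Sequence[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = np.array([t.s for t in trials], dtype=float)
    w = np.array([_DEFAULT_W if t.w is None else t.w for t in trials], dtype=float)
    r = np.array([t.r for t in trials], dtype=float)
    return s, w, r


def _minimize_1d(objective, lo: float, hi: float, n_grid: int = _GRID_POINTS,
                 vector_objective=None) -> tuple[float, float]:
    """Coarse grid scan followed by bounded local refinement.

    The grid removes any local-minimum risk at this smoothness; the bounded
    scalar minimizer then refines within the bracketing grid cell pair.
    """
    grid = np.linspace(lo, hi, n_grid)
    if vector_objective is not None:
        values = np.asarray(vector_objective(grid))
    else:
        values = np.array([objective(g) for g in grid])
    i = int(np.argmin(values))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(objective, bounds=(b_lo, b_hi), method="bounded",
                          options={"xatol": 1e-9})
    # never return something worse than the best grid point
    if res.fun <= values[i]:
        return float(res.x), float(res.fun)
    return float(grid[i]), float(values[i])


def fit_kappa(trials: Sequence[Trial], kappa_max: float = KAPPA_MAX) -> KappaFit:
    """Least-squares fit of the leak rate with eta fixed at 1.

    Requires at least 3 trials spanning at least 2 distinct encoded
    durations; otherwise the leak rate is not identifiable.
    """
    trials = list(trials)
    if len(trials) < 3:
        raise ValueError(f"need >= 3 trials to fit kappa, got {len(trials)}")
    s, w, r = _trial_arrays(trials)
    if np.unique(s).size < 2:
        raise ValueError("need >= 2 distinct encoded durations to fit kappa")
    if np.any(r <= 0):
        raise ValueError("all responses must be > 0")

    def sse(kappa: float) -> float:
        return float(np.sum((r - krf_vec(s, w, kappa, 1.0)) ** 2))

    def sse_grid(kappas: np.ndarray) -> np.ndarray:
        pred = krf_vec(s[None, :], w[None, :], kappas[:, None], 1.0)
        return np.sum((r[None, :] - pred) ** 2, axis=1)

    kappa_hat, best = _minimize_1d(sse, 0.0, kappa_max, vector_objective=sse_grid)
    # the boundary is a genuine candidate: accept it when no interior point beats it
    sse0 = sse(0.0)
    if sse0 <= best + 1e-12 * max(best, 1.0):
        kappa_hat, best = 0.0, sse0
    return KappaFit(
        kappa_hat=kappa_hat,
        sse=best,
        n_trials=len(trials),
        at_lower_bound=(kappa_hat == 0.0),
    )


def fit_eta(
    trials_of_condition: Sequence[Trial],
    kappa: float,
    method: str = "lsq",
    eta_max: float = ETA_MAX,
) -> float:
    """Estimate the inflow ratio for one condition at a fixed leak rate.

    ``method="lsq"`` minimises the sum of squared response errors;
    ``method="invert-mean"`` averages the exact per-trial inversions
    (closed form, useful for diagnostics; differs from lsq under noise).
    """
    trials = list(trials_of_condition)
    if not trials:
        raise ValueError("cannot fit eta on an empty trial list")
    if not (np.isfinite(kappa) and kappa >= 0):
        raise ValueError(f"kappa must be finite and >= 0, got {kappa}")
    s, w, r = _trial_arrays(trials)

    if method == "invert-mean":
        etas = [
            krf_inverse_eta(ri, ReproductionSetting(si, wi), kappa)
            for si, wi, ri in zip(s, w, r)
        ]
        return float(np.mean(etas))
    if method != "lsq":
        raise ValueError(f"unknown eta estimation method: {method!r}")

    def sse(eta: float) -> float:
        return float(np.sum((r - krf_vec(s, w, kappa, eta)) ** 2))

    def sse_grid(etas: np.ndarray) -> np.ndarray:
        pred = krf_vec(s[None, :], w[None, :], kappa, etas[:, None])
        return np.sum((r[None, :] - pred) ** 2, axis=1)

    eta_hat, _ = _minimize_1d(sse, 1e-6, eta_max, vector_objective=sse_grid)
    return eta_hat


def fit_eta_by_condition(
    trials: Sequence[Trial],
    kappa: float,
    method: str = "lsq",
) -> EtaFit:
    """Step-2 fits for all three valence conditions of one subject."""
    eta_hat: dict[str, float] = {}
    sse: dict[str, float] = {}
    for v in VALENCES:
        cond = [t for t in trials if t.valence == v]
        eta_hat[v] = fit_eta(cond, kappa, method=method)
        s, w, r = _trial_arrays(cond)
        sse[v] = float(np.sum((r - krf_vec(s, w, kappa, eta_hat[v])) ** 2))
    return EtaFit(eta_hat=eta_hat, sse=sse)


def eta_ratios(eta_fit: EtaFit) -> EtaRatios:
    """Net inflow ratios of the emotional conditions relative to neutral."""
    eta = eta_fit.eta_hat
    missing = [v for v in VALENCES if v not in eta]
    if missing:
        raise ValueError(f"missing condition estimates: {missing}")
    return EtaRatios(eta_pe=eta["P"] / eta["E"], eta_ne=eta["N"] / eta["E"])


def _response_slope(trials: Sequence[Trial]) -> float:
    s, _, r = _trial_arrays(trials)
    if np.unique(s).size < 2:
        return 0.0
    return float(np.polyfit(s, r, 1)[0])


def screen_subjects(
    fits: Mapping[str, KappaFit],
    trials_by_subject: Mapping[str, Sequence[Trial]],
    slope_min: float = 0.15,
    k_mad: float = 5.0,
) -> list[ScreeningReport]:
    """Flag subjects the model cannot describe.

    Rules, in order of precedence: fit stopped at the ``kappa = 0`` boundary
    (over-reproduction); response-vs-duration regression slope below
    ``slope_min`` (non-responder); ``kappa`` further than ``k_mad``
    median-absolute-deviations from the cohort median (outlier).  The
    median/MAD reference is computed over subjects passing the first two
    rules, so injected anomalies cannot distort it.
    """
    first_pass: dict[str, str] = {}
    for sid, fit in fits.items():
        if fit.at_lower_bound:
            first_pass[sid] = "over_reproducer_boundary"
        elif _response_slope(trials_by_subject[sid]) < slope_min:
            first_pass[sid] = "non_responder"
        else:
            first_pass[sid] = "none"

    kappas = np.array([fits[sid].kappa_hat for sid, reason in first_pass.items()
                       if reason == "none"])
    median = float(np.median(kappas)) if kappas.size else 0.0
    # normal-consistent scaled MAD (x1.4826), the usual robust SD estimate
    mad = 1.4826 * float(np.median(np.abs(kappas - median))) if kappas.size else 0.0

    reports: list[ScreeningReport] = []
    for sid, fit in fits.items():
        reason = first_pass[sid]
        if reason == "none" and mad > 0 and abs(fit.kappa_hat - median) > k_mad * mad:
            reason = "kappa_outlier"
        reports.append(ScreeningReport(subject_id=sid, excluded=reason != "none",
                                       reason=reason))
    return reports
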