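"""Seeded generators for synthetic duration-reproduction cohorts.

The default design is the canonical factorial session: 3 valences (P, N, E) x 3
encoded durations (2, 4, 6 s) x 5 trials per cell = 45 trials per subject,
with the pause before reproduction drawn from {1.5, 2, 3} s.  Responses are
forward-simulated through the leaky-integrator reproduction function with
multiplicative lognormal noise.  Anomalous subjects (systematic
over-reproducers, flat non-responders) can be injected for screening tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import Trial
from .model import krf_vec

__all__ = [
    "DesignSpec",
    "SubjectParams",
    "CohortSpec",
    "make_design",
    "simulate_subject",
    "simulate_cohort",
]

_SUBGROUPS = ("a", "b", "c")


@dataclass(frozen=True)
class DesignSpec:
    """Factorial trial schedule of one session."""

    durations: tuple[float, ...] = (2.0, 4.0, 6.0)
    trials_per_cell: int = 5
    valences: tuple[str, ...] = ("P", "N", "E")
    pause_choices: tuple[float, ...] = (1.5, 2.0, 3.0)
    seed: int = 0


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one simulated subject."""

    kappa: float
    eta_v: Mapping[str, float] = field(
        default_factory=lambda: {"P": 1.0, "N": 1.0, "E": 1.0}
    )
    sigma_log: float = 0.10

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if any(e <= 0 for e in self.eta_v.values()):
            raise ValueError("all eta values must be > 0")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a whole cohort.

    The leak rate is drawn per subject from a lognormal parameterised by its
    median and geometric SD, clipped to ``kappa_clip``; the inflow effects
    are shared (eta_E = 1).  Anomalies replace the model response entirely:
    over-reproducers respond ``(1 + gamma) * s``, non-responders a constant.
    """

    n_subjects: int = 31
    kappa_median: float = 0.03
    kappa_gsd: float = 2.0
    kappa_clip: tuple[float, float] = (0.003, 0.096)
    eta_pe_true: float = 1.0
    eta_ne_true: float = 1.0
    sigma_log: float = 0.10
    n_over_reproducers: int = 0
    over_reproduction_gamma: float = 0.2
    n_non_responders: int = 0
    non_responder_level: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.kappa_clip
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("kappa_clip bounds must lie within [0, 0.5]")
        if self.n_over_reproducers + self.n_non_responders > self.n_subjects:
            raise ValueError("more anomalies than subjects")


def make_design(spec: DesignSpec) -> list[tuple[str, float, float, str]]:
    """Randomised trial schedule: list of (valence, s, w, stimulus_id).

    Exactly ``trials_per_cell`` trials per (valence, duration) cell; pauses
    drawn uniformly from ``pause_choices``; stimulus sub-groups (a, b, c)
    assigned to durations by a random permutation; trial order shuffled.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    schedule: list[tuple[str, float, float, str]] = []
    for v in spec.valences:
        # counterbalancing of sub-group <-> duration is unspecified upstream;
        # a seeded random permutation per valence is used
        perm = rng.permutation(len(spec.durations))
        for di, s in enumerate(spec.durations):
            sub = _SUBGROUPS[perm[di] % len(_SUBGROUPS)]
            for j in range(spec.trials_per_cell):
                w = float(rng.choice(spec.pause_choices))
                schedule.append((v, float(s), w, f"{v}{sub}{j + 1}"))
    order = rng.permutation(len(schedule))
    return [schedule[i] for i in order]


def simulate_subject(
    params: SubjectParams,
    design: Sequence[tuple[str, float, float, str]],
    seed: int,
    subject_id: str = "s01",
) -> list[Trial]:
    """Forward-simulate one subject's responses over a trial schedule.

    ``r = krf(s, w; kappa, eta_v) * exp(eps)`` with iid
    ``eps ~ Normal(0, sigma_log^2)``; responses are positive by construction.
    """
    rng = np.random.default_rng(seed)
    v = [d[0] for d in design]
    s = np.array([d[1] for d in design])
    w = np.array([d[2] for d in design])
    eta = np.array([params.eta_v[vi] for vi in v])
    r = krf_vec(s, w, params.kappa, eta)
    if params.sigma_log > 0:
        r = r * np.exp(rng.normal(0.0, params.sigma_log, size=len(design)))
    return [
        Trial(s=float(si), w=float(wi), r=float(ri), valence=vi, subject_id=subject_id)
        for si, wi, ri, vi in zip(s, w, r, v)
    ]


def _anomalous_responses(kind, spec, s, rng):
    eps = rng.normal(0.0, spec.sigma_log, size=s.size) if spec.sigma_log > 0 else 0.0
    if kind == "over_reproducer":
        return (1.0 + spec.over_reproduction_gamma) * s * np.exp(eps)
    return spec.non_responder_level * np.exp(eps)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trial table, true-parameter table).

    The trial table follows the canonical schema (subject_id, trial_index,
    valence, stimulus_id, s_sec, w_sec, r_sec).  The truth table carries each
    subject's generative parameters and anomaly label for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    mu = np.log(spec.kappa_median)
    sigma = np.log(spec.kappa_gsd)
    kappas = np.clip(rng.lognormal(mu, sigma, size=n), *spec.kappa_clip)

    kinds = (
        ["over_reproducer"] * spec.n_over_reproducers
        + ["non_responder"] * spec.n_non_responders
        + ["normal"] * (n - spec.n_over_reproducers - spec.n_non_responders)
    )
    kinds = [kinds[i] for i in rng.permutation(n)]

    trial_rows = []
    truth_rows = []
    for idx in range(n):
        sid = f"s{idx + 1:03d}"
        design = make_design(DesignSpec(seed=int(rng.integers(2**31))))
        eta_v = {"P": spec.eta_pe_true, "N": spec.eta_ne_true, "E": 1.0}
        if kinds[idx] == "normal":
            params = SubjectParams(kappa=float(kappas[idx]), eta_v=eta_v,
                                   sigma_log=spec.sigma_log)
            trials = simulate_subject(params, design, seed=int(rng.integers(2**31)),
                                      subject_id=sid)
            rs = [t.r for t in trials]
        else:
            s_arr = np.array([d[1] for d in design])
            rs = _anomalous_responses(kinds[idx], spec, s_arr,
                                      np.random.default_rng(int(rng.integers(2**31))))
            trials = [
                Trial(s=d[1], w=d[2], r=float(r), valence=d[0], subject_id=sid)
                for d, r in zip(design, rs)
            ]
        for t_i, (trial, d) in enumerate(zip(trials, design), start=1):
            trial_rows.append(
                dict(subject_id=sid, trial_index=t_i, valence=trial.valence,
                     stimulus_id=d[3], s_sec=trial.s, w_sec=trial.w, r_sec=trial.r)
            )
        truth_rows.append(
            dict(subject_id=sid, kappa_true=float(kappas[idx]),
                 eta_P=eta_v["P"], eta_N=eta_v["N"], eta_E=eta_v["E"],
                 kind=kinds[idx])
        )
    return pd.DataFrame(trial_rows), pd.DataFrame(truth_rows)
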