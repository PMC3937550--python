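"""Orchestration: trial-table I/O, the full analysis pipeline, reporting.

The pipeline runs the two parallel analysis strategies over a validated
trial table: model-free cell means and aggregate ratio indices for every
subject, and the three-step model fit (leak rate, per-condition inflow
ratios, ratios to neutral) for subjects surviving the screening rules.
Group statistics are computed on both the full and the cleaned cohort and
labelled as such, because the two strategies apply to different sets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .estimation import (
    Trial,
    fit_kappa,
    fit_eta_by_condition,
    eta_ratios,
    screen_subjects,
    KAPPA_MAX,
)
from .indices import cell_means, aggregate_ratio, DURATIONS
from .stats import one_sample_t, paired_t, pearson, rm_anova_gg, gaussian_kde

__all__ = ["AnalysisConfig", "load_trials", "trials_by_subject", "run_analysis", "write_report"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "trial_index", "valence", "stimulus_id",
                    "s_sec", "w_sec", "r_sec")
VALID_VALENCES = {"P", "N", "E"}


class TrialTableError(ValueError):
    """Raised when a trial table violates the canonical schema."""


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable defaults of the pipeline, loggable as one mapping."""

    kappa_max: float = KAPPA_MAX
    slope_min: float = 0.15
    k_mad: float = 5.0
    eta_method: str = "lsq"
    default_w: float = 2.0
    kde_bandwidth: float = 0.04
    clean: bool = True
    bonferroni: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_trials(path: str | Path) -> pd.DataFrame:
    """Load and validate a canonical trial CSV.

    Raises :class:`TrialTableError` with 1-based data-row numbers for any
    schema violation: missing columns, non-numeric or out-of-range
    durations/responses, unknown valence codes.
    """
    path = Path(path)
    if not path.exists():
        raise TrialTableError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "stimulus_id": str})
    except pd.errors.EmptyDataError:
        raise TrialTableError(f"empty input file: {path}") from None
    if df.empty:
        raise TrialTableError(f"no trial rows in: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")

    errors: list[str] = []
    for col in ("s_sec", "w_sec", "r_sec"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        for i in bad[:10]:
            errors.append(f"row {i + 1}: non-numeric {col}: {df.at[i, col]!r}")
        df[col] = vals
    if not errors:
        for i in df.index[(df["s_sec"] <= 0) | df["s_sec"].isna()][:10]:
            errors.append(f"row {i + 1}: s_sec must be > 0, got {df.at[i, 's_sec']}")
        for i in df.index[(df["w_sec"] < 0) | df["w_sec"].isna()][:10]:
            errors.append(f"row {i + 1}: w_sec must be >= 0, got {df.at[i, 'w_sec']}")
        for i in df.index[(df["r_sec"] <= 0) | df["r_sec"].isna()][:10]:
            errors.append(f"row {i + 1}: r_sec must be > 0, got {df.at[i, 'r_sec']}")
    for i in df.index[~df["valence"].isin(VALID_VALENCES)][:10]:
        errors.append(f"row {i + 1}: unknown valence code {df.at[i, 'valence']!r}")
    if errors:
        raise TrialTableError("; ".join(errors))

    df["trial_index"] = df["trial_index"].astype(int)
    counts = df.groupby("subject_id").size()
    logger.info("loaded %d trials from %d subjects (per-subject counts: %s)",
                len(df), counts.size, counts.to_dict())
    return df


def trials_by_subject(table: pd.DataFrame) -> dict[str, list[Trial]]:
    out: dict[str, list[Trial]] = {}
    for sid, grp in table.groupby("subject_id", sort=True):
        out[str(sid)] = [
            Trial(s=row.s_sec, w=row.w_sec, r=row.r_sec, valence=row.valence,
                  subject_id=str(sid))
            for row in grp.itertuples()
        ]
    return out


def _test_dict(res) -> dict[str, float | str]:
    return {"statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            "method": res.method}


def _group_block(per_subject: pd.DataFrame, cfg: AnalysisConfig,
                 subjects: Sequence[str], label: str,
                 cm_by_subject: Mapping[str, Any]) -> dict[str, Any]:
    """Group statistics over one cohort (full or cleaned)."""
    sub = per_subject[per_subject["subject_id"].isin(subjects)]
    block: dict[str, Any] = {"label": label, "n": len(sub)}
    block["means"] = {
        k: float(sub[k].mean()) for k in ("a_N", "a_P", "eta_pe", "eta_ne")
        if sub[k].notna().any()
    }

    tests: dict[str, Any] = {}
    for k in ("a_N", "a_P", "eta_pe", "eta_ne"):
        vals = sub[k].dropna()
        if len(vals) >= 2 and vals.std() > 0:
            tests[f"{k}_vs_1"] = _test_dict(one_sample_t(vals.to_numpy(), 1.0))
    block["one_sample_t"] = tests

    # RM-ANOVA on the cell means: subjects x valence (P, N, E) x duration
    cms = [cm_by_subject[s] for s in sub["subject_id"]]
    if len(cms) >= 3:
        cube = np.array([[cm.r_bar[v] for v in ("P", "N", "E")] for cm in cms])
        res = rm_anova_gg(cube)
        block["rm_anova"] = {
            name: asdict(eff) for name, eff in
            zip(("valence", "duration", "valence_x_duration"),
                (res.effects["A"], res.effects["B"], res.effects["AxB"]))
        }
        posthoc: dict[str, Any] = {}
        n_tests = 3 * len(DURATIONS)
        for di, s in enumerate(DURATIONS):
            for v1, v2 in (("P", "E"), ("N", "E"), ("P", "N")):
                x = np.array([cm.r_bar[v1][di] for cm in cms])
                y = np.array([cm.r_bar[v2][di] for cm in cms])
                if np.std(x - y) == 0:
                    continue
                res_t = _test_dict(paired_t(x, y))
                if cfg.bonferroni:
                    res_t["p_value"] = min(1.0, res_t["p_value"] * n_tests)
                posthoc[f"{v1}_vs_{v2}_at_s{s:g}"] = res_t
        block["posthoc_paired_t"] = posthoc

    corr: dict[str, Any] = {}
    pairs = [("a_N", "eta_ne"), ("a_P", "eta_pe"), ("a_N", "a_P"),
             ("eta_ne", "eta_pe")]
    for k1, k2 in pairs:
        both = sub[[k1, k2]].dropna()
        if len(both) >= 3 and both[k1].std() > 0 and both[k2].std() > 0:
            corr[f"{k1}_vs_{k2}"] = _test_dict(
                pearson(both[k1].to_numpy(), both[k2].to_numpy())
            )
    block["pearson"] = corr

    kde: dict[str, Any] = {}
    for k in ("a_N", "a_P", "eta_pe", "eta_ne"):
        vals = sub[k].dropna()
        if len(vals) >= 1:
            est = gaussian_kde(vals.to_numpy(), bandwidth=cfg.kde_bandwidth,
                               grid_points=256)
            kde[k] = {"grid": est.grid.tolist(), "density": est.density.tolist(),
                      "bandwidth": est.bandwidth}
    block["kde"] = kde
    return block


def run_analysis(table: pd.DataFrame, config: AnalysisConfig | None = None) -> dict[str, Any]:
    """Execute the full pipeline and return the report as a nested dict.

    Deterministic given (table, config).  Model-free indices are computed for
    every subject; model-based ratios only for subjects passing the
    screening (unless ``config.clean`` is off, in which case boundary
    subjects still have no meaningful ratios but are not excluded from the
    model-based cohort).
    """
    cfg = config or AnalysisConfig()
    by_subject = trials_by_subject(table)
    if len(by_subject) < 2:
        raise ValueError(f"need >= 2 subjects for group analysis, got {len(by_subject)}")

    rows = []
    cm_by_subject = {}
    kappa_fits = {}
    for sid, trials in by_subject.items():
        cm = cell_means(trials)
        cm_by_subject[sid] = cm
        fit = fit_kappa(trials, kappa_max=cfg.kappa_max)
        kappa_fits[sid] = fit
        rows.append({
            "subject_id": sid,
            "n_trials": len(trials),
            "a_N": aggregate_ratio(cm, "N"),
            "a_P": aggregate_ratio(cm, "P"),
            "kappa_hat": fit.kappa_hat,
            "kappa_sse": fit.sse,
            "at_lower_bound": fit.at_lower_bound,
        })
    per_subject = pd.DataFrame(rows)

    reports = screen_subjects(kappa_fits, by_subject,
                              slope_min=cfg.slope_min, k_mad=cfg.k_mad)
    excl = {rep.subject_id: rep for rep in reports}
    per_subject["excluded"] = [excl[s].excluded for s in per_subject["subject_id"]]
    per_subject["exclusion_reason"] = [excl[s].reason for s in per_subject["subject_id"]]

    if cfg.clean:
        model_subjects = [s for s in by_subject if not excl[s].excluded]
    else:
        model_subjects = list(by_subject)
    if not model_subjects:
        raise ValueError("all subjects excluded; no model-based cohort left")

    eta_cols = {"eta_P": [], "eta_N": [], "eta_E": [], "eta_pe": [], "eta_ne": []}
    for sid in per_subject["subject_id"]:
        if sid in model_subjects:
            efit = fit_eta_by_condition(by_subject[sid], kappa_fits[sid].kappa_hat,
                                        method=cfg.eta_method)
            ratios = eta_ratios(efit)
            eta_cols["eta_P"].append(efit.eta_hat["P"])
            eta_cols["eta_N"].append(efit.eta_hat["N"])
            eta_cols["eta_E"].append(efit.eta_hat["E"])
            eta_cols["eta_pe"].append(ratios.eta_pe)
            eta_cols["eta_ne"].append(ratios.eta_ne)
        else:
            for k in eta_cols:
                eta_cols[k].append(np.nan)
    for k, vals in eta_cols.items():
        per_subject[k] = vals

    all_subjects = list(per_subject["subject_id"])
    report = {
        "per_subject": per_subject.to_dict(orient="records"),
        "group": {
            "full": _group_block(per_subject, cfg, all_subjects, "full",
                                 cm_by_subject),
            "cleaned": _group_block(per_subject, cfg, model_subjects, "cleaned",
                                    cm_by_subject),
        },
        "screening": [asdict(rep) for rep in reports],
        "provenance": {
            "config": asdict(cfg),
            "seed": cfg.seed,
            "n_subjects_input": len(by_subject),
            "n_subjects_cleaned": len(model_subjects),
            "versions": {"reprotime": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
        },
    }
    return report


def _rounded_view(report: Mapping[str, Any]) -> dict[str, Any]:
    """Display-precision rendering: 4 decimals for means/ratios, 3 for t/F."""
    out: dict[str, Any] = {}
    for label, block in report["group"].items():
        view: dict[str, Any] = {"n": block["n"]}
        view["means"] = {k: round(v, 4) for k, v in block["means"].items()}
        view["one_sample_t"] = {
            k: {"t": round(d["statistic"], 3), "df": d["df"],
                "p": round(d["p_value"], 4)}
            for k, d in block["one_sample_t"].items()
        }
        if "rm_anova" in block:
            view["rm_anova"] = {
                k: {"F": round(d["F"], 3), "epsilon": round(d["epsilon"], 3),
                    "p_gg": round(d["p_gg"], 4)}
                for k, d in block["rm_anova"].items()
            }
        view["pearson"] = {
            k: {"r": round(d["statistic"], 3), "p": round(d["p_value"], 4)}
            for k, d in block["pearson"].items()
        }
        out[label] = view
    return out


def write_report(report: Mapping[str, Any], out_dir: str | Path) -> list[Path]:
    """Write the report bundle; returns the paths written.

    Files: ``report.json`` (machine-readable, full precision),
    ``per_subject.csv``, ``kde_curves.csv`` (plot data),
    ``summary.json`` (numbers at display precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "report.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    written.append(p)

    p = out_dir / "per_subject.csv"
    pd.DataFrame(report["per_subject"]).to_csv(p, index=False)
    written.append(p)

    kde_rows = []
    for label, block in report["group"].items():
        for measure, est in block.get("kde", {}).items():
            for g, d in zip(est["grid"], est["density"]):
                kde_rows.append({"cohort": label, "measure": measure,
                                 "grid": g, "density": d})
    p = out_dir / "kde_curves.csv"
    pd.DataFrame(kde_rows).to_csv(p, index=False)
    written.append(p)

    p = out_dir / "summary.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(_rounded_view(report), fh, indent=1, sort_keys=True)
    written.append(p)
    return written
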