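"""Trial-log I/O, pipeline configuration, and the end-to-end runner.

Trial logs are plain CSV with one row per answered ITC trial and the
fixed column order::

    participant_id, phase, block, trial_index, delay_days,
    immediate_krw, delayed_krw, arm_delay, arm_initial, step, choice

Every stochastic stage of the pipeline derives its own child seed from
the global seed through a stable hash of (seed, stage name, participant
id), so any single participant can be replayed without rerunning the
whole cohort.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from itclab import analysis as an
from itclab.cohort import Cohort, CohortDesign, GroupSpec, WMLearning, simulate_cohort
from itclab.model import FitResult, fit_mle
from itclab.staircase import StaircaseConfig, TrialRecord, TRIALS_PER_SESSION

TRIAL_COLUMNS = [
    "participant_id", "phase", "block", "trial_index", "delay_days",
    "immediate_krw", "delayed_krw", "arm_delay", "arm_initial", "step",
    "choice",
]


def derive_seed(global_seed: int, stage: str, participant_id: str | None = None) -> int:
    """Stable child seed (< 2^31) for a pipeline stage / participant."""
    key = f"{global_seed}:{stage}:{participant_id or ''}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write trial records as the documented CSV (UTF-8, fixed columns)."""
    rows = [{
        "participant_id": t.participant_id,
        "phase": t.phase,
        "block": t.block,
        "trial_index": t.trial_index,
        "delay_days": t.delay_days,
        "immediate_krw": t.immediate_reward,
        "delayed_krw": t.delayed_reward,
        "arm_delay": t.arm_id[0],
        "arm_initial": t.arm_id[1],
        "step": t.step,
        "choice": t.choice,
    } for t in trials]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False,
                                                     encoding="utf-8")


def read_trials(path: str | Path, require_full_sessions: bool = True) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Checks the header, the choice labels, duplicate (participant, phase,
    trial_index) rows, and — unless ``require_full_sessions=False`` —
    that every session has exactly 180 trials.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing columns: {missing}")
    bad = df.loc[~df["choice"].isin(["immediate", "delayed"])]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(f"unknown choice label {bad['choice'].iloc[0]!r} "
                         f"at row {row} of {path}")
    dup = df.duplicated(subset=["participant_id", "phase", "trial_index"])
    if dup.any():
        raise ValueError(f"duplicate (participant, phase, trial_index) rows "
                         f"in {path}: {df.loc[dup].iloc[0].to_dict()}")
    if require_full_sessions:
        counts = df.groupby(["participant_id", "phase"]).size()
        short = counts[counts != TRIALS_PER_SESSION]
        if not short.empty:
            (pid, phase), n = short.index[0], short.iloc[0]
            raise ValueError(
                f"participant {pid!r} phase {phase!r} has {n} trials, "
                f"expected {TRIALS_PER_SESSION}")
    return df


def trials_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], list[TrialRecord]]:
    """Group a validated trial table into per-(participant, phase) records."""
    out: dict[tuple[str, str], list[TrialRecord]] = {}
    for row in df.itertuples(index=False):
        rec = TrialRecord(
            participant_id=str(row.participant_id),
            phase=row.phase,
            block=int(row.block),
            trial_index=int(row.trial_index),
            delay_days=int(row.delay_days),
            immediate_reward=float(row.immediate_krw),
            delayed_reward=float(row.delayed_krw),
            arm_id=(int(row.arm_delay), int(row.arm_initial)),
            step=int(row.step),
            choice=row.choice,
        )
        out.setdefault((rec.participant_id, rec.phase), []).append(rec)
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, with provenance-friendly defaults."""

    design: CohortDesign = field(default_factory=CohortDesign)
    n_starts: int = 10
    nll_tol: float = 0.01
    param_tol: float = 0.1
    mad_threshold: float = 3.0
    bootstrap_B: int = 10_000
    alpha: float = 0.05
    window: int = 10
    window_step: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design_raw = raw.pop("design", {})
        staircase_raw = raw.pop("staircase", design_raw.pop("staircase", {}))
        groups = tuple(GroupSpec(**g) for g in design_raw.pop("groups", [])) or None
        wm = design_raw.pop("wm_learning", None)
        kwargs: dict[str, Any] = {}
        if groups:
            kwargs["groups"] = groups
        if wm is not None:
            kwargs["wm_learning"] = WMLearning(**wm)
        if staircase_raw:
            kwargs["staircase"] = StaircaseConfig(**staircase_raw)
        design = CohortDesign(**design_raw, **kwargs)
        return cls(design=design, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d


def fit_cohort(cohort: Cohort, config: PipelineConfig) -> pd.DataFrame:
    """Fit (k, mu) for every participant-session; one row per session."""
    rows = []
    sessions: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in cohort.trials:
        sessions.setdefault((t.participant_id, t.phase), []).append(t)
    for (pid, phase), trials in sessions.items():
        fit = fit_mle(trials, n_starts=config.n_starts,
                      seed=derive_seed(config.seed, f"fit-{phase}", pid))
        rows.append({
            "participant_id": pid, "phase": phase,
            "k": fit.params.k, "mu": fit.params.mu,
            "log10_k": fit.log10_k, "nll": fit.nll,
            "n_starts": fit.n_starts, "unique": fit.unique,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def _group_of(cohort: Cohort) -> dict[str, str]:
    return dict(zip(cohort.truth["participant_id"], cohort.truth["group"]))


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """simulate (or accept) -> fit -> exclude -> analyze -> report.

    Returns a JSON-serialisable report: per-group effect means, bootstrap
    tests (with their seeds), the mixed ANOVA table, performance
    correlations, and a full exclusion log.
    """
    if cohort is None:
        design = config.design
        if design.seed != config.seed:
            design = CohortDesign(**{**asdict(design),
                                     "groups": design.groups,
                                     "wm_learning": design.wm_learning,
                                     "staircase": design.staircase,
                                     "seed": derive_seed(config.seed, "simulate")})
        cohort = simulate_cohort(design)
    fits = fit_cohort(cohort, config)

    wide = fits.pivot(index="participant_id", columns="phase",
                      values=["log10_k", "unique"])
    n_input = wide.shape[0]
    unique_mask = (wide["unique"]["pre"].astype(bool)
                   & wide["unique"]["post"].astype(bool))
    excluded_nonunique = sorted(wide.index[~unique_mask])
    wide = wide[unique_mask]

    mad_ok_pre = an.mad_filter(wide["log10_k"]["pre"], config.mad_threshold)
    mad_ok_post = an.mad_filter(wide["log10_k"]["post"], config.mad_threshold)
    mad_mask = mad_ok_pre & mad_ok_post
    excluded_mad = sorted(wide.index[~mad_mask])
    included = wide[mad_mask]

    groups = _group_of(cohort)
    sessions: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in cohort.trials:
        sessions.setdefault((t.participant_id, t.phase), []).append(t)

    effects = pd.DataFrame({
        "participant_id": included.index,
        "group": [groups[p] for p in included.index],
        "delta_log_k": (included["log10_k"]["pre"]
                        - included["log10_k"]["post"]).to_numpy(),
        "delta_p_immediate": [
            an.p_immediate_ratio(sessions[(p, "pre")])
            - an.p_immediate_ratio(sessions[(p, "post")])
            for p in included.index
        ],
    })

    report: dict[str, Any] = {
        "config": config.to_dict(),
        "n_input": int(n_input),
        "n_included": int(len(included)),
        "exclusions": {
            "nonunique_mle": excluded_nonunique,
            "mad_outlier": excluded_mad,
        },
        "groups": {},
    }
    B = config.bootstrap_B
    for label, sub in effects.groupby("group"):
        seed = derive_seed(config.seed, f"bootstrap-{label}")
        test = an.bootstrap_mean_test(sub["delta_log_k"].to_numpy(),
                                      B=B, seed=seed)
        report["groups"][label] = {
            "n": int(len(sub)),
            "mean_delta_log_k": float(sub["delta_log_k"].mean()),
            "mean_delta_p_immediate": float(sub["delta_p_immediate"].mean()),
            "t": test.statistic_observed,
            "bootstrap_p": test.p_value,
            "cohens_d": test.cohens_d,
            "seed": seed,
        }

    labels = sorted(effects["group"].unique())
    report["pairwise"] = {}
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            seed = derive_seed(config.seed, f"bootstrap-{g1}-vs-{g2}")
            test = an.bootstrap_mean_test(
                effects.loc[effects["group"] == g1, "delta_log_k"].to_numpy(),
                effects.loc[effects["group"] == g2, "delta_log_k"].to_numpy(),
                paired=False, B=B, seed=seed)
            report["pairwise"][f"{g1} vs {g2}"] = {
                "t": test.statistic_observed, "bootstrap_p": test.p_value,
                "cohens_d": test.cohens_d, "seed": seed,
            }

    long = pd.concat([
        pd.DataFrame({"participant_id": included.index,
                      "group": [groups[p] for p in included.index],
                      "phase": phase,
                      "log10_k": included["log10_k"][phase].to_numpy()})
        for phase in ("pre", "post")
    ])
    if len(labels) >= 2 and all(
            (effects["group"] == g).sum() >= 2 for g in labels):
        table = an.mixed_anova(long)
        report["anova"] = table.to_dict(orient="records")

    # working-memory performance vs impulsivity change (needs >= 4 included)
    if len(effects) < 4:
        report["effects"] = effects.to_dict(orient="records")
        return report
    traces = np.array([cohort.traces[p] for p in effects["participant_id"]])
    slopes = np.array([
        an.windowed_accuracy(tr, config.window, config.window_step).slope
        for tr in traces
    ])
    mean_acc = traces.mean(axis=1)
    eff = effects["delta_log_k"].to_numpy()
    seed_s = derive_seed(config.seed, "corr-slope")
    seed_a = derive_seed(config.seed, "corr-accuracy")
    corr_slope = an.bootstrap_correlation_test(slopes, eff, B=B, seed=seed_s)
    corr_acc = an.bootstrap_correlation_test(mean_acc, eff, B=B, seed=seed_a)
    report["performance"] = {
        "slope_vs_delta_log_k": {"r": corr_slope.statistic_observed,
                                 "bootstrap_p": corr_slope.p_value,
                                 "seed": seed_s},
        "accuracy_vs_delta_log_k": {"r": corr_acc.statistic_observed,
                                    "bootstrap_p": corr_acc.p_value,
                                    "seed": seed_a},
        "quintile_association": an.quintile_bin_association(
            traces, eff).to_dict(orient="records"),
    }
    report["effects"] = effects.to_dict(orient="records")
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
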