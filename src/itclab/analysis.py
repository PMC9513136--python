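"""Group-level statistics for intervention effects on delay discounting.

Effect measures
    ``delta_log_k = log10(k_pre) - log10(k_post)`` (positive = impulsivity
    reduced) and the model-agnostic ``delta_p_immediate``, the drop in the
    fraction of immediate choices.

Inference
    Bootstrap t-tests (10,000 resamples by default): samples are shifted
    to the null (mean-centred), resampled with replacement, and the
    two-sided p-value is the corrected proportion of resampled |t*| at or
    beyond the observed |t|. Correlation tests break the pairing under
    the null by resampling each vector independently. A two-way
    mixed-design ANOVA (within factor: session/time; between factor:
    intervention type) uses the standard split-plot sums-of-squares
    decomposition.

Screening
    Participants whose fits are non-unique are excluded upstream; a
    3-MAD rule on log10 k screens outlying discount-rate estimates.

Task-performance measures
    Sliding-window accuracy (10-trial windows, 5-trial step), its OLS
    slope, and the five coarse bins (width L/3, step L/6) used to relate
    within-task performance to the impulsivity change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from itclab.model import FitResult
from itclab.staircase import TrialRecord

DEFAULT_B = 10_000


@dataclass(frozen=True)
class EffectMeasure:
    participant_id: str
    delta_log_k: float
    delta_p_immediate: float


@dataclass(frozen=True)
class BootstrapResult:
    statistic_observed: float
    n_iterations: int
    p_value: float
    seed: int | None
    cohens_d: float | None = None


@dataclass(frozen=True)
class AccuracyWindowSeries:
    values: np.ndarray
    window_size: int = 10
    step: int = 5

    @property
    def n_windows(self) -> int:
        return len(self.values)

    @property
    def slope(self) -> float:
        return performance_slope(self)


def p_immediate_ratio(trials: Sequence[TrialRecord]) -> float:
    """Fraction of trials on which the immediate option was chosen."""
    if len(trials) == 0:
        raise ValueError("empty session")
    return sum(t.choice == "immediate" for t in trials) / len(trials)


def effect_measures(pre_fit: FitResult, post_fit: FitResult,
                    pre_trials: Sequence[TrialRecord],
                    post_trials: Sequence[TrialRecord]) -> EffectMeasure:
    """Per-participant intervention effect (log10 convention).

    Both fits must have passed the uniqueness screen; a positive
    ``delta_log_k`` means the post-session discount rate is smaller.
    """
    if not pre_fit.unique or not post_fit.unique:
        raise ValueError("effect measures require unique MLE fits in both sessions")
    pid = pre_trials[0].participant_id if pre_trials else "unknown"
    return EffectMeasure(
        participant_id=pid,
        delta_log_k=pre_fit.log10_k - post_fit.log10_k,
        delta_p_immediate=p_immediate_ratio(pre_trials) - p_immediate_ratio(post_trials),
    )


def mad_filter(values: Sequence[float], threshold: float = 3.0) -> np.ndarray:
    """Inclusion mask: keep values within ``threshold`` MADs of the median.

    MAD is the raw median absolute deviation (no consistency constant),
    applied on the scale of the input — log10 k throughout this package.
    If the MAD is zero (all values equal up to the median) nothing is
    excluded.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for MAD screening")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return np.ones_like(x, dtype=bool)
    return np.abs(x - med) <= threshold * mad


# ---------------------------------------------------------------------------
# Bootstrap tests


def _t_one_sample(d: np.ndarray) -> float:
    n = d.shape[-1]
    m, sd = np.mean(d), np.std(d, ddof=1)
    if sd == 0.0:
        return 0.0 if m == 0.0 else math.copysign(math.inf, m)
    return float(m / (sd / np.sqrt(n)))


def _t_rows(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[1]
    sd = np.std(mat, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.mean(mat, axis=1) / (sd / np.sqrt(n))


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
           / (nx + ny - 2))
    return float((np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def _pooled_t_rows(xmat: np.ndarray, ymat: np.ndarray) -> np.ndarray:
    nx, ny = xmat.shape[1], ymat.shape[1]
    sp2 = (((nx - 1) * np.var(xmat, axis=1, ddof=1)
            + (ny - 1) * np.var(ymat, axis=1, ddof=1)) / (nx + ny - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return ((np.mean(xmat, axis=1) - np.mean(ymat, axis=1))
                / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def bootstrap_mean_test(x: Sequence[float], y: Sequence[float] | None = None,
                        paired: bool = False, B: int = DEFAULT_B,
                        seed: int | None = 0) -> BootstrapResult:
    """Bootstrap t-test of a mean (one-sample/paired) or mean difference.

    The null distribution is built by shifting each sample to mean zero
    (difference scores for paired data), resampling with replacement B
    times, and recomputing the t statistic; the two-sided p-value is
    ``(#{|t*| >= |t_obs|} + 1) / (B + 1)``. Cohen's d is the mean over
    the difference-score SD (one-sample/paired) or over the pooled SD
    (two-sample).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("x is empty")
    if paired or y is None:
        if y is not None:
            y = np.asarray(y, dtype=float)
            if y.shape != x.shape:
                raise ValueError("paired test requires equal-length samples")
            d = x - y
        else:
            d = x
        if d.size < 2:
            raise ValueError("need at least 2 observations")
        t_obs = _t_one_sample(d)
        d0 = d - np.mean(d)
        idx = rng.integers(0, d.size, size=(B, d.size))
        t_star = _t_rows(d0[idx])
        sd = np.std(d, ddof=1)
        cohens_d = float(np.mean(d) / sd) if sd > 0 else 0.0
    else:
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("y is empty")
        t_obs = _pooled_t(x, y)
        x0, y0 = x - np.mean(x), y - np.mean(y)
        xs = x0[rng.integers(0, x.size, size=(B, x.size))]
        ys = y0[rng.integers(0, y.size, size=(B, y.size))]
        t_star = _pooled_t_rows(xs, ys)
        sp2 = (((x.size - 1) * np.var(x, ddof=1) + (y.size - 1) * np.var(y, ddof=1))
               / (x.size + y.size - 2))
        cohens_d = float((np.mean(x) - np.mean(y)) / np.sqrt(sp2))
    t_star = t_star[np.isfinite(t_star)]
    p = (np.sum(np.abs(t_star) >= abs(t_obs)) + 1) / (len(t_star) + 1)
    return BootstrapResult(statistic_observed=t_obs, n_iterations=B,
                           p_value=float(p), seed=seed, cohens_d=cohens_d)


def bootstrap_correlation_test(a: Sequence[float], b: Sequence[float],
                               B: int = DEFAULT_B,
                               seed: int | None = 0) -> BootstrapResult:
    """Bootstrap test of a Pearson correlation against independence.

    The null resamples each vector independently with replacement
    (breaking the pairing); the two-sided p-value uses the same corrected
    proportion as :func:`bootstrap_mean_test`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rng = np.random.default_rng(seed)
    r_obs = float(stats.pearsonr(a, b).statistic)
    amat = a[rng.integers(0, n, size=(B, n))]
    bmat = b[rng.integers(0, n, size=(B, n))]
    az = amat - amat.mean(axis=1, keepdims=True)
    bz = bmat - bmat.mean(axis=1, keepdims=True)
    denom = np.sqrt((az ** 2).sum(axis=1) * (bz ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_star = (az * bz).sum(axis=1) / denom
    r_star = r_star[np.isfinite(r_star)]
    p = (np.sum(np.abs(r_star) >= abs(r_obs)) + 1) / (len(r_star) + 1)
    return BootstrapResult(statistic_observed=r_obs, n_iterations=B,
                           p_value=float(p), seed=seed)


# ---------------------------------------------------------------------------
# Mixed-design ANOVA


def mixed_anova(data: pd.DataFrame, dv: str = "log10_k",
                within: str = "phase", between: str = "group",
                subject: str = "participant_id") -> pd.DataFrame:
    """Two-way mixed-design (split-plot) ANOVA.

    ``within`` is the repeated factor (every subject observed at every
    level, e.g. pre/post session), ``between`` the grouping factor. Group
    sizes may differ; the decomposition uses observation-weighted means.
    Returns a table with rows for the between factor, the within factor,
    and their interaction (SS, df, MS, F, p), plus the two error strata.
    """
    df = data[[subject, between, within, dv]].dropna()
    counts = df.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("each subject needs exactly one observation per "
                         f"level of {within!r}")
    levels_w = df[within].unique()
    p = len(levels_w)
    per_subj = df.groupby(subject)[within].nunique()
    if (per_subj != p).any():
        raise ValueError(f"unbalanced within-factor data: every subject must "
                         f"appear at all {p} levels of {within!r}")

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()
    n_subj = len(subj_means)
    a = subj_group.nunique()

    ss_subjects = float(p * ((subj_means - grand) ** 2).sum())
    group_means = subj_means.groupby(subj_group).mean()
    group_n = subj_group.value_counts()
    ss_between = float(p * (group_n * (group_means - grand) ** 2).sum())
    ss_error_between = ss_subjects - ss_between

    time_means = df.groupby(within)[dv].mean()
    ss_time = float(n_subj * ((time_means - grand) ** 2).sum())

    cell = df.groupby([between, within])[dv].mean()
    ss_cells = 0.0
    for (g, w), m in cell.items():
        ss_cells += group_n[g] * (m - grand) ** 2
    ss_interaction = float(ss_cells - ss_between - ss_time)
    ss_error_within = ss_total - ss_subjects - ss_time - ss_interaction

    df_between, df_eb = a - 1, n_subj - a
    df_time = p - 1
    df_int = (a - 1) * (p - 1)
    df_ew = (n_subj - a) * (p - 1)

    ms_eb = ss_error_between / df_eb
    ms_ew = ss_error_within / df_ew
    rows = []
    for name, ss, dfn, ms_err, dfe in (
        ("type", ss_between, df_between, ms_eb, df_eb),
        ("time", ss_time, df_time, ms_ew, df_ew),
        ("time*type", ss_interaction, df_int, ms_ew, df_ew),
    ):
        ms = ss / dfn
        F = ms / ms_err if ms_err > 0 else np.inf
        rows.append({"source": name, "SS": ss, "df": dfn, "MS": ms,
                     "F": F, "p": float(stats.f.sf(F, dfn, dfe))})
    rows.append({"source": "error(between)", "SS": ss_error_between,
                 "df": df_eb, "MS": ms_eb, "F": np.nan, "p": np.nan})
    rows.append({"source": "error(within)", "SS": ss_error_within,
                 "df": df_ew, "MS": ms_ew, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Task-performance measures


def windowed_accuracy(trace: Sequence[float], window: int = 10,
                      step: int = 5) -> AccuracyWindowSeries:
    """Sliding-window mean accuracy (default 10-trial window, 5-trial step)."""
    x = np.asarray(trace, dtype=float)
    if x.size < window:
        raise ValueError(f"trace length {x.size} is shorter than one "
                         f"window ({window})")
    n_windows = (x.size - window) // step + 1
    values = np.array([x[i * step: i * step + window].mean()
                       for i in range(n_windows)])
    return AccuracyWindowSeries(values=values, window_size=window, step=step)


def performance_slope(series: AccuracyWindowSeries) -> float:
    """OLS slope of window accuracy on 0-based window index."""
    v = np.asarray(series.values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 windows for a slope")
    idx = np.arange(v.size, dtype=float)
    return float(np.polyfit(idx, v, 1)[0])


def quintile_bins(L: int) -> list[tuple[int, int]]:
    """Five coarse bins over a length-L task: width L//3, step L//6.

    The final bin is right-anchored at the trace end, so the five bins
    always cover the whole task even when L is not divisible by 6.
    """
    size, step = L // 3, L // 6
    if size < 1 or step < 1:
        raise ValueError(f"task length {L} too short for L/3 bins")
    starts = [0, step, 2 * step, 3 * step, L - size]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError(f"task length {L} does not admit 5 ascending bins")
    return [(s, s + size) for s in starts]


def quintile_bin_association(traces: Sequence[Sequence[float]],
                             effects: Sequence[float]) -> pd.DataFrame:
    """Per-bin Pearson correlation of bin accuracy with delta log k.

    For each of the five coarse bins, each participant's mean accuracy in
    the bin is correlated (across participants) with their impulsivity
    change. Returns a table with r and the parametric two-sided p per bin.
    """
    mat = np.asarray(traces, dtype=float)
    eff = np.asarray(effects, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != eff.size:
        raise ValueError("traces must be (n_participants, L) matching effects")
    bins = quintile_bins(mat.shape[1])
    rows = []
    for i, (lo, hi) in enumerate(bins, start=1):
        acc = mat[:, lo:hi].mean(axis=1)
        res = stats.pearsonr(acc, eff)
        rows.append({"bin": i, "start": lo, "stop": hi,
                     "r": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
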