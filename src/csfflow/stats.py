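"""Group aggregation and comparative statistics for synchronized waveforms.

Provides per-bin group-mean waveforms with pointwise 95% confidence bands,
per-session peak caudal/rostral velocities, the study's comparison tests
(pooled-variance unpaired t, paired t, one-way ANOVA with Tukey HSD), and a
per-ROI summary table of the three groups: for each ROI, control mean (SD),
control-vs-preop p, preop mean (SD), preop-vs-postop p, postop mean (SD).
The cervical cord contributes two rows — its caudal peak and its
paradoxical rostral peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .waveform import (
    GROUP_LABELS,
    ROI_LABELS,
    SYNC_BINS,
    InvalidParameterError,
    MRISession,
    VelocityWaveform,
)

DEFAULT_ALPHA = 0.05

#: Rows of the summary table: (row name, ROI, which peak).
TABLE_ROWS = (
    ("tonsil", "tonsil", "caudal"),
    ("ventral_sa", "ventral_sa", "caudal"),
    ("dorsal_sa", "dorsal_sa", "caudal"),
    ("syrinx", "syrinx", "caudal"),
    ("cord_rostral", "cord", "rostral"),
    ("cord_caudal", "cord", "caudal"),
    ("medulla", "medulla", "caudal"),
)


class UnsynchronizedError(RuntimeError):
    """A statistic requiring synchronized sessions received a raw one."""


@dataclass(frozen=True)
class StatResult:
    """One hypothesis-test outcome."""

    test_name: str  # unpaired_t | paired_t | anova | tukey_pair
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    comparison: tuple[str, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise InvalidParameterError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class GroupMeanWaveform:
    """Per-bin mean waveform of one group with its pointwise 95% band."""

    roi_label: str
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sessions: int


@dataclass
class GroupSummary:
    """Per-group aggregate: mean waveforms, bands, and peak statistics."""

    group_label: str
    n_sessions: int
    waveforms: dict[str, GroupMeanWaveform] = field(default_factory=dict)
    peak_caudal: dict[str, tuple[float, float]] = field(default_factory=dict)  # roi -> (mean, sd)
    peak_rostral: dict[str, tuple[float, float]] = field(default_factory=dict)


def peak_velocities(wave: VelocityWaveform) -> tuple[float, float]:
    """(peak caudal, peak rostral) = (max, min) over the cycle, signed cm/s."""
    return float(np.max(wave.values)), float(np.min(wave.values))


def _require_synchronized(sessions: list[MRISession]) -> None:
    for s in sessions:
        if not s.is_synchronized:
            raise UnsynchronizedError(
                f"session {s.subject_id!r} ({s.group_label}) is not synchronized"
            )


def group_mean_waveform(
    sessions: list[MRISession], roi_label: str, confidence: float = 0.95
) -> GroupMeanWaveform:
    """Per-bin mean across sessions with a pointwise t confidence band.

    band = mean +/- t(1-(1-confidence)/2, n-1) * SD / sqrt(n), per bin.
    """
    _require_synchronized(sessions)
    n = len(sessions)
    if n < 2:
        raise InvalidParameterError("confidence band needs at least 2 sessions")
    stack = np.stack([s.waveforms[roi_label].values for s in sessions])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return GroupMeanWaveform(roi_label, mean, mean - half, mean + half, n)


def peak_samples(
    sessions: list[MRISession], roi_label: str, which: str = "caudal"
) -> np.ndarray:
    """Per-session peak velocities of one ROI: 'caudal' (max) or 'rostral' (min)."""
    idx = 0 if which == "caudal" else 1
    return np.asarray([peak_velocities(s.waveforms[roi_label])[idx] for s in sessions])


def summarize_group(sessions: list[MRISession], group_label: str) -> GroupSummary:
    """Aggregate one group's synchronized sessions."""
    members = [s for s in sessions if s.group_label == group_label]
    _require_synchronized(members)
    summary = GroupSummary(group_label=group_label, n_sessions=len(members))
    for roi in ROI_LABELS:
        if len(members) >= 2:
            summary.waveforms[roi] = group_mean_waveform(members, roi)
        for which, store in (("caudal", summary.peak_caudal), ("rostral", summary.peak_rostral)):
            peaks = peak_samples(members, roi, which)
            if peaks.size:
                sd = float(peaks.std(ddof=1)) if peaks.size > 1 else float("nan")
                store[roi] = (float(peaks.mean()), sd)
    return summary


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def unpaired_t(
    sample_a, sample_b, labels: tuple[str, str] = ("a", "b"), welch: bool = False
) -> StatResult:
    """Two-sided two-sample t test (pooled-variance Student form by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    df = float(a.size + b.size - 2)
    # zero within-sample spread defeats the t denominator; detect it by exact
    # value equality (sample std of identical values can round to ~1e-17)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return StatResult("unpaired_t", 0.0, df, 1.0, labels, degenerate=True)
        stat = np.inf if a[0] > b[0] else -np.inf
        return StatResult("unpaired_t", float(stat), df, 0.0, labels, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return StatResult("unpaired_t", float(res.statistic), df, float(res.pvalue), labels)


def paired_t(pairs, labels: tuple[str, str] = ("pre", "post")) -> StatResult:
    """Two-sided paired t test on (pre, post) differences."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidParameterError("need >= 2 complete (pre, post) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    df = float(diffs.size - 1)
    if np.ptp(diffs) == 0.0:
        if diffs[0] == 0.0:
            return StatResult("paired_t", 0.0, df, 1.0, labels, degenerate=True)
        stat = np.inf if diffs[0] > 0 else -np.inf
        return StatResult("paired_t", float(stat), df, 0.0, labels, degenerate=True)
    res = sps.ttest_rel(arr[:, 0], arr[:, 1])
    return StatResult("paired_t", float(res.statistic), df, float(res.pvalue), labels)


def anova_tukey(samples: dict[str, np.ndarray]) -> tuple[StatResult, list[StatResult]]:
    """One-way fixed-effects ANOVA plus Tukey HSD over all group pairs.

    Tukey p-values come from the studentized-range distribution with the
    pooled within-group degrees of freedom.
    """
    labels = list(samples)
    groups = [np.asarray(v, dtype=float) for v in samples.values()]
    if len(groups) < 2:
        raise InvalidParameterError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise InvalidParameterError("every group needs n >= 2")
    n_total = sum(g.size for g in groups)
    dfn, dfd = float(len(groups) - 1), float(n_total - len(groups))

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        anova = StatResult("anova", 0.0, (dfn, dfd), 1.0, tuple(labels), degenerate=True)
        pairs = [
            StatResult("tukey_pair", 0.0, dfd, 1.0, (labels[i], labels[j]), degenerate=True)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return anova, pairs

    f_res = sps.f_oneway(*groups)
    anova = StatResult(
        "anova", float(f_res.statistic), (dfn, dfd), float(f_res.pvalue), tuple(labels)
    )
    hsd = sps.tukey_hsd(*groups)
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs.append(
                StatResult(
                    "tukey_pair",
                    float(hsd.statistic[i, j]),
                    dfd,
                    float(hsd.pvalue[i, j]),
                    (labels[i], labels[j]),
                )
            )
    return anova, pairs


# ---------------------------------------------------------------------------
# Summary table (per-ROI three-group comparison)
# ---------------------------------------------------------------------------

def _paired_peaks(
    preop: list[MRISession], postop: list[MRISession], roi: str, which: str
) -> list[tuple[float, float]]:
    """Match pre/post sessions by subject id; unpaired subjects are excluded."""
    idx = 0 if which == "caudal" else 1
    pre_by_id = {s.subject_id: s for s in preop}
    post_by_id = {s.subject_id: s for s in postop}
    pairs = []
    for sid in pre_by_id:
        if sid in post_by_id:
            pairs.append(
                (
                    peak_velocities(pre_by_id[sid].waveforms[roi])[idx],
                    peak_velocities(post_by_id[sid].waveforms[roi])[idx],
                )
            )
    return pairs


def build_table1(sessions: list[MRISession], alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-ROI peak-velocity comparison of the three groups.

    One row per ROI (the cord contributes a rostral-peak and a caudal-peak
    row): control mean (SD), control-vs-preop unpaired-t p, preop mean (SD),
    preop-vs-postop paired-t p, postop mean (SD). Missing groups or
    insufficient pairs leave NaN entries.
    """
    _require_synchronized(sessions)
    by_group = {g: [s for s in sessions if s.group_label == g] for g in GROUP_LABELS}
    rows = []
    for row_name, roi, which in TABLE_ROWS:
        row: dict[str, float | str | bool] = {"row": row_name}
        peaks = {
            g: peak_samples(by_group[g], roi, which) for g in GROUP_LABELS
        }
        for g in GROUP_LABELS:
            row[f"{g}_n"] = len(peaks[g])
            row[f"{g}_mean"] = float(peaks[g].mean()) if peaks[g].size else np.nan
            row[f"{g}_sd"] = (
                float(peaks[g].std(ddof=1)) if peaks[g].size > 1 else np.nan
            )
        if peaks["control"].size >= 2 and peaks["preop"].size >= 2:
            res = unpaired_t(peaks["control"], peaks["preop"], ("control", "preop"))
            row["p_control_vs_preop"] = res.p_value
        else:
            row["p_control_vs_preop"] = np.nan
        pairs = _paired_peaks(by_group["preop"], by_group["postop"], roi, which)
        if len(pairs) >= 2:
            res = paired_t(pairs, ("preop", "postop"))
            row["p_preop_vs_postop"] = res.p_value
        else:
            row["p_preop_vs_postop"] = np.nan
        row["sig_control_vs_preop"] = bool(row["p_control_vs_preop"] < alpha)
        row["sig_preop_vs_postop"] = bool(row["p_preop_vs_postop"] < alpha)
        rows.append(row)
    cols = ["row"]
    for g in GROUP_LABELS:
        cols += [f"{g}_n", f"{g}_mean", f"{g}_sd"]
    cols += [
        "p_control_vs_preop",
        "p_preop_vs_postop",
        "sig_control_vs_preop",
        "sig_preop_vs_postop",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("row")


def format_table1(table: pd.DataFrame) -> str:
    """Human-readable rendering of the three-group summary table."""
    lines = [
        f"{'ROI':<14}{'Control':>14}{'p(c vs pre)':>12}{'Preop':>14}"
        f"{'p(pre vs post)':>15}{'Postop':>14}"
    ]
    for name, r in table.iterrows():
        def ms(g):
            if np.isnan(r[f"{g}_mean"]):
                return "n/a"
            return f"{r[f'{g}_mean']:.2f} ({r[f'{g}_sd']:.2f})"

        def pv(key):
            return "n/a" if np.isnan(r[key]) else f"{r[key]:.3f}"

        lines.append(
            f"{name:<14}{ms('control'):>14}{pv('p_control_vs_preop'):>12}"
            f"{ms('preop'):>14}{pv('p_preop_vs_postop'):>15}{ms('postop'):>14}"
        )
    return "\n".join(lines)


def csf_tonsil_anova(sessions: list[MRISession], group_label: str = "preop"):
    """ANOVA (with Tukey HSD) of tonsil vs dorsal vs ventral peak caudal velocity.

    Replicates the comparison of tonsillar velocity with the CSF velocities
    in the two subarachnoid spaces within one group; the three per-session
    samples are treated as independent groups.
    """
    members = [s for s in sessions if s.group_label == group_label]
    _require_synchronized(members)
    samples = {
        roi: peak_samples(members, roi, "caudal")
        for roi in ("tonsil", "dorsal_sa", "ventral_sa")
    }
    return anova_tukey(samples)
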