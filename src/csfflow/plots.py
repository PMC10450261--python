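"""Waveform figures: group mean velocity curves with 95% confidence bands."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import GroupSummary  # noqa: E402
from .waveform import ROI_LABELS, SYNC_BINS  # noqa: E402

_ROI_COLORS = {
    "tonsil": "tab:red",
    "ventral_sa": "tab:blue",
    "dorsal_sa": "tab:orange",
    "syrinx": "tab:green",
    "cord": "tab:purple",
    "medulla": "tab:gray",
}


def plot_group_waveforms(
    summary: GroupSummary,
    out_path,
    rois: tuple[str, ...] = ROI_LABELS,
    with_band: bool = True,
) -> Path:
    """Plot one group's mean ROI waveforms over the cardiac cycle.

    The abscissa is the cardiac cycle in percent; the trigger (steepest
    caudal rise of the ventral subarachnoid CSF) sits at the 50% mark.
    """
    fig, ax = plt.subplots(figsize=(7, 4.2))
    x = [100.0 * i / SYNC_BINS for i in range(SYNC_BINS)]
    for roi in rois:
        if roi not in summary.waveforms:
            continue
        gw = summary.waveforms[roi]
        color = _ROI_COLORS.get(roi, None)
        ax.plot(x, gw.mean, label=roi, color=color)
        if with_band:
            ax.fill_between(x, gw.lower, gw.upper, alpha=0.15, color=color, lw=0)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvline(50.0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("cardiac cycle (%)")
    ax.set_ylabel("velocity (cm/s, caudal positive)")
    ax.set_title(f"{summary.group_label} (n={summary.n_sessions})")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
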