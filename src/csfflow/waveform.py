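"""Core velocity-waveform containers and the biphasic cycle template.

A :class:`VelocityWaveform` holds one region of interest's craniocaudal
velocity over a single cardiac cycle, sampled on a uniform bin grid.
The sign convention throughout the package is caudal-positive (flow toward
the feet is positive, rostral motion negative), in cm/s.

An :class:`MRISession` bundles the six waveforms of one scan: cerebellar
tonsil, upper cervical cord, ventral and dorsal subarachnoid space, syrinx
(or cord at C3/C5 in controls) and medulla.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical region-of-interest labels, in reporting order.
ROI_LABELS = ("tonsil", "cord", "ventral_sa", "dorsal_sa", "syrinx", "medulla")

#: Canonical cohort group labels.
GROUP_LABELS = ("control", "preop", "postop")

#: Number of bins every waveform is resampled to before alignment.
SYNC_BINS = 50

#: Cycle midpoint (0-based) where the CSF trigger point is placed.
TRIGGER_INDEX = SYNC_BINS // 2

RAW_STATE = "raw"
SYNC_STATE = "synchronized"


class InvalidParameterError(ValueError):
    """A waveform or cohort parameter violates its contract."""


class DegenerateWaveformWarning(UserWarning):
    """Emitted when an operation receives a constant (featureless) waveform."""


@dataclass(frozen=True)
class VelocityWaveform:
    """One ROI's velocity time series over one cardiac cycle.

    Parameters
    ----------
    roi_label
        One of :data:`ROI_LABELS`.
    values
        Velocity in cm/s per cardiac bin, caudal-positive. Stored as a
        read-only float64 array.
    """

    roi_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidParameterError("waveform values must be a non-empty 1-D array")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def bin_count(self) -> int:
        return int(self.values.size)

    def with_values(self, values: np.ndarray) -> "VelocityWaveform":
        return VelocityWaveform(self.roi_label, np.asarray(values, dtype=float))


@dataclass(frozen=True)
class MRISession:
    """One cardiac-gated scan: six ROI waveforms on a shared bin grid."""

    subject_id: str
    group_label: str
    waveforms: dict[str, VelocityWaveform]
    sync_state: str = RAW_STATE
    trigger_index: int | None = None

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise InvalidParameterError(
                f"unknown group label {self.group_label!r}; expected one of {GROUP_LABELS}"
            )
        labels = set(self.waveforms)
        if labels != set(ROI_LABELS):
            missing = set(ROI_LABELS) - labels
            extra = labels - set(ROI_LABELS)
            raise InvalidParameterError(
                f"session {self.subject_id!r} must carry exactly the six canonical ROIs; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        counts = {w.bin_count for w in self.waveforms.values()}
        if len(counts) != 1:
            raise InvalidParameterError(
                f"session {self.subject_id!r}: all six waveforms must share one bin grid, "
                f"got bin counts {sorted(counts)}"
            )
        for label, wave in self.waveforms.items():
            if wave.roi_label != label:
                raise InvalidParameterError(
                    f"waveform labelled {wave.roi_label!r} stored under key {label!r}"
                )
        if self.sync_state not in (RAW_STATE, SYNC_STATE):
            raise InvalidParameterError(f"unknown sync state {self.sync_state!r}")
        if self.sync_state == SYNC_STATE:
            if self.bin_count != SYNC_BINS or self.trigger_index != TRIGGER_INDEX:
                raise InvalidParameterError(
                    "synchronized sessions must have "
                    f"{SYNC_BINS} bins and trigger index {TRIGGER_INDEX}"
                )

    @property
    def bin_count(self) -> int:
        return next(iter(self.waveforms.values())).bin_count

    @property
    def is_synchronized(self) -> bool:
        return self.sync_state == SYNC_STATE

    def replace(self, **kwargs) -> "MRISession":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Biphasic cycle template
# ---------------------------------------------------------------------------
#
# The template is a sum of two raised-cosine lobes with disjoint supports on
# the unit cycle: a sharp caudal (positive) lobe around mid-late systole
# followed by a broader rostral (negative) return lobe. Disjoint supports and
# a per-part rescale guarantee that the sampled waveform attains its stated
# peak amplitudes exactly, for any bin count >= 8. The waveform is zero in
# early diastole, so it starts and ends the cycle at rest.

_CAUDAL_CENTER, _CAUDAL_WIDTH = 0.575, 0.25
_ROSTRAL_CENTER, _ROSTRAL_WIDTH = 0.83, 0.26  # support ends at 0.96: rest at cycle end


def _raised_cosine(frac: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-amplitude raised-cosine bump on [center - width/2, center + width/2]."""
    x = frac - center
    out = np.zeros_like(frac)
    inside = np.abs(x) < width / 2.0
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[inside] / width))
    return out


def make_waveform_template(
    roi_label: str,
    peak_caudal: float,
    peak_rostral: float,
    n_bins: int,
    *,
    rostral_first: bool = False,
) -> VelocityWaveform:
    """Build a noise-free biphasic cycle waveform with exact peak amplitudes.

    Parameters
    ----------
    roi_label
        ROI label carried on the returned waveform.
    peak_caudal
        Maximum caudal velocity in cm/s; must be >= 0.
    peak_rostral
        Minimum (rostral) velocity in cm/s; must be <= 0.
    n_bins
        Number of cardiac bins (>= 8).
    rostral_first
        If True, the rostral lobe precedes the caudal lobe in the cycle.
        Used for the cervical cord, which in patients moves rostrally while
        CSF and tonsils move caudally.

    Returns
    -------
    VelocityWaveform
        ``max(values) == peak_caudal`` and ``min(values) == peak_rostral``
        to machine precision (each whenever the amplitude is nonzero).
    """
    if n_bins < 8:
        raise InvalidParameterError(f"n_bins must be >= 8, got {n_bins}")
    if peak_caudal < 0:
        raise InvalidParameterError(f"peak_caudal must be >= 0, got {peak_caudal}")
    if peak_rostral > 0:
        raise InvalidParameterError(f"peak_rostral must be <= 0, got {peak_rostral}")

    frac = np.arange(n_bins, dtype=float) / n_bins
    if rostral_first:
        caudal_c, caudal_w = _ROSTRAL_CENTER, _ROSTRAL_WIDTH
        rostral_c, rostral_w = _CAUDAL_CENTER, _CAUDAL_WIDTH
    else:
        caudal_c, caudal_w = _CAUDAL_CENTER, _CAUDAL_WIDTH
        rostral_c, rostral_w = _ROSTRAL_CENTER, _ROSTRAL_WIDTH

    pos = _raised_cosine(frac, caudal_c, caudal_w)
    neg = _raised_cosine(frac, rostral_c, rostral_w)

    values = np.zeros(n_bins)
    if peak_caudal > 0:
        # normalize to unit sampled max before scaling so the peak bin holds
        # exactly 1.0 * peak_caudal (no rescale rounding)
        values += (pos / pos.max()) * peak_caudal
    if peak_rostral < 0:
        # neg is a unit positive bump; scaling by the (negative) rostral peak
        # flips it and pins the sampled minimum exactly.
        values += (neg / neg.max()) * peak_rostral
    return VelocityWaveform(roi_label, values)


def circular_delay(wave: VelocityWaveform, shift_bins: int) -> VelocityWaveform:
    """Delay a periodic waveform by ``shift_bins`` whole bins (circular)."""
    return wave.with_values(np.roll(wave.values, int(shift_bins)))


def warn_degenerate(message: str) -> None:
    warnings.warn(message, DegenerateWaveformWarning, stacklevel=3)
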