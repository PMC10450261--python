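"""Cardiac-cycle waveform synchronization.

Acquisition is triggered by the ECG QRS complex, but the latency between
the QRS wave and the arrival of the CSF pulse at the craniovertebral
junction varies between subjects. To make waveforms comparable across
sessions, each session is (1) resampled to a common 50-bin cycle by
periodic linear interpolation, (2) anchored at its *CSF trigger point* —
the bin where the ventral subarachnoid velocity rises most steeply in the
caudal direction — and (3) circularly shifted as a ring buffer so that
trigger lands at the cycle midpoint (bin 25 of 50). All six ROI waveforms
of a session receive the same shift, preserving their relative timing.
"""

from __future__ import annotations

import numpy as np

from .waveform import (
    MRISession,
    RAW_STATE,
    SYNC_BINS,
    SYNC_STATE,
    TRIGGER_INDEX,
    InvalidParameterError,
    VelocityWaveform,
    warn_degenerate,
)


class SyncStateError(RuntimeError):
    """Operation applied to a session in the wrong synchronization state."""


def find_trigger(wave: VelocityWaveform) -> int:
    """Index of the CSF trigger point: steepest caudal rise, circularly.

    Returns the index ``t`` maximizing the circular forward difference
    ``values[(t+1) % N] - values[t]`` (caudal-positive convention). Ties
    resolve to the smallest index. A constant waveform has no trigger; a
    degenerate-waveform warning is emitted and index 0 returned.
    """
    if wave.bin_count < 3:
        raise InvalidParameterError("trigger detection needs at least 3 bins")
    diffs = np.roll(wave.values, -1) - wave.values
    if np.all(diffs == diffs[0]):
        warn_degenerate(
            f"waveform {wave.roi_label!r} is constant; trigger undefined, using index 0"
        )
        return 0
    return int(np.argmax(diffs))


def resample_to_50(wave: VelocityWaveform) -> VelocityWaveform:
    """Resample to 50 bins by periodic linear interpolation.

    Input sample ``j`` sits at cycle fraction ``j/N``; output bin ``k`` at
    fraction ``k/50`` is interpolated between its two bracketing input
    samples, with bin ``N`` wrapping to bin 0. Coincident grid points pass
    through exactly.
    """
    n = wave.bin_count
    if n < 2:
        raise InvalidParameterError("resampling needs at least 2 bins")
    if n == SYNC_BINS:
        return wave
    pos = np.arange(SYNC_BINS) * n / SYNC_BINS  # position on the input grid
    left = np.floor(pos).astype(int)
    frac = pos - left
    right = (left + 1) % n
    values = (1.0 - frac) * wave.values[left] + frac * wave.values[right]
    return wave.with_values(values)


def ring_shift(wave: VelocityWaveform, shift: int) -> VelocityWaveform:
    """Circularly rotate a 50-bin waveform: ``out[i] = in[(i + shift) % 50]``."""
    if wave.bin_count != SYNC_BINS:
        raise InvalidParameterError(
            f"ring_shift operates on {SYNC_BINS}-bin waveforms, got {wave.bin_count}"
        )
    return wave.with_values(np.roll(wave.values, -int(shift)))


def synchronize_session(session: MRISession) -> MRISession:
    """Resample a raw session to 50 bins and align its CSF trigger to bin 25.

    The trigger is detected on the ventral subarachnoid waveform only,
    after resampling; the resulting shift is applied to all six waveforms
    so relative timing between ROIs is untouched.
    """
    if session.sync_state != RAW_STATE:
        raise SyncStateError(
            f"session {session.subject_id!r} is already {session.sync_state}"
        )
    if "ventral_sa" not in session.waveforms:
        raise InvalidParameterError(
            f"session {session.subject_id!r} lacks the ventral_sa waveform "
            "needed for trigger detection"
        )
    resampled = {label: resample_to_50(w) for label, w in session.waveforms.items()}
    trigger = find_trigger(resampled["ventral_sa"])
    shift = trigger - TRIGGER_INDEX
    shifted = {label: ring_shift(w, shift) for label, w in resampled.items()}
    return MRISession(
        subject_id=session.subject_id,
        group_label=session.group_label,
        waveforms=shifted,
        sync_state=SYNC_STATE,
        trigger_index=TRIGGER_INDEX,
    )


def synchronize_cohort(sessions: list[MRISession]) -> list[MRISession]:
    """Synchronize every session, reporting the offender on failure."""
    out = []
    for session in sessions:
        try:
            out.append(synchronize_session(session))
        except Exception as exc:
            raise SyncStateError(
                f"synchronization failed for session {session.subject_id!r} "
                f"({session.group_label}): {exc}"
            ) from exc
    return out
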