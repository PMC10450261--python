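"""Synthetic cohort generator for cardiac-gated CSF velocity waveforms.

Emulates the statistical structure of a three-group phase-contrast MRI
study of Chiari-I malformation with syringomyelia: preoperative patients,
postoperative patients (same subjects after foramen magnum decompression)
and healthy controls. Each synthetic session carries six ROI waveforms on a
shared raw bin grid of 25 or 35 cardiac bins, a subject-specific latency
between the ECG trigger and the CSF pulse, group- and ROI-specific peak
amplitudes, and additive measurement noise.

Ground truth (drawn latencies and amplitudes) is returned alongside the
sessions so downstream synchronization and statistics can be tested as
recovery problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .waveform import (
    GROUP_LABELS,
    ROI_LABELS,
    InvalidParameterError,
    MRISession,
    VelocityWaveform,
    circular_delay,
    make_waveform_template,
)

# Per-group, per-ROI peak caudal velocity (mean, SD) in cm/s. The cord entry
# is the caudal peak; its paradoxical rostral peak has its own table below.
DEFAULT_PEAK_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("control", "tonsil"): (0.31, 0.14),
    ("control", "ventral_sa"): (2.5, 0.77),
    ("control", "dorsal_sa"): (1.3, 0.61),
    ("control", "syrinx"): (0.34, 0.19),
    ("control", "cord"): (0.34, 0.13),
    ("control", "medulla"): (0.31, 0.11),
    ("preop", "tonsil"): (0.76, 0.47),
    ("preop", "ventral_sa"): (3.5, 2.0),
    ("preop", "dorsal_sa"): (2.3, 1.7),
    ("preop", "syrinx"): (1.4, 1.1),
    ("preop", "cord"): (0.51, 0.32),
    ("preop", "medulla"): (0.34, 0.25),
    ("postop", "tonsil"): (0.32, 0.39),
    ("postop", "ventral_sa"): (3.4, 1.3),
    ("postop", "dorsal_sa"): (1.9, 1.1),
    ("postop", "syrinx"): (1.1, 1.0),
    ("postop", "cord"): (0.39, 0.23),
    ("postop", "medulla"): (0.31, 0.20),
}

# Peak rostral (negative) cord velocity (mean, SD) in cm/s: near zero in
# controls, a clear paradoxical rostral excursion in patients.
DEFAULT_CORD_ROSTRAL_TABLE: dict[str, tuple[float, float]] = {
    "control": (-0.0087, 0.0085),
    "preop": (-0.31, 0.25),
    "postop": (-0.46, 0.34),
}

#: Rostral return-lobe amplitude of non-cord ROIs, as a fraction of the
#: session's caudal peak. Not a measured quantity; see docs/methods.md.
DEFAULT_ROSTRAL_FRACTION = 0.35

#: Latencies are truncated to +/- this fraction of the cycle so the CSF
#: trigger point stays unambiguous under circular shifting.
LATENCY_TRUNCATION = 0.20


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic three-group cohort.

    Defaults reproduce the study conditions: 21 controls, 17 preoperative and
    18 postoperative patient sessions (one patient lacks a preoperative
    scan), 25- or 35-bin raw grids, and per-ROI peak amplitudes at the
    published group means/SDs.
    """

    n_control: int = 21
    n_preop: int = 17
    n_postop: int = 18
    raw_bins_choices: tuple[int, ...] = (25, 35)
    latency_jitter_sd: float = 0.08
    noise_sd: float = 0.025
    amplitude_table: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_TABLE)
    )
    cord_rostral_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CORD_ROSTRAL_TABLE)
    )
    rostral_fraction: float = DEFAULT_ROSTRAL_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_preop, self.n_postop) < 0:
            raise InvalidParameterError("group sizes must be >= 0")
        if not self.raw_bins_choices or any(b < 8 for b in self.raw_bins_choices):
            raise InvalidParameterError("raw_bins_choices must be bin counts >= 8")
        if not 0.0 <= self.latency_jitter_sd < 0.5:
            raise InvalidParameterError("latency_jitter_sd must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        for group in GROUP_LABELS:
            for roi in ROI_LABELS:
                if (group, roi) not in self.amplitude_table:
                    raise InvalidParameterError(
                        f"amplitude_table missing entry for ({group!r}, {roi!r})"
                    )
        for (group, roi), (_, sd) in self.amplitude_table.items():
            if sd < 0:
                raise InvalidParameterError(
                    f"amplitude_table SD for ({group!r}, {roi!r}) must be >= 0"
                )
        for group, (_, sd) in self.cord_rostral_table.items():
            if sd < 0:
                raise InvalidParameterError(f"cord rostral SD for {group!r} must be >= 0")
        if not 0.0 <= self.rostral_fraction <= 1.0:
            raise InvalidParameterError("rostral_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Drawn generator state, keyed by (subject_id, group_label)."""

    latency: dict[tuple[str, str], float] = field(default_factory=dict)
    peak_caudal: dict[tuple[str, str, str], float] = field(default_factory=dict)
    peak_rostral: dict[tuple[str, str, str], float] = field(default_factory=dict)
    raw_bins: dict[tuple[str, str], int] = field(default_factory=dict)


def _draw_signed_amplitude(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw a one-signed amplitude with exactly the requested mean and SD.

    Peak speeds are strictly one-signed, so a moment-matched lognormal is
    used (the sign of ``mean`` is carried separately). ``sd == 0`` returns
    the mean; ``mean == 0`` with ``sd > 0`` has no one-signed solution.
    """
    if sd == 0.0:
        return mean
    if mean == 0.0:
        raise InvalidParameterError("cannot draw one-signed amplitude with mean 0 and sd > 0")
    sign = 1.0 if mean > 0 else -1.0
    m = abs(mean)
    sigma2 = math.log1p((sd / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return sign * float(rng.lognormal(mu, math.sqrt(sigma2)))


def _draw_latency(rng: np.random.Generator, sd: float) -> float:
    """Truncated-normal latency in fractions of the cardiac cycle."""
    if sd == 0.0:
        return 0.0
    while True:
        lat = float(rng.normal(0.0, sd))
        if abs(lat) <= LATENCY_TRUNCATION:
            return lat


def _make_session(
    rng: np.random.Generator,
    spec: CohortSpec,
    subject_id: str,
    group: str,
    truth: GroundTruth,
) -> MRISession:
    n_raw = int(rng.choice(np.asarray(spec.raw_bins_choices)))
    latency = _draw_latency(rng, spec.latency_jitter_sd)
    shift_bins = int(round(latency * n_raw))
    realized_latency = shift_bins / n_raw

    waveforms: dict[str, VelocityWaveform] = {}
    for roi in ROI_LABELS:
        mean, sd = spec.amplitude_table[(group, roi)]
        caudal = _draw_signed_amplitude(rng, mean, sd)
        caudal = max(caudal, 0.0)
        if roi == "cord":
            r_mean, r_sd = spec.cord_rostral_table[group]
            rostral = min(_draw_signed_amplitude(rng, r_mean, r_sd), 0.0)
        else:
            rostral = -spec.rostral_fraction * caudal
        wave = make_waveform_template(
            roi, caudal, rostral, n_raw, rostral_first=(roi == "cord")
        )
        wave = circular_delay(wave, shift_bins)
        if spec.noise_sd > 0:
            wave = wave.with_values(
                wave.values + rng.normal(0.0, spec.noise_sd, n_raw)
            )
        waveforms[roi] = wave
        truth.peak_caudal[(subject_id, group, roi)] = caudal
        truth.peak_rostral[(subject_id, group, roi)] = rostral

    truth.latency[(subject_id, group)] = realized_latency
    truth.raw_bins[(subject_id, group)] = n_raw
    return MRISession(subject_id=subject_id, group_label=group, waveforms=waveforms)


def generate_cohort(spec: CohortSpec) -> tuple[list[MRISession], GroundTruth]:
    """Generate a synthetic cohort of cardiac-gated six-ROI sessions.

    Patient subject ids are shared between the preop and postop groups so
    paired pre/post comparisons are possible: patients ``patient-000`` ..
    ``patient-(max(n_preop, n_postop)-1)`` exist, the first ``n_preop`` of
    them with a preoperative session and the first ``n_postop`` with a
    postoperative one (with the defaults, patient 17 has only a
    postoperative scan). Controls are independent subjects.

    Returns the sessions (controls, then preop, then postop) and the drawn
    ground truth. Identical specs (including seed) give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    sessions: list[MRISession] = []
    for i in range(spec.n_control):
        sessions.append(_make_session(rng, spec, f"control-{i:03d}", "control", truth))
    for i in range(spec.n_preop):
        sessions.append(_make_session(rng, spec, f"patient-{i:03d}", "preop", truth))
    for i in range(spec.n_postop):
        sessions.append(_make_session(rng, spec, f"patient-{i:03d}", "postop", truth))
    return sessions, truth
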