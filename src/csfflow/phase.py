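"""Phase-contrast image decoding and ROI waveform extraction.

Phase-contrast MRI encodes velocity along the chosen axis (here
craniocaudal) into image intensity, linearly up to the velocity-encoding
limit VENC. This module models that encoding as an affine intensity map

    velocity [cm/s] = (intensity - intensity_zero) / intensity_per_cms

with zero velocity at mid-scale, decodes per-bin frames back to velocity
maps, and reduces circular ROIs to per-bin mean-velocity waveforms.

A matching synthetic encoder (:func:`generate_phase_series`) renders a
session's waveforms into quantized per-bin frames, giving the extraction
path an exact round-trip oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .waveform import (
    InvalidParameterError,
    MRISession,
    ROI_LABELS,
    VelocityWaveform,
)

logger = logging.getLogger(__name__)

DEFAULT_VENC = 10.0  # cm/s, craniocaudal
DEFAULT_INTENSITY_ZERO = 2048.0  # mid-scale of a 12-bit phase image
DEFAULT_INTENSITY_PER_CMS = 204.7  # full scale (+/-2047) at +/-VENC = 10 cm/s


class AliasingError(ValueError):
    """A velocity beyond +/-VENC cannot be encoded without phase wrapping."""


class InvalidROIError(ValueError):
    """ROI placement violates image bounds or selects no pixels."""


@dataclass(frozen=True)
class ROISpec:
    """A circular region of interest: label, (row, col) center, radius in pixels."""

    label: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise InvalidROIError(f"unknown ROI label {self.label!r}")
        if self.radius <= 0:
            raise InvalidROIError("ROI radius must be > 0")

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers lie strictly inside the circle.

        Pixel centers sit at integer (row, col) coordinates, 0-based,
        top-left origin.
        """
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        rr = rows - self.center[0]
        cc = cols - self.center[1]
        return rr * rr + cc * cc < self.radius**2

    def check_bounds(self, shape: tuple[int, int]) -> None:
        r0, c0 = self.center
        if (
            r0 - self.radius < -0.5
            or c0 - self.radius < -0.5
            or r0 + self.radius > shape[0] - 0.5
            or c0 + self.radius > shape[1] - 0.5
        ):
            raise InvalidROIError(
                f"ROI {self.label!r} (center {self.center}, radius {self.radius}) "
                f"extends outside a {shape[0]}x{shape[1]} frame"
            )


@dataclass(frozen=True)
class PhaseImageSeries:
    """Per-cardiac-bin 2-D phase images plus their velocity-encoding map."""

    frames: np.ndarray  # (bin_count, rows, cols)
    venc: float = DEFAULT_VENC
    intensity_zero: float = DEFAULT_INTENSITY_ZERO
    intensity_per_cms: float = DEFAULT_INTENSITY_PER_CMS

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3 or arr.shape[0] < 8:
            raise InvalidParameterError(
                "frames must be a (bin_count >= 8, rows, cols) stack"
            )
        if self.venc <= 0 or self.intensity_per_cms <= 0:
            raise InvalidParameterError("venc and intensity_per_cms must be > 0")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "frames", arr)

    @property
    def bin_count(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


def decode_velocity(series: PhaseImageSeries, bin_index: int) -> np.ndarray:
    """Decode one cardiac bin's frame to a craniocaudal velocity map in cm/s.

    Values beyond +/-VENC are passed through unchanged but logged as
    possible aliasing (the decoder never clips).
    """
    if not 0 <= bin_index < series.bin_count:
        raise IndexError(f"bin_index {bin_index} outside [0, {series.bin_count})")
    vel = (series.frames[bin_index] - series.intensity_zero) / series.intensity_per_cms
    n_over = int(np.count_nonzero(np.abs(vel) > series.venc))
    if n_over:
        logger.warning(
            "bin %d: %d pixel(s) decode beyond VENC=%.3g cm/s (possible aliasing)",
            bin_index,
            n_over,
            series.venc,
        )
    return vel


def roi_mean_waveform(series: PhaseImageSeries, roi: ROISpec) -> VelocityWaveform:
    """Signed mean velocity over the ROI's member pixels, per cardiac bin."""
    roi.check_bounds(series.frame_shape)
    mask = roi.pixel_mask(series.frame_shape)
    if not mask.any():
        raise InvalidROIError(f"ROI {roi.label!r} contains no pixel centers")
    values = [float(decode_velocity(series, b)[mask].mean()) for b in range(series.bin_count)]
    return VelocityWaveform(roi.label, np.asarray(values))


def extract_session(
    series_set: PhaseImageSeries | dict[str, PhaseImageSeries],
    roi_layout: list[ROISpec],
    subject_id: str,
    group_label: str,
) -> MRISession:
    """Extract the six ROI waveforms of one scan into a raw session.

    ``series_set`` may be a single shared series (the usual midline sagittal
    acquisition) or a per-ROI-label mapping.
    """
    labels = [roi.label for roi in roi_layout]
    if sorted(labels) != sorted(ROI_LABELS):
        raise InvalidROIError(
            f"roi_layout must name the six canonical ROIs exactly once, got {labels}"
        )
    waveforms: dict[str, VelocityWaveform] = {}
    for roi in roi_layout:
        if isinstance(series_set, dict):
            if roi.label not in series_set:
                raise InvalidROIError(f"no image series supplied for ROI {roi.label!r}")
            series = series_set[roi.label]
        else:
            series = series_set
        waveforms[roi.label] = roi_mean_waveform(series, roi)
    return MRISession(subject_id=subject_id, group_label=group_label, waveforms=waveforms)


def default_roi_layout(image_size: int = 64) -> list[ROISpec]:
    """A compact non-overlapping six-ROI layout for synthetic frames."""
    if image_size < 32:
        raise InvalidROIError("image_size must be >= 32 for the default layout")
    q = image_size // 4
    r = max(3.0, image_size / 16)
    return [
        ROISpec("tonsil", (q, q), r),
        ROISpec("cord", (q, 3 * q), r),
        ROISpec("ventral_sa", (2 * q, q), r),
        ROISpec("dorsal_sa", (2 * q, 3 * q), r),
        ROISpec("syrinx", (3 * q, q), r),
        ROISpec("medulla", (3 * q, 3 * q), r),
    ]


def generate_phase_series(
    session: MRISession,
    image_size: int = 64,
    roi_layout: list[ROISpec] | None = None,
    venc: float = DEFAULT_VENC,
    intensity_zero: float = DEFAULT_INTENSITY_ZERO,
    intensity_per_cms: float = DEFAULT_INTENSITY_PER_CMS,
    quantize: bool = True,
) -> PhaseImageSeries:
    """Render a session's waveforms into synthetic phase-contrast frames.

    For each cardiac bin, pixels inside ROI *k* encode that ROI's velocity at
    that bin; pixels outside every ROI encode zero velocity (mid-scale
    intensity). Intensities are rounded to integers by default, modelling
    scanner quantization. Velocities beyond +/-VENC raise
    :class:`AliasingError` — phase wrapping is deliberately not modelled.
    """
    if roi_layout is None:
        roi_layout = default_roi_layout(image_size)
    shape = (image_size, image_size)
    masks = {}
    for roi in roi_layout:
        roi.check_bounds(shape)
        masks[roi.label] = roi.pixel_mask(shape)

    n_bins = session.bin_count
    frames = np.full((n_bins, *shape), float(intensity_zero))
    for roi in roi_layout:
        wave = session.waveforms[roi.label]
        if np.max(np.abs(wave.values)) > venc:
            raise AliasingError(
                f"ROI {roi.label!r} of session {session.subject_id!r} exceeds "
                f"VENC={venc:g} cm/s; phase wrapping is not modelled"
            )
        for b in range(n_bins):
            frames[b][masks[roi.label]] = (
                intensity_zero + wave.values[b] * intensity_per_cms
            )
    if quantize:
        frames = np.round(frames)
    return PhaseImageSeries(
        frames=frames,
        venc=venc,
        intensity_zero=intensity_zero,
        intensity_per_cms=intensity_per_cms,
    )


# ---------------------------------------------------------------------------
# Optional ingestion of real per-bin images
# ---------------------------------------------------------------------------

def load_phase_series_nifti(
    path,
    venc: float = DEFAULT_VENC,
    intensity_zero: float = DEFAULT_INTENSITY_ZERO,
    intensity_per_cms: float = DEFAULT_INTENSITY_PER_CMS,
) -> PhaseImageSeries:
    """Load a cardiac-binned phase series from a 3-D NIfTI volume.

    The last axis is taken as the cardiac bin axis (rows, cols, bins).
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise InvalidParameterError(f"expected a 3-D volume, got shape {data.shape}")
    frames = np.moveaxis(data.astype(float), -1, 0)
    return PhaseImageSeries(frames, venc, intensity_zero, intensity_per_cms)


def load_phase_series_dicom(
    paths,
    venc: float = DEFAULT_VENC,
    intensity_zero: float = DEFAULT_INTENSITY_ZERO,
    intensity_per_cms: float = DEFAULT_INTENSITY_PER_CMS,
) -> PhaseImageSeries:
    """Load per-bin single-frame DICOM files (one file per cardiac bin).

    Files are sorted by InstanceNumber when present, else by path; the
    RescaleSlope/RescaleIntercept affine is applied to stored pixel values.
    """
    import pydicom

    datasets = [pydicom.dcmread(str(p)) for p in paths]

    def order_key(item):
        idx, ds = item
        return (int(getattr(ds, "InstanceNumber", idx)), idx)

    datasets = [ds for _, ds in sorted(enumerate(datasets), key=order_key)]
    frames = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(arr * slope + intercept)
    return PhaseImageSeries(np.stack(frames), venc, intensity_zero, intensity_per_cms)
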