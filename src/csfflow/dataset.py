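"""Waveform-dataset JSON schema: validation, readers, writers, adapters.

The package's native dataset is a single JSON document::

    {
      "schema_version": "1",
      "provenance": {...free-form, e.g. seed and config hash...},
      "sessions": [
        {
          "subject_id": "patient-000",
          "group_label": "preop",
          "bin_count": 25,
          "sync_state": "raw",
          "trigger_index": null,
          "waveforms": {"tonsil": [...cm/s...], ...six ROI arrays...}
        }, ...
      ]
    }

Serialization is deterministic (sorted keys, repr-roundtrip floats), so
identical datasets produce identical bytes. Unknown top-level and record
fields are preserved on a round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .waveform import (
    GROUP_LABELS,
    RAW_STATE,
    ROI_LABELS,
    MRISession,
    VelocityWaveform,
)

SCHEMA_VERSION = "1"

_SESSION_KEYS = {
    "subject_id",
    "group_label",
    "bin_count",
    "sync_state",
    "trigger_index",
    "waveforms",
}


class DatasetValidationError(ValueError):
    """The dataset violates the waveform-dataset schema."""


@dataclass
class WaveformDataset:
    """A collection of sessions plus provenance, as read from/written to JSON."""

    sessions: list[MRISession]
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION
    extras: dict = field(default_factory=dict)  # unknown fields, preserved
    session_extras: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.session_extras:
            self.session_extras = [{} for _ in self.sessions]


def _session_to_record(session: MRISession, extra: dict) -> dict:
    rec = dict(extra)
    rec.update(
        {
            "subject_id": session.subject_id,
            "group_label": session.group_label,
            "bin_count": session.bin_count,
            "sync_state": session.sync_state,
            "trigger_index": session.trigger_index,
            "waveforms": {
                label: [float(v) for v in session.waveforms[label].values]
                for label in ROI_LABELS
            },
        }
    )
    return rec


def _record_to_session(rec: dict, index: int) -> tuple[MRISession, dict]:
    def fail(msg: str):
        raise DatasetValidationError(f"session record {index}: {msg}")

    for key in ("subject_id", "group_label", "waveforms"):
        if key not in rec:
            fail(f"missing required field {key!r}")
    if rec["group_label"] not in GROUP_LABELS:
        fail(f"unknown group label {rec['group_label']!r}")
    bad = sorted(set(rec["waveforms"]) - set(ROI_LABELS))
    if bad:
        fail(f"unknown ROI label(s) {bad}; canonical labels are {list(ROI_LABELS)}")
    missing = sorted(set(ROI_LABELS) - set(rec["waveforms"]))
    if missing:
        fail(f"missing ROI waveform(s) {missing}")
    waveforms = {
        label: VelocityWaveform(label, np.asarray(vals, dtype=float))
        for label, vals in rec["waveforms"].items()
    }
    declared = rec.get("bin_count")
    actual = next(iter(waveforms.values())).bin_count
    if declared is not None and declared != actual:
        fail(f"declared bin_count {declared} != array length {actual}")
    try:
        session = MRISession(
            subject_id=str(rec["subject_id"]),
            group_label=rec["group_label"],
            waveforms=waveforms,
            sync_state=rec.get("sync_state", RAW_STATE),
            trigger_index=rec.get("trigger_index"),
        )
    except ValueError as exc:
        fail(str(exc))
    extra = {k: v for k, v in rec.items() if k not in _SESSION_KEYS}
    return session, extra


def write_dataset(dataset: WaveformDataset, path) -> None:
    """Write a dataset deterministically: sorted keys, stable float text."""
    doc = dict(dataset.extras)
    doc["schema_version"] = dataset.schema_version
    doc["provenance"] = dataset.provenance
    doc["sessions"] = [
        _session_to_record(s, e)
        for s, e in zip(dataset.sessions, dataset.session_extras)
    ]
    text = json.dumps(doc, sort_keys=True, indent=1)
    Path(path).write_text(text + "\n")


def read_dataset(path) -> WaveformDataset:
    """Read and validate a waveform dataset; unknown fields are preserved."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DatasetValidationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "sessions" not in doc:
        raise DatasetValidationError(f"{path}: missing top-level 'sessions' list")
    sessions, extras = [], []
    for i, rec in enumerate(doc["sessions"]):
        session, extra = _record_to_session(rec, i)
        sessions.append(session)
        extras.append(extra)
    top_extras = {
        k: v for k, v in doc.items() if k not in ("schema_version", "provenance", "sessions")
    }
    return WaveformDataset(
        sessions=sessions,
        provenance=doc.get("provenance", {}),
        schema_version=str(doc.get("schema_version", SCHEMA_VERSION)),
        extras=top_extras,
        session_extras=extras,
    )


# ---------------------------------------------------------------------------
# Best-effort adapter for the deposited post-processed waveform file
# ---------------------------------------------------------------------------

_ROI_ALIASES = {
    "tonsil": "tonsil",
    "tonsils": "tonsil",
    "cord": "cord",
    "spinal_cord": "cord",
    "ventral_sa": "ventral_sa",
    "ventral": "ventral_sa",
    "ventral_csf": "ventral_sa",
    "dorsal_sa": "dorsal_sa",
    "dorsal": "dorsal_sa",
    "dorsal_csf": "dorsal_sa",
    "syrinx": "syrinx",
    "medulla": "medulla",
}

_GROUP_ALIASES = {
    "control": "control",
    "controls": "control",
    "normal": "control",
    "volunteer": "control",
    "preop": "preop",
    "pre": "preop",
    "preoperative": "preop",
    "postop": "postop",
    "post": "postop",
    "postoperative": "postop",
}


def _canon(mapping: dict[str, str], raw: str, kind: str) -> str:
    key = str(raw).strip().lower().replace("-", "_").replace(" ", "_")
    if key not in mapping:
        raise DatasetValidationError(f"unrecognized {kind} label {raw!r}")
    return mapping[key]


def load_deposited_waveforms(path) -> WaveformDataset:
    """Best-effort adapter for an externally deposited waveform JSON file.

    Accepts either a flat list of session records or a mapping of group
    label to a list of records; ROI and group labels are normalized through
    an alias table. After parsing, the caudal-positive sign convention is
    verified against the known physiology (the group-median ventral
    subarachnoid peak caudal velocity must be positive); if the file is
    stored caudal-negative, all waveforms are flipped, and the flip is
    recorded in the dataset provenance.
    """
    doc = json.loads(Path(path).read_text())
    records: list[dict] = []
    if isinstance(doc, list):
        records = list(doc)
    elif isinstance(doc, dict):
        if "sessions" in doc:
            records = list(doc["sessions"])
        else:
            for group_raw, items in doc.items():
                group = _canon(_GROUP_ALIASES, group_raw, "group")
                for rec in items:
                    rec = dict(rec)
                    rec.setdefault("group_label", group)
                    records.append(rec)
    else:
        raise DatasetValidationError(f"{path}: unsupported top-level JSON structure")

    sessions = []
    for i, rec in enumerate(records):
        group = _canon(
            _GROUP_ALIASES, rec.get("group_label") or rec.get("group", ""), "group"
        )
        subject = str(
            rec.get("subject_id") or rec.get("subject") or rec.get("id") or f"subject-{i:03d}"
        )
        wf_src = rec.get("waveforms") or rec.get("rois") or rec.get("data")
        if not isinstance(wf_src, dict):
            raise DatasetValidationError(f"record {i}: no per-ROI waveform mapping found")
        waveforms = {}
        for roi_raw, vals in wf_src.items():
            roi = _canon(_ROI_ALIASES, roi_raw, "ROI")
            waveforms[roi] = VelocityWaveform(roi, np.asarray(vals, dtype=float))
        try:
            sessions.append(
                MRISession(subject_id=subject, group_label=group, waveforms=waveforms)
            )
        except ValueError as exc:
            raise DatasetValidationError(f"record {i}: {exc}") from exc

    flipped = _fix_sign_convention(sessions)
    provenance = {"source": str(path), "adapter": "load_deposited_waveforms"}
    if flipped:
        provenance["sign_flipped"] = True
    return WaveformDataset(sessions=sessions, provenance=provenance)


def _fix_sign_convention(sessions: list[MRISession]) -> bool:
    """Flip all waveforms in place if the file is stored caudal-negative.

    Caudal CSF flow dominates the ventral subarachnoid waveform, so the
    median over sessions of max(|max|) vs |min| decides orientation.
    """
    extremes = []
    for s in sessions:
        v = s.waveforms["ventral_sa"].values
        extremes.append(abs(float(v.min())) - float(v.max()))
    if not extremes or float(np.median(extremes)) <= 0:
        return False
    for i, s in enumerate(sessions):
        sessions[i] = MRISession(
            subject_id=s.subject_id,
            group_label=s.group_label,
            waveforms={
                label: w.with_values(-w.values) for label, w in s.waveforms.items()
            },
            sync_state=s.sync_state,
            trigger_index=s.trigger_index,
        )
    return True
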