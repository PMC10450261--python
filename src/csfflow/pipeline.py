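"""End-to-end pipeline: simulate/load -> synchronize -> aggregate -> report.

A :class:`PipelineConfig` names either an input dataset file or synthetic
cohort parameters, plus an output directory. :func:`run_pipeline` executes
the stages, writes the per-ROI comparison table (CSV and plain text),
per-group mean-waveform plots, and a run log carrying the seed, a config
hash, and per-stage timings. With a fixed seed and config the text outputs
are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .dataset import WaveformDataset, read_dataset, write_dataset
from .plots import plot_group_waveforms
from .stats import (
    DEFAULT_ALPHA,
    build_table1,
    csf_tonsil_anova,
    format_table1,
    summarize_group,
)
from .sync import SyncStateError, synchronize_cohort
from .waveform import GROUP_LABELS

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Pipeline inputs: a dataset path OR synthetic cohort parameters."""

    output_dir: str | Path = "results/run"
    dataset_path: str | Path | None = None
    simulate: CohortSpec | None = None
    alpha: float = DEFAULT_ALPHA
    make_plots: bool = True
    anova_group: str = "preop"

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        payload = json.dumps(
            {
                "dataset_path": str(self.dataset_path) if self.dataset_path else None,
                "simulate": enc(self.simulate) if self.simulate else None,
                "alpha": self.alpha,
                "anova_group": self.anova_group,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths and in-memory products of one pipeline run."""

    output_dir: Path
    table1 = None
    summaries: dict = field(default_factory=dict)
    anova = None
    tukey_pairs: list = field(default_factory=list)
    run_log: dict = field(default_factory=dict)


def _stage(name: str, timings: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc
    timings[name] = round(time.perf_counter() - t0, 4)
    return result


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    if (config.dataset_path is None) == (config.simulate is None):
        raise ValueError("config must name exactly one of dataset_path or simulate")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out)
    timings: dict[str, float] = {}

    # -- acquire ------------------------------------------------------------
    if config.simulate is not None:
        def simulate():
            sessions, _truth = generate_cohort(config.simulate)
            ds = WaveformDataset(
                sessions=sessions,
                provenance={
                    "generator": "csfflow.cohort.generate_cohort",
                    "seed": config.simulate.seed,
                    "config_hash": config.config_hash(),
                },
            )
            write_dataset(ds, out / "cohort_raw.json")
            return ds

        dataset = _stage("simulate", timings, simulate)
    else:
        dataset = _stage("load", timings, read_dataset, config.dataset_path)

    # -- synchronize --------------------------------------------------------
    synced = _stage("synchronize", timings, synchronize_cohort, dataset.sessions)

    # -- aggregate ----------------------------------------------------------
    def aggregate():
        summaries = {}
        for group in GROUP_LABELS:
            if any(s.group_label == group for s in synced):
                summaries[group] = summarize_group(synced, group)
        return summaries

    bundle.summaries = _stage("aggregate", timings, aggregate)

    # -- statistics ---------------------------------------------------------
    bundle.table1 = _stage("stats", timings, build_table1, synced, config.alpha)
    if any(s.group_label == config.anova_group for s in synced):
        def anova():
            return csf_tonsil_anova(synced, config.anova_group)

        bundle.anova, bundle.tukey_pairs = _stage("anova", timings, anova)

    # -- report -------------------------------------------------------------
    def report():
        bundle.table1.to_csv(out / "table1.csv", float_format="%.6g")
        (out / "table1.txt").write_text(format_table1(bundle.table1) + "\n")
        if bundle.anova is not None:
            stats_doc = {
                "anova": {
                    "comparison": list(bundle.anova.comparison),
                    "F": bundle.anova.statistic,
                    "df": list(bundle.anova.df),
                    "p": bundle.anova.p_value,
                },
                "tukey": [
                    {"pair": list(t.comparison), "p": t.p_value, "diff": t.statistic}
                    for t in bundle.tukey_pairs
                ],
            }
            (out / "anova.json").write_text(json.dumps(stats_doc, indent=1, sort_keys=True) + "\n")
        if config.make_plots:
            for group, summary in bundle.summaries.items():
                plot_group_waveforms(summary, out / f"waveforms_{group}.png")
        return True

    _stage("report", timings, report)

    bundle.run_log = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.simulate.seed if config.simulate else None,
        "alpha": config.alpha,
        "n_sessions": len(dataset.sessions),
        "stage_seconds": timings,
    }
    log_doc = dict(bundle.run_log)
    log_doc["stage_seconds"] = {k: None for k in timings}  # timings vary; keep file stable
    (out / "run_log.json").write_text(json.dumps(log_doc, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline finished: %s", bundle.run_log)
    return bundle
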