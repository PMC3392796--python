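"""End-to-end orchestration: simulate -> summarize -> compare -> panels.

A run is fully described by a :class:`RunConfig`; identical config + seed
reproduces identical tabular outputs (verified by the checksums written to
the run manifest).  Stages communicate only through the documented file
formats; any stage failure aborts with a stage-named error and leaves a
``<stage>.partial`` marker next to whatever was already written.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as _io
from .markers import build_dataset, summarize_study
from .panels import results_frame, search_panels
from .stats import compare_cohorts
from .synthetic import CohortDesign, default_design, generate_study

__version__ = "0.1.0"

PARAMETERS = ("mfi_corrected", "affected_area")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    design: CohortDesign = field(default_factory=default_design)
    seed: int = 0
    outdir: str = "lscpanel_run"
    max_fpr: float = 0.05
    tile_edge: int = 20
    scatter_cutoff: float = 500.0
    cv_k: int = 10
    cv_reps: int = 10
    target_specificity: float = 0.90
    ci_method: str = "delong"
    panel_max_size: int = 2
    rank_criterion: str = "auc"
    parameters: tuple[str, ...] = PARAMETERS
    contrasts: tuple[str, ...] = ("control-vs-ra", "control-vs-ra+", "control-vs-ra++")
    write_tables: bool = False
    stages: tuple[str, ...] = ("simulate", "summarize", "compare", "panels")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = _io.design_to_dict(self.design)
        for key in ("parameters", "contrasts", "stages"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = _io.design_from_dict(d["design"])
        for key in ("parameters", "contrasts", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and return the run manifest.

    The manifest records the package version, the full configuration, and a
    SHA-256 checksum of every output file, which is what the reproducibility
    contract is checked against.
    """
    outdir = _io.ensure_dir(config.outdir)
    outputs: list[Path] = []
    state: dict = {}

    design = dataclasses.replace(config.design, seed=config.seed)

    def _stage(name, fn):
        if name not in config.stages:
            return
        marker = outdir / f"{name}.partial"
        marker.touch()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage name
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        marker.unlink()

    def _simulate():
        tables, metadata = generate_study(design)
        state["tables"], state["metadata"] = tables, metadata
        _io.write_frame(metadata, outdir / "metadata.csv")
        outputs.append(outdir / "metadata.csv")
        if config.write_tables:
            _io.write_table(tables, outdir / "phantom_tables.csv")
            outputs.append(outdir / "phantom_tables.csv")

    def _need(key, filename, reader):
        # stages toggled off are replaced by their on-disk artifact
        if key not in state:
            state[key] = reader(outdir / filename)
        return state[key]

    def _summarize():
        tables = _need("tables", "phantom_tables.csv", _io.read_table)
        summaries = summarize_study(tables, max_fpr=config.max_fpr)
        state["summaries"] = summaries
        _io.write_frame(summaries, outdir / "summaries.csv")
        outputs.append(outdir / "summaries.csv")

    def _compare():
        frames = []
        summaries = _need("summaries", "summaries.csv", _io.read_frame)
        metadata = _need("metadata", "metadata.csv", _io.read_frame)
        for parameter in config.parameters:
            ds = build_dataset(summaries, metadata, parameter)
            cmp = compare_cohorts(ds)
            cmp.insert(0, "parameter", parameter)
            frames.append(cmp)
        comparisons = pd.concat(frames, ignore_index=True)
        _io.write_frame(comparisons, outdir / "comparisons.csv")
        outputs.append(outdir / "comparisons.csv")

    def _panels():
        frames = []
        summaries = _need("summaries", "summaries.csv", _io.read_frame)
        metadata = _need("metadata", "metadata.csv", _io.read_frame)
        for parameter in config.parameters:
            ds = build_dataset(summaries, metadata, parameter)
            for contrast in config.contrasts:
                ranked = search_panels(
                    ds,
                    contrast=contrast,
                    max_size=config.panel_max_size,
                    k=config.cv_k,
                    reps=config.cv_reps,
                    seed=config.seed,
                    criterion=config.rank_criterion,
                    target_specificity=config.target_specificity,
                    ci_method=config.ci_method,
                )
                frames.append(results_frame(ranked))
        panels = pd.concat(frames, ignore_index=True)
        _io.write_frame(panels, outdir / "panels.csv")
        outputs.append(outdir / "panels.csv")

    _stage("simulate", _simulate)
    _stage("summarize", _summarize)
    _stage("compare", _compare)
    _stage("panels", _panels)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {p.name: _io.sha256_file(p) for p in outputs},
    }
    _io.write_json(manifest, outdir / "manifest.json")
    return manifest
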