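"""Pipeline orchestration: simulate -> count -> classify -> index -> dda -> compare.

Every run writes a JSON manifest recording the tool version, the config
snapshot, the seeds actually used per stage, per-stage timings and all
output paths, so any number in the outputs is traceable.  All randomness
derives from the one root seed through named substreams, so adding a stage
never perturbs another stage's draws.  CSV floats are rounded to 6
significant digits at write time, making repeated runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._errors import LGQuantError, ValidationError
from .config import RunConfig
from .dye import pearson_colocalization
from .experiments import derive_seeds
from .image_io import write_stack, write_table
from .pipeline import analyze_specimen
from .stats import compare_groups
from .synthetic import render_barrier_pair, render_scene, sample_scene

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    version: str
    config: dict
    config_hash: str
    seeds: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages: list = field(default_factory=list)

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


class StageError(LGQuantError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _nuclei_frame(detections) -> pd.DataFrame:
    return pd.DataFrame([{"label": d.label,
                          "z_um": d.centroid_um[0], "y_um": d.centroid_um[1],
                          "x_um": d.centroid_um[2], "voxels": d.voxel_count,
                          "radius_um": d.equivalent_radius_um}
                         for d in detections])


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    Idempotent for a fixed config and seed: analysis CSVs are byte-identical
    across runs.  Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dict(config.raw) or {"seed": config.seed}
    manifest = RunManifest(
        version=__version__, config=cfg_dict,
        config_hash=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest())
    stages = config.stages
    analysis_needed = any(s in stages for s in ("count", "classify", "index", "compare"))
    simulate_only = set(stages) == {"simulate"}
    report_rows = []

    def record(stage, path):
        manifest.outputs.append(str(path))

    t0 = time.perf_counter()
    try:
        for cond in config.effective_conditions():
            seeds = derive_seeds(config.seed, cond.n_specimens, f"specimen-{cond.name}")
            manifest.seeds[cond.name] = seeds
            markers = sorted(cond.scene.marker_fractions)
            for i, seed in enumerate(seeds):
                scene = sample_scene(cond.scene, seed)
                volume = render_scene(scene, config.noise)
                tag = f"{cond.name}_{i:02d}"
                if "simulate" in stages:
                    record("simulate", write_table(
                        scene.to_dataframe(), outdir / f"truth_{tag}.csv"))
                    if config.write_stacks or simulate_only:
                        record("simulate", write_stack(
                            volume, outdir / f"stack_{tag}.ome.tif"))
                if not analysis_needed:
                    continue
                result = analyze_specimen(volume, cond.scene.nuclear_channel,
                                          markers if markers else [],
                                          config.detection, config.classification)
                if "count" in stages:
                    record("count", write_table(
                        _nuclei_frame(result.detections), outdir / f"nuclei_{tag}.csv"))
                if "classify" in stages and markers:
                    from .classify import classifications_frame
                    record("classify", write_table(
                        classifications_frame(result.classifications),
                        outdir / f"cells_{tag}.csv"))
                if ("index" in stages or "compare" in stages) and result.report:
                    for m in markers:
                        report_rows.append({
                            "condition": cond.name, "specimen": i, "marker": m,
                            "total_cells": result.report.total_cells,
                            "positive": result.report.positives[m],
                            "index": result.report.index[m],
                            "threshold": result.thresholds.get(m)})
    except LGQuantError as exc:
        raise StageError("analysis", exc) from exc
    manifest.timings_s["analysis"] = round(time.perf_counter() - t0, 3)
    manifest.stages = list(stages)

    if report_rows and "index" in stages:
        record("index", write_table(pd.DataFrame(report_rows), outdir / "report.csv"))

    if "compare" in stages:
        t1 = time.perf_counter()
        if not report_rows:
            raise StageError("compare", ValidationError("no indices to compare"))
        report = pd.DataFrame(report_rows)
        stats_frames = []
        control = config.effective_conditions()[0].name
        for marker, sub in report.groupby("marker"):
            res = compare_groups(sub, "condition", "index", control=control)
            res.insert(0, "marker", marker)
            stats_frames.append(res)
        record("compare", write_table(pd.concat(stats_frames, ignore_index=True),
                                      outdir / "stats.csv"))
        manifest.timings_s["compare"] = round(time.perf_counter() - t1, 3)

    if "dda" in stages:
        t1 = time.perf_counter()
        if config.scene.psc_count <= 0:
            raise StageError("dda", ValidationError(
                "dda stage needs a scene with psc_count > 0"))
        rows = []
        for intact in (True, False):
            label = "intact" if intact else "broken"
            seeds = derive_seeds(config.seed, config.dda_specimens, f"dda-{label}")
            manifest.seeds[f"dda-{label}"] = seeds
            for j, seed in enumerate(seeds):
                scene = sample_scene(config.scene, seed)
                vol = render_barrier_pair(scene, config.noise, barrier_intact=intact)
                small, large = config.scene.dye_channels
                psc = scene.exclusion_mask()
                nonpsc = scene.exclusion_mask(dilate=1.3).complement("non-PSC")
                r_psc = pearson_colocalization(vol, small, large, psc)
                r_non = pearson_colocalization(vol, small, large, nonpsc)
                rows.append({"condition": label, "specimen": j,
                             "r_psc": r_psc.pearson_r, "r_nonpsc": r_non.pearson_r,
                             "contrast": r_psc.pearson_r - r_non.pearson_r})
        record("dda", write_table(pd.DataFrame(rows), outdir / "dda.csv"))
        manifest.timings_s["dda"] = round(time.perf_counter() - t1, 3)

    manifest.write(outdir / "manifest.json")
    return manifest
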