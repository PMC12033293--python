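"""Orchestration of the streaming-vs-offline reconstruction study.

For each scan step size the runner builds a scene, simulates one noisy
dataset, reconstructs it twice — offline (all frames from the start) and in
streaming mode (frames arriving in chunks on the logical clock) with matched
total iteration counts — and compares the three ordered pairs:

* offline vs ground truth,
* real-time vs ground truth,
* real-time vs offline,

each through the full ambiguity-corrected pipeline. The central quantity is
the NMSE block per step size: the study's claim is that the real-time and
offline reconstructions agree with each other more closely than either
agrees with the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .compare import ComparisonReport, CropSpec, compare_pair
from .engine import (
    EngineConfig,
    make_initial_estimates,
    run_offline,
    run_realtime,
)
from .scene import Scene, SceneConfig, build_scene, default_scene_config, scaled_scene_config
from .simulate import make_chunk_stream, simulate_scene_dataset

PAIRS = ("offline_vs_truth", "realtime_vs_truth", "realtime_vs_offline")

#: the study's step sizes in real-space pixels, densest first
DEFAULT_STEP_SIZES = (10.0, 19.0, 27.0, 35.0, 40.0)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study matrix run."""

    profile: str = "full"  # 'full' (256 px frames) or 'scaled' (smaller CI profile)
    step_sizes: tuple[float, ...] = DEFAULT_STEP_SIZES
    engine: EngineConfig = field(default_factory=EngineConfig)
    chunk_size: int = 25
    inter_frame_delay: float = 0.6
    crop: CropSpec = field(default_factory=CropSpec)
    base_seed: int = 1
    compute_traces: bool = False
    trace_stride: int = 10

    def scene_config(self, step_px: float) -> SceneConfig:
        if self.profile == "full":
            return default_scene_config(step_px=step_px)
        if self.profile == "scaled":
            return scaled_scene_config(step_px=step_px)
        raise ValueError(f"unknown study profile {self.profile!r}")


def scaled_study_config(**overrides) -> StudyConfig:
    """Small-scene study profile: 64 px frames, short spiral, 10-frame chunks."""
    defaults = dict(
        profile="scaled",
        step_sizes=(4.0, 8.0),
        engine=EngineConfig(
            iterations_per_interval=4,
            post_load_iterations=60,
            probe_update_start=20,
        ),
        chunk_size=10,
        crop=CropSpec(side=48),
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


@dataclass(frozen=True)
class StudyRow:
    """One Table row: metrics of one ordered pair at one step size."""

    step_px: float
    pair: str
    mean_abs_od: float
    se_abs_od: float
    mean_abs_phase: float
    se_abs_phase: float
    nmse: float


@dataclass(frozen=True)
class StudyCell:
    """Bookkeeping for one step size: seed and iteration accounting."""

    step_px: float
    seed: int
    overlap_label: float
    iterations_at_last_load: int
    total_iterations: int


@dataclass(frozen=True)
class TracePoint:
    step_px: float
    pair: str
    iteration: int
    nmse: float


@dataclass
class StudyResults:
    rows: list[StudyRow]
    cells: list[StudyCell]
    traces: list[TracePoint] = field(default_factory=list)
    reports: dict = field(default_factory=dict, compare=False, repr=False)

    def row(self, step_px: float, pair: str) -> StudyRow:
        for r in self.rows:
            if r.step_px == step_px and r.pair == pair:
                return r
        raise KeyError(f"no row for step {step_px}, pair {pair}")

    def nmse_block(self, step_px: float) -> dict[str, float]:
        return {p: self.row(step_px, p).nmse for p in PAIRS}

    def to_json(self) -> str:
        payload = {
            "rows": [vars(r) for r in self.rows],
            "cells": [vars(c) for c in self.cells],
            "traces": [vars(t) for t in self.traces],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyResults":
        payload = json.loads(text)
        return cls(
            rows=[StudyRow(**r) for r in payload["rows"]],
            cells=[StudyCell(**c) for c in payload["cells"]],
            traces=[TracePoint(**t) for t in payload["traces"]],
        )


def cell_seed(base_seed: int, step_index: int) -> int:
    """Deterministic per-step noise seed derived from the study seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(step_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _report_row(step_px: float, pair: str, report: ComparisonReport) -> StudyRow:
    return StudyRow(
        step_px=step_px,
        pair=pair,
        mean_abs_od=report.mean_abs_od,
        se_abs_od=report.se_abs_od,
        mean_abs_phase=report.mean_abs_phase,
        se_abs_phase=report.se_abs_phase,
        nmse=report.nmse,
    )


def run_study_cell(
    config: StudyConfig, step_px: float, seed: int
) -> tuple[list[StudyRow], StudyCell, dict[str, ComparisonReport], dict]:
    """Run one step size end to end; returns rows, cell info and reports."""
    scene: Scene = build_scene(config.scene_config(step_px))
    dataset = simulate_scene_dataset(scene, seed=seed)
    stream = make_chunk_stream(
        dataset, chunk_size=config.chunk_size, delay=config.inter_frame_delay
    )
    initial = make_initial_estimates(scene)

    rt_config = config.engine
    if config.compute_traces:
        rt_config = replace(
            rt_config,
            snapshot_stride=config.trace_stride,
            snapshot_side=_trace_side(config, scene),
        )
    realtime = run_realtime(stream, dataset, initial, rt_config)
    total = realtime.iteration
    offline_config = replace(rt_config, start_after_frames=dataset.n_frames)
    offline = run_offline(dataset, initial, offline_config, total)

    truth = scene.object_truth.field
    crop = config.crop
    reports = {
        "offline_vs_truth": compare_pair(truth, offline.object_estimate, crop),
        "realtime_vs_truth": compare_pair(truth, realtime.object_estimate, crop),
        "realtime_vs_offline": compare_pair(
            offline.object_estimate, realtime.object_estimate, crop
        ),
    }
    rows = [_report_row(step_px, pair, reports[pair]) for pair in PAIRS]
    cell = StudyCell(
        step_px=step_px,
        seed=seed,
        overlap_label=float(scene.scan.overlap or 0.0),
        iterations_at_last_load=int(realtime.iterations_at_last_load or 0),
        total_iterations=total,
    )
    states = {"offline": offline, "realtime": realtime, "scene": scene}
    return rows, cell, reports, states


def _trace_side(config: StudyConfig, scene: Scene) -> int:
    # snapshots only need the analysis crop plus room for registration
    return min(scene.grid_side, config.crop.side + 16)


def run_study(config: StudyConfig) -> StudyResults:
    """Run the full matrix: every step size, offline and streaming modes."""
    rows: list[StudyRow] = []
    cells: list[StudyCell] = []
    traces: list[TracePoint] = []
    reports: dict = {}
    for index, step in enumerate(config.step_sizes):
        seed = cell_seed(config.base_seed, index)
        try:
            cell_rows, cell, cell_reports, states = run_study_cell(config, step, seed)
        except Exception as exc:  # identify the failing cell
            raise RuntimeError(f"study cell step={step} px failed: {exc}") from exc
        rows.extend(cell_rows)
        cells.append(cell)
        for pair, report in cell_reports.items():
            reports[(step, pair)] = report
        if config.compute_traces and step == max(config.step_sizes):
            traces.extend(_cell_traces(config, step, states))
    return StudyResults(rows=rows, cells=cells, traces=traces, reports=reports)


def nmse_trace(
    snapshots: dict[int, np.ndarray],
    reference_objects: dict[int, np.ndarray] | np.ndarray,
    crop: CropSpec,
) -> list[tuple[int, float]]:
    """Ambiguity-corrected NMSE per snapshot iteration.

    ``reference_objects`` is either a single fixed reference map (ground
    truth) or a per-iteration dict (another run's snapshots); in the latter
    case only common iterations are evaluated. Registration is applied per
    snapshot — during early growth the estimates can drift laterally.
    """
    if not snapshots:
        raise ValueError("no snapshots available for the trace")
    out: list[tuple[int, float]] = []
    for iteration in sorted(snapshots):
        if isinstance(reference_objects, dict):
            if iteration not in reference_objects:
                continue
            ref = reference_objects[iteration]
        else:
            ref = reference_objects
        report = compare_pair(ref, snapshots[iteration], crop)
        out.append((iteration, report.nmse))
    return out


def _cell_traces(config: StudyConfig, step: float, states: dict) -> list[TracePoint]:
    scene = states["scene"]
    side = _trace_side(config, scene)
    lo = scene.grid_side // 2 - side // 2
    truth_crop = scene.object_truth.field[lo : lo + side, lo : lo + side]
    crop = CropSpec(side=config.crop.side)
    off = states["offline"].snapshots
    rt = states["realtime"].snapshots
    points: list[TracePoint] = []
    for pair, snaps, ref in (
        ("offline_vs_truth", off, truth_crop),
        ("realtime_vs_truth", rt, truth_crop),
        ("realtime_vs_offline", rt, off),
    ):
        for iteration, value in nmse_trace(snaps, ref, crop):
            points.append(TracePoint(step_px=step, pair=pair, iteration=iteration, nmse=value))
    return points


def render_outputs(results: StudyResults, out_dir: str | Path) -> dict[str, Path]:
    """Write the table (TSV), traces (CSV), scalars (JSON) and map PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    if not results.rows:
        raise ValueError("cannot render empty study results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table = pd.DataFrame(
        [
            {
                "step_px": r.step_px,
                "pair": r.pair,
                "abs_OD_difference": f"{r.mean_abs_od:.3g} ± {r.se_abs_od:.3g}",
                "abs_phase_difference": f"{r.mean_abs_phase:.3g} ± {r.se_abs_phase:.3g}",
                "NMSE": f"{r.nmse:.3g}",
            }
            for r in results.rows
        ]
    )
    table_path = out_dir / "table.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    written["table"] = table_path

    json_path = out_dir / "results.json"
    json_path.write_text(results.to_json())
    written["json"] = json_path

    if results.traces:
        trace_path = out_dir / "nmse_trace.csv"
        pd.DataFrame([vars(t) for t in results.traces]).to_csv(trace_path, index=False)
        written["traces"] = trace_path

    for (step, pair), report in results.reports.items():
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        for ax, data, title in (
            (axes[0], report.od_diff_map, "OD difference"),
            (axes[1], report.phase_diff_map, "phase difference (rad)"),
        ):
            im = ax.imshow(data, cmap="RdBu_r")
            ax.set_title(title)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.suptitle(f"step {step} px — {pair.replace('_', ' ')}")
        png = out_dir / f"diff_step{step:g}_{pair}.png"
        fig.savefig(png, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written[f"map_{step:g}_{pair}"] = png
    return written
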