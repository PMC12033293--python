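"""HDF5 persistence for scenes, datasets and reconstructions.

Scene bundles use a simple layout (/object, /probe_truth, /probe_init,
/scan, /geometry). Diffraction datasets follow the CXI convention for the
essentials: frames under /entry_1/data_1/data and scan translations in
metres under /entry_1/data_1/translation, with the geometry stored as
attributes. These files are interchange artifacts; all in-memory work uses
the dataclasses directly.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import ExperimentGeometry, make_geometry
from .scene import GroundTruthObject, Probe, ScanPlan, Scene
from .simulate import DiffractionDataset, DiffractionFrame

_GEOM_ATTRS = (
    "photon_energy",
    "detector_side",
    "detector_pixel",
    "sample_detector_distance",
)


def _write_geometry(group: h5py.Group, geometry: ExperimentGeometry) -> None:
    for name in _GEOM_ATTRS:
        group.attrs[name] = getattr(geometry, name)


def _read_geometry(group: h5py.Group) -> ExperimentGeometry:
    return make_geometry(
        group.attrs["photon_energy"],
        int(group.attrs["detector_side"]),
        group.attrs["detector_pixel"],
        group.attrs["sample_detector_distance"],
    )


def save_scene(scene: Scene, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        obj = fh.create_dataset(
            "object", data=scene.object_truth.field.astype(np.complex64)
        )
        obj.attrs["pixel_m"] = scene.object_truth.pixel
        for name, probe in (
            ("probe_truth", scene.probe_truth),
            ("probe_init", scene.probe_init),
        ):
            ds = fh.create_dataset(name, data=probe.field.astype(np.complex64))
            ds.attrs["total_photons"] = probe.total_photons
        scan = fh.create_group("scan")
        scan.create_dataset("positions", data=scene.scan.positions)
        scan.attrs["step_px"] = scene.scan.step
        if scene.scan.overlap is not None:
            scan.attrs["overlap"] = scene.scan.overlap
        _write_geometry(fh.create_group("geometry"), scene.geometry)


def load_scene(path: str | Path) -> Scene:
    with h5py.File(path, "r") as fh:
        geometry = _read_geometry(fh["geometry"])
        obj = GroundTruthObject(
            field=fh["object"][...], pixel=float(fh["object"].attrs["pixel_m"])
        )
        probes = {}
        for name in ("probe_truth", "probe_init"):
            field_map = fh[name][...]
            budget = float(fh[name].attrs["total_photons"])
            # renormalise away the complex64 round-off so the invariant holds
            power = float(np.sum(np.abs(field_map.astype(np.complex128)) ** 2))
            field_map = field_map.astype(np.complex128) * np.sqrt(budget / power)
            probes[name] = Probe(field=field_map, total_photons=budget)
        positions = fh["scan/positions"][...]
        scan = ScanPlan(
            positions=positions,
            step=float(fh["scan"].attrs["step_px"]),
            n_points=len(positions),
            overlap=float(fh["scan"].attrs["overlap"])
            if "overlap" in fh["scan"].attrs
            else None,
        )
    return Scene(
        geometry=geometry,
        object_truth=obj,
        probe_truth=probes["probe_truth"],
        probe_init=probes["probe_init"],
        scan=scan,
    )


def save_dataset(dataset: DiffractionDataset, path: str | Path) -> None:
    pixel = dataset.geometry.real_space_pixel
    with h5py.File(path, "w") as fh:
        entry = fh.create_group("entry_1/data_1")
        entry.create_dataset(
            "data", data=dataset.counts_stack(), compression="gzip", compression_opts=4
        )
        translation = np.zeros((dataset.n_frames, 3))
        translation[:, 0] = dataset.scan.positions[:, 1] * pixel  # x
        translation[:, 1] = dataset.scan.positions[:, 0] * pixel  # y
        entry.create_dataset("translation", data=translation)
        entry.attrs["rng_seed"] = dataset.rng_seed
        scan = fh.create_group("scan")
        scan.create_dataset("positions_px", data=dataset.scan.positions)
        scan.attrs["step_px"] = dataset.scan.step
        _write_geometry(fh.create_group("geometry"), dataset.geometry)


def load_dataset(path: str | Path) -> DiffractionDataset:
    with h5py.File(path, "r") as fh:
        geometry = _read_geometry(fh["geometry"])
        counts = fh["entry_1/data_1/data"][...]
        seed = int(fh["entry_1/data_1"].attrs["rng_seed"])
        positions = fh["scan/positions_px"][...]
        step = float(fh["scan"].attrs["step_px"])
    scan = ScanPlan(positions=positions, step=step, n_points=len(positions))
    frames = [
        DiffractionFrame(
            counts=counts[j],
            position_index=j,
            position=(float(positions[j, 0]), float(positions[j, 1])),
        )
        for j in range(len(positions))
    ]
    return DiffractionDataset(frames=frames, scan=scan, geometry=geometry, rng_seed=seed)


def save_reconstruction(state, path: str | Path, config_note: str = "") -> None:
    """Store the final object/probe, the loading history and any snapshots."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("object", data=state.object_estimate)
        fh.create_dataset("probe", data=state.probe_estimate)
        fh.create_dataset(
            "history/frames_loaded",
            data=np.asarray(state.frames_loaded_history, dtype=np.int64),
        )
        for iteration, snap in state.snapshots.items():
            fh.create_dataset(f"snapshots/iter_{iteration:04d}", data=snap)
        if config_note:
            fh.attrs["config"] = config_note
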