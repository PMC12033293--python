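"""Far-field diffraction simulation and the chunked arrival-schedule emulator.

The forward model is the standard thin-sample ptychographic one: at scan
position ``j`` the exit wave is the probe times the local object view, and
the detector records ``|FFT2(P * O_j)|^2`` with an orthonormal FFT so that
photon numbers are conserved (Parseval). Photon-counting noise is Poisson
with the noiseless intensity as the mean; each frame draws from its own
deterministic substream so datasets are reproducible under any delivery
order.

Streaming delivery is emulated on a logical clock: frames are produced at a
fixed cadence and handed to the reconstruction engine in chunks, each chunk
becoming available when its last frame has been produced. No wall-clock time
is involved anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .geometry import ExperimentGeometry
from .scene import GroundTruthObject, Probe, ScanPlan, Scene


@dataclass(frozen=True)
class DiffractionFrame:
    """Photon counts for one scan position (zero frequency at the centre)."""

    counts: np.ndarray
    position_index: int
    position: tuple[float, float]


@dataclass(frozen=True)
class DiffractionDataset:
    frames: list[DiffractionFrame]
    scan: ScanPlan
    geometry: ExperimentGeometry
    rng_seed: int

    def __post_init__(self) -> None:
        if len(self.frames) != self.scan.n_points:
            raise ValueError("frame count must equal scan point count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def counts_stack(self) -> np.ndarray:
        return np.stack([f.counts for f in self.frames])


@dataclass(frozen=True)
class ChunkStream:
    """Deterministic chunked delivery schedule over a dataset."""

    chunk_size: int
    inter_frame_delay: float
    chunks: list[range]
    arrival_times: list[float]

    @property
    def n_frames(self) -> int:
        return self.chunks[-1].stop if self.chunks else 0


def view_corner(
    position: tuple[float, float], grid_side: int, det_side: int
) -> tuple[int, int]:
    """Top-left corner of the probe view for a (possibly fractional) position.

    Positions are offsets from the grid centre in real-space pixels and are
    rounded to the nearest integer pixel; the same rounding is used by the
    simulator and the reconstruction engine so they always agree.
    """
    cy = grid_side // 2 + int(round(position[0])) - det_side // 2
    cx = grid_side // 2 + int(round(position[1])) - det_side // 2
    return cy, cx


def simulate_intensity(
    obj: GroundTruthObject | np.ndarray,
    probe: Probe | np.ndarray,
    position: tuple[float, float],
) -> np.ndarray:
    """Noiseless far-field intensity ``|FFT2(P * O_view)|^2`` (centred).

    Uses the orthonormal FFT, so the total intensity equals the exit-wave
    power. Raises if the probe view does not fit inside the object grid.
    """
    obj_field = obj.field if isinstance(obj, GroundTruthObject) else np.asarray(obj)
    probe_field = probe.field if isinstance(probe, Probe) else np.asarray(probe)
    det = probe_field.shape[0]
    grid = obj_field.shape[0]
    cy, cx = view_corner(position, grid, det)
    if cy < 0 or cx < 0 or cy + det > grid or cx + det > grid:
        raise ValueError(
            f"probe view at position {position} falls outside the object grid"
        )
    exit_wave = probe_field.astype(np.complex128) * obj_field[
        cy : cy + det, cx : cx + det
    ].astype(np.complex128)
    far_field = sfft.fftshift(sfft.fft2(exit_wave, norm="ortho"))
    return np.abs(far_field) ** 2


def add_poisson(intensity: np.ndarray, seed: int) -> np.ndarray:
    """Element-wise Poisson draw with the given mean map; reproducible."""
    intensity = np.asarray(intensity)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("intensity must be finite")
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(intensity).astype(np.int64)


def _frame_seed_sequence(seed: int, position_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(position_index,))


def simulate_dataset(
    obj: GroundTruthObject,
    probe: Probe,
    scan: ScanPlan,
    geometry: ExperimentGeometry,
    seed: int = 0,
    noiseless: bool = False,
) -> DiffractionDataset:
    """Simulate one frame per scan position, in scan order.

    Each frame's Poisson noise comes from an independent substream keyed by
    ``(seed, position_index)``. With ``noiseless=True`` the exact intensities
    are stored instead (floating point, not integer counts).
    """
    frames: list[DiffractionFrame] = []
    for j, pos in enumerate(scan.positions):
        position = (float(pos[0]), float(pos[1]))
        intensity = simulate_intensity(obj, probe, position)
        if noiseless:
            counts = intensity
        else:
            rng = np.random.default_rng(_frame_seed_sequence(seed, j))
            counts = rng.poisson(intensity).astype(np.int64)
        frames.append(
            DiffractionFrame(counts=counts, position_index=j, position=position)
        )
    return DiffractionDataset(frames=frames, scan=scan, geometry=geometry, rng_seed=seed)


def simulate_scene_dataset(
    scene: Scene, seed: int = 0, noiseless: bool = False
) -> DiffractionDataset:
    """Convenience wrapper: simulate with the scene's ground-truth pair."""
    return simulate_dataset(
        scene.object_truth,
        scene.probe_truth,
        scene.scan,
        scene.geometry,
        seed=seed,
        noiseless=noiseless,
    )


def make_chunk_stream(
    dataset: DiffractionDataset | int,
    chunk_size: int = 25,
    delay: float = 0.6,
) -> ChunkStream:
    """Partition a dataset into arrival chunks on the logical clock.

    Chunk ``c`` covers frames ``[c*chunk_size, ...)`` and becomes available
    when its last frame has been produced, i.e. at
    ``(last_index + 1) * delay`` seconds.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    n = dataset if isinstance(dataset, int) else dataset.n_frames
    n_chunks = math.ceil(n / chunk_size)
    chunks = [range(c * chunk_size, min((c + 1) * chunk_size, n)) for c in range(n_chunks)]
    arrivals = [(ch.stop) * delay for ch in chunks]
    return ChunkStream(
        chunk_size=chunk_size,
        inter_frame_delay=delay,
        chunks=chunks,
        arrival_times=arrivals,
    )
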