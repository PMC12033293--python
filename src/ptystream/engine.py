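"""Iterative ptychographic reconstruction: Difference Map and Error Reduction.

Both algorithms alternate between two constraints. The Fourier (modulus)
projection replaces the modulus of each propagated exit wave with the square
root of the measured counts while keeping the phase. The overlap projection
rebuilds a single consistent object (and, after a short warm-up, probe) from
all exit waves by the standard least-squares accumulation

    O <- sum_j P* psi_j / (sum_j |P|^2 + eps)        (at each view)
    P <- sum_j O_j* psi_j / (sum_j |O_j|^2 + eps)

Error Reduction applies the Fourier projection to ``P * O_j`` directly;
the Difference Map uses the update ``psi <- psi + PF(2 P O_j - psi) - P O_j``
which escapes the stagnation ER is prone to. The engine mixes the two in
deterministic blocks of ten iterations (eight DM then two ER by default).

The engine is fully deterministic: it contains no randomness, runs in single
precision with double-precision accumulations, and supports a growing active
frame set so that streaming (real-time) reconstruction reuses exactly the
same iteration code as offline reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .scene import Probe, Scene
from .simulate import ChunkStream, DiffractionDataset, view_corner


@dataclass(frozen=True)
class EngineConfig:
    """Reconstruction parameters.

    ``dm_fraction``/``er_fraction`` set the DM/ER mix (per block of ten
    iterations). ``start_after_frames`` is the number of received frames
    after which iterations may begin: the full scan for offline runs, 1 for
    streaming runs (i.e. start right after the first chunk).
    ``iterations_per_interval`` is the number of iterations run between
    chunk arrivals in streaming mode (mode ``per_interval``); mode
    ``schedule_list`` takes an explicit per-interval list instead. After the
    last chunk, ``post_load_iterations`` more iterations run and the total is
    rounded to the nearest ``round_total_to`` (ties round up).
    """

    dm_fraction: float = 0.8
    er_fraction: float = 0.2
    start_after_frames: int = 1
    chunk_iterations_mode: str = "per_interval"
    iterations_per_interval: int = 10
    schedule_list: tuple[int, ...] | None = None
    post_load_iterations: int = 100
    round_total_to: int = 10
    probe_update_start: int = 120
    fourier_eps: float = 1e-12
    overlap_eps_rel: float = 1e-8
    illum_mask_rel: float = 1e-2
    object_inertia: float = 1e-2
    probe_inertia: float = 1e-4
    probe_support_fraction: float | None = None
    overlap_inner_iterations: int = 3
    overlap_converge_tol: float = 1e-3
    recenter_probe: bool = True
    recenter_threshold: float = 0.75
    object_amplitude_clip: float | None = 1.0
    fourier_relax_sigmas: float | None = None
    snapshot_stride: int | None = None
    snapshot_side: int | None = None

    def __post_init__(self) -> None:
        if abs(self.dm_fraction + self.er_fraction - 1.0) > 1e-12:
            raise ValueError("dm_fraction + er_fraction must equal 1")
        for name in (
            "start_after_frames",
            "iterations_per_interval",
            "post_load_iterations",
            "round_total_to",
            "probe_update_start",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class InitialEstimates:
    """Starting object (unit amplitude, uniform phase) and probe."""

    object: np.ndarray
    probe: np.ndarray


def make_initial_estimates(scene: Scene) -> InitialEstimates:
    """Unit-amplitude zero-phase object plus the scene's initial probe."""
    obj = np.ones(scene.object_truth.field.shape, dtype=np.complex64)
    return InitialEstimates(object=obj, probe=scene.probe_init.field.astype(np.complex64))


class _Workspace:
    """Precomputed per-dataset arrays: sqrt-count amplitudes and view corners."""

    def __init__(self, dataset: DiffractionDataset, grid_side: int):
        det = dataset.frames[0].counts.shape[0]
        n = dataset.n_frames
        self.det = det
        self.n_frames = n
        self.amplitudes = np.empty((n, det, det), dtype=np.float32)
        self.corners = np.empty((n, 2), dtype=np.int64)
        # scratch buffers reused every iteration to avoid large allocations
        self.buf_views = np.empty((n, det, det), dtype=np.complex64)
        self.buf_arg = np.empty((n, det, det), dtype=np.complex64)
        for j, frame in enumerate(dataset.frames):
            # counts are stored centred; the engine works in FFT order
            self.amplitudes[j] = sfft.ifftshift(
                np.sqrt(np.maximum(frame.counts, 0)).astype(np.float32)
            )
            cy, cx = view_corner(frame.position, grid_side, det)
            if cy < 0 or cx < 0 or cy + det > grid_side or cx + det > grid_side:
                raise ValueError(
                    f"frame {j} view at {frame.position} outside the object grid"
                )
            self.corners[j] = (cy, cx)


@dataclass
class ReconstructionState:
    """Mutable state of one reconstruction run."""

    object_estimate: np.ndarray
    probe_estimate: np.ndarray
    exit_waves: np.ndarray  # (n_frames, det, det) complex64; first n_active valid
    n_active: int
    iteration: int
    config: EngineConfig
    workspace: _Workspace
    frames_loaded_history: list[tuple[int, int]] = field(default_factory=list)
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    iterations_at_last_load: int | None = None

    @property
    def active_frames(self) -> range:
        return range(self.n_active)


def initialize_state(
    dataset: DiffractionDataset, initial: InitialEstimates, config: EngineConfig
) -> ReconstructionState:
    grid_side = initial.object.shape[0]
    ws = _Workspace(dataset, grid_side)
    return ReconstructionState(
        object_estimate=initial.object.astype(np.complex64).copy(),
        probe_estimate=initial.probe.astype(np.complex64).copy(),
        exit_waves=np.zeros((ws.n_frames, ws.det, ws.det), dtype=np.complex64),
        n_active=0,
        iteration=0,
        config=config,
        workspace=ws,
    )


def activate_frames(state: ReconstructionState, n_active: int) -> None:
    """Grow the active set; new exit waves start at ``P * O_view``."""
    ws = state.workspace
    if n_active < state.n_active:
        raise ValueError("active frame set cannot shrink")
    det = ws.det
    for j in range(state.n_active, n_active):
        cy, cx = ws.corners[j]
        state.exit_waves[j] = (
            state.probe_estimate
            * state.object_estimate[cy : cy + det, cx : cx + det]
        )
    state.n_active = n_active


def _fourier_project_batch(
    batch: np.ndarray,
    amplitudes: np.ndarray,
    eps: float,
    overwrite: bool = False,
    relax_sigmas: float | None = None,
) -> np.ndarray:
    """Replace FFT moduli by measured amplitudes (phase kept), batched.

    With ``relax_sigmas`` set, the modulus is only pulled to the edge of the
    band ``amplitude +- relax_sigmas * 0.5`` (0.5 being the standard
    deviation of sqrt(counts) under Poisson statistics), i.e. moduli already
    inside the photon-noise band are left alone.
    """
    spectra = sfft.fft2(batch, norm="ortho", workers=1, overwrite_x=overwrite)
    mag = np.abs(spectra)
    unconstrained = mag < eps
    if relax_sigmas:
        half_band = np.float32(0.5 * relax_sigmas)
        target = np.clip(mag, amplitudes - half_band, amplitudes + half_band)
    else:
        target = amplitudes
    np.maximum(mag, np.float32(1e-30), out=mag)
    np.divide(target, mag, out=mag)
    mag[unconstrained] = 1.0
    spectra *= mag
    return sfft.ifft2(spectra, norm="ortho", workers=1, overwrite_x=True)


def fourier_projection(
    exit_wave: np.ndarray, counts: np.ndarray, eps: float = 1e-12
) -> np.ndarray:
    """Fourier-modulus projection of a single exit wave.

    ``counts`` are centred photon counts; the result keeps the propagated
    phase and takes modulus ``sqrt(counts)``, except where the FFT modulus is
    below ``eps``, where it is left unchanged.
    """
    exit_wave = np.asarray(exit_wave)
    counts = np.asarray(counts)
    if exit_wave.shape != counts.shape:
        raise ValueError(
            f"shape mismatch: exit wave {exit_wave.shape} vs counts {counts.shape}"
        )
    amps = sfft.ifftshift(np.sqrt(np.maximum(counts, 0))).astype(
        np.float32 if exit_wave.dtype == np.complex64 else np.float64
    )
    return _fourier_project_batch(exit_wave[None], amps[None], eps)[0]


def _gather_views(obj: np.ndarray, corners: np.ndarray, det: int) -> np.ndarray:
    views = np.empty((len(corners), det, det), dtype=obj.dtype)
    for j, (cy, cx) in enumerate(corners):
        views[j] = obj[cy : cy + det, cx : cx + det]
    return views


def _object_update(state: ReconstructionState) -> None:
    ws = state.workspace
    cfg = state.config
    det = ws.det
    n = state.n_active
    corners = ws.corners[:n]
    psi = state.exit_waves[:n]
    probe = state.probe_estimate

    contrib = np.conj(probe)[None, :, :] * psi
    probe_sq = (np.abs(probe) ** 2).astype(np.float64)
    grid = state.object_estimate.shape[0]
    num = np.zeros((grid, grid), dtype=np.complex128)
    den = np.zeros((grid, grid), dtype=np.float64)
    for j, (cy, cx) in enumerate(corners):
        num[cy : cy + det, cx : cx + det] += contrib[j]
        den[cy : cy + det, cx : cx + det] += probe_sq
    den_max = den.max()
    if cfg.object_inertia > 0:
        # damped (inertial) update: blends toward the previous object with a
        # weight tied to the peak illumination; preserves consistent fixed
        # points exactly (num == den * O there) and degrades gracefully to a
        # no-op where the illumination vanishes, so no mask is needed
        lam = cfg.object_inertia * den_max
        num += lam * state.object_estimate.astype(np.complex128)
        state.object_estimate[...] = (num / (den + lam)).astype(np.complex64)
    else:
        mask = den > cfg.illum_mask_rel * den_max
        new_obj = (num / (den + cfg.overlap_eps_rel * den_max)).astype(np.complex64)
        state.object_estimate[mask] = new_obj[mask]
    clip = cfg.object_amplitude_clip
    if clip is not None:
        # a transmission object only attenuates; clamping the amplitude
        # suppresses the amplitude-overshoot stagnation mode
        obj = state.object_estimate
        amp = np.abs(obj)
        over = amp > clip
        if np.any(over):
            obj[over] *= (clip / amp[over]).astype(np.float32)


def _probe_update(state: ReconstructionState) -> float:
    """Least-squares probe from the exit waves; returns the relative change."""
    ws = state.workspace
    cfg = state.config
    det = ws.det
    n = state.n_active
    corners = ws.corners[:n]
    psi = state.exit_waves[:n]
    obj = state.object_estimate
    pnum = np.zeros((det, det), dtype=np.complex128)
    pden = np.zeros((det, det), dtype=np.float64)
    for j, (cy, cx) in enumerate(corners):
        view = obj[cy : cy + det, cx : cx + det]
        pnum += np.conj(view) * psi[j]
        view_abs = np.abs(view)
        pden += view_abs * view_abs
    lam = (
        cfg.probe_inertia if cfg.probe_inertia > 0 else cfg.overlap_eps_rel
    ) * pden.max()
    if cfg.probe_inertia > 0:
        pnum += lam * state.probe_estimate.astype(np.complex128)
    new_probe = (pnum / (pden + lam)).astype(np.complex64)
    if cfg.probe_support_fraction is not None:
        new_probe *= _probe_support(state, det)
    old = state.probe_estimate
    change = float(
        np.linalg.norm(new_probe - old) / max(np.linalg.norm(old), 1e-30)
    )
    state.probe_estimate = new_probe
    return change


def _probe_support(state: ReconstructionState, det: int) -> np.ndarray:
    """Centred circular support mask clamping the probe's spatial extent.

    Constraining the probe to a disc covering ``probe_support_fraction`` of
    the frame area suppresses runaway tails during joint retrieval; cached
    on the state's workspace.
    """
    ws = state.workspace
    mask = getattr(ws, "_support_mask", None)
    if mask is None:
        frac = state.config.probe_support_fraction
        radius = frac * det / 2.0  # support diameter as a fraction of the frame
        c = (det - 1) / 2.0
        yy, xx = np.mgrid[0:det, 0:det]
        mask = (np.hypot(yy - c, xx - c) <= radius).astype(np.float32)
        ws._support_mask = mask
    return mask


def overlap_update(state: ReconstructionState) -> None:
    """Rebuild object (and probe, past the warm-up) from the exit waves.

    Object and probe are alternated up to ``overlap_inner_iterations`` times
    per call (block coordinate descent on the shared least-squares
    objective, the scheme production engines use to keep joint retrieval
    stable), stopping early once the probe's relative change drops below
    ``overlap_converge_tol``. While the probe is frozen (before
    ``probe_update_start``) a single object pass suffices and the inner
    loop collapses to it.

    Accumulations run in double precision; the object is only updated where
    the summed illumination exceeds ``illum_mask_rel`` of its maximum, so
    unilluminated pixels keep their current value.
    """
    if state.n_active < 1:
        raise ValueError("overlap update requires at least one active frame")
    cfg = state.config
    update_probe = state.iteration >= cfg.probe_update_start
    inner = max(1, cfg.overlap_inner_iterations) if update_probe else 1
    for _ in range(inner):
        _object_update(state)
        if not update_probe:
            break
        if _probe_update(state) < cfg.overlap_converge_tol:
            break


def _recenter_probe(state: ReconstructionState) -> None:
    """Pin the probe's intensity centroid to the frame centre.

    Probe, object and exit waves are translated jointly by integer pixels, a
    pure relabelling that leaves the data fit untouched. This removes the
    lateral-shift ambiguity, which otherwise lets a growing-dataset run
    drift to a shifted (but equivalent) solution during early acquisition.
    """
    probe = state.probe_estimate
    det = probe.shape[0]
    intensity = np.abs(probe) ** 2
    total = intensity.sum()
    if total <= 0:
        return
    idx = np.arange(det)
    cy = float((intensity.sum(axis=1) * idx).sum() / total)
    cx = float((intensity.sum(axis=0) * idx).sum() / total)
    target = (det - 1) / 2.0
    off_y, off_x = target - cy, target - cx
    thresh = state.config.recenter_threshold
    if abs(off_y) < thresh and abs(off_x) < thresh:
        return
    dy, dx = int(round(off_y)), int(round(off_x))
    if dy == 0 and dx == 0:
        return
    state.probe_estimate = np.roll(probe, (dy, dx), axis=(0, 1))
    state.object_estimate = np.roll(state.object_estimate, (dy, dx), axis=(0, 1))
    n = state.n_active
    state.exit_waves[:n] = np.roll(state.exit_waves[:n], (dy, dx), axis=(1, 2))


def _one_iteration(state: ReconstructionState, kind: str) -> None:
    ws = state.workspace
    cfg = state.config
    n = state.n_active
    if n < 1:
        raise ValueError("iteration requires at least one active frame")
    det = ws.det
    corners = ws.corners[:n]
    obj = state.object_estimate
    views = ws.buf_views[:n]
    for j, (cy, cx) in enumerate(corners):
        views[j] = obj[cy : cy + det, cx : cx + det]
    views *= state.probe_estimate  # now P * O_j
    psi = state.exit_waves
    if kind == "dm":
        arg = ws.buf_arg[:n]
        np.multiply(views, np.complex64(2), out=arg)
        arg -= psi[:n]
        corrected = _fourier_project_batch(
            arg, ws.amplitudes[:n], cfg.fourier_eps, overwrite=True,
            relax_sigmas=cfg.fourier_relax_sigmas
        )
        psi[:n] += corrected
        psi[:n] -= views
    elif kind == "er":
        psi[:n] = _fourier_project_batch(
            views, ws.amplitudes[:n], cfg.fourier_eps, overwrite=True,
            relax_sigmas=cfg.fourier_relax_sigmas
        )
    else:
        raise ValueError(f"unknown iteration kind {kind!r}")
    overlap_update(state)
    if cfg.recenter_probe and state.iteration >= cfg.probe_update_start:
        _recenter_probe(state)
    state.iteration += 1
    state.frames_loaded_history.append((state.iteration, n))
    stride = cfg.snapshot_stride
    if stride and state.iteration % stride == 0:
        state.snapshots[state.iteration] = _snapshot(state)


def _snapshot(state: ReconstructionState) -> np.ndarray:
    side = state.config.snapshot_side
    obj = state.object_estimate
    if side is None or side >= obj.shape[0]:
        return obj.copy()
    lo = obj.shape[0] // 2 - side // 2
    return obj[lo : lo + side, lo : lo + side].copy()


def iteration_kind(iteration: int, config: EngineConfig) -> str:
    """Deterministic DM/ER interleave: per block of ten, DM first."""
    n_dm = int(round(10 * config.dm_fraction))
    return "dm" if (iteration % 10) < n_dm else "er"


def dm_iteration(
    state: ReconstructionState, dataset: DiffractionDataset | None = None
) -> ReconstructionState:
    """One Difference Map iteration over the active frames (in place)."""
    _one_iteration(state, "dm")
    return state


def er_iteration(
    state: ReconstructionState, dataset: DiffractionDataset | None = None
) -> ReconstructionState:
    """One Error Reduction iteration over the active frames (in place)."""
    _one_iteration(state, "er")
    return state


def _run_iterations(state: ReconstructionState, count: int) -> None:
    for _ in range(count):
        _one_iteration(state, iteration_kind(state.iteration, state.config))


def total_iterations_for(config: EngineConfig, iterations_at_last_load: int) -> int:
    """Post-acquisition total: add the extra iterations, round to nearest ten.

    Rounding granularity is ``round_total_to``; ties round up.
    """
    if iterations_at_last_load < 0:
        raise ValueError("iterations_at_last_load must be >= 0")
    raw = iterations_at_last_load + config.post_load_iterations
    r = config.round_total_to
    if r <= 1:
        return raw
    return ((raw + r // 2) // r) * r


def run_offline(
    dataset: DiffractionDataset,
    initial: InitialEstimates,
    config: EngineConfig,
    total_iterations: int,
) -> ReconstructionState:
    """Reconstruct with every frame active from the start."""
    if total_iterations < 1:
        raise ValueError("total_iterations must be >= 1")
    state = initialize_state(dataset, initial, config)
    activate_frames(state, dataset.n_frames)
    state.iterations_at_last_load = 0
    _run_iterations(state, total_iterations)
    return state


def realtime_interval_iterations(stream: ChunkStream, config: EngineConfig) -> list[int]:
    """Iterations to run after each chunk arrival except the last."""
    n_chunks = len(stream.chunks)
    # index of the chunk whose arrival satisfies start_after_frames
    start_chunk = 0
    for c, ch in enumerate(stream.chunks):
        if ch.stop >= config.start_after_frames:
            start_chunk = c
            break
    else:
        raise ValueError("start_after_frames exceeds the number of frames")
    n_intervals = n_chunks - 1 - start_chunk
    if config.chunk_iterations_mode == "schedule_list":
        if config.schedule_list is None or len(config.schedule_list) != n_intervals:
            raise ValueError(
                f"schedule_list must provide {n_intervals} interval counts"
            )
        counts = list(config.schedule_list)
    elif config.chunk_iterations_mode == "per_interval":
        counts = [config.iterations_per_interval] * n_intervals
    else:
        raise ValueError(
            f"unknown chunk_iterations_mode {config.chunk_iterations_mode!r}"
        )
    if n_intervals > 0 and sum(counts) == 0:
        raise ValueError("streaming schedule runs zero iterations in every interval")
    return counts


def run_realtime(
    stream: ChunkStream,
    dataset: DiffractionDataset,
    initial: InitialEstimates,
    config: EngineConfig,
) -> ReconstructionState:
    """Reconstruct on the growing dataset delivered by ``stream``.

    Iterations begin once at least ``start_after_frames`` frames have
    arrived, run ``iterations_per_interval`` (or the explicit schedule)
    between chunk arrivals, and finish with the post-acquisition block whose
    total is given by :func:`total_iterations_for`. A single-chunk stream
    degenerates to an offline run.
    """
    if stream.n_frames != dataset.n_frames:
        raise ValueError("stream does not partition the dataset")
    interval_counts = realtime_interval_iterations(stream, config)
    start_chunk = len(stream.chunks) - 1 - len(interval_counts)

    state = initialize_state(dataset, initial, config)
    activate_frames(state, stream.chunks[start_chunk].stop)
    for c, count in enumerate(interval_counts, start=start_chunk):
        _run_iterations(state, count)
        activate_frames(state, stream.chunks[c + 1].stop)
    state.iterations_at_last_load = state.iteration
    total = total_iterations_for(config, state.iteration)
    _run_iterations(state, total - state.iteration)
    return state
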