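import numpy as np
import pytest

import ptystream as ps
from ptystream.engine import _Workspace
from ptystream.simulate import view_corner


def naive_dft2(field):
    n = field.shape[0]
    j = np.arange(n)
    w = np.exp(-2j * np.pi * np.outer(j, j) / n)
    return w @ field @ w / n


def naive_idft2(field):
    n = field.shape[0]
    j = np.arange(n)
    w = np.exp(2j * np.pi * np.outer(j, j) / n)
    return w @ field @ w / n


class TestFourierProjection:
    def test_consistent_data_is_fixed_point(self):
        rng = np.random.default_rng(2)
        psi = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        counts = np.abs(np.fft.fftshift(np.fft.fft2(psi, norm="ortho"))) ** 2
        out = ps.fourier_projection(psi, counts)
        np.testing.assert_allclose(out, psi, rtol=0, atol=1e-6 * np.abs(psi).max())

    def test_zero_counts_give_zero_wave(self):
        rng = np.random.default_rng(3)
        psi = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        out = ps.fourier_projection(psi, np.zeros((8, 8)))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(4)
        psi = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        counts = rng.uniform(0.5, 4.0, (4, 4))
        expected_spec = naive_dft2(psi)
        amps = np.fft.ifftshift(np.sqrt(counts))
        expected = naive_idft2(amps * expected_spec / np.abs(expected_spec))
        out = ps.fourier_projection(psi, counts)
        np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ps.fourier_projection(np.ones((4, 4), complex), np.ones((8, 8)))


def _toy_state(obj, probe, positions, counts_shape=None, config=None):
    """Build a state around hand-made exit waves on a small grid."""
    from ptystream.scene import ScanPlan
    from ptystream.simulate import DiffractionDataset, DiffractionFrame

    det = probe.shape[0]
    frames = [
        DiffractionFrame(
            counts=np.zeros((det, det)), position_index=j, position=tuple(p)
        )
        for j, p in enumerate(positions)
    ]
    scan = ScanPlan(
        positions=np.asarray(positions, float),
        step=1.0,
        n_points=len(positions),
    )
    geometry = ps.make_geometry(8.0, det, 75e-6, 1.0)
    dataset = DiffractionDataset(
        frames=frames, scan=scan, geometry=geometry, rng_seed=0
    )
    config = config or ps.EngineConfig(
        probe_update_start=10**9, object_inertia=0.0, probe_inertia=0.0
    )
    initial = ps.InitialEstimates(
        object=obj.astype(np.complex64), probe=probe.astype(np.complex64)
    )
    state = ps.initialize_state(dataset, initial, config)
    ps.activate_frames(state, len(positions))
    return state


class TestOverlapUpdate:
    def test_single_frame_exact_division(self):
        rng = np.random.default_rng(6)
        obj = np.exp(1j * rng.uniform(-1, 1, (8, 8)))
        probe = rng.uniform(0.5, 1.5, (4, 4)) * np.exp(
            1j * rng.uniform(-1, 1, (4, 4))
        )
        state = _toy_state(np.ones((8, 8)), probe, [(0.0, 0.0)])
        cy, cx = view_corner((0.0, 0.0), 8, 4)
        state.exit_waves[0] = (probe * obj[cy : cy + 4, cx : cx + 4]).astype(
            np.complex64
        )
        ps.overlap_update(state)
        np.testing.assert_allclose(
            state.object_estimate[cy : cy + 4, cx : cx + 4],
            obj[cy : cy + 4, cx : cx + 4],
            rtol=1e-5,
        )

    def test_matches_normal_equations_oracle(self):
        """Two overlapping consistent frames equal a per-pixel least-squares solve."""
        rng = np.random.default_rng(7)
        obj_true = rng.uniform(0.5, 1.0, (6, 6)) * np.exp(
            1j * rng.uniform(-2, 2, (6, 6))
        )
        probe = rng.uniform(0.5, 1.5, (4, 4)) * np.exp(
            1j * rng.uniform(-1, 1, (4, 4))
        )
        positions = [(0.0, 0.0), (0.0, 1.0)]
        state = _toy_state(np.ones((6, 6)), probe, positions)
        corners = [view_corner(p, 6, 4) for p in positions]
        for j, (cy, cx) in enumerate(corners):
            state.exit_waves[j] = (
                probe * obj_true[cy : cy + 4, cx : cx + 4]
            ).astype(np.complex64)
        ps.overlap_update(state)

        # independent per-pixel normal equations: O = sum P* psi / sum |P|^2
        num = np.zeros((6, 6), complex)
        den = np.zeros((6, 6))
        for j, (cy, cx) in enumerate(corners):
            num[cy : cy + 4, cx : cx + 4] += np.conj(probe) * np.asarray(
                state.exit_waves[j], dtype=complex
            )
            den[cy : cy + 4, cx : cx + 4] += np.abs(probe) ** 2
        mask = den > 1e-2 * den.max()
        expected = np.where(mask, num / np.maximum(den, 1e-300), 1.0)
        np.testing.assert_allclose(
            state.object_estimate[mask], expected[mask], rtol=1e-6
        )

    def test_probe_frozen_before_warmup(self):
        rng = np.random.default_rng(8)
        probe = (rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))).astype(
            np.complex64
        )
        state = _toy_state(np.ones((8, 8)), probe, [(0.0, 0.0)])
        state.exit_waves[0] = probe
        before = state.probe_estimate.copy()
        ps.overlap_update(state)  # iteration 0 < probe_update_start
        np.testing.assert_array_equal(state.probe_estimate, before)

    def test_empty_active_set_rejected(self):
        state = _toy_state(np.ones((8, 8)), np.ones((4, 4)), [(0.0, 0.0)])
        state.n_active = 0
        with pytest.raises(ValueError, match="active"):
            ps.overlap_update(state)


class TestFixedPoints:
    @pytest.mark.parametrize("step", [ps.dm_iteration, ps.er_iteration])
    def test_consistent_solution_is_fixed_point(self, truth_state, step):
        """At a noiseless solution, one DM/ER iteration changes nothing."""
        state = truth_state()
        before = state.object_estimate.copy()
        step(state)
        delta = np.linalg.norm(state.object_estimate - before)
        assert delta / np.linalg.norm(before) < 1e-6


class TestIterationMix:
    def test_eight_dm_two_er_per_block(self):
        cfg = ps.EngineConfig()
        kinds = [ps.iteration_kind(i, cfg) for i in range(20)]
        assert kinds[:10] == ["dm"] * 8 + ["er"] * 2
        assert kinds[10:] == ["dm"] * 8 + ["er"] * 2

    def test_fraction_respected_for_other_mixes(self):
        cfg = ps.EngineConfig(dm_fraction=0.5, er_fraction=0.5)
        kinds = [ps.iteration_kind(i, cfg) for i in range(10)]
        assert kinds.count("dm") == 5


class TestTotalIterations:
    @pytest.mark.parametrize(
        "at_load,expected",
        [(47, 150), (0, 100), (55, 160), (48, 150), (52, 150)],
    )
    def test_rounding_to_nearest_ten_ties_up(self, at_load, expected):
        cfg = ps.EngineConfig(post_load_iterations=100, round_total_to=10)
        assert ps.total_iterations_for(cfg, at_load) == expected

    def test_no_rounding_when_granularity_one(self):
        cfg = ps.EngineConfig(post_load_iterations=100, round_total_to=1)
        assert ps.total_iterations_for(cfg, 47) == 147


class TestRunners:
    def test_zero_total_iterations_rejected(self, scaled_noiseless_dataset, scaled_scene):
        initial = ps.make_initial_estimates(scaled_scene)
        with pytest.raises(ValueError):
            ps.run_offline(
                scaled_noiseless_dataset, initial, ps.EngineConfig(), 0
            )

    def test_offline_deterministic(self, scaled_noiseless_dataset, scaled_scene):
        initial = ps.make_initial_estimates(scaled_scene)
        cfg = ps.EngineConfig()
        a = ps.run_offline(scaled_noiseless_dataset, initial, cfg, 12)
        b = ps.run_offline(scaled_noiseless_dataset, initial, cfg, 12)
        np.testing.assert_array_equal(a.object_estimate, b.object_estimate)
        np.testing.assert_array_equal(a.probe_estimate, b.probe_estimate)

    def test_noiseless_convergence_on_scaled_scene(
        self, scaled_scene, scaled_noiseless_dataset
    ):
        initial = ps.make_initial_estimates(scaled_scene)
        state = ps.run_offline(
            scaled_noiseless_dataset, initial, ps.EngineConfig(), 200
        )
        report = ps.compare_pair(
            scaled_scene.object_truth.field,
            state.object_estimate,
            ps.CropSpec(side=40),
        )
        assert report.nmse <= 1e-3

    def test_realtime_starts_after_first_chunk(
        self, scaled_scene, scaled_noisy_dataset
    ):
        stream = ps.make_chunk_stream(scaled_noisy_dataset, chunk_size=25)
        initial = ps.make_initial_estimates(scaled_scene)
        cfg = ps.EngineConfig(
            start_after_frames=1, iterations_per_interval=2, post_load_iterations=10
        )
        state = ps.run_realtime(stream, scaled_noisy_dataset, initial, cfg)
        history = state.frames_loaded_history
        assert history[0][1] == 25  # first chunk active at the first iteration
        loads = [n for _, n in history]
        assert loads == sorted(loads)
        assert loads[-1] == scaled_noisy_dataset.n_frames

    def test_single_chunk_stream_matches_offline_bitwise(
        self, scaled_scene, scaled_noisy_dataset
    ):
        initial = ps.make_initial_estimates(scaled_scene)
        cfg = ps.EngineConfig(post_load_iterations=30, round_total_to=10)
        stream = ps.make_chunk_stream(
            scaled_noisy_dataset, chunk_size=scaled_noisy_dataset.n_frames
        )
        rt = ps.run_realtime(stream, scaled_noisy_dataset, initial, cfg)
        off = ps.run_offline(scaled_noisy_dataset, initial, cfg, rt.iteration)
        np.testing.assert_array_equal(rt.object_estimate, off.object_estimate)
        np.testing.assert_array_equal(rt.probe_estimate, off.probe_estimate)

    def test_all_zero_interval_schedule_rejected(
        self, scaled_scene, scaled_noisy_dataset
    ):
        stream = ps.make_chunk_stream(scaled_noisy_dataset, chunk_size=10)
        initial = ps.make_initial_estimates(scaled_scene)
        cfg = ps.EngineConfig(iterations_per_interval=0)
        with pytest.raises(ValueError, match="zero iterations"):
            ps.run_realtime(stream, scaled_noisy_dataset, initial, cfg)


def test_toy_scene_converges_to_machine_level():
    """Dense 9-frame scan of an 8 px probe: mixed DM/ER reaches the oracle
    solution (probe known, noiseless)."""
    rng = np.random.default_rng(12)
    grid, det = 16, 8
    yy, xx = np.mgrid[0:det, 0:det]
    # broad, well-conditioned illumination: weak probe tails leave corner
    # pixels underdetermined and stall the projection iterations
    probe = np.exp(
        -((yy - 3.5) ** 2 + (xx - 3.5) ** 2) / 32.0
    ) * np.exp(1j * 0.3 * (xx - yy))
    smooth = rng.normal(size=(grid, grid))
    from scipy.ndimage import gaussian_filter

    obj_true = np.exp(
        0.08j * gaussian_filter(smooth, 2) * 10 - 0.05 * np.abs(gaussian_filter(smooth, 3)) * 2
    )
    positions = [(dy, dx) for dy in (-2.0, 0.0, 2.0) for dx in (-2.0, 0.0, 2.0)]

    from ptystream.scene import GroundTruthObject, Probe, ScanPlan
    from ptystream.simulate import DiffractionDataset, DiffractionFrame, simulate_intensity

    frames = []
    for j, p in enumerate(positions):
        inten = simulate_intensity(obj_true, probe, p)
        frames.append(DiffractionFrame(counts=inten, position_index=j, position=p))
    scan = ScanPlan(positions=np.asarray(positions), step=2.0, n_points=9)
    geometry = ps.make_geometry(8.0, det, 75e-6, 1.0)
    dataset = DiffractionDataset(frames=frames, scan=scan, geometry=geometry, rng_seed=0)

    cfg = ps.EngineConfig(probe_update_start=10**9)
    initial = ps.InitialEstimates(
        object=np.ones((grid, grid), np.complex64), probe=probe.astype(np.complex64)
    )
    state = ps.run_offline(dataset, initial, cfg, 200)
    lo = grid // 2 - 4
    crop = slice(lo, lo + 8)
    value, _ = ps.nmse(obj_true[crop, crop], state.object_estimate[crop, crop])
    assert value <= 1e-6
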