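import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptystream as ps


def _ramp(shape, u, v):
    ny, nx = shape
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    return np.exp(1j * (u * x[None, :] + v * y[:, None]))


class TestRemovePhaseRamp:
    def test_pure_ramp_recovered(self):
        field = np.full((64, 64), 2.0, complex) * _ramp((64, 64), 0.1, 0.05)
        out, slopes = ps.remove_phase_ramp(field, passes=3)
        assert slopes[0][0] == pytest.approx(0.1, abs=1e-6)
        assert slopes[0][1] == pytest.approx(0.05, abs=1e-6)
        assert abs(slopes[-1][0]) < 1e-9 and abs(slopes[-1][1]) < 1e-9

    def test_ramp_free_field_unchanged_up_to_global_phase(self, star_crop):
        out, slopes = ps.remove_phase_ramp(star_crop, passes=1)
        # the estimator's structural bias is small for this phantom
        ratio = out / star_crop
        assert np.std(np.angle(ratio)) < 0.05

    def test_second_pass_correction_shrinks(self, star_crop):
        ramped = star_crop * _ramp(star_crop.shape, 0.2, -0.15)
        _, slopes = ps.remove_phase_ramp(ramped, passes=3, tol=0.0)
        first = np.hypot(*slopes[0])
        second = np.hypot(*slopes[1])
        assert second < 0.1 * first

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError):
            ps.remove_phase_ramp(np.zeros((8, 8), complex))


class TestRegister:
    def test_identity(self, star_crop):
        shift, phase = ps.register(star_crop, star_crop)
        assert shift == (0.0, 0.0)
        assert phase == pytest.approx(0.0, abs=1e-12)

    def test_integer_shift_recovered_exactly(self, star_crop):
        moved = np.roll(star_crop, (3, -2), axis=(0, 1))
        shift, _ = ps.register(star_crop, moved)
        assert shift == (-3.0, 2.0)
        aligned = ps.apply_shift(moved, shift)
        np.testing.assert_allclose(aligned, star_crop, atol=1e-10)

    def test_global_phase_recovered(self, star_crop):
        rotated = np.exp(1j * 0.7) * star_crop
        shift, phase = ps.register(star_crop, rotated)
        assert shift == (0.0, 0.0)
        assert phase == pytest.approx(0.7, abs=1e-3)

    def test_degenerate_input_rejected(self, star_crop):
        with pytest.raises(ValueError):
            ps.register(star_crop, np.zeros_like(star_crop))


class TestScaleAmplitude:
    def test_half_amplitude_scale_two(self, star_crop):
        scaled, scale = ps.scale_amplitude(star_crop, star_crop / 2)
        assert scale == pytest.approx(2.0)
        np.testing.assert_allclose(np.abs(scaled), np.abs(star_crop), rtol=1e-12)

    def test_identity_scale_one(self, star_crop):
        _, scale = ps.scale_amplitude(star_crop, star_crop)
        assert scale == pytest.approx(1.0)

    def test_two_by_two_hand_example(self):
        ref = np.array([[1, 2], [3, 4]], complex)
        tgt = np.full((2, 2), 2.0, complex)
        _, scale = ps.scale_amplitude(ref, tgt)
        assert scale == pytest.approx((0.5 + 1.0 + 1.5 + 2.0) / 4)

    def test_zero_target_pixel_rejected(self):
        tgt = np.ones((2, 2), complex)
        tgt[0, 0] = 0
        with pytest.raises(ValueError):
            ps.scale_amplitude(np.ones((2, 2), complex), tgt)


class TestOdDifference:
    def test_identical_arrays_zero(self, star_crop):
        np.testing.assert_allclose(ps.od_difference(star_crop, star_crop), 0.0)

    def test_factor_e_gives_unit_map(self, star_crop):
        out = ps.od_difference(star_crop, np.e * star_crop)
        np.testing.assert_allclose(out, 1.0, rtol=1e-10)

    def test_scalar_spot_check(self):
        out = ps.od_difference(np.array([[0.25]], complex), np.array([[0.5]], complex))
        assert out[0, 0] == pytest.approx(np.log(2), rel=1e-12)


class TestPhaseDifference:
    def test_identical_zero(self, star_crop):
        np.testing.assert_allclose(
            ps.phase_difference(star_crop, star_crop, 0.0), 0.0, atol=1e-12
        )

    def test_wrap_above_pi(self):
        ref = np.array([[1.0 + 0j]])
        tgt = np.array([[np.exp(1j * (np.pi + 0.1))]])
        out = ps.phase_difference(ref, tgt, 0.0)
        assert out[0, 0] == pytest.approx(-np.pi + 0.1, abs=1e-12)

    def test_exact_compensation(self, star_crop):
        tgt = np.exp(2j) * star_crop
        out = ps.phase_difference(star_crop, tgt, 2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(
        dphi=st.floats(-np.pi, np.pi),
        phase_a=st.floats(-np.pi, np.pi),
        phase_b=st.floats(-np.pi, np.pi),
    )
    def test_result_always_within_pi(self, dphi, phase_a, phase_b):
        ref = np.array([[np.exp(1j * phase_a)]])
        tgt = np.array([[np.exp(1j * phase_b)]])
        out = ps.phase_difference(ref, tgt, dphi)
        assert -np.pi <= out[0, 0] <= np.pi


class TestNmse:
    def test_identity(self, star_crop):
        value, gamma = ps.nmse(star_crop, star_crop)
        assert value == pytest.approx(0.0, abs=1e-14)
        assert gamma == pytest.approx(1.0)

    def test_gamma_absorbs_scale_and_phase(self, star_crop):
        tgt = 3 * np.exp(1j * np.pi / 4) * star_crop
        value, gamma = ps.nmse(star_crop, tgt)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert gamma == pytest.approx((1 / 3) * np.exp(-1j * np.pi / 4))

    def test_two_pixel_hand_example(self):
        value, gamma = ps.nmse(np.array([1.0, 2.0], complex), np.array([1.0, 1.0], complex))
        assert gamma == pytest.approx(1.5)
        assert value == pytest.approx(0.1)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ps.nmse(np.zeros(4, complex), np.ones(4, complex))

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10**6))
    def test_gamma_minimises_over_complex_grid(self, seed):
        """The closed-form gamma beats every candidate on a complex grid."""
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=6) + 1j * rng.normal(size=6)
        tgt = rng.normal(size=6) + 1j * rng.normal(size=6)
        value, gamma = ps.nmse(ref, tgt)
        denom = np.sum(np.abs(ref) ** 2)
        for re in np.linspace(gamma.real - 1, gamma.real + 1, 11):
            for im in np.linspace(gamma.imag - 1, gamma.imag + 1, 11):
                cand = np.sum(np.abs(ref - (re + 1j * im) * tgt) ** 2) / denom
                assert cand >= value - 1e-12


class TestComparePair:
    def test_self_comparison_is_zero(self, star_crop):
        report = ps.compare_pair(star_crop, star_crop, ps.CropSpec(side=40))
        assert report.nmse == pytest.approx(0.0, abs=1e-12)
        assert report.mean_abs_od == pytest.approx(0.0, abs=1e-9)
        assert report.mean_abs_phase == pytest.approx(0.0, abs=1e-9)

    def test_pure_ambiguity_pair_fully_corrected(self, star_crop):
        tgt = star_crop * _ramp(star_crop.shape, 0.07, -0.04)
        tgt = np.roll(tgt, (2, -3), axis=(0, 1))
        tgt = 1.7 * np.exp(1j * 0.9) * tgt
        report = ps.compare_pair(star_crop, tgt, ps.CropSpec(side=32))
        assert report.nmse < 1e-6
        assert report.mean_abs_od < 1e-4
        assert report.mean_abs_phase < 1e-4

    def test_noise_level_reflected_in_nmse(self, star_crop):
        rng = np.random.default_rng(21)
        sigma = 0.01
        noise = sigma * (
            rng.normal(size=star_crop.shape) + 1j * rng.normal(size=star_crop.shape)
        ) / np.sqrt(2)
        crop = ps.CropSpec(side=40)
        report = ps.compare_pair(star_crop, star_crop + noise, crop)
        ref_c = crop.apply(star_crop)
        expected = sigma**2 * ref_c.size / np.sum(np.abs(ref_c) ** 2)
        assert report.nmse == pytest.approx(expected, rel=0.2)

    @pytest.mark.parametrize("u,v,dy,dx,scale,phi", [
        (0.0, 0.0, 0, 0, 1.0, 0.0),
        (0.05, -0.03, 1, 2, 0.6, 2.5),
        (-0.11, 0.08, -4, 3, 3.2, -1.2),
    ])
    def test_metrics_invariant_under_composed_ambiguities(
        self, star_crop, u, v, dy, dx, scale, phi
    ):
        base = ps.compare_pair(star_crop, star_crop, ps.CropSpec(side=32))
        tgt = scale * np.exp(1j * phi) * np.roll(
            star_crop * _ramp(star_crop.shape, u, v), (dy, dx), axis=(0, 1)
        )
        report = ps.compare_pair(star_crop, tgt, ps.CropSpec(side=32))
        assert abs(report.nmse - base.nmse) < 1e-6
        assert abs(report.mean_abs_od - base.mean_abs_od) < 1e-6
        assert abs(report.mean_abs_phase - base.mean_abs_phase) < 1e-6

    def test_phase_map_invariant_enforced(self, star_crop):
        report = ps.compare_pair(star_crop, star_crop * np.exp(1.5j), ps.CropSpec(side=32))
        assert np.all(report.phase_diff_map >= -np.pi)
        assert np.all(report.phase_diff_map <= np.pi)
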