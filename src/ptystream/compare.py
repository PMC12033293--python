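"""Quantitative comparison of complex object maps up to ptychographic ambiguities.

A ptychographic object is only determined up to a global complex factor, a
lateral shift and a linear phase ramp (exchangeable with a probe offset).
Before any metric is computed the two maps are therefore cropped to the
well-illuminated region, ramp-corrected, registered to sub-pixel precision,
amplitude-scaled and phase-aligned. Three metrics are then reported:

* the optical-density difference ``log|O_r| - log|O_g|`` (natural log),
* the wrapped phase difference ``arg(O_r) - dphi - arg(O_g)`` in [-pi, pi],
* the NMSE ``sum |O_g - gamma O_r|^2 / sum |O_g|^2`` with the least-squares
  complex factor ``gamma = sum O_g O_r* / sum |O_r|^2``, which absorbs any
  residual global scale and phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation


@dataclass(frozen=True)
class CropSpec:
    """Square analysis window: side in pixels, centre (y, x) or array centre."""

    side: int = 165
    centre: tuple[int, int] | None = None

    def slices(self, shape: tuple[int, ...]) -> tuple[slice, slice]:
        cy, cx = self.centre if self.centre is not None else (
            shape[0] // 2,
            shape[1] // 2,
        )
        lo_y = cy - self.side // 2
        lo_x = cx - self.side // 2
        if lo_y < 0 or lo_x < 0 or lo_y + self.side > shape[0] or lo_x + self.side > shape[1]:
            raise ValueError(
                f"crop {self.side} px at centre ({cy}, {cx}) exceeds array {shape}"
            )
        return slice(lo_y, lo_y + self.side), slice(lo_x, lo_x + self.side)

    def apply(self, array: np.ndarray) -> np.ndarray:
        sy, sx = self.slices(array.shape)
        return array[sy, sx]


@dataclass(frozen=True)
class AmbiguityCorrection:
    """Corrections applied to the target before the metrics were computed."""

    ramp_slopes_reference: tuple[tuple[float, float], ...]
    ramp_slopes_target: tuple[tuple[float, float], ...]
    lateral_shift: tuple[float, float]
    global_phase: float
    amplitude_scale: float

    def __post_init__(self) -> None:
        if not (-np.pi < self.global_phase <= np.pi + 1e-12):
            raise ValueError("global_phase must lie in (-pi, pi]")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")


@dataclass(frozen=True)
class ComparisonReport:
    """All metrics for one ordered (reference, target) pair."""

    od_diff_map: np.ndarray
    phase_diff_map: np.ndarray
    mean_abs_od: float
    se_abs_od: float
    mean_abs_phase: float
    se_abs_phase: float
    nmse: float
    gamma: complex
    correction: AmbiguityCorrection
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nmse < 0:
            raise ValueError("nmse must be >= 0")
        if np.any(self.phase_diff_map < -np.pi) or np.any(self.phase_diff_map > np.pi):
            raise ValueError("phase difference map must lie within [-pi, pi]")


def remove_phase_ramp(
    field_map: np.ndarray, passes: int = 3, tol: float = 1e-9
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Iteratively remove the best-fit linear phase ramp.

    Per pass the per-axis slope is the amplitude-weighted circular mean of
    the wrapped phase difference between adjacent pixels; the conjugate ramp
    is applied about the array centre (so the value at the centre keeps its
    phase). Stops early once both slopes fall below ``tol`` rad/px.
    """
    f = np.asarray(field_map, dtype=np.complex128).copy()
    if not np.any(f):
        raise ValueError("cannot remove a phase ramp from an all-zero field")
    ny, nx = f.shape
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    slopes: list[tuple[float, float]] = []
    for _ in range(passes):
        # angle of the summed adjacent-pixel products = weighted mean slope
        u = float(np.angle(np.sum(f[:, 1:] * np.conj(f[:, :-1]))))  # along x
        v = float(np.angle(np.sum(f[1:, :] * np.conj(f[:-1, :]))))  # along y
        slopes.append((u, v))
        if abs(u) < tol and abs(v) < tol:
            break
        f *= np.exp(-1j * (u * x[None, :] + v * y[:, None]))
    return f, slopes


def register(
    reference: np.ndarray, moving: np.ndarray, upsample_factor: int = 100
) -> tuple[tuple[float, float], float]:
    """Sub-pixel shift and residual global phase of ``moving`` vs ``reference``.

    The shift is the one to apply to ``moving`` to align it with
    ``reference`` (upsampled cross-correlation); the global phase is the
    amplitude-weighted mean phase of ``moving_aligned * conj(reference)``,
    wrapped to (-pi, pi].
    """
    reference = np.asarray(reference)
    moving = np.asarray(moving)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving must share a shape")
    if not np.any(reference) or not np.any(moving):
        raise ValueError("registration requires non-zero inputs")
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    aligned = apply_shift(moving, tuple(shift))
    phase = float(np.angle(np.sum(aligned * np.conj(reference))))
    return (float(shift[0]), float(shift[1])), phase


def apply_shift(field_map: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Apply a (possibly sub-pixel) translation via the Fourier shift theorem.

    Integer shifts take the exact circular-roll path, which avoids any
    interpolation error on non-periodic content.
    """
    field_map = np.asarray(field_map, dtype=np.complex128)
    if shift == (0.0, 0.0):
        return field_map.copy()
    if all(float(s).is_integer() for s in shift):
        return np.roll(field_map, (int(shift[0]), int(shift[1])), axis=(0, 1))
    spectrum = sfft.fft2(field_map)
    return sfft.ifft2(fourier_shift(spectrum, shift))


def scale_amplitude(
    reference: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scale ``target`` by the mean amplitude ratio ``<|ref| / |target|>``."""
    ref_amp = np.abs(reference)
    tgt_amp = np.abs(target)
    if np.any(tgt_amp == 0):
        raise ValueError("target amplitude must be non-zero at every crop pixel")
    scale = float(np.mean(ref_amp / tgt_amp))
    return target * scale, scale


def od_difference(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optical-density difference ``log|target| - log|reference|`` (natural log)."""
    ref_amp = np.abs(reference)
    tgt_amp = np.abs(target)
    if np.any(ref_amp == 0) or np.any(tgt_amp == 0):
        raise ValueError("optical density requires non-zero amplitudes")
    return np.log(tgt_amp) - np.log(ref_amp)


def phase_difference(
    reference: np.ndarray, target: np.ndarray, global_phase: float = 0.0
) -> np.ndarray:
    """Wrapped phase difference ``arg(target) - global_phase - arg(reference)``.

    A single +-2 pi wrap confines the raw difference (which lies in
    (-2 pi - |dphi|, 2 pi + |dphi|)) to [-pi, pi].
    """
    if reference.shape != target.shape:
        raise ValueError("reference and target must share a shape")
    diff = np.angle(target) - global_phase - np.angle(reference)
    diff = np.mod(diff + np.pi, 2 * np.pi) - np.pi
    return diff


def nmse(reference: np.ndarray, target: np.ndarray) -> tuple[float, complex]:
    """Normalised mean square error after the optimal complex scaling.

    ``gamma = sum(ref * conj(target)) / sum(|target|^2)`` minimises
    ``sum |ref - gamma * target|^2``; the NMSE is that minimum divided by
    ``sum |ref|^2``.
    """
    reference = np.asarray(reference, dtype=np.complex128)
    target = np.asarray(target, dtype=np.complex128)
    ref_power = np.sum(np.abs(reference) ** 2)
    if ref_power == 0:
        raise ValueError("reference must not be identically zero")
    tgt_power = np.sum(np.abs(target) ** 2)
    if tgt_power == 0:
        return 1.0, 0j
    gamma = np.sum(reference * np.conj(target)) / tgt_power
    value = float(np.sum(np.abs(reference - gamma * target) ** 2) / ref_power)
    return max(value, 0.0), complex(gamma)


def _ramp_field(shape: tuple[int, int], u: float, v: float) -> np.ndarray:
    ny, nx = shape
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    return np.exp(1j * (u * x[None, :] + v * y[:, None]))


def _relative_ramp_slopes(ratio: np.ndarray) -> tuple[float, float]:
    u = float(np.angle(np.sum(ratio[:, 1:] * np.conj(ratio[:, :-1]))))
    v = float(np.angle(np.sum(ratio[1:, :] * np.conj(ratio[:-1, :]))))
    return u, v


def compare_pair(
    reference: np.ndarray,
    target: np.ndarray,
    crop: CropSpec | None = None,
    ramp_passes: int = 3,
    upsample_factor: int = 100,
    refine_passes: int = 4,
) -> ComparisonReport:
    """Full ambiguity-corrected comparison of two complex maps.

    Pipeline: crop both maps and remove each one's phase ramp (the ramp
    estimator imposes the same structural bias on both, which then cancels
    in the differences); then alternate sub-pixel registration with removal
    of the *relative* residual ramp of the aligned pair — estimated on the
    product ``target * conj(reference)``, where the structural bias cancels
    exactly. Ramp and shift corrections are applied to the full-size target
    and the analysis window re-cropped, so translation wrap-around never
    contaminates the metrics. Finally the target amplitude is scaled to the
    reference and the OD difference, wrapped phase difference and NMSE are
    computed, with means of the absolute maps and their standard errors
    (sample std / N).
    """
    crop = crop or CropSpec(side=min(reference.shape[0], reference.shape[1]))
    ref_c = crop.apply(np.asarray(reference))
    ref_r, ref_slopes = remove_phase_ramp(ref_c, passes=ramp_passes)
    tgt_c = crop.apply(np.asarray(target))
    _, tgt_slopes = remove_phase_ramp(tgt_c, passes=ramp_passes)
    tgt_slopes = list(tgt_slopes)
    total_u = sum(s[0] for s in tgt_slopes)
    total_v = sum(s[1] for s in tgt_slopes)
    tgt_full = np.asarray(target, dtype=np.complex128) * _ramp_field(
        target.shape, -total_u, -total_v
    )
    shift_total = np.zeros(2)
    for _ in range(max(1, refine_passes)):
        step_shift, _ = register(
            ref_r, crop.apply(tgt_full), upsample_factor=upsample_factor
        )
        if step_shift != (0.0, 0.0):
            tgt_full = apply_shift(tgt_full, step_shift)
            shift_total += step_shift
        rel_u, rel_v = _relative_ramp_slopes(crop.apply(tgt_full) * np.conj(ref_r))
        if rel_u != 0.0 or rel_v != 0.0:
            tgt_full *= _ramp_field(tgt_full.shape, -rel_u, -rel_v)
            tgt_slopes.append((rel_u, rel_v))
        if step_shift == (0.0, 0.0) and abs(rel_u) < 1e-9 and abs(rel_v) < 1e-9:
            break
    shift = (float(shift_total[0]), float(shift_total[1]))
    # rebuild in one pass from the original target: a single composed ramp
    # followed by a single translation (commuting them only changes a global
    # phase), so intermediate interpolation error never reaches the metrics
    total_u = sum(s[0] for s in tgt_slopes)
    total_v = sum(s[1] for s in tgt_slopes)
    tgt_full = np.asarray(target, dtype=np.complex128) * _ramp_field(
        target.shape, -total_u, -total_v
    )
    if shift != (0.0, 0.0):
        tgt_full = apply_shift(tgt_full, shift)
    tgt_a = crop.apply(tgt_full)
    # final polish in the rebuilt frame: any leftover relative ramp is a pure
    # linear phase on identical structures, where the estimator is unbiased
    rel_u, rel_v = _relative_ramp_slopes(tgt_a * np.conj(ref_r))
    if rel_u != 0.0 or rel_v != 0.0:
        tgt_a = tgt_a * _ramp_field(tgt_a.shape, -rel_u, -rel_v)
        tgt_slopes.append((rel_u, rel_v))
    dphi = float(np.angle(np.sum(tgt_a * np.conj(ref_r))))
    tgt_s, scale = scale_amplitude(ref_r, tgt_a)

    od_map = od_difference(ref_r, tgt_s)
    phase_map = phase_difference(ref_r, tgt_s, dphi)
    nmse_value, gamma = nmse(ref_r, tgt_s)

    n_pix = od_map.size
    abs_od = np.abs(od_map)
    abs_phase = np.abs(phase_map)
    report = ComparisonReport(
        od_diff_map=od_map,
        phase_diff_map=phase_map,
        mean_abs_od=float(abs_od.mean()),
        se_abs_od=float(abs_od.std(ddof=1) / np.sqrt(n_pix)),
        mean_abs_phase=float(abs_phase.mean()),
        se_abs_phase=float(abs_phase.std(ddof=1) / np.sqrt(n_pix)),
        nmse=nmse_value,
        gamma=gamma,
        correction=AmbiguityCorrection(
            ramp_slopes_reference=tuple(ref_slopes),
            ramp_slopes_target=tuple(tgt_slopes),
            lateral_shift=shift,
            global_phase=float(np.mod(dphi + np.pi, 2 * np.pi) - np.pi),
            amplitude_scale=scale,
        ),
        metadata={"crop_side": crop.side, "log_base": "e"},
    )
    return report
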