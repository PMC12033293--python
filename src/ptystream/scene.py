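"""Synthetic scene generation: test object, probes, and spiral scan plans.

The study object is a classic resolution phantom: a thick gold Siemens star
on a silicon-nitride membrane, expressed as a complex transmission function
``T = exp(i k (n - 1) t)`` per material layer with refractive index
``n = 1 - delta + i*beta``. Gold at hard-X-ray energies both absorbs and
phase-shifts strongly, so the star provides amplitude and phase contrast at
all spatial frequencies up to the spoke pitch.

Probes are formed by uniformly illuminating a small circular aperture and
propagating the wavefront downstream with the angular-spectrum method. Two
probes are produced per scene: a ground-truth probe used to simulate the
data (longer propagation distance plus a mild quadratic phase) and a
deliberately different initial-estimate probe, so that joint object/probe
retrieval is genuinely exercised.

Scan plans are outward Archimedean spirals with approximately constant
neighbour spacing, the natural geometry for streaming reconstruction: the
already-measured region stays convex and densely sampled as frames arrive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ExperimentGeometry, make_geometry
from .propagation import angular_spectrum_propagate

# Default refractive-index decrements/absorption indices at 8 keV, computed
# from tabulated atomic scattering factors and bulk densities (Au: 19.32
# g/cm^3; Si3N4: 3.44 g/cm^3). These are configuration defaults, not
# constants of the model; override them for other energies or materials.
AU_DELTA_8KEV = 4.70e-5
AU_BETA_8KEV = 4.9e-6
SI3N4_DELTA_8KEV = 1.11e-5
SI3N4_BETA_8KEV = 1.6e-7


@dataclass(frozen=True)
class MaterialLayer:
    """A homogeneous slab: name, thickness (m), and n = 1 - delta + i*beta."""

    name: str
    thickness: float
    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"thickness must be >= 0, got {self.thickness}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def gold_layer(thickness: float = 1e-6) -> MaterialLayer:
    return MaterialLayer("Au", thickness, AU_DELTA_8KEV, AU_BETA_8KEV)


def silicon_nitride_layer(thickness: float = 0.5e-6) -> MaterialLayer:
    return MaterialLayer("Si3N4", thickness, SI3N4_DELTA_8KEV, SI3N4_BETA_8KEV)


@dataclass(frozen=True)
class SiemensStarSpec:
    """Geometry and materials of the Siemens-star phantom.

    ``n_spokes`` counts the opaque (gold) sectors; opaque and open sectors
    alternate, each subtending ``pi / n_spokes`` radians.
    """

    n_spokes: int = 36
    outer_radius: float = 6e-6
    inner_radius: float = 0.0
    star_layer: MaterialLayer = field(default_factory=gold_layer)
    substrate_layer: MaterialLayer = field(default_factory=silicon_nitride_layer)

    def __post_init__(self) -> None:
        if not (0 <= self.inner_radius < self.outer_radius):
            raise ValueError("require 0 <= inner_radius < outer_radius")
        if self.n_spokes < 2 or self.n_spokes % 2 != 0:
            raise ValueError("n_spokes must be even and >= 2")


@dataclass(frozen=True)
class GroundTruthObject:
    """Complex transmission map of the phantom on the reconstruction grid."""

    field: np.ndarray
    pixel: float
    provenance: SiemensStarSpec | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.field)):
            raise ValueError("ground-truth field must be finite everywhere")


@dataclass(frozen=True)
class ProbeSpec:
    """Recipe for an aperture-formed probe.

    Parameters
    ----------
    aperture_diameter : float
        Diameter of the uniformly illuminated circular aperture (m).
    propagation_distance : float
        Free-space propagation downstream of the aperture (m).
    total_photons : float
        Photon budget; the final field is normalised so sum(|P|^2) equals it.
    quadratic_phase : float
        Phase curvature applied across the aperture, in radians at the
        aperture edge (0 for a flat wavefront).
    role : str
        'ground_truth' or 'initial_estimate'; metadata only.
    """

    aperture_diameter: float
    propagation_distance: float
    total_photons: float = 1e10
    quadratic_phase: float = 0.0
    role: str = "initial_estimate"

    def __post_init__(self) -> None:
        if self.aperture_diameter <= 0:
            raise ValueError("aperture_diameter must be positive")
        if self.propagation_distance < 0:
            raise ValueError("propagation_distance must be >= 0")
        if self.total_photons <= 0:
            raise ValueError("total_photons must be positive")


@dataclass(frozen=True)
class Probe:
    """A complex illumination field sampled at the object pixel pitch."""

    field: np.ndarray
    total_photons: float

    def __post_init__(self) -> None:
        power = float(np.sum(np.abs(self.field) ** 2))
        if not math.isclose(power, self.total_photons, rel_tol=1e-6):
            raise ValueError(
                f"probe power {power:g} does not match budget {self.total_photons:g}"
            )


@dataclass(frozen=True)
class ScanPlan:
    """Ordered scan positions in real-space pixels relative to the grid centre."""

    positions: np.ndarray  # (n, 2) float, (y, x)
    step: float
    n_points: int
    overlap: float | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != self.n_points:
            raise ValueError("n_points must equal len(positions)")

    @property
    def max_radius(self) -> float:
        return float(np.max(np.hypot(self.positions[:, 0], self.positions[:, 1])))


def make_siemens_star(
    spec: SiemensStarSpec,
    geometry: ExperimentGeometry,
    grid_side: int,
    supersample: int = 4,
) -> GroundTruthObject:
    """Rasterise the Siemens-star transmission function on a square grid.

    Spoke edges are anti-aliased by area-fraction supersampling; the gold
    thickness of a boundary pixel is scaled by its coverage fraction. The
    substrate covers the whole grid.
    """
    pixel = geometry.real_space_pixel
    outer_px = spec.outer_radius / pixel
    half = int(math.ceil(outer_px)) + 2
    if 2 * half > grid_side:
        raise ValueError(
            f"star of radius {outer_px:.1f} px does not fit a {grid_side} px grid"
        )

    ss = int(supersample)
    n_box = 2 * half * ss
    # subpixel centre coordinates relative to the grid centre, in metres
    coord = (np.arange(n_box) - n_box / 2 + 0.5) * (pixel / ss)
    yy = coord[:, None]
    xx = coord[None, :]
    r = np.hypot(yy, xx)
    theta = np.mod(np.arctan2(yy, xx), 2 * np.pi)
    sector = np.floor(theta / (np.pi / spec.n_spokes)).astype(np.int64)
    in_star = (sector % 2 == 0) & (r >= spec.inner_radius) & (r <= spec.outer_radius)
    coverage = in_star.astype(np.float64).reshape(2 * half, ss, 2 * half, ss).mean(
        axis=(1, 3)
    )

    k = geometry.wavenumber
    sub = spec.substrate_layer
    star = spec.star_layer
    # T = exp(i k (n-1) t): amplitude exp(-k beta t), phase -k delta t
    phase = np.full((grid_side, grid_side), -k * sub.delta * sub.thickness)
    absorb = np.full((grid_side, grid_side), k * sub.beta * sub.thickness)
    lo = grid_side // 2 - half
    hi = grid_side // 2 + half
    phase[lo:hi, lo:hi] += -k * star.delta * star.thickness * coverage
    absorb[lo:hi, lo:hi] += k * star.beta * star.thickness * coverage
    field_map = np.exp(-absorb + 1j * phase)
    return GroundTruthObject(field=field_map, pixel=pixel, provenance=spec)


def make_probe(
    spec: ProbeSpec, geometry: ExperimentGeometry, grid_side: int
) -> Probe:
    """Form a probe by aperture illumination plus free-space propagation.

    The aperture is rasterised with sub-pixel anti-aliasing on an oversampled
    grid (the aperture can span less than two object pixels), propagated with
    the unitary angular-spectrum method on a padded grid, then box-averaged
    back to the object pitch and renormalised to the photon budget.
    """
    pixel = geometry.real_space_pixel
    d_px = spec.aperture_diameter / pixel
    ss = max(1, min(8, int(math.ceil(8.0 / d_px))))
    if d_px * ss < 4:
        raise ValueError(
            f"aperture of {d_px:.2f} px cannot be resolved even at "
            f"{ss}x oversampling"
        )

    pitch = pixel / ss
    n_work = 2 * grid_side * ss  # factor-2 padding for propagation
    coord = (np.arange(n_work) - n_work / 2 + 0.5) * pitch
    r = np.hypot(coord[:, None], coord[None, :])
    radius = spec.aperture_diameter / 2.0
    # radial anti-aliasing: linear edge roll-off over one sub-pixel
    aperture = np.clip((radius - r) / pitch + 0.5, 0.0, 1.0)
    if spec.quadratic_phase != 0.0:
        aperture = aperture * np.exp(
            1j * spec.quadratic_phase * (r / radius) ** 2
        )
    propagated = angular_spectrum_propagate(
        aperture.astype(np.complex128),
        pitch,
        geometry.wavelength,
        spec.propagation_distance,
    )
    lo = (n_work - grid_side * ss) // 2
    core = propagated[lo : lo + grid_side * ss, lo : lo + grid_side * ss]
    field_map = core.reshape(grid_side, ss, grid_side, ss).mean(axis=(1, 3))
    power = np.sum(np.abs(field_map) ** 2)
    if power <= 0:
        raise ValueError("probe field has zero power after propagation")
    field_map = field_map * math.sqrt(spec.total_photons / power)
    return Probe(field=field_map, total_photons=spec.total_photons)


def archimedean_spiral(n_points: int, step: float) -> ScanPlan:
    """Outward Archimedean spiral with ~constant arc-length spacing.

    The spiral ``r = (step / 2 pi) * theta`` is sampled incrementally with
    ``delta theta = step / r`` (and a full turn for the first point off
    centre), which keeps consecutive points about ``step`` pixels apart.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    b = step / (2 * np.pi)
    positions = np.zeros((n_points, 2))
    theta = 0.0
    for i in range(1, n_points):
        theta += 2 * np.pi if theta == 0.0 else step / (b * theta)
        r = b * theta
        positions[i] = (r * np.sin(theta), r * np.cos(theta))
    return ScanPlan(positions=positions, step=float(step), n_points=n_points)


def overlap_ratio(
    step: float, probe_footprint_diameter: float, method: str = "circle_area"
) -> float:
    """Nominal overlap between adjacent scan positions.

    ``linear`` is ``1 - step/d``; ``circle_area`` is the normalised lens area
    of two circles of diameter ``d`` whose centres are ``step`` apart.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if probe_footprint_diameter <= 0:
        raise ValueError("probe_footprint_diameter must be positive")
    x = min(step / probe_footprint_diameter, 1.0)
    if method == "linear":
        return max(0.0, 1.0 - x)
    if method == "circle_area":
        return float((2.0 / np.pi) * (np.arccos(x) - x * np.sqrt(1.0 - x * x)))
    raise ValueError(f"unknown overlap method {method!r}")


def probe_power_diameter(
    probe_field: np.ndarray, fraction: float = 0.9
) -> float:
    """Diameter (pixels) of the centred circle containing ``fraction`` of power."""
    intensity = np.abs(np.asarray(probe_field)) ** 2
    total = intensity.sum()
    if total <= 0:
        raise ValueError("probe field has zero power")
    n = intensity.shape[0]
    idx = np.arange(n)
    cy = float((intensity.sum(axis=1) * idx).sum() / total)
    cx = float((intensity.sum(axis=0) * idx).sum() / total)
    r = np.hypot(idx[:, None] - cy, idx[None, :] - cx).ravel()
    order = np.argsort(r)
    cum = np.cumsum(intensity.ravel()[order])
    k = int(np.searchsorted(cum, fraction * total))
    return 2.0 * float(r[order[min(k, r.size - 1)]])


# ---------------------------------------------------------------------------
# Scene assembly


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to build one synthetic experiment."""

    photon_energy: float = 8.0
    detector_side: int = 256
    detector_pixel: float = 75e-6
    sample_detector_distance: float = 3.67
    star: SiemensStarSpec = field(default_factory=SiemensStarSpec)
    aperture_diameter: float = 50e-9
    init_propagation: float = 980e-6
    truth_propagation: float = 980e-6
    truth_quadratic_phase: float = 2.0
    total_photons: float = 1e10
    n_points: int = 315
    step_px: float = 10.0
    grid_margin: int = 16

    def geometry(self) -> ExperimentGeometry:
        return make_geometry(
            self.photon_energy,
            self.detector_side,
            self.detector_pixel,
            self.sample_detector_distance,
        )


@dataclass(frozen=True)
class Scene:
    """A complete synthetic experiment: object, probes, geometry, scan."""

    geometry: ExperimentGeometry
    object_truth: GroundTruthObject
    probe_truth: Probe
    probe_init: Probe
    scan: ScanPlan
    config: SceneConfig | None = None

    @property
    def grid_side(self) -> int:
        return self.object_truth.field.shape[0]


def grid_side_for(
    scan: ScanPlan,
    detector_side: int,
    margin: int = 16,
    star: SiemensStarSpec | None = None,
    pixel: float | None = None,
) -> int:
    """Smallest even grid containing every probe view plus a safety margin.

    When the star spec and pixel pitch are given, the grid is also made large
    enough to hold the full phantom, so the same sample underlies every scan
    regardless of its extent.
    """
    side = int(math.ceil(2 * scan.max_radius)) + detector_side + 2 * margin
    if star is not None and pixel is not None:
        star_side = 2 * (int(math.ceil(star.outer_radius / pixel)) + 2 + margin)
        side = max(side, star_side)
    return side + side % 2


def build_scene(config: SceneConfig) -> Scene:
    """Assemble the full synthetic experiment from a :class:`SceneConfig`."""
    geometry = config.geometry()
    scan = archimedean_spiral(config.n_points, config.step_px)
    grid = grid_side_for(
        scan,
        config.detector_side,
        config.grid_margin,
        star=config.star,
        pixel=geometry.real_space_pixel,
    )
    obj = make_siemens_star(config.star, geometry, grid)
    probe_truth = make_probe(
        ProbeSpec(
            aperture_diameter=config.aperture_diameter,
            propagation_distance=config.truth_propagation,
            total_photons=config.total_photons,
            quadratic_phase=config.truth_quadratic_phase,
            role="ground_truth",
        ),
        geometry,
        config.detector_side,
    )
    probe_init = make_probe(
        ProbeSpec(
            aperture_diameter=config.aperture_diameter,
            propagation_distance=config.init_propagation,
            total_photons=config.total_photons,
            role="initial_estimate",
        ),
        geometry,
        config.detector_side,
    )
    diameter = probe_power_diameter(probe_truth.field)
    scan = replace(scan, overlap=overlap_ratio(config.step_px, diameter))
    return Scene(
        geometry=geometry,
        object_truth=obj,
        probe_truth=probe_truth,
        probe_init=probe_init,
        scan=scan,
        config=config,
    )


def default_scene_config(step_px: float = 10.0, n_points: int = 315) -> SceneConfig:
    """The study's full-scale conditions (256 px detector, 1e10 photons)."""
    return SceneConfig(step_px=step_px, n_points=n_points)


def scaled_scene_config(
    step_px: float = 4.0,
    n_points: int = 60,
    det_side: int = 64,
) -> SceneConfig:
    """A reduced scene (64 px frames) preserving the 29.6 nm pixel pitch.

    The sample-detector distance shrinks with the detector side so the
    real-space pixel stays at the full-scale value; the aperture is enlarged
    and the propagation shortened so the probe still fits the smaller frame.
    """
    scale = det_side / 256.0
    return SceneConfig(
        detector_side=det_side,
        sample_detector_distance=3.67 * scale,
        star=SiemensStarSpec(n_spokes=18, outer_radius=1.5e-6),
        aperture_diameter=400e-9,
        init_propagation=400e-6,
        truth_propagation=600e-6,
        truth_quadratic_phase=1.0,
        n_points=n_points,
        step_px=step_px,
    )
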