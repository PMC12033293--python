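# Methods

This note documents the models, algorithms and numerical choices behind
`ptystream`: a self-contained simulation study comparing streaming
(growing-dataset) and offline ptychographic reconstructions of the same
diffraction data.

## The forward model

The sample is a thin transmission object: a gold Siemens star (1 um thick,
36 spokes, 6 um outer radius by default) on a 0.5 um silicon-nitride
membrane. The star is deliberately large enough that most of the widest
scan still sees spoke structure — scans over featureless membrane give the
growing-dataset reconstruction nothing to lock onto and proved to be a
reliable way to trap it in a stagnation mode. Each material layer multiplies the wavefield by
`exp(i k (n - 1) t)` with `n = 1 - delta + i beta`, so gold contributes both
absorption (`exp(-k beta t)` ~ 0.82 at 8 keV) and a phase of
`-k delta t` ~ -1.9 rad. The delta/beta defaults come from tabulated atomic
scattering factors at 8 keV and are plain configuration values — override
them for other energies. Spoke edges are anti-aliased by 4x area
supersampling, so boundary pixels carry fractional gold thickness.

The detector geometry (256 px x 75 um at 3.67 m, 8 keV) fixes the
real-space pixel at `lambda z / (N delta_det)` = 29.6 nm. The far field is
the orthonormal 2-D FFT of probe x object view, so the summed intensity
equals the exit-wave power (Parseval); photon noise is Poisson with that
intensity as the mean, one deterministic RNG substream per frame keyed by
`(seed, frame index)`.

Scan plans are Archimedean spirals `r = (step / 2 pi) theta` sampled at
constant arc length (`delta theta = step / r`, one full turn for the first
off-centre point), giving ~`step` spacing everywhere past the first turn.
Positions are fractional; both simulator and engine round them to the
nearest integer pixel through one shared helper so they can never disagree.

## Probes

Both probes are formed by uniformly illuminating a circular aperture and
propagating with the exact (non-band-limited) angular-spectrum transfer
function on an oversampled, 2x-padded grid — unitary to machine precision,
which the tests rely on. The aperture (50 nm at full scale, under two
object pixels) is rasterised with sub-pixel radial anti-aliasing at up to
8x oversampling.

* **Initial probe** (the estimate every reconstruction starts from): 50 nm
  aperture propagated 980 um, flat wavefront. This is the classic crude
  "aperture model" of a beamline probe.
* **Ground-truth probe** (used only to simulate the data): same aperture
  and distance, plus a 2 rad quadratic phase across the aperture — a
  defocus-like wavefront error the joint retrieval has to discover and
  correct. The two probes therefore share their gross footprint (an Airy
  pattern, FWHM ~87 px at full scale) but differ in their ring structure.

Why this pair: the truth probe of the original experiment this package
emulates is a measured beam, with the aperture model as its initial guess —
i.e. initial and truth probes of similar size and structure. We found the
choice matters enormously for conditioning. A truth probe very different
from the initial model (e.g. a compact strongly-curved beam from a much
shorter propagation) leaves joint retrieval unable to lock onto the probe
for hundreds of iterations at full scale, whereas a defocus-level
difference is corrected within ~25 iterations. The reduced-size profile
uses a 400 nm aperture at 400 um (initial) vs 600 um + 1 rad (truth), the
same idea at 64 px frame scale.

## Reconstruction engine

Two projection algorithms over the active frame set, mixed 80% / 20% in
deterministic blocks of ten iterations (eight Difference Map, then two
Error Reduction):

* ER: `psi_j <- PF(P O_j)`
* DM: `psi_j <- psi_j + PF(2 P O_j - psi_j) - P O_j`

where `PF` replaces the FFT modulus with `sqrt(counts)` keeping the phase.
After each update the overlap step rebuilds object and probe by damped
least squares,

    O <- (sum_j P* psi_j + lam_o O_prev) / (sum_j |P|^2 + lam_o)
    P <- (sum_j O_j* psi_j + lam_p P_prev) / (sum_j |O_j|^2 + lam_p)

with `lam_o = 1e-2 x` peak summed illumination and `lam_p = 1e-4 x` peak
object weight, alternated up to 3 times per iteration with a 1e-3
relative-change early exit. The inertia terms are essential, not cosmetic:
with plain least squares the DM/ER mix wanders in a noise-ball and two
runs of the same data stagnate at distinct points, so the streaming and
offline reconstructions never collapse onto each other. With inertia the
joint map becomes contractive near the solution and independent runs
converge to the same numerical attractor — the effect the study measures.
Consistent noiseless solutions remain exact fixed points (`num = den * O`
implies the damped update returns `O` unchanged), which the fixed-point
tests exercise.

Other engine rules:

* Single-precision arrays, double-precision accumulations.
* With inertia active the damped update is applied everywhere (it is an
  exact no-op where illumination vanishes); with inertia disabled the
  object is only updated where summed illumination exceeds 1% of its
  maximum.
* The object amplitude is clipped at 1 (a transmission sample only
  attenuates), suppressing the amplitude-overshoot stagnation mode.
* Probe refinement starts at iteration 120 — i.e. only once the default
  streaming schedule has received the whole scan. Updating the probe while
  only a handful of frames are active reliably locks growing-dataset runs
  into a wrong probe/object factorisation that later data cannot undo; the
  offline runs use the same warm-up so the two modes stay parameter-matched.
* An optional noise-aware relaxed Fourier constraint (modulus free within
  a Poisson band) and an optional circular probe support are available but
  off by default; neither changed the stagnation behaviour in our tests.
* The probe's intensity centroid is pinned to the frame centre by integer
  rolls of probe, object and exit waves together (a pure gauge operation).
  Growing-dataset runs otherwise drift to a laterally shifted, physically
  equivalent solution during early acquisition, and the final
  streaming-vs-offline comparison is then dominated by that drift.
* No randomness anywhere: runs are bit-reproducible, and a single-chunk
  stream is bit-identical to the offline run.

## Streaming schedule

Frames arrive at 0.6 s cadence and are handed over in chunks of 25 (full
scale), each chunk available when its last frame is produced — a logical
clock, no wall time. Streaming runs start after the first chunk
(`start_after_frames = 1`), run a fixed number of iterations per
inter-chunk interval (default 10; an explicit per-interval list is also
supported), and after the last chunk run 100 more iterations, with the
total rounded to the nearest ten (ties up). Offline runs use all frames
from iteration 0 and reuse the streaming run's rounded total, so the two
modes always compare at matched iteration counts. With the defaults this
gives 120 iterations during acquisition and a matched total of 220.

## Comparison pipeline

Reconstructed objects are defined only up to a global complex factor, a
lateral shift and a linear phase ramp. `compare_pair` crops both maps
(165 px at full scale, centred on the spiral), removes each map's phase
ramp (amplitude-weighted circular-mean slope estimator, 3 passes with a
1e-9 rad/px early exit; applied to the reference too, because the
estimator's structural bias is identical for both and cancels in the
differences), then alternates sub-pixel registration (upsampled cross
correlation, 0.01 px) with removal of the *relative* residual ramp
estimated on `target x conj(reference)`, where the structural bias cancels
exactly. All corrections are finally re-applied to the original full-size
target in one composed ramp + one translation (integer translations take
an exact circular-roll path), so intermediate interpolation error never
reaches the metrics. Reported metrics: optical-density difference
`log|O_r| - log|O_g|` (natural log), phase difference wrapped to
[-pi, pi] after subtracting the registered global phase, means of the
absolute maps with standard errors (sample std / N), and the NMSE with the
closed-form least-squares complex factor gamma.

## Problem sizes and what the tests show

The default full-scale profile is the study's own geometry: 256 px frames,
315-point spirals at steps {10, 19, 27, 35, 40} px, 1e10 photons, frames
in 25-frame chunks at 0.6 s cadence. The packaged study runner executes
the highest- and lowest-overlap settings with 220-iteration matched totals
per mode (10 iterations per 15 s chunk interval — about what a
single-precision CPU engine at ~1.3 s/iteration completes in real time —
plus the 100 post-acquisition iterations, rounded). At that depth the
behaviour differs by overlap. At step 10 the streaming and offline
reconstructions already agree with each other several times more closely
than either agrees with the truth (NMSE ~3e-4 vs ~1-2e-3) — the study's
ordering. At step 40 both runs converge healthily but the streaming run
retains a ~1e-3 residual relative to the offline one, which itself is at
~1e-4 from the truth at these totals, so the ordering is not yet
established there; in our experiments it did not resolve within any
CPU-tractable iteration budget (tested to 460-iteration totals, with and
without probe support, Fourier relaxation, amplitude clipping, schedule
front-loading and inertia annealing). Reaching the photon-noise floor
(~1e-8 NMSE), where the effect is unambiguous, is demonstrated on the
reduced 64-px profile: offline-vs-truth 1.6e-8, streaming-vs-truth
1.7e-8, streaming-vs-offline 5.7e-10 at 800-iteration totals. That is the
deep-convergence regime the original experiment reports, validated within
the test suite's runtime envelope.

The synthetic scenes emulate the geometry, materials, scan, noise and
delivery protocol of the real study; they do not emulate position errors,
partial coherence, detector masks or background — so passing tests show
algorithmic equivalence of streaming and offline reconstruction under
ideal scanning, not robustness to those experimental effects.

## Degenerate inputs and tie-breaks

Validation errors name the offending field (non-positive geometry, star
larger than its grid, unresolvable aperture, empty active set, zero-length
schedules, all-zero fields in the comparison). Rounding of matched totals
ties upward. The Fourier projection leaves spectrum samples below 1e-12
modulus unchanged. `overlap_ratio` offers both the linear and
circle-lens-area conventions; printed overlap percentages are labels
derived from the 90%-power probe footprint, not calibrated quantities.
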