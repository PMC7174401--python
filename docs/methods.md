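# Methods

## Physical model

The package treats chromatin granules as passive tracer particles
embedded in a viscoelastic medium.  Three regimes are modeled and
simulated:

* **Free diffusion** — per-axis displacement increments over a frame
  interval `δt` are independent Gaussians of variance `2 D δt`, so the
  in-plane MSD is `MSD(τ) = 4 D τ`.
* **Confined (Kelvin–Voigt) motion** — a tracer tethered by a spring of
  rigidity `G'` in parallel with a dashpot of viscosity `η` performs
  Ornstein–Uhlenbeck motion with relaxation time `τ_r = η/G'` and
  per-axis stationary variance `D τ_r`, giving
  `MSD(τ) = 4 D τ_r (1 − e^(−τ/τ_r))`: free-like at `τ ≪ τ_r`, a plateau
  `A = 4 D τ_r` at `τ ≫ τ_r`.
* **Collective drift** — a rigid translation of the whole field applied
  identically to all particles, emulating slow motion of the nucleus on
  the stage.

The bridge from trajectories to mechanics is the (generalized)
Stokes–Einstein relation.  At short lags,
`D_eff = k_B T / (6π η_app R)` defines the apparent viscosity from the
fitted diffusivity and the granule's optical radius `R` (half the fitted
FWHM).  Across frequencies, the modulus magnitude is evaluated in the
Mason local power-law approximation of the GSER,

    G_d(ω) ≈ 2 k_B T / (3π R · MSD(τ) · Γ(1 + α(τ))),   ω = 1/τ,
    δ(ω)  ≈ (π/2) · d ln G_d / d ln ω,

with `α = d ln MSD / d ln τ`, and `G' = G_d cos δ`, `G'' = G_d sin δ`,
`η(ω) = G''/ω`.  The `2/(3π R)` prefactor is the convention for a 2D
(in-plane) MSD; with it, a pure power law `MSD = 4Dτ` returns
`η(ω) = k_B T/(6π R D)` at every frequency, so the spectral route and
the short-lag Stokes–Einstein route agree identically — a property the
test suite asserts to better than 1%.  A direct numerical
Laplace-transform evaluation of the GSER (same prefactor) is provided as
a validation route only; on exact power laws the two agree to <1%.

For a Kelvin–Voigt tracer the spectrum has a plateau
`G' = 2 k_B T / (3π R A)` at low frequency and `η(ω) → η` at high
frequency; `fit_voigt` reads both off a spectrum.

## Pipeline and estimators

**Detection.**  Candidates are local maxima of a lightly smoothed frame
(Gaussian `σ = 2 px`, well under the ≥10 px spot widths) exceeding the
image median by 4 robust standard deviations (MAD-scaled), separated by
≥3 px, excluding a thin border strip where smoothing correlates the
noise.  Each candidate is refined by least-squares fitting of a
symmetric 2D Gaussian plus constant offset on a window of 2× the
expected FWHM, refit with a window matched to its own fitted FWHM when
that turns out larger (a window much narrower than the spot makes
offset, amplitude and width degenerate and the intensity estimate
noisy); window pixels lying closer to another comparably bright
candidate are excluded so a neighbor's tail cannot bias the parameters
(faint noise candidates do not mask), and the fitted center is
constrained within 3 px of the candidate peak.  Fits
with `σ < 0.5 px` (sub-resolution artifacts) or non-convergence are
rejected with a reason.  On noise-free rendered data the fits recover
positions to <0.05 px and diameters/intensities to <2%; at peak SNR 10
the Monte-Carlo localization error is <0.2 px.  Coordinates follow the
pixel-center-at-integer convention, x rightward, y downward, origin at
the top-left pixel.

**Descriptors and matching.**  Each spot anchors a SURF-style
descriptor: integral-image Haar responses of filter size `2s` (sampling
scale `s = σ_px/2`, clipped to [1, 5] px), a dominant orientation from
vector-summed responses over a sliding π/3 window in a radius-6s disc,
and a 64-vector of `(Σdx, Σ|dx|, Σdy, Σ|dy|)` over a 4×4 grid of an
oriented 20s×20s patch, Gaussian-weighted and unit-normalized.
Unit normalization makes descriptors exactly invariant to uniform
contrast scaling; orientation assignment makes them rotation-invariant
to within ~0.1 descriptor distance for 90° rotations of rendered scenes.
Matching is mutual-nearest-neighbor in descriptor space gated by a
maximum spatial displacement (default 0.25 µm per frame, several times
the expected RMS step); spots too close to the border for a descriptor
window fall back to gated spatial mutual-nearest-neighbor so edge spots
are not silently dropped.  A lost match terminates a trajectory — there
is no gap closing.

**Quality control.**  Two discard rules run along each trajectory:
(i) diameter or integrated intensity changing by more than 10% between
consecutive frames (spot exchange / defocusing); (ii) a step-length
rule with two selectable readings — `step_change`
(`||Δr(t)| − |Δr(t−δt)|| > 0.5 |Δr(t−δt)|`) and `step_ratio`
(`|Δr(t)| > 1.5 |Δr(t−δt)|`).  The head of a trajectory before the
first violation is kept if it spans at least 64 frames (0.125 s at
512 Hz — enough lags for a short-lag fit).  *Default:* the pipeline
ships with the displacement rule **off** and only the size/intensity
rules active.  Consecutive step lengths of a genuinely Brownian
trajectory are independent Rayleigh draws, which violate either reading
with ~50–60% probability per frame, so a frame-wise displacement rule
rejects essentially every correct trajectory; it remains available (and
unit-tested in both readings) for data where jumps indicate
mis-matching, e.g. when tracking sparse bright outliers.

**Drift correction.**  Stage 1 estimates the least-squares rigid
transform (rotation + translation, Kabsch construction with the
reflection branch corrected by the determinant sign) between every
consecutive frame pair from the particles present in both, accumulates
the inverses, and maps all frames into the first frame's coordinates.
Stage 2 recomputes the intensity-weighted center of mass per frame on
the rigid-corrected coordinates and subtracts it.  Rigid-first ordering
is used because a rotation cannot be removed by center-of-mass
subtraction; the order is configurable (`com_only`).  The composite
correction is exactly equivariant under any per-frame global rigid
motion: applying an arbitrary rotation+translation sequence to a
simulated fixture changes corrected MSDs only at floating-point level
(tested).  Frames with fewer than 2 matched pairs get an identity
transform with a warning; frames with no spots get a linearly
interpolated center of mass, flagged in the drift record.

Two refinements make the center-of-mass reference usable on estimated
(rather than exact) spot tables; both reduce exactly to the plain
per-frame weighted COM when every particle spans every frame.  First,
the weights are per-particle trajectory-mean intensities: instantaneous
fitted intensities fluctuate by a few percent at realistic SNR, and
those fluctuations multiply the ~µm-scale spread of particle positions,
which would inject tens of nanometres of reference-frame jitter per
frame — an order of magnitude above the localization noise.  Second,
the COM path is integrated from the weighted mean displacement of the
particles common to consecutive frames, so a trajectory that starts or
ends mid-movie (QC truncation, lost match) shifts the membership
without producing a step discontinuity in the reference frame — a
single such step would otherwise dominate every particle's MSD.

*Known bias:* subtracting the center of mass removes an
intensity-weighted share of each particle's own Brownian motion,
deflating per-particle `D_eff` by a factor of order `1 − w_i` (weight of
particle i).  This is inherent to the reference-frame construction and
is why a phenotype requires ≥10 accepted granules (and ≥2 as a hard
error — a single particle is its own center of mass and corrects to
zero).  Comparisons between conditions processed identically are
unaffected; the synthetic demos with 5 granules show the bias clearly.

**MSD and fits.**  MSDs are time-averaged over all overlapping origins
(maximal data use; this correlates neighboring lags, which is why
ensemble standard errors are computed across trajectories, not across
origins).  Lags run to 25% of the trajectory length; long trajectories
use a log-spaced subset (default 60 lags) for economy.  `D_eff` is a
weighted least-squares slope of `MSD = 4Dτ` through the origin over lags
`τ ≤ 0.1 s` (the short-time free-diffusive window; configurable),
weights proportional to the origin counts.  The default fit has no
intercept, matching the short-lag law; an intercept mode absorbing
static localization noise exists but is off by default, and a
non-overlapping-origin MSD mode is available when independent squared
displacements are needed.  Anomalous exponents are log-log slopes
over a lag window.  Viscosity uncertainty propagates linearly from the
`D_eff` standard error; `D_eff = 0` flags an infinite viscosity that is
excluded from phenotype averages.

**Spectra.**  Local log-log slopes (for both `α(τ)` and the phase) come
from centered quadratic fits over 5-point windows in log τ — raw finite
differences amplify MSD noise.  Endpoints use truncated one-sided
windows and are flagged.  Points with `α ∉ (−0.5, 1.5)` are masked (the
Γ argument approaches a pole); phases outside `[0, π/2]` by more than 5%
are masked, small excursions are clipped.  The frequency grid is exactly
the reciprocal measured lags — no resampling.  `fit_voigt` takes the
plateau `G'` as the median of `G'(ω)` over the lowest half-decade of the
flat region (local log-slope magnitude < 0.2) — the plateau is a
low-frequency limit, and shoulder points still relaxing toward it would
otherwise bias `G'` upward — and `η` as the mean of `η(ω)` over the top
half-decade of frequency.  A spectrum without a flat region (purely
viscous media) is flagged `non-plateau`.

**Phenotype and statistics.**  A nucleus is summarized by the mean and
sample SD of `η_app` over accepted granules (infinite values excluded),
an optical density (total background-corrected integrated spot intensity
per total spot area, a.u./µm²), and the mean optical radius.  Optical
density has no single standard operationalization; intensity-per-area
over the tracked spots is used because it needs no segmentation mask,
and a whole-mask mean can be supplied through `area_um2` when a
segmentation exists.  Group comparison uses the two-sided Mann–Whitney U
test for 2 groups and Kruskal–Wallis for more, midranks for ties, raw
p-values (Holm correction available but off by default), significance
labeled at 0.05 without ever filtering data.

## Synthetic data: what it does and does not emulate

The generator renders granules as symmetric 2D Gaussians
(`σ = FWHM/2√(2 ln 2)`), diameters 0.5–1.5 µm, on a constant background
with additive Gaussian pixel noise, at the default acquisition geometry
(50 nm pixels, 512 Hz, 10 s = 5120 frames, 298 K).  Confined motion uses
the exact OU discretization — not Euler — so plateau values are unbiased
at any step size.  One master seed drives three independent substreams
(initialization, motion, pixel noise); the `free` and `drifting` models
consume the motion stream identically, so fixtures differing only by
drift share their Brownian paths and drift-correction tests can compare
them pathwise.  Particles must stay 3σ inside the frame; violations
raise an error listing the offending particles rather than clipping.

Deliberate simplifications: no chromatin texture or spatially varying
background, no defocus/3D rendering, additive Gaussian rather than
Poisson shot noise (phase-contrast background is not photon-limited at
these intensities), no camera artifacts.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to structured backgrounds or overlapping granules — the
detector explicitly does not deblend overlaps.

Preset choices: fields of view are 320×320 px (16 µm; no standard value
exists, chosen to hold 5–8 well-separated granules), spot peak SNR ≈ 10
(peak over background-noise SD; an assumption, as real SNR varies with
illumination), granule diameters fixed at interior values of the
0.5–1.5 µm band so detection noise cannot flicker a spot across the
selection boundary, and minimum 3 µm spacing so Gaussian tails overlap
negligibly.  The `free_jurkat_like` preset keeps the full 5120-frame
acquisition; `confined_voigt` (2 s) and `drifting` (0.5 s, noise-free)
are shorter because their test roles (plateau recovery, drift oracle)
do not need the full record.

## Validation problem sizes

The calibration suite simulates 200 free trajectories of 5120 steps
(D = 0.1 µm²/s, 512 Hz) and checks the `MSD/(Dτ)` coefficient, the
log-log slope, and the RMSD exponent each within 3 standard errors
across trajectories.  Kelvin–Voigt recovery spans a 3×3 grid of
`G' ∈ {2, 6.3, 20} Pa × η ∈ {10⁻³, 10⁻², 10⁻¹} Pa·s`, 20 seeds × 200
trajectories each, simulated at `δt = τ_r/25` for 2500 steps so that
both the free branch and the plateau are resolved for every grid point
(at a fixed 512 Hz, pairs with `τ_r < δt` are unrecoverable by any
estimator); medians recover `G'` within ~1% and `η` within ~6%
(tolerance 15%).  End-to-end: the noise-free drifting fixture, after
detection, linking and drift correction, reproduces its drift-free
counterpart's MSD within 3 standard errors.

## Numerical conventions

`k_B = 1.380649×10⁻²³ J/K` (exact SI).  Lengths in µm, times in s,
moduli in Pa throughout the API; SI conversions happen only inside the
viscosity/modulus formulas.  Gaussian-fit initialization uses
background-subtracted moments; `σ` is bounded in [0.25 px, 4×window].
Diameter-band bounds are inclusive.  Degenerate inputs — flat frames,
empty spot lists, all-equal group data — return empty results or `p = 1`
rather than raising, except where a result would be meaningless
(<2 particles for drift correction, <3 usable lags for a log-log fit,
spectra narrower than a decade).
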