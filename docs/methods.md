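# Methods

## Signal model

A voxel's OCT amplitude is modelled as fully developed speckle: a circular
complex Gaussian field whose intensity `I = |E|²` is exponentially
distributed. Temporal dynamics enter as a static/dynamic mixture

    E(t) = √(1−m) · E_s + √m · E_d(t),

with `m ∈ [0, 1]` the *motility fraction* (fraction of field power that
fluctuates) and `E_d` a stationary circular-Gaussian process with field
correlation `exp(−|Δt|/τ_c)`; `τ_c` is the decorrelation time in ms. Both
components have unit variance, so the mean intensity equals the region's
reflectivity. For this model the normalised field correlation is
`g₁(τ) = (1−m) + m·e^(−τ/τ_c)` and the Siegert relation for circular
Gaussian fields gives the *ensemble* intensity Pearson autocorrelation

    ρ(τ) = |g₁(τ)|²,     ρ(0) = 1,

which is the package's analytic oracle
(`phantom.analytic_intensity_correlation`).

Two limits give closed-form calibration points:

* `m = 0`: the field is static, every repeat is identical, LIV = 0 and
  OCDS_l = 0.
* `m = 1`, `τ_c ≪` frame interval: repeats are i.i.d. exponential
  intensities; the variance of the dB-scaled intensity is
  `(10/ln 10)² · π²/6 ≈ 31.03 dB²` (population variance; multiplied by
  `(N−1)/N` for an N-frame divisor-N estimate).

## Metrics

Both contrasts operate on the dB-scaled sequence
`I_dB(t) = 10·log₁₀(I(t) + ε)`, where the floor
`ε = 10⁻⁶ × mean(I)` keeps empty voxels finite without biasing tissue
voxels (`MetricConfig.db_floor_rel`).

**LIV** is the per-voxel time variance of `I_dB` over the repeats, divisor
N by default (`variance_divisor` exposes N−1). Units dB²; non-negative by
construction.

**Temporal autocorrelation** is the per-voxel sample Pearson
autocorrelation of `I_dB`: residuals about the full-series temporal mean,
normalised by the divisor-N variance so ρ(0) = 1, with the lag-k numerator
averaged over the N−k available pairs. Voxels whose temporal variance is
below `static_var_rel_tol` (relative to the mean square signal) are flagged
static and assigned a non-decaying curve (ρ ≡ 1), hence OCDS_l = 0 exactly.
`correlation_domain = "linear"` computes the same estimator on linear
intensity; the Siegert oracle applies exactly in that domain, and the
oracle tests use it. In the dB domain the pooled correlation deviates from
the linear-domain curve (the log transform is nonlinear); this bias is
bounded empirically by the test suite rather than assumed zero.

**OCDS_l** is the ordinary least-squares slope of ρ(τ) versus τ over the
lags whose delays fall inside [204.8, 1228.8] ms — exactly lags 1…6 at the
204.8 ms frame interval — reported negated (`ocds_sign`), so a faster decay
yields a larger positive value, consistent with a positive "dead" cut-off.
Negative values from noisy voxels are not clamped.

### Estimator bias and the saturation of OCDS_l

Two properties of the 32-frame estimator shape the design:

1. **Saturation.** If the decay completes within the first lag
   (`τ_c ≲ 100 ms` for intensity correlation), ρ is already flat across the
   late window and OCDS_l ≈ 0 even though the dynamics are fast. From the
   analytic curve at m = 1, the late-window slope peaks near
   `τ_c ≈ 1.2–1.6 s` and decreases on both sides (analytic OCDS_l =
   3.0, 5.2, 5.4, 4.0, 2.5 ×10⁻⁴ ms⁻¹ at τ_c = 0.4, 0.8, 1.6, 3.2, 5 s).
   "OCDS_l increases with decay rate 1/τ_c" therefore holds only on the
   *unsaturated* branch, τ_c well above the window span; the ordering tests
   use τ_c ∈ {1.6, 3.2, 6.4} s.
2. **Mean-subtraction bias.** Per voxel, the temporal mean removes the
   static component, so the per-voxel correlation decays to zero regardless
   of m, and with only 32 samples a slowly drifting field (large τ_c) shows
   an artificially steep late-window decay. A "slow" region therefore does
   *not* read as low OCDS_l with this estimator. Consequently the oracle
   and ordering checks against the analytic curve use the pooled *ensemble*
   estimator (`metrics.pooled_autocorrelation`: Pearson correlation over
   all (voxel, t, t+k) pairs of a region), which is effectively unbiased,
   while the imaging pipeline keeps the per-voxel estimator that a 32-frame
   acquisition permits.

## Synthetic spheroid phantom

The generator rasterises an ellipsoid (radii in µm) with a smooth angular
perturbation of the boundary radius (sum of random von-Mises–Fisher bumps,
amplitude = `boundary_perturbation`, emulating drug-induced shape
corruption), a concentric necrotic core at relative radius
`core_fraction`, optional labelled sub-regions (spheres or radial bands),
and a bright static plate plane under the spheroid (10× tissue
reflectivity) to exercise plate removal. Speckle fields are generated per
voxel (filtered complex white noise), not by ray-tracing scatterers: the
analysis depends only on the field's spatio-temporal correlation, and this
construction has closed-form statistics. The dynamic component uses the
exact discrete Ornstein–Uhlenbeck update
`E_d(t+Δ) = a·E_d(t) + √(1−a²)·w`, `a = e^(−Δ/τ_c)`. Fields are blurred
with the Gaussian PSF (FWHM 18.1 µm lateral, 14 µm axial;
σ = FWHM/(2√(2 ln 2))) using wrap-around boundaries and renormalised by the
kernel's L2 norm, preserving unit per-voxel variance exactly. A shot-noise
floor is added as independent exponential intensity (default 10⁻³ of the
viable-shell reflectivity, ≈30 dB SNR). Oracle simulations disable the PSF
so voxels are statistically independent.

**Dynamics semantics.** Viable tissue: high m (0.5–0.85) with τ_c of a few
hundred ms, so the correlation decays measurably across the late window —
high LIV and high OCDS_l. Dead/necrotic tissue: small m (0.02–0.05) with
τ_c ≈ 50 ms — a noise-like residual that reads low in *both* contrasts (low
amplitude → low LIV; decay saturated within one lag and no slow drift →
OCDS_l ≈ 0). This choice follows from the estimator analysis above: residual
fluctuations in dead tissue are dominated by uncorrelated measurement
noise, and a slow-drift parameterisation would invert the expected contrast
under the per-voxel estimator. Regions that appear *only* in OCDS_l
(contiguous low-OCDS_l domains with unremarkable LIV, as under paclitaxel)
use high m with τ_c ≈ 60 ms: large-amplitude fluctuations whose decay
completes within the first lag.

**Drug scenarios.** `data/scenarios.json` holds one editable row per
(condition, treatment day): radii, core fraction, boundary perturbation,
shell/core dynamics and sub-region lists. The rows encode the qualitative
response patterns with known ground truth: control and low-dose tamoxifen
grow with an enlarging core; 10 µM tamoxifen shrinks (strongly after day
3) with large shape corruption and collapsing shell dynamics; paclitaxel
shrinks at 1/10 µM while accumulating low-LIV spots and concentration-
dependent low-OCDS_l domains; doxorubicin shrinks at 1 µM with a dead
peripheral rim but swells at 10 µM with concentric low/high-dynamics
layers; all effective treatments drive m down and τ_c toward the noise-like
regime, so mean LIV/OCDS_l fall and dead-cell ratios rise. The table is
calibrated to orderings only — absolute values, absolute volumes and real
anatomical texture are out of scope. `expected_directions` in the same
file records the expected sign of each condition's day-1 → day-6 change
(day-3 → day-6 for the 10 µM tamoxifen volume) and is what the end-to-end
study run is scored against.

## Segmentation and quantification

Segmentation operates on the temporal-mean dB volume: Otsu threshold (or a
user threshold in dB) → automatic plate removal → per-B-scan largest
connected region → largest 3D component → morphological closing (ball,
radius 1) → plate slab re-excluded → largest component again, guaranteeing
a single connected component that excludes the plate. Plate detection uses
the per-depth median intensity across all B-scans: the plate spans the full
lateral field, so its depth row is an outlier (> 6 SD above the median of
the other rows); a ±2-voxel slab around it is excluded. An empty result
raises "no spheroid found" with the threshold used.

Scalars per spheroid: volume = voxel count × voxel volume (voxel volume
derives from the FOV and pixel counts, so absolute volumes are
protocol-dependent); mean LIV and mean OCDS_l are arithmetic means over the
raw in-mask metric volumes (no smoothing); dead-cell ratios are fractions
of in-mask voxels *strictly below* 3 dB² (LIV) or 2 × 10⁻⁴ ms⁻¹ (OCDS_l).
Group comparisons use Welch's unequal-variance t-test with Satterthwaite
degrees of freedom, two-sided, computed directly and cross-checked against
an independent reference implementation in the tests; no multiple-testing
correction is applied to the three day-pair comparisons per condition.
Degenerate inputs: two identical constant groups give t = 0, p = 1;
constant groups with different means give p = 0. Note that at n = 3 per
group the Welch test is conservative — its empirical type-I error at
α = 0.05, which the acceptance script computes by simulation, sits near
0.035 rather than the nominal 0.05; this is a property of the
Satterthwaite approximation at minimal sample size, not of the
implementation, which matches the reference implementation to 10⁻¹⁰.

## Study pipeline and problem sizes

The study protocol keeps the full 1 × 1 mm field, block-repeat structure
(2 blocks × 16 locations) and 32 repeats, on a 32 × 48 × 48 voxel grid
(31.25 µm location spacing, 16 µm depth pixels, 20.8 µm lateral pixels) —
a grid chosen so the complete 90-spheroid study, which every qualitative
conclusion is computed from, runs in well under a minute per seed on one
CPU while leaving ≥ 10 voxels across the smallest spheroid radius. The
full-resolution 8-block protocol (128 × 256 × 128) remains the default for
protocol arithmetic and is configurable everywhere. Per-spheroid seeds fan
out deterministically from (master seed, drug, concentration, day,
replicate), so adding conditions never changes existing spheroids' data,
and a rerun with the same master seed reproduces byte-identical reports.

## Known limitations

* The phantom reproduces correlation structure, not anatomy: no
  depth-dependent attenuation, no refraction or shadowing under the
  spheroid, no systematic speckle blinking from scanner jitter, and
  sub-regions are geometric primitives. Passing tests show the *estimators
  and pipeline* behave correctly on fields with known statistics, not that
  real tissue obeys the two-parameter (m, τ_c) model.
* Absolute LIV values of the phantom's viable tissue (≈ 25–30 dB²) sit at
  the fully-developed-speckle ceiling and are higher than typical tissue
  values; only orderings and threshold crossings are meaningful.
* The per-voxel OCDS_l estimator is biased for slowly decorrelating voxels
  (see above); between-condition comparisons remain valid because every
  spheroid is processed identically.
* The scan schedule ignores inter-block flyback/settling time, so the
  per-volume wall time is slightly underestimated; per-location timing,
  which the metrics depend on, is exact.
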