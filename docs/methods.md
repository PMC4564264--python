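# Methods

## FRAP normalization

The bleach-spot trace is the per-frame arithmetic mean over pixels whose
centers fall inside the bleach ROI (0-based indices, centers at integer
positions; membership is center-in-circle, boundary inclusive). The
per-frame background-ROI mean is subtracted from both the bleach and
reference traces; the bleach trace is then divided by the reference trace
normalized to its own mean over the first five pre-bleach scans. This
ratio correction cancels *exactly* any multiplicative per-frame factor
shared by the two regions — the model of acquisition photobleaching — and
makes the normalized curve invariant to rescaling all intensities or
adding a constant offset to every pixel.

Anchors: I_max is the mean corrected intensity of the first five
pre-bleach scans; I_min is the corrected intensity at the first
post-bleach frame (not a minimum search, which would be biased low by
noise). f(t) = (I − I_min)/(I_max − I_min) × 100, so f is exactly 0 at
the first post-bleach frame and averages exactly 100 over the pre-bleach
anchor scans. Bleach efficiency is I_min/I_max × 100. I_max ≤ I_min and a
non-positive reference value are hard errors, never clamped.

## Recovery models and fitting

The diffusion model for a uniform circular bleach spot of radius w is

    f(t) = A e^(−2τ_D/t) [I₀(2τ_D/t) + I₁(2τ_D/t)],    τ_D = w²/(4D),

evaluated through the exponentially scaled Bessel functions
(`i0e`, `i1e`) so the large-argument regime (t → 0) cannot overflow; the
t = 0 value is the analytic limit 0, and f → A as t → ∞. The alternative
saturating single exponential is f(t) = A(1 − e^(−kt)). (A printed form
of the exponential that evaluates to 2A at t = 0 and decreases cannot
describe a bleach-then-recover experiment; the saturating form with the
same boundary behavior as the diffusion model is implemented.)

Fits use post-bleach points only — pre-bleach scans anchor the
normalization, not the model — with time zero at the first post-bleach
frame, matching the simulator's convention that the bleach is
instantaneous immediately before that frame. Nonlinear least squares runs
from a 3×3 multi-start grid (A₀ ∈ {0.25, 0.5, 0.9}; τ_D or 1/k starting
at {0.1, 0.5, 1.0} × the post-bleach time span), bounded A ∈ [0, 1.2]
(tolerating normalization overshoot) and timescale ∈ (0, 100 × span]; the
lowest residual sum of squares wins, and failure of all starts is
reported as `converged=False`, never silently. Per-cell fits are computed
first and aggregated afterwards; the pooled average curve is never
fitted. τ_D → D conversion is provided as a labelled convenience only.

The "significant recovery" decision averages each cell's f over the first
three post-bleach points (early bin) and over a late window (default
150–170 s after bleach) and compares the bins across cells with a
repeated-measures test; with two levels this is the paired t-test and the
F statistic is t². Under the null (flat curves, i.i.d. noise) the
rejection rate at α = 0.05 is calibrated to 0.05 (verified by Monte
Carlo). Whether the original analysis binned within cells or across
treatment groups is not documented; the within-cell two-bin design is the
implemented reading.

## Fluctuation (σ²/μ) analysis

Per-pixel temporal mean μ and *unbiased* (n−1) variance σ² over the
series; at 225 frames the estimator choice moves the ratio by <0.5%, but
tests fix the convention. For independent Poisson counts E[σ²/μ] = 1
regardless of rate — the detector calibration the analysis rests on.
Pixels with μ = 0 are flagged undefined (NaN), not coerced, so background
statistics are not distorted. No temporal ordering is used, so the map is
invariant under frame permutation; consequently slow drift inflates the
ratio, and a boxcar detrend option exists but defaults off to match the
raw-counts protocol. A static intensity offset strictly dilutes a
super-Poisson ratio toward 1, which is why region comparisons only make
sense between matched acquisitions.

Segmentation of cell vs background is a quantile threshold on the mean
image (default: cell above the 0.90 quantile after small-object removal,
background below the 0.50 quantile); manual outlining is out of scope and
user-supplied masks bypass segmentation entirely. Region comparison
computes one mean ratio per acquisition and region and pairs them in a
t-test across acquisitions.

## Nonlinear capacitance and morphometry

C(V) = C_lin + Q_max α b/(1+b)², b = e^(−α(V−V_h)) — the derivative of a
two-state Boltzmann charge transfer, the standard form for prestin NLC;
α absorbs zF/RT of the valence parameterization. The curve is symmetric
about V_h, peaks at C_lin + Q_max α/4, and integrates over voltage to
exactly Q_max. Units are kept consistent as capacitance in pF, voltage in
mV, charge in fC (1 pF·mV = 1 fC). Initialization: C_lin from the
capacitance minimum, V_h from the peak location, α = 0.03 /mV, Q_max from
the peak identity; parameters are bounded positive (V_h free). A peak at
a sweep endpoint sets a warning flag since V_h is then extrapolated.
Group Q_max ratios are reported as percent of a reference group with SEM
by first-order (delta-method) propagation.

Morphometry is the cylinder formula A_lat = πDL on user-supplied length
and diameter measurements; 3-D reconstruction is out of scope.

## Synthetic generators

**FRAP.** The membrane is a horizontal strip (default rows 32–96 of a
128×128 grid at 0.203 µm/pixel): a closed reservoir ~27× the bleach-disc
area, so finite-reservoir depression of the plateau is negligible.
Fluorophore density splits into an immobile field (1−φ) and a mobile
field (φ); between frames the mobile field is convolved with an isotropic
Gaussian of per-axis σ = √(2DΔt) (reflective boundaries at the strip
edges) — the ensemble description the recovery model assumes. The bleach
is instantaneous at the frame boundary before the first post-bleach
frame, multiplying both fields by (1−β) inside the disc; every frame all
fields decay by (1−k_acq); detection is Poisson with mean
gain × density + dark rate. An independent particle-level random-walk
simulator (2×10⁶ walkers) lives in the test suite and reproduces the same
ensemble recovery, and the Axelrod fit recovers φ and w²/(4D) from both.
Defaults state the analysed regime: Δt = 10 s, 5 pre- + 17 post-bleach
frames (170 s), w = 2 µm, β = 0.6 (within the 50–75% bleach-depth
setting), φ = 0.75 and D = 0.1 µm²/s (τ_D = 10 s) for the mobile case,
k_acq = 0.002/frame, gain 100 counts/density (spot-mean SNR ≫ 10).
Whether "50–75% bleached" refers to the removed fraction or to the
efficiency I_min/I_max is ambiguous in the source description; the
generator exposes β (the removed fraction) directly and does not resolve
it.

**Number & brightness.** Defaults 225 frames of 256×256 pixels (the
photon-counting acquisition regime). Fixed emitters deposit a static
normalized Gaussian kernel (σ = psf_sd); mobile emitters take one
Gaussian random-walk step per frame with periodic boundaries; counts are
Poisson with mean background + ε × summed kernel weights, so each emitter
contributes exactly ε expected counts per frame. Background defaults to
2 counts/pixel/frame (the calibration benchmark's rate; the Poisson
identity is rate-independent). Ground-truth occupancy masks (within
2 psf_sd of fixed emitters, and of the mobile trajectory) ride along.

**NLC.** The exact Boltzmann curve plus i.i.d. Gaussian noise; default
noise 0.13 pF ≈ 2% of the peak NLC at the default Q_max = 750 fC,
α = 0.035 /mV, V_h = −70 mV, C_lin = 7 pF — typical healthy-OHC values.

What the generators do *not* emulate: 3-D sectioning optics and axial
drift, EMCCD read/gain noise (detection is pure photon counting plus an
optional gain), membrane curvature, binding/unbinding (reaction–diffusion
FRAP), cell-to-cell biological variability beyond the seeds. A green
parameter-recovery test therefore establishes correctness of the analysis
chain under the stated statistical model, not robustness to every
instrumental artifact of live-cell data.

## Numerical and testing choices

Seeds are explicit and mandatory for every stochastic operation; stacks
are bit-reproducible from params + seed. Bessel evaluation is checked in
tests against two independent oracles: a 20-term power series (small
arguments, the printed constants e⁻²(I₀(2)+I₁(2)) ≈ 0.5237 and
e⁻¹(I₀(1)+I₁(1)) ≈ 0.6737) and the integral representation
e⁻ˣIₙ(x) = (1/π)∫₀^π e^(x(cosθ−1)) cos(nθ) dθ evaluated by trapezoidal
quadrature, which stays conditioned at arbitrarily large x (grid
agreement to 10⁻¹⁰). Monte-Carlo null calibrations of both statistical
decisions use 1000 replicates on small fields — the type-I rate of a
paired t-test does not depend on map size, and full-size maps would waste
the runtime budget.

## Known limitations

* The Axelrod model assumes an effectively infinite reservoir and a
  uniform disc bleach; strongly depleted (small) cells or Gaussian bleach
  profiles bias A low and τ_D accordingly.
* Acquisition-bleach correction assumes the reference region bleaches at
  the same per-frame rate as the bleach region; differential bleaching is
  not modelled.
* σ²/μ distinguishes mobile from fixed but deliberately stops short of
  molecular-brightness (ε, n) decomposition or detector S-factor
  calibration for analog detectors.
* The "second-order Boltzmann" terminology in the NLC literature is not
  tied to a single printed equation; the implemented derivative-of-
  two-state form matches the bell shape and peak/integral identities but
  a squared-exponent variant cannot be ruled out from shape alone.
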