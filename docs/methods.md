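# Methods

## The observer and its three calculation routes

The nonprewhitening matched filter applies the expected-signal template
Δī to an image and thresholds the scalar L = Δī^T i.  The three routes
implemented here differ only in what they estimate from data:

1. **Fourier** (`dprime_fourier`): assumes shift invariance and
   (quasi-)stationary noise, so the template and covariance collapse to
   radial curves — the task spectrum ΔF, transfer function T, and noise
   power spectrum N.  d′² = [∫|ΔF|²T² dν]² / ∫|ΔF|²T² N dν, evaluated as
   1-D radial trapezoids with 2πρ weighting on a grid of 2048 points up
   to the Nyquist frequency of the coarser input.
2. **Spatial, Gaussian responses** (`dprime_spatial` → `auc_from_dprime`):
   needs no stationarity; d′ from the sample means and unbiased sample
   variances of the decision variables, AUC = Φ(d′/√(1+β)/√2).
3. **Spatial, nonparametric** (`auc_empirical`): needs neither
   stationarity nor Gaussianity; the exact pairwise comparison over all
   n₁n₂ pairs with the tie convention H(0) = ½, internal noise entering
   as Φ((L₂−L₁)/σ) with σ² = β(Var[L₁]+Var[L₂]).

Internal noise β defaults to 3.0, the value that matches this observer
family to human forced-choice performance on low-contrast CT tasks; β is
a pure efficiency degradation and does not alter the ranking of
conditions within one route.

## ROI geometry and background correction

The feature ROI is a circle of the feature's physical radius in pixels
(kept real-valued, not rounded) expanded by `n_exp` pixels; the local
background is the mean of an annulus `n_ann` wide starting `n_gap`
beyond the ROI, averaged over all repeat scans, computed per slice
position.  Defaults `n_exp = n_ann = n_gap = 4` (a `catphan` preset sets
3, 3, 3).  Annulus pixels inside a neighbouring feature's ROI are
excluded.  Feature-absent ROIs mirror the feature ROIs about the image's
vertical midline by default; an explicit centre list is accepted for
layouts where the mirror position is occupied.  Pixel centres sit at
integer (row, col) coordinates; mm positions map through the pixel size.

## The analytic d′ uncertainty and the ROI-route estimator

The relative one-sigma uncertainty of a repeat-scan d′ estimate,
u = 100·√(1/(nm·d′²) + 1/(4(n−1)m)), corresponds term by term to an
estimator in which (a) the numerator is the present-class mean alone —
legitimate because the background-corrected absent class has zero
expectation by construction — and (b) the class variances are estimated
per slice across repeats and pooled over both classes, giving 2(n−1)m
degrees of freedom.  `dprime_roi_route` implements exactly this
estimator and reproduces u in simulation to within a few percent (250
ensembles, n = 10, m = 5, designed d′ = 2.79: sd ratio 1.03).  The
generic pooled estimator `dprime_spatial` is what the d′ point estimates
use; its sampling sd is ~12–15% larger than u in the same conditions
because both class means are estimated and the variance pool has
2(nm−1) effective degrees of freedom.  Confidence intervals for method 2
are built on the d′ scale (±1.959964 σ_d′) and mapped through the
Gaussian-response relation; a delta-method interval on the AUC scale
agrees within the third decimal.

## NPS estimation

Noise realisations are each image minus the across-repeat mean of its
slice (removing the deterministic scene), rescaled by n/(n−1) for the
variance deficit of mean subtraction.  Square background ROIs (default
128 px) are laid on an overlap-thinned grid avoiding all feature and
absent ROIs; each ROI is detrended (mean removal), Hann-tapered, and its
periodogram (Δx·Δy/Σw²)|DFT|² averaged and binned radially with width
1/(roi_size·Δx).  Three bias controls matter for strongly coloured
(ramp-like) spectra and were verified against the known synthetic NPS:
the Hann taper suppresses boxcar sidelobe leakage into the deep
low-frequency hole; the DC and first radial bins — destroyed by
detrending and mainlobe mixing — are replaced by linear extrapolation
from bins 2–5 (exact for flat spectra); and each bin reports its
occupancy-weighted mean frequency rather than the nominal centre, which
halves interpolation error across the spectral peak.  With these, the
Fourier d′ of a stationary simulated ensemble is unbiased to ~1%.

## TTF estimation

From the across-repeat mean image: intensity-weighted centroid of the
thresholded disk, radial edge-spread function in 0.1-px bins (empty bins
interpolated), derivative to a line-spread function, Hann window centred
on the edge, and the modulus of the continuous Fourier transform
normalised at zero frequency; the curve is truncated to zero beyond its
first zero crossing.  Requires a disk of at least ~15 px diameter and a
mean-image contrast-to-noise ratio above a configurable threshold
(default 15).  Against a closed-form Gaussian PSF the estimate is within
3% down to the 10% amplitude point when the PSF is resolved (σ ≳ 3–4
pixels); at coarser sampling the measured curve correctly includes the
pixel-aperture transfer of the image itself.

## The synthetic phantom

`default_phantom` renders a 320×320 grid at 0.469 mm (a 150 mm field, the
pixel pitch of a 240 mm / 512 reconstruction): a 6 mm, 10 HU task disk, a
16 mm, 100 HU disk for TTF measurement, Gaussian PSF σ = 0.8 mm, and
correlated noise with a ramp-apodised radial NPS
S(ρ) ∝ ρ·exp(−(ρ/0.35 mm⁻¹)²) at 20 HU — chosen so the task disk sits
near d′ ≈ 2.8, i.e. AUC < 0.9 at β = 3, the regime where low-contrast
detection is genuinely uncertain.  Disks are rasterised by
centre-in-circle membership on a 4× supersampled grid and block-averaged
(anti-aliasing that keeps 2 mm features free of quantisation bias);
noise is coloured white Gaussian noise, scaled so the ensemble pixel
variance is exact, with one child stream per repeat×slice spawned from a
single master seed.

The denoiser surrogate is an edge-preserving shrink toward a Gaussian
smooth, gated by local gradient magnitude relative to a 10 HU/px scale:
flat regions lose noise, strong edges survive.  It reproduces the
qualitative behaviour of iterative/deep-learning reconstruction that
matters here — background NPS suppression with preserved high-contrast
edges and smoothed faint features — but no vendor algorithm's quantitative
behaviour.  What the simulator deliberately omits: anatomical background
structure, reconstruction streaks, slice-direction correlations, and
non-Gaussian photon statistics.  Passing tests therefore demonstrate the
estimators and the direction of the Fourier/spatial divergence, not
scanner-specific magnitudes.

## Test problem sizes

Cross-method and consistency checks run at n = 110 repeats × m = 5
slices (the repeat-scan study size); the cross-method comparison
averages three independent ensembles because a single spatial d′
estimate carries ~3% sampling sd at nm = 550, which a 5% equivalence
check must not conflate with systematic disagreement.  The uncertainty
calibration uses 250 ensembles at n = 10, m = 5 to keep hundreds of
full simulate-extract-estimate cycles inside a few minutes.  The M-AFC
conversion is verified against a 10⁶-draw Monte-Carlo oracle; all other
oracles are closed forms or exhaustive enumeration.

## Degenerate inputs and numerical conventions

Zero-noise ensembles produce decision variables whose pooled variance is
only floating-point dust; a relative threshold (10⁻¹⁰ of the decision
scale) converts these to explicit degenerate-variance errors, which the
pipeline turns into per-method skips rather than aborts.  AUC saturation
at 1.0 (very high d′) is handled by building CIs from d′ directly.  The
M-AFC psychometric function is integrated with adaptive quadrature to
1e-10 and inverted by bracketed root finding; below-chance proportions
return AUC < 0.5 with a warning rather than an error.  All randomness in
the pipeline descends from one configured seed, and reports are written
without timestamps, so reruns are byte-identical.
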