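# Methods

This note documents the models, numerical choices and open design decisions
behind `lumigain`, and what the synthetic-data generators do and do not
emulate.

## Units and geometry

All luminance inside the stimulus and recording pipelines is in normalized
units L/I_max ∈ [0, 1]; the physical maximum photon rate
(I_max ≈ 2.17×10⁵ photons s⁻¹ photoreceptor⁻¹) is carried as metadata only.
The screen is flat, 60°×60° at 0.5°/pixel and 100 Hz by default, with
x = azimuth, y = elevation, the origin at the screen center and pixel
centers at half-integer multiples of the pitch. Drifting gratings reference
their phase so that the central pixel sits at the luminance peak at epoch
onset; this makes the rendered extremes — and therefore the measured
Michelson contrast — exact at onset. Extremes at later frames fall between
pixel centers and are exact only when the frame-phase step is a multiple of
the pixel-phase step.

The one deliberate exception to normalized units is the Tm circuit
simulation (below), which defaults to the grating intensities in physical
photon rates.

## LMC membrane model

The lamina-neuron model integrates much faster than the stimulus changes,
so the membrane ODE dv/dt = −(v − v_L) + g⁻¹s(t) is evaluated at its
pseudo-stationary point v = v_L + g⁻¹s throughout; an explicit-Euler
integrator exists purely to validate that approximation and is off by
default. The calcium proxy is α·max(v, 0)² with a ramp rectifier.

**Identifiability and the fitting gauge.** Whenever the rectifier never
engages — true for every non-negative stimulus when v_L > 0 — the response
is *exactly* invariant under (g⁻¹, v_L, α) → (k·g⁻¹, k·v_L, α/k²). Only two
parameter combinations are then identifiable from response data, no matter
the optimizer. `fit_membrane_params` therefore runs bounded multi-start
nonlinear least squares (bounds g⁻¹ ∈ [0,1], v_L ∈ [−1,1], α ∈ [0,100];
8 seeded random restarts plus one heuristic start) over all three
parameters and afterwards rescales the solution along the invariance ridge
so that v_L equals a reference value (default 0.3); the rescaling is
adopted only when it does not increase the cost, so rectified regimes where
the symmetry is broken are left untouched. A second, softer conditioning
limit remains within the gauge: at the L3 parameter scale the quadratic
term of the F1 surface is only a few percent of the signal, so ~5% response
noise produces tens of percent of scatter in g⁻¹ and α individually even
though the fitted response surface is recovered to well under the noise
level. Tests assert exact noiseless recovery, consistency (error shrinking
proportionally with noise), and response-surface recovery — not tight
parameter recovery at high noise, which the data do not support.

L2 parameters are not independently constrained here; L2 defaults to the
L3 values and is overridable, with the choice recorded in run metadata.

## Synthetic scene ensembles

The generator emulates calibrated photographs of one scene under different
illuminations. A log-reflectance field with an isotropic 1/|k| amplitude
spectrum (spectral exponent β = 1, log-s.d. 0.8 — natural-image-like
second-order statistics) is exponentiated to positivity and shared by all
conditions. Each condition multiplies it by a smooth log-normal
illumination field (Gaussian correlation scale 8° of visual angle) and is
rescaled to an exact target mean: "shaded" conditions have mean 0.1 and
weak illumination structure (log-strength 0.15, diffuse light), "sunny"
conditions mean 0.4 (4× brighter) and strong structure (log-strength 0.5,
cast shadows). The default ensemble is 256×256 px at 0.25°/px with four
conditions: two gain levels × two illumination fields. What this does *not*
emulate: occlusion edges, specularities, sky/ground anisotropy, chromatic
content, and camera noise — so passing tests demonstrate the pooling
trade-off under controlled second-order statistics, not performance on
arbitrary photographs.

Gaze trajectories are forward waves T(z) = 30·sin(2π·3·ω_z z) + γz +
60·N(0,1) with ω_z the inverse horizontal scene length and γ = 1/3 by
default; z and T are in pixels, the noise is i.i.d. per sample, and
vertical positions are clipped to the image. Trajectories are sampled at
pixel resolution along z.

## Pooling normalization and the loss

`normalize_by_pooled_luminance` divides a response image by
(g_l + disc-mean of the raw scene luminance), with uniform weights over
pixels whose centers fall in the disc and boundary discs renormalized over
in-bounds pixels; g_l defaults to 0.05 in normalized units.

The pooling *scan*, however, normalizes by the pooled lamina **response**
by default: the divisor is g_l plus the disc-summed LMC response expressed
in medulla-column units (disc mean × discs's column count; hexagonal column
area √3/2·pitch² at the 5° column pitch). This is the circuit-consistent
reading — the wide-field neuron sums lamina inputs over columns, and the
lamina signal is the luminance signal — and it is what produces the
documented trade-off: at sub-column pooling the divisor tracks each point's
own response (structure collapses and the divisor is tiny, so the loss and
its variance blow up), at near-global pooling the summed divisor grows with
disc area (responses shrink and condition-specific illumination structure
survives), and in between, around the diameter where the summed pool has
roughly unit gain (a few columns), both terms are small. Dividing by pooled
raw luminance instead (`background="luminance"`) is retained as an option;
with the compressive LMC response at normalized luminance scales it leaves
a pooling-independent offset between conditions and produces no interior
minimum.

Wasserstein distances are computed exactly from the raw samples (integrated
absolute CDF difference), never from the KDE; the Gaussian KDE (Scott's
rule, 512-point grid spanning the samples ±3 bandwidths) is reporting and
visualization only. This removes bandwidth sensitivity from the loss; it
also means the KDE is not invariant to duplicating samples (Scott's factor
depends on n) while the loss is. In the loss, term 1 compares the two
conditions' normalized distributions; term 2 compares the dimmer
condition's mean-centered raw and normalized distributions, following the
printed form (a switch selects the brighter condition instead). Pairs are
ordered brighter/dimmer by scene mean, and the scan reports mean ± s.d.
across all condition pairs.

## Tm normalization circuit

Columns are laid out on a 1-D row at the 5° medulla pitch within the
pooling diameter (15° → 3 columns; a 2-D hexagonal layout is a possible
extension, the 1-D row matches the wide-field neuron's ~3-column span).
Each simulated trace draws one uniform phase shared across columns up to
the per-column spatial offset 2π·x_i/λ; J is the *sum* (not mean) of column
responses as the circuit equation states, and the quadratic variant applies
p to the summed pool (J²), with per-column squaring left as an alternative
reading. F1 amplitudes are computed over exactly one stimulus period
(200 samples), matching the analysis pipeline's convention (a pure sinusoid
of amplitude A reads A).

**Luminance units.** The circuit simulation defaults to the five printed
grating intensities in photons s⁻¹ (1.2–10.6 ×10⁴). Divisive luminance
invariance of the p = 1 circuit requires the regime g⁻¹L ≫ v_L, where both
the main input's F1 and the pooled signal grow ∝ L²; at normalized
luminance (L ≤ 0.5, g⁻¹L ≤ 0.025 ≪ v_L = 0.3) the pooled signal is nearly
luminance-independent and no choice of g_l flattens the curve. The printed
membrane parameters act as dimensionless gains on whatever stimulus scale
is supplied, and only the photon-rate scale reproduces the flat Tm1 and
inverted Tm9 curves; it is therefore the default, with the luminance grid
fully caller-configurable.

**Leak conductance.** g_l is not printed anywhere; the default comes from a
seeded one-dimensional calibration minimizing |slope| of the p = 1 model at
15° pooling over log₁₀ g_l ∈ [−3, 8] (64 evenly spaced phases for a smooth
objective). In the photon-rate regime the objective is flat for any g_l
small against the pooled signal, and the calibration settles near the lower
bound; the exact value is immaterial there, which is itself the invariance
property. Slopes for comparing models are computed on max-normalized F1
curves (each curve divided by its maximum, as the recordings are normalized
per fly) against log₁₀ luminance; comparing raw-unit slopes would make the
ratio an artifact of absolute response scale.

## Imaging analysis

- ΔF/F: baseline is the trace mean by default, or the mean of the first 4 s
  (mid-luminance prelude) for noise protocols; non-positive baselines raise
  an error naming the ROI.
- Trial reliability: mean of *pairwise* Pearson correlations across trials
  (not trial-vs-mean); keep threshold 0.6, configurable. Zero-variance
  trials make the value undefined and flag the ROI.
- F1 amplitude: 2|DFT coefficient|/N over the largest whole number of
  stimulus periods, with a half-bin alignment tolerance; linear in amplitude
  and phase-invariant.
- Luminance slope: OLS slope of response vs log₁₀ luminance.
- OFF-edge metric: peak in the edge window minus the mean of the preceding
  1 s window.
- Contrast–luminance heatmap: order-1 spline zoom ×5 (5×5 → 25×25), then
  Gaussian smoothing with σ = 10 interpreted in zoomed-grid pixels (the
  alternative, base-grid units, is configurable), then 8 contour levels
  spaced linearly strictly between the extrema (quantile spacing was the
  other open reading); a constant map is flagged degenerate, not an error.
- STRF: the trace is linearly interpolated to the 20 Hz update rate, ΔF/F
  against the prelude, mean-centered; stimulus levels map to {−1, 0, +1};
  kernel[τ] = Σ r_t s(t−τ)/(T−τ) over a 2 s backward window, with the
  normalization constant fixed at the window length as printed.
- STRF quality filters: default keeps max|kernel| ≥ 0.005; the low-SNR mode
  (for noisier indicators) keeps amplitude ≥ 0.003 *and* SNR ≥ 10. The
  literal SNR reading "max of the STRF divided by its mean" is numerically
  unstable because a sign-balanced kernel has mean ≈ 0; SNR is implemented
  as max|kernel| / mean|kernel| (peak versus background), preserving the
  screening intent.
- Filter extraction uses the kernel *minimum* (OFF cells have negative
  STRF amplitudes), ties broken at the first occurrence in row-major order;
  the FWHM constant is the exact 2√(2 ln 2) = 2.3548…, matching the rounded
  2.355 to three decimals.
- Gaussian fits (1-D and 2-D) are nonlinear least squares initialized at
  the extremum location with second-moment width estimates; non-convergence
  returns a flagged result rather than raising.

## Synthetic recordings

Ground-truth neurons are linear–nonlinear: Gaussian spatial weighting of
the movie, subtraction of the full-field background P(t) (the spatial frame
mean — exact for gratings spanning whole wavelengths; an optional smoothing
window exists for stimuli without that property), polarity flip for OFF
cells, then one of three gain laws: none (luminance-scaling, lamina-like),
division by g₀+P (invariant, Tm1-like) or by g₀+P² (low-luminance
enhancing, Tm9-like), with g₀ = 10⁻³ normalized units — far below the
lowest stimulus luminance (≈0.055), so the division is luminance-dominated
across the tested range, which is what the gain law means. The result is
convolved with a calcium-indicator kernel (unit-area biexponential, 50 ms
rise, 400 ms decay; a delta kernel gives instantaneous responses for
estimator tests), rescaled to a target peak ΔF/F (0.3), sampled at the scan
rate (default 12 Hz, typical of the 10–15 Hz two-photon range; 20 Hz is
used for reverse-correlation recovery tests so that no stimulus information
is lost to scanning), and repeated over trials with fresh additive Gaussian
noise (s.d. = noise_sd × response s.d.). Not emulated: neuropil
contamination, bleaching, motion, indicator saturation — recovery results
bound estimator error, not biological measurement error.

## Anatomy geometry

Principal axes come from the eigendecomposition of the centered covariance
of the synapse cloud; near-collinear clouds (second eigenvalue ≤ 10⁻¹² of
the first) are rejected. Sign conventions (axis z-positive, basis vectors
largest-component-positive) make the basis reproducible. Volumes are
represented by their synapse point clouds and flattened by orthogonal
projection; area is the 2-D convex hull of the projection, the column span
is the maximal pairwise projected distance over *all* points (identical to
using hull vertices) divided by the 11.2 μm column pitch.

## Reproducibility plumbing

Every stochastic stage derives an independent substream from the global
seed via `numpy.random.SeedSequence` spawn keys; HDF5 outputs are written
without timestamps so identical configurations produce byte-identical
files, which the pipeline manifest verifies by SHA-256.

## Problem sizes

Defaults were chosen so each analysis is statistically comfortable yet runs
in seconds on one core: 1000 random-phase traces for circuit curves (slope
s.d. across seeds ≪ the effects measured), 15 trajectories per condition on
a 256² scene for the pooling scan, 10 minutes of 20 Hz ternary noise
(12 000 updates) for receptive-field recovery, 25 grid points for the
membrane fit, and 3 trials per synthetic recording.

## Known limitations

- The pseudo-stationary membrane evaluation ignores genuine temporal
  filtering in lamina neurons; the Euler mode only validates the limit.
- The pooling scan's absolute loss values depend on the response-unit
  convention of the divisor; the *shape* over diameters is the meaningful
  output.
- The KDE is descriptive; quantitative distribution comparisons go through
  the sample-based Wasserstein distance.
- Gaussian RF fits assume a single dominant lobe; center–surround kernels
  would need a difference-of-Gaussians extension.
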