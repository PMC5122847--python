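# Methods

This note documents the models, conventions and numerical choices behind
`smtrack`, in the spirit of a methods section: what is computed, under what
assumptions, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and units

Pixel coordinates are 0-based; a localization at the center of pixel
(row i, col j) has x = j, y = i, and sub-pixel positions are floats in
pixel units.  Physical positions are `x * pixel_size_nm`.  Frames are
0-based integers in [0, T).  Movies carry a `unit_flag`: `counts` before
camera correction, `photons` after — the Poisson likelihood is only valid
in photon units.

## Camera correction

`photons = max(0, counts − offset − dark) / gain`, with `dark` the
pixelwise mean of a dark-calibration movie when one is supplied.  Negative
corrected values are clipped to zero (a Poisson mean cannot be negative);
the clip count is logged.  EMCCD excess noise and flat-field correction are
out of scope.

## Detection

All filters use mirror boundary handling to avoid spurious edge maxima.

* **bandpass** — difference of two Gaussian smoothings (feature scale vs
  background scale); zero response on constant input.
* **crosscorr** — normalized cross-correlation of each window against a
  pixel-integrated Gaussian template; values in [−1, 1]; zero-variance
  patches score 0 (a flat patch is never a candidate).  Scores are
  invariant to additive intensity offsets.
* **wavelet** — à-trous (undecimated) B3-spline decomposition; the n-th
  detail plane is the score (default plane 2, which isolates structure at
  the scale of a diffraction-limited spot).  The decomposition is exactly
  invertible: detail planes plus the final smooth plane reconstruct the
  input.  The noise level is estimated robustly from the finest plane as
  `median(|plane1|)/0.6745`, and the suggested threshold is `k_sigma`
  (default 2.0) times that.  Which detail plane and threshold constant to
  use are genuinely open choices; both are exposed as parameters.

Candidate extraction keeps strict local maxima above the threshold
(strict inequality), suppresses any maximum within `min_distance`
(Euclidean) of a stronger one — equal scores resolved in favour of the
smaller (y, x), for determinism — and drops candidates within half a fit
window of the border so refinement is always well-posed.

## Refinement

The PSF is a pixel-integrated 2D Gaussian (see README for the formula).
For the astigmatic model the pixel integration is performed along the
rotated principal axes at each pixel center — exact for θ = 0, the
standard approximation otherwise.

Fitting minimizes the Poisson negative log-likelihood with L-BFGS-B.
Positivity of N, b, σ is enforced by optimizing their logarithms (with
wide log-bounds that keep the model finite); the position is bounded to
the fit window.  Initialization: position from the candidate pixel,
background from the window-border median, N from the
background-subtracted window sum, σ from `sigma_init` (default from
σ = 0.21·λ/NA).  Convergence uses scipy's function/gradient tolerances
derived from `tol` (default 1e-6, `max_iter` 100); an all-zero window
yields a flagged non-converged localization rather than an exception.

**Precision** is the CRLB of the fitted model: the Fisher information
`I_ij = Σ_k (∂μ_k/∂θ_i)(∂μ_k/∂θ_j)/μ_k` over the fit window, with central
finite differences in the natural parameters, inverted and evaluated at
the fitted values.  This is model-consistent by construction (isotropic
and astigmatic fits get precision from their own model) and is validated
against Monte-Carlo refit scatter in the tests.  In the bright-spot
regime with negligible background it reproduces the shot-noise limit
σ·a/√N.

A caveat verified empirically in this package: the CRLB is attained by
the MLE only in its asymptotic regime.  At N ≥ 100 photons (b = 10) the
refit scatter matches the bound within a few percent, but for very dim
spots (N = 50, b = 10, peak-pixel SNR ≈ 1.7) the error distribution
develops heavy tails — background fluctuations inside the window compete
with the true spot — and the empirical std exceeds the bound by ~25-30%.
A multi-start global optimizer makes this worse, not better; the excess
is a property of the likelihood, not of the optimizer.

**Signal-to-background ratio** (`sbr`) is defined per pixel: the expected
signal photons in the pixel under the fitted position divided by the
fitted background.  This makes the dSTORM quality cutoff (0.8) scale-free.

**radial_symmetry** offers a non-iterative alternative: the weighted
least-squares intersection point of image-gradient lines on the
half-pixel dual lattice.  It needs no photon calibration and is exact for
noiseless radially symmetric input; a gradient-free window returns its
center, flagged degenerate.

## Tracking

"Nearest neighbor" is resolved as per-frame-pair *optimal* assignment
(`scipy.optimize.linear_sum_assignment`) restricted to pairs within
`max_dist`: maximum number of links first, minimum total distance among
those — deterministic and processing-order-independent, unlike greedy
matching, and testable against an exhaustive brute-force oracle.  A track
unmatched at its last frame stays open for up to `max_gap` frames and may
claim a localization g frames later within radius `max_dist·√g` (the
scaling expected of diffusive motion).  Tracks shorter than `min_length`
are removed; ids are assigned in order of track start (frame, y, x).
Kalman motion models and merge/split events are out of scope.

## Simulator

* **Star geometry** — emitters are placed uniformly at random on the "on"
  sectors (angular width π/n) of an n-arm star inscribed in the field.
  The emitter count is Poisson with mean `density ×` (on-area in px²);
  the published density figure (7.5 px⁻¹) does not carry a
  self-consistent areal unit, so the absolute count is exposed as an
  override (`n_emitters`).
* **Kinetics** — the standard two-state telegraph model in continuous
  time: dark times Exp(k_on), active durations Exp(k_deactivate) with
  k_deactivate = k_off + k_bleach, and bleaching with probability
  p_bleach = k_bleach/k_deactivate at the end of each active period, so
  the number of activations before bleaching is geometric.  "Poissonian"
  dwell-time language in the SMLM literature is interpreted as these
  exponential dwell times — the only continuous-time reading consistent
  with the rate identities 1/k_active = 1/k_deactivate + 1/k_on.  The
  per-frame ground truth stores the active fraction A ∈ [0, 1] of each
  frame.  Defaults: k_off = 1, k_bleach = 0.15 frame⁻¹,
  k_on = k_off/(5·density).
* **Rendering** — expected image b + Σ A·N·g(μ) with g the integrated
  Gaussian of σ from the optics (λ = 670 nm, NA = 1.4, a = 100 nm,
  N = 50, b = 10 by default); every pixel drawn Poisson.  **SNR** is
  defined as peak-pixel signal over the Poisson noise at the peak,
  s/√(s + b), averaged over active emitters; normalizing to a target SNR
  rescales N globally (solved by bisection).  This is the common
  shot-noise form; the definition is a package convention and is exposed
  in the configuration.
* **Grid preset** — 16 × 16 always-on emitters on a 512 px field, one
  expected frame duplicated 3500 times with noise redrawn per frame
  (duplicating noisy frames would make repeated detection trivial);
  16² × 3500 = 896,000 ground-truth instances.
* **Brownian preset** — per-frame Gaussian steps of per-axis variance
  2·D·t_a, reflected at the field borders; defaults 200 particles,
  200 frames, SNR 10.

All generators are bit-deterministic under a fixed seed (independent
child seeds for geometry, kinetics and noise).

## Evaluation

Matching uses the same optimal-assignment machinery as tracking, per
frame, with a default pairing radius of 2σ_PSF (the common SMLM-challenge
convention; the radius is a parameter).  JAC = TP/(TP+FN+FP) exactly;
RMSE is over paired distances (reported in nm when a pixel size is
given).  Two empty sets score JAC 1 / RMSE 0, flagged degenerate.

FRC bins both localization sets into super-resolution histograms
(default 10 nm), correlates their Fourier transforms over integer-radius
frequency rings, smooths the curve with a 3-ring moving average (raw ring
noise causes spurious early crossings), and reports the inverse of the
first frequency where the smoothed curve drops below 1/7 of its maximum.
Ground-truth-versus-observations is the default mode for simulations;
split-half FRC is available by passing the halves explicitly.

## Post-processing

The dSTORM filter chain keeps sbr > 0.8 and |σ − 1.42| ≤ 0.4 px
(defaults; both exposed), and discards localizations on tracks longer
than 25 frames (non-blinking fluorophore clusters; exactly 25 is kept).
Super-resolution rendering is a 10 nm histogram, either plain counts or
with each localization splatted as a unit-integral integrated Gaussian of
per-axis width equal to its precision ("weighted by localization
precision"); an amplitude-weighting variant would change normalization
and is deliberately not offered.

MSD analysis pools within-track displacement components per axis at each
lag k ≤ 5 (default); intervals spanning a gap-bridged stretch are
excluded since their effective Δt is ambiguous.  The per-lag variance is
the closed-form zero-mean Gaussian MLE, mean(d²) (a histogram
least-squares mode exists for comparison; both agree asymptotically).
The per-axis convention σ²(k·t_a) = 2·D·k·t_a + ε fixes the dimensional
factor: D is half the OLS slope over lag times and ε absorbs localization
error and finite exposure.  Negative D estimates are flagged, never
silently clipped.

## Benchmark problem sizes

The standard benchmarks (see `smtrack.benchmarks`, used by the test suite
and `scripts/acceptance.py`) run at desk scale, chosen so the whole suite
completes in minutes on one core while keeping photon budgets, kinetics
and per-frame spot density at their standard values:

* kinetics identities: 10⁴ emitters simulated to bleaching;
* CRLB comparison: 1000 Poisson refits of one spot (N = 50, b = 10,
  σ = 1 px, 9 px window);
* SNR sweep: 128² px fields, 100 frames, 1500 emitters on the star
  (≈ 35 active emitters per frame — STORM-like sparsity), SNR ∈ {2, 3, 5},
  wavelet detection, 2 px pairing radius, 10 nm FRC super-pixels.  The
  Jaccard index and FRC use the full truth/localization sets.  The
  headline RMSE is computed over matched pairs whose truth emitter was
  active ≥ 75% of the frame with no simultaneously active neighbor within
  4 px.  Two verified confounds motivate this restriction: an all-pairs
  RMSE is dominated (i) by merged detections of overlapping active
  emitters (a ~0.4 px error floor independent of SNR) and (ii) by
  detection-limit selection — raising the SNR recruits dimmer emitters
  whose errors match those of the low-SNR population, cancelling the
  precision gain of the bright ones.  Restricting to resolvable,
  well-sampled emitters isolates the localization-precision trend the
  sweep is meant to measure; the all-pairs RMSE is reported alongside;
* diffusion: D = 10 µm²/s at 950 Hz (t_a = 1.053 ms), 200 particles,
  200 frames on a 256² field at SNR 10, linking radius 6 px, lags 1–5.

## What the synthetic tests do and do not show

The simulator draws i.i.d. Poisson noise on an ideal integrated-Gaussian
PSF with a flat background and static (or ideally diffusing) emitters.
Real data adds camera read noise and EMCCD excess noise, PSF aberrations
and depth-dependent width, structured background, drift, and
heterogeneous labeling.  Passing these benchmarks therefore demonstrates
the correctness of the algorithms under their stated model — unbiased
sub-pixel recovery, CRLB-consistent precision in the asymptotic regime,
optimal linking, calibrated statistics — not performance on any
particular microscope.  Conversely the quality-versus-SNR trends and
diffusion recovery are structural properties that should survive model
mismatch.
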