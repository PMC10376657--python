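# Methods

This note records the models, parameter choices and numerical decisions
behind `dipmap`, and what the synthetic data can and cannot show.

## Session protocol and sampling

A session is 60 s pre-rest, six trials of 10 s tapping + 20 s rest, and
10 s post-rest, sampled at 9.19 Hz (250 s, 2297 samples; 275 samples per
30 s trial). Sample counts are `floor(duration · fs)` throughout; a
window of *w* seconds keeps `floor(w · fs)` samples (4 samples at 0.5 s,
128 at 14 s). Trial onsets are the first sample at or after each task
start.

## Canonical and designed response

The cHRF is a signed sum of three gamma densities (shape *a*, scale *b*
seconds, each density integrating to 1 so the amplitude *A* is the
component's area):

| component  | sign | A    | a  | b   | peak (a−1)·b |
|------------|------|------|----|-----|--------------|
| dip        | −    | 0.35 | 5  | 0.5 | 2 s          |
| main       | +    | 1.00 | 7  | 1.0 | 6 s          |
| undershoot | −    | 0.35 | 17 | 1.0 | 16 s         |

These values are a documented stand-in chosen to place the dip extremum
near 2 s with the dip resolving by ≈4 s, the main peak in 5–7 s and a
shallow undershoot; the composite curve's dip minimum falls at 1.86 s and
its zero-crossing at ≈3.5 s. All six parameters are overridable and the
set round-trips through YAML. The dHRF is the causal discrete convolution
of the cHRF with the task boxcar scaled by 1/fs (a left Riemann sum of the
continuous convolution), truncated to the boxcar's grid. Per-trial
regressors use a single-trial boxcar (10 s on / 20 s off), because the
analysis produces one map per trial.

## Band-pass filtering

A 4th-order Butterworth band-pass, 0.01–0.15 Hz, applied
forward–backward (zero phase) so the dip latency is not shifted;
zero-phase application squares the magnitude response, which is what the
analytic-oracle tests check against. A causal single-pass mode exists
behind a flag. Filtering runs on the whole session before trial
segmentation to keep edge transients out of the short windows. At the
defaults the passband gain at 0.08 Hz is 0.999 and the cardiac band
(1.2 Hz) is attenuated by far more than 20 dB.

## Robust regression and t-maps

Each windowed channel series is regressed on `[1, x]` (x = windowed dHRF)
by IRLS with bisquare weights, tuning constant 4.685, leverage-adjusted
residuals, and scale re-estimated each iteration as `median(|r|)/0.6745`;
iteration stops when the largest coefficient change is below 1e−6 or at
50 iterations. The slope's standard error uses the
Street–Carroll–Ruppert robust variance with the standard small-sample
correction — the estimator behind MATLAB-style `robustfit` statistics —
because the naive MAD-plus-weighted-normal-equations error is
anti-conservative under the null (measured ≈5.4–7% exceedance of the
1.65 threshold on windowed noise versus the nominal 5%; the SCR form
gives ≈4.5%). Exactly-fitting data (zero residual) fall back to OLS with
unit weights, since the robust scale degenerates there; the resulting
infinite t saturates the activation value at 1. A `force_unit_weights`
mode reproduces textbook OLS exactly.

The p-value is the one-sided upper tail of Student's t with n − 2 degrees
of freedom (1.65 is the one-sided 5% critical value at large df). t_crt
is held at 1.65 for every window, including 4-sample windows where the
correct small-sample critical value would be far larger — a deliberate
reproduction of the published procedure; `df` is overridable for a
df-correct variant. Windowed fits use only the samples
`[onset, onset + floor(w·fs))`; a `full_trial` mode fits the whole 275
sample trial and merely tags the map with the window, since the published
degrees-of-freedom remark (274) corresponds to full-trial fits.

Thresholded values (t > 1.65 and p < 0.05, strict) are divided by their
maximum, interpolated linearly over the optode coordinates onto a
227 × 227 grid (nearest-neighbour outside the convex hull or for
degenerate geometries), and mapped through a fixed 256-entry blue-to-red
lookup table (grayscale behind a flag) so images are bit-reproducible.

## Synthetic sessions

No recordings for this paradigm are public, so the generator *defines*
the study conditions. One 36-channel patch (6 × 6 grid on [0.1, 0.9]²;
real coordinates injectable from JSON) hosts:

* **Focal activation** — 8-channel blocks on opposite edges of the patch
  for RHTF and RHLF (adjacent-digit somatotopy), carrying the dip plus
  5% of the delayed components at 3 µM, with trial-level lognormal
  amplitude jitter (σ = 0.2), per-channel per-trial vascular gain jitter
  (σ = 0.25) and a subject-level gain drawn once (σ = 0.15).
* **Shared vascular response** — the delayed-only (dip-free) response on
  *every* channel, 6 µM at the patch centre, weighted by a Gaussian of
  distance (σ = 0.5) whose centre wanders trial-to-trial (σ = 0.08).
  This is the physiological premise of the analysis: blood flow, unlike
  oxygen extraction, is spatially unspecific, so delayed-window maps look
  alike for both tasks.
* **Spontaneous vasomotion** — per-channel band-limited noise
  (0.01–0.08 Hz, 1.75 µM rms at the blob centre, carried by the same
  blob weights). Being slow, it is nearly constant inside short dip
  windows (absorbed by the fit's intercept) but acts as a slope bias over
  14 s — it is what keeps delayed-window t-maps realistically unstable.
* **Nuisance noise** — cardiac 1.2 Hz (0.08 µM), respiration 0.3 Hz
  (0.06 µM), Mayer 0.1 Hz (0.03 µM), linear drift 0.002 µM/s with random
  sign, white noise 0.25–0.375 µM (0.375 at the default 3 µM amplitude).

The focal amplitude / white-noise ratio was calibrated once so that
single-trial t-values of active channels at the 4 s window land mostly in
2–8 (measured: median 4.9, 87% within the band) — the regime where the
1.65 threshold is informative. Oscillation amplitudes are kept below the
white level so that windowed t-statistics on raw data follow their
nominal null distribution; strongly autocorrelated noise would otherwise
inflate the false-positive rate of the fixed threshold (on band-pass
*filtered* noise the measured exceedance is 12–38%, which is why the
ground-truth-recovery check runs on raw sessions).

**Ground-truth recovery** is evaluated on focal-only sessions (shared
vascular component and vasomotion disabled): with the shared component
present, every channel genuinely responds and "inactive channel" has no
crisp meaning. Passing recovery therefore shows that the GLM detects a
known focal footprint under white-plus-oscillatory noise at the nominal
threshold — not that detection would be as clean on real, systemically
contaminated recordings.

What the generator does **not** emulate: motion artifacts, superficial
(scalp) hemodynamics and short-separation channels, the modified
Beer–Lambert conversion from raw intensities, ΔHbR, heterogeneous optode
sensitivities, and 1/f instrument drift beyond a linear term. Passing
end-to-end tests therefore demonstrates internal consistency of the
pipeline and the qualitative dip-versus-delayed contrast under these
conditions, not field performance.

## CNN family and training

Depth D ∈ {16, 19, 22, 25} counts every declared layer (input, softmax
and classification output included), giving k = (D − 7)/3 convolution
blocks: two conv–ReLU–LRN–maxpool blocks, then k − 2 conv–ReLU–maxpool
blocks, then dropout (0.5), a two-way fully connected layer, softmax and
the output layer. The first convolution is 7 × 7 stride 2, later ones
3 × 3 pad 1; pooling is 2 × 2 stride 2; cross-channel LRN uses window 5,
α = 1e−4, β = 0.75, k = 2; filter counts double per block from a base
(default 8) capped at a maximum (default 128). All of this is
configurable; building an architecture fails fast if the spatial map
would collapse below one pixel for the given input size.

Training is plain minibatch SGD with momentum (default 0.01 / 0.9 /
batch 32) on softmax cross-entropy, with He-normal initialisation and
inverted dropout. The input layer zero-centres images with per-channel
training-set means, matching the usual image-input-layer convention;
without centring, SGD at 0.01 converges unreliably. Forward,
backward (im2col convolutions, exact LRN gradient, argmax pooling) and
the optimiser are all numpy, single-threaded and bit-deterministic for a
fixed seed. Non-finite loss aborts with a diagnostic rather than
continuing.

The train/validation split is stratified by class with
`round(0.7 · n_class)` training images per class (528 → 370/158), pooling
trials across subjects as the published design does; a subject-grouped
split is available as the leakage-safe alternative.

## Experiment orchestration

`run_experiment` derives per-stage seeds as
`blake2s(f"{master}:{stage}") mod 2³¹`, so each stage is independently
reproducible, and executes both regimes: per-interval datasets (66 per
class per window) and the combined initial-dip dataset (528 per class),
plus the 14 s delayed dataset for contrast. Reports carry accuracies,
confusion-rate metrics, AUC, dataset checksums and stage timings.

## Scaled-down experiment sizes

The shipped experiment configuration uses 11 simulated subjects, 112 px
images, the depth-22 network at half width (base 8 filters, cap 64),
25 epochs, batch 32 — sizes chosen so a full run completes in a few
minutes on one CPU while keeping the dataset counts (66, 528, 370/158) of
the full design. Under these conditions the combined initial-dip dataset
reaches ≈0.85–0.86 validation accuracy (AUC ≈0.93–0.95) and the
delayed-window dataset ≈0.55–0.70 across seeds; the mean recovery Jaccard
is ≈0.81–0.83.

## Known limitations

* The gamma parameters of the cHRF are a plausible stand-in; analyses
  sensitive to exact dip latency should fit their own parameters.
* The fixed t_crt = 1.65 is statistically wrong for 4-sample windows (a
  faithful-reproduction choice); the df-correct path is available but not
  default.
* Robust-fit p-values assume exchangeable noise within the window;
  band-pass filtering violates this, which is documented rather than
  corrected (no pre-whitening).
* The CNN stack favours clarity over speed; it is adequate for the
  shipped image sizes, not for large-scale use.
* No multiple-comparison correction across channels is applied, matching
  the published procedure.
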