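# Methods

This note documents the models, procedures, parameters, and numerical
choices behind `ppgsepsis`, and what the synthetic test bench does and does
not demonstrate.

## Synthetic PPG model

Each beat is the sum of two Gaussian components on the beat period *T*:

* systolic wave: amplitude 1.0, center 0.30 *T*, width 0.10 *T*;
* dicrotic wave: amplitude 0.35, center 0.62 *T*, width 0.12 *T*.

Centers and widths are fractions of the period so the pulse shape scales
with heart rate. These defaults were chosen to visually resemble a typical
fingertip pulse with a clear dicrotic wave; the parameterization is smooth,
differentiable and fully controllable, which the tests rely on. It is a
rendering convention, **not** a validated hemodynamic model.

Per-beat periods are i.i.d. Gaussian perturbations of the mean period
(`hr_jitter_frac`, truncated at ±3σ) — the simplest law that preserves a
well-defined mean heart rate. Records can carry sinusoidal baseline drift,
multiplicative low-frequency amplitude modulation (modulation frequency
drawn in 0.04–0.15 Hz, the LF band of fingertip PPG), and additive white
noise. The simulator records the sample index of every systolic maximum as
ground truth (each index is a local maximum of the noise-free waveform
within ±2 samples; the only deviation source is the sub-sample position of
the Gaussian center).

Artifacts can be injected into any sample span: `constant` (flat line,
zero variance), `gaussian_burst` (pure white noise), and `motion`
(large-amplitude low-frequency additive sweep). These produce exactly the
failure modes the quality stage must catch.

### Synthetic cohorts

`simulate_cohort` draws one continuous record per subject (heart rate
uniform in 60–100 bpm, duration in a configurable range) plus a metadata
row that satisfies the corresponding cohort-selection rules, so the
labeling stage classifies every synthetic subject correctly. The
`class_effect` parameter creates a learnable separation: sepsis-class
subjects have the dicrotic amplitude attenuated (factor 1 − 0.6·e, floored)
and the LF amplitude modulation suppressed (factor 1 − 0.9·e, floored at
0), while controls have the modulation deepened (factor 1 + e). At
`class_effect = 0` both classes are drawn from the same distribution, which
provides the null condition used by the tests. The mechanism is loosely
motivated by reports of suppressed LF power in septic-shock PPG, but it is
a simulation convention for producing graded separability — passing the
learning tests shows the pipeline can extract a morphology/modulation
signal, not that it detects sepsis in real patients.

Each subject's random stream is seeded from `(cohort_seed, subject_index)`
so cohorts are reproducible independent of generation order.

## Preprocessing

* Segmentation: non-overlapping 2-minute chunks from sample 0; a trailing
  partial chunk is dropped; only even-positioned chunks (0, 2, 4, …) are
  kept. The starting phase of the "every other" rule is a convention; even
  positions maximize retained data for short records.
* Only 125 Hz input is accepted; other rates raise instead of being
  silently resampled.
* Filtering: third-order Butterworth band-pass, 0.5–8 Hz, applied
  forward-backward (zero-phase) as second-order sections. Zero phase keeps
  peak locations identical between raw and filtered traces, which first-peak
  alignment requires. Edge transients are not trimmed; windows of interest
  are interior to 2-minute segments.
* Peak detection: the clipped-and-squared filtered signal is compared
  against two moving averages — a peak-scale one (W1 = 111 ms) and a
  beat-scale one (W2 = 667 ms) plus the offset β·mean(squared signal) with
  β = 0.02. Runs where the short average exceeds the threshold and that
  last at least W1 become systolic blocks; the filtered-signal maximum in
  each block is the peak. Constants are exposed in the function signature.
  A zero-variance input returns an empty peak list (not an error), which
  the quality stage maps to an exclusion flag.
* Mean heart rate = 60 / mean inter-peak interval; with fewer than two
  peaks the estimate is `None` ("undefined"), never a fabricated number.

## Quality control

Per 3-s window: variance check → peak detection on the band-passed trace
(<2 peaks → `NO_PEAKS`) → heart-rate estimate (<45 bpm → `LOW_HR`) →
template simulation at the estimated rate → first-peak alignment → Pearson
correlation → group I–IV. Design choices:

* The scanning step defaults to 3 s (non-overlapping tiling, 40 windows per
  segment); each window is then judged exactly once. The step is
  configurable.
* The template is simulated one beat period longer than the window so the
  aligned overlap normally covers the whole window; when the window's first
  detected peak comes later than the template's, the overlap shrinks by the
  offset. Overlaps shorter than 1 s are treated as an exclusion
  (correlation over too few samples is meaningless).
* The segment is filtered once (zero-phase) and windows reuse the filtered
  trace for peak finding; the correlation itself is computed on the raw
  window against the raw template.
* A segment is accepted iff every window lands in group I or II. All
  observed failure kinds are reported, not just the first.

Thresholds (0.8 / 0.6 / 0.5, minimum 45 bpm) are configuration with those
defaults; there is no procedure to re-derive them.

## Cohort rules and splits

Sepsis: death in hospital ∧ single ICU stay ∧ single admission ∧ a sepsis
ICD-9 code (99591, 99592, 78552) ∧ present in the matched waveform subset.
Control: survived ∧ single ICU stay ∧ single admission ∧ a control code
(311, 3051, 30000, 2948, 3004) ∧ no sepsis code ∧ matched. Codes are
compared as dot-free strings. Anything else is excluded with the first
failing rule as the reason. Controls are capped at 40 per code; a control
qualifying under several codes is attributed to the first code in the fixed
order above (the deterministic rule needed for capping). Subjects
contribute at most 90 and at least 30 accepted 2-minute segments (3 h cap
by seeded subsampling, then the 1 h floor).

The 80/20 split and the 5 folds are subject-level partitions, stratified by
class (per-class counts differ by at most one across folds). Stratification
keeps small synthetic cohorts balanced; an unstratified mode is available.
The splits are delegated to scikit-learn's stratified splitters with the
plan's seed.

## Network and training

Architecture (channels-first, length 15 000 by default):
conv(40 filters, width 3, same padding) → max-pool(2) → 8 × [identity
block → max-pool(2)] → flatten → dense(100) → ReLU → dropout(0.2) →
dense(2) → softmax. The identity block is conv→BN→ReLU→conv→BN→ReLU with
the block input added to the branch output after the final ReLU; same
padding keeps the shortcut a pure sum. After 9 pools of size 2 the
15 000-sample input leaves a length-29 feature map (195 182 trainable
parameters with the defaults). Convolutions and dense layers use Glorot
uniform initialization with zero biases; batch normalization uses
ε = 1e-3 and running-average momentum 0.99.

The engine is written in NumPy (float32, `(batch, channels, length)`
layout) with reverse-mode gradients checked against finite differences in
the test suite. All randomness (initialization, shuffling, dropout,
augmentations) flows through one seeded generator, so training is bitwise
reproducible.

Training: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) on softmax cross-entropy —
with two classes this is exactly binary cross-entropy on the sepsis
probability, which reconciles the softmax head with the binary loss.
Per-epoch training and validation losses are recorded and the weights with
the lowest validation loss are restored. Reference hyperparameters
(lr 1e-6, batch 128, 800 epochs) suit long GPU runs; the desk-scale
experiments below use explicit smaller settings.

Augmentations (off by default, as in the final reference configuration):
Gaussian jitter applied with 50 % probability and followed by
renormalization to exactly [−1, 1]; and a random contiguous 90-s window.
When the window augmentation is on, the network is built at the window
length and non-augmented inputs are center-cropped to match.

Open details resolved as conventions: pools are size 2 / stride 2 without
padding; the initial convolution has stride 1; dropout follows the
dense-100 ReLU; the dense head sees the flattened final feature map.

## Evaluation

Per-model decisions threshold the sepsis probability at 0.5. The ensemble
label is the majority of the five binary votes (odd k required; ties are
undefined). Because a majority vote has no continuous output, the ensemble
ROC/AUC uses the mean sepsis probability across models; mean and vote can
disagree (e.g. probabilities 0.9, 0.9, 0.4, 0.4, 0.4 give mean 0.6 but
vote "control"), which is documented behaviour. Metrics are segment-level
accuracy, sensitivity (sepsis recall) and specificity (control recall);
ROC by threshold sweep with trapezoid AUC (scikit-learn), equal to the
Mann–Whitney concordance statistic, which the tests verify against an
O(n²) oracle. A subject-level aggregation (majority of a subject's
segment votes) is available as a secondary report.

## Desk-scale experiment sizes

The test bench trains real models but at deliberately small problem sizes,
chosen as the package's own desk-scale defaults (`SmokeConfig`):

* cohort: 20 subjects per class, 2 h simulated per subject — after the
  every-other-segment rule each subject retains exactly 30 accepted
  segments (1 h of signal), which sits exactly at the per-subject floor;
* inputs decimated ×10 to 12.5 Hz (1500 samples) with an anti-aliasing
  filter before normalization — the class-separating cues (pulse-shape
  ratio and LF amplitude modulation) live far below the reduced Nyquist
  frequency;
* a narrow variant of the architecture (8 filters instead of 40, same
  depth and head), trained with Adam at lr 1e-4, batch 16, 10 epochs;
* quality control is skipped for these artifact-free cohorts (it accepts
  clean simulated segments, which the QC tests verify separately).

With a strong class effect (`class_effect = 2`) the 5-fold majority-vote
ensemble reaches high test AUC and accuracy across seeds; with
`class_effect = 0` the AUC averages near 0.5. Note that with only 4
held-out subjects per class, segment scores are correlated within subject,
so a single null replicate's AUC is noisy; the mean over replicates is the
stable chance-level quantity, and that is what the null test asserts.

## Limitations

* The simulator does not model SpO₂, respiration-induced modulation,
  arrhythmias, or realistic motion artifacts beyond what quality control
  needs; passing tests demonstrate the pipeline's mechanics, not clinical
  performance.
* Peak ground truth is only defined for synthetic records.
* The quality stage judges each window against a fixed two-Gaussian
  template family; real morphological variants (e.g. absent dicrotic wave)
  may correlate below the group-II threshold and be discarded.
* The heart-rate gate compares the *estimated* rate against 45 bpm; at a
  true rate exactly on the boundary, sample quantization of the inter-peak
  intervals (8 ms at 125 Hz) can push the estimate just below the gate, so
  boundary-rate windows may be excluded.
* Filter edge transients are not trimmed; the first/last fraction of a
  second of each segment slightly deviates from the steady-state filter
  response.
* The NumPy engine targets clarity and reproducibility over speed; the
  reference regimen (800 epochs at full scale) is impractical on CPU and
  is retained as configuration defaults only.
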