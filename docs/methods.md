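# Methods

This note records the models, conventions and design choices behind
`weakeeg`, in the package's own words. Empirical statements below are the
ones the test suite and `scripts/acceptance.py` actually compute.

## Problem setting

Seizure-onset detection is cast as binary classification of fixed-length
scalp-EEG clips: an input `x ∈ R^{2400×19}` (12-s clips at 200 Hz over the
19 electrodes of the 10–20 montage) or `x ∈ R^{12000×19}` (60-s clips) maps
to a probability `y` that the clip contains a seizure onset. Training
labels come from *weak annotations* — timestamped free-text seizure markers
produced in the routine clinical workflow. A clinician audit of such
annotations measured precision 0.37 and recall 0.45, with markers tending
to land near seizure onset; those numbers define the label-noise regime the
whole package emulates.

Because the clinical recordings themselves are PHI-restricted, every
experiment here runs on synthetic EEG with known ground truth. The
synthetic generator is therefore first-class, tested code, and its defaults
define the study conditions.

## Synthetic EEG model

Each record is the sum of three seeded components per channel:

* **1/f broadband noise** (spectral exponent α = 1), scaled to a
  per-record RMS drawn from 8–25 µV — the dominant "pink" envelope of
  resting EEG, with deliberate cross-record gain variability;
* **posterior-dominant alpha** (8–12 Hz, occipital amplitude 8–35 µV)
  with a slow waxing–waning envelope, fading toward frontal leads;
* **white sensor noise** (2 µV RMS).

Three ictal morphologies are injected additively, with raised-cosine onset
and offset ramps of 1 s so activity is confined to the half-open event
interval `[onset, onset+duration)`:

* `generalized_spike_wave` — 2–4 Hz spike-and-slow-wave complexes over all
  19 channels with frontal emphasis, 40–140 µV;
* `focal_evolving` — fast spiking (sharpened sinusoid with an odd
  harmonic) chirping from ~7–10 Hz up to ~16–24 Hz with an amplitude ramp,
  maximal on a 2-electrode focus and falling off as a Gaussian of scalp
  distance, 30–90 µV;
* `rhythmic_delta_ictal` — 1–3 Hz rhythmic slow waves over frontal leads,
  40–110 µV.

Two artifact kinds provide the canonical false-positive triggers:
60 Hz mains pickup on all channels, and a **non-evolving rhythmic
artifact** at a fixed 1–6 Hz frequency on a contiguous channel group
(40–110 µV). The latter deliberately shares the delta–theta band
signature of rhythmic ictal slowing while lacking evolution and spike
sharpness, so band-power features alone cannot separate it from seizures —
the confound that motivates waveform-level models.

Events are placed by slots (slot width = minimum gap + maximum duration),
which guarantees a 90 s default gap; with the 30 s annotation-matching
tolerance this keeps the matching windows of neighbouring events disjoint,
so corpus-level recall is a clean binomial of the per-event annotation
probability. 40% of records are seizure-free by default, mirroring the
preponderance of unremarkable clinical EEGs and supplying the
annotation-free records that negative sampling requires.

## Weak-annotation noise model

Per corpus: each gold event is annotated independently with probability
`target_recall` (0.45). The marker lands at onset + Gaussian jitter
(SD 8 s), or uniformly inside the event with probability 0.3. False
annotations are then added so that expected corpus precision equals
`target_precision` (0.37): their count is `T·(1−p)/p` for `T` realized true
annotations; half are placed inside artifact intervals when any exist
(rhythmic artifact being the typical trigger of a false call), half on
plain seizure-free background, and all are rejection-sampled to stay
outside every `[onset−30 s, offset+30 s]` matching window so they never
match by accident. The 30 s tolerance is a declared convention reflecting
page-level reading, not an audited value.

Calibration is verified on a dedicated scenario with ≥1000 gold events
(150 records of 1100 s, densely seeded — annotation quality depends only on
the event/artifact layout, so seizure density there exceeds the default
scenario's for economy). Realized precision and recall must sit within 3
binomial standard errors of the targets.

## Clip datasets

Positive clips start at the annotation time and cover `[t, t+L)`: the task
is onset detection and markers tend to sit near onset, so start-anchoring
is the natural convention (centering is an alternative nothing here
requires). Negatives are sampled only from records with no annotation of
the relevant kind (weak for training, gold for evaluation), choosing
records in proportion to eligible duration. Training sets are balanced to
50% positive by undersampling negatives (odd counts resolve toward one
extra negative); evaluation pools are built at the 80–20
negative–positive balance and split into dev and test halves **by record**,
never by clip, to avoid leakage. A record-level partition likewise
separates the training pool from the evaluation pool, so no record id ever
appears on both sides.

Resampling to 200 Hz uses polyphase filtering with a Kaiser window at
β ≈ 14.77 (the high-quality design); a source already at 200 Hz passes
through bit-exact.

## Baseline features

The classical battery, per 12-s or 60-s clip:

* per-channel time domain: mean, variance, skewness, kurtosis
  (standardized central moments; kurtosis non-excess, so a Gaussian scores
  3; both defined 0 for constant channels), total signal area `Σ|x|·dt`,
  peak-to-peak, strict zero crossings after mean removal, decorrelation
  time (first zero crossing of the autocorrelation, linearly interpolated);
* per-channel frequency domain: total spectral energy (Parseval-consistent
  with the time-domain sum of squares), fractional energies of delta
  0.5–4, theta 4–8, alpha 8–13, beta 13–30 and gamma 30–70 Hz, and DWT
  detail energies (Daubechies-4, 5 levels) — band edges and wavelet are
  standard clinical/processing choices, configurable;
* connectivity: max over ±0.5 s lags of |normalized cross-correlation| for
  each of the 171 electrode pairs (normalization by the global channel
  norms, so a linearly shifted copy scores ≈1 up to the lost edge overlap);
* graph measures on the thresholded (default 0.7) connectivity graph:
  per-node degree and clustering coefficient, global efficiency — a
  representative local/global trio, since no canonical set exists.

571 features in total. Classifiers: random forest with 100 trees of max
depth 4 (the reference hyperparameters) and L2 logistic regression (C = 1,
its reference never states hyperparameters). Features are z-scored with
training-set statistics only.

## Dense-inception CNN

The classifier is a densely connected inception network: a stem convolution
lifts the 19 electrode channels to a feature basis; each of the 8 inception
layers applies three parallel temporal convolutions (kernel sizes 3/5/7,
`growth` maps per branch, 'same' padding) to the concatenation of the stem
output and **all** previous layers' outputs; strided average-pooling
transitions downsample the whole concatenated state between layers; global
average pooling over time feeds two fully connected layers ending in one
logistic unit. Implementation is a small NumPy framework with explicit
backward passes (im2col convolutions, manually verified against finite
differences), an Adam optimizer, and inverted dropout.

**Published preset.** The published description fixes 8 inception layers, three
kernels per block, two FC layers, and a total of 12,677,803 parameters,
leaving widths to a supplementary table. The preset here — stem 19→160
(kernel 5, stride 2), growth 48 per branch, kernels 3/5/7, transitions of
stride 4 after layers 2/4/6, FC 1312→6725→1 — was solved so the closed-form
count

    stem 19·5·160+160 = 15,360
    conv Σᵢ Σ_k Dᵢ·k·48+48 (D₁=160, Dᵢ₊₁=Dᵢ+144) = 3,825,792
    fc   1312·6725+6725 + 6725+1 = 8,836,651

reproduces 12,677,803 exactly. This preset is buildable and verified by
shape arithmetic; it is not trained at desk scale.

**Desk preset** (trained everywhere in the tests): 4 inception layers,
growth 8, stem 19→20 (kernel 7, stride 4), pooling stride 4 after every
layer, FC 116→64→1 — 37,209 parameters. Each input clip is divided by its
global RMS (all samples and channels) before the stem, making the model
invariant to per-record gain while preserving channel topography and
waveform shape; the scale is treated as a constant in the backward pass
(it depends only on the input, so parameter gradients are exact).

Dropout 0.2 acts on the input of the final FC layer ("applied to the last
layer" is read as the last layer's input; a switch moves it to the first FC
input instead). Weight initialization is seeded He fan-in.

## Training protocol

Adam on binary cross-entropy (the loss is unstated in the source protocol;
BCE is the natural choice for a logistic output), batches of 10 clips, and
the learning-rate schedule `lr(e) = lr0 · 2^(−⌊e/T⌋)`. The published
protocol is `lr0 = 1e−6`, `T = 10`, 25 epochs at full scale; the desk
default is `lr0 = 1e−3`, `T = 5`, 15 epochs, appropriate for a 37k-parameter
model on hundreds of clips. The checkpoint with the best dev AUROC is kept
(the selection rule is a declared convention). All stochastic sources of a
run — initialization, shuffling, subsampling, dropout — derive from the
run's single seed; `epochs = 0` is the identity, which makes the
fine-tuning no-op contract testable.

**Scaling experiment.** Per training-set size, one class-stratified subset
of the weak pool is drawn with the experiment seed; five models with
different training seeds are then trained on that same subset and scored on
the fixed gold test set. Varying only the training seed mirrors "confidence
intervals from training runs with different random seeds" and makes the
across-seed spread a measure of model variance, which is the quantity whose
shrinkage with sample size the experiment checks.

**Transfer.** `freeze_all_but_last_two_fc` marks exactly the FC parameters
trainable; fine-tuning then runs the ordinary protocol on a copy of the
pretrained model. The desk transfer scenario trains the source model on the
default experiment corpus and fine-tunes on an 8-clip weak-labeled set from
a target population with a shifted morphology mix (more rhythmic delta,
less generalized spike-wave). Eight clips is deliberately extreme: it is
the regime where from-scratch training is high-variance and frozen source
features pay off, which is the phenomenon the comparison demonstrates.

## Metrics

Precision, recall, F1 and FPR are computed from confusion counts with
documented zero-denominator conventions (all 0). AUROC equals the
probability that a random positive outscores a random negative with ties
counting ½; the ROC curve is enumerated at all distinct thresholds
(scikit-learn backend; the tests verify equivalence against brute-force
pair counting on every random instance up to 20 clips). Operating points:
for a TPR floor, the largest threshold whose TPR meets it (ties toward
lower FPR); for an FPR ceiling, the smallest threshold whose FPR respects
it (ties toward higher TPR). Seed aggregation reports mean, Student-t 95%
interval and median; ROC curves aggregate by pointwise median TPR over a
101-point FPR grid.

## Occlusion saliency

`value[c,t] = (p(clip) − p(clip with channel c, second t zeroed)) / p(clip) · 100`,
cells aligned to the clip start. Signed values are kept so suppressive
cells remain visible; per-map normalization (divide by max |value|) is the
display convention. The batched and the naive cell-by-cell paths run the
same forward mathematics and agree to single-precision accuracy (~1e−5 of
the value scale); they are not bit-identical because BLAS kernels differ
with batch shape, and the tests assert equality at that numerical
tolerance. The localization score takes the top-k map cells (k = number of
in-event, in-focus cells) and reports the fraction on the event's support;
ties are broken by a seeded permutation when an RNG is supplied, giving a
uniform map an expected score equal to the support fraction.

## Desk-scale study conditions

The default experiment corpus is 200 records of 360 s (≈20 hours of
signal), 35% of records reserved for evaluation, yielding ≈370 balanced
weak-labeled training clips and ≈400 gold evaluation clips at 80–20. The
calibration corpus holds ≥1000 gold events. The scaling grid is
(40, 120, 360) clips × 5 seeds; the weak-vs-gold comparison trains 5 seeds
per arm with the gold arm at 1/100 of the weak set (minimum 4 clips). These
sizes are the package's desk-scale choices: large enough for the qualitative
phenomena — weak-supervision advantage, scaling gains, variance shrinkage,
transfer benefit — to be stable under fixed seeds, and small enough that
the full suite runs on a single CPU in minutes.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the clinical problem — noisy
onset-biased labels at the audited precision/recall, rhythmic confounds,
cross-record gain variability, record-level splits — but not the diversity
of real patients: electrode artifacts beyond the two modelled kinds,
age-dependent background, true inter-patient morphology variability, or
non-stationary recording conditions. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that the expected qualitative
phenomena emerge under controlled conditions; they do not certify clinical
performance numbers, which is why the headline clinical AUROC/F1 values are
not targets of this package.

## Known limitations

* The CNN stack is single-threaded NumPy; the published preset is buildable
  and checkpointable but not practically trainable here.
* EDF export is not provided; the container format is the documented
  `.npz`-plus-YAML layout.
* The non-overlapping average pooling drops a trailing remainder shorter
  than the window (it receives zero gradient).
* Weak-annotation quality is not differentiated by annotator source; the
  `source` field is generated but statistically uniform across sources.
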