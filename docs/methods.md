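# Methods

This note documents the models and procedures implemented in `anxeeg`, the
assumptions behind them, the parameters that matter, and the choices made
where the underlying study leaves the design open.

## Synthetic data generator

The generator (`anxeeg.synth`) emulates the *shape* of an exposure-therapy
EEG study: `n_subjects=23` subjects × `n_trials=6` trials × `trial_seconds=30`
seconds of analyzed EEG per trial, 14 channels in the Emotiv EPOC montage at
`fs=128` Hz, amplitudes in µV. Each subject carries a latent anxiety level
in {0,1,2,3} drawn from `class_prevalence`, which defaults to the 360:900:540:2340
proportions of the reference study's four-level HAM-A instance counts, so
synthetic runs mirror its class imbalance.

**Signal model.** Each channel is the sum of

* 1/f^`pink_exponent` background noise (default exponent 1, RMS
  `pink_sigma` = 6 µV), generated by spectral shaping of white noise;
* one sinusoidal oscillator per canonical band (δ, θ, α, β, γ) whose
  amplitude, frequency (uniform inside the band) and phase are **redrawn
  every second**. Amplitudes are log-normal around per-band baselines
  (α-dominant: 6 µV α, 4 µV δ/θ, 3 µV β, 1.5 µV γ, log-σ 0.3).

Redrawing oscillator parameters per second models the waxing and waning of
cortical rhythms and — because epochs are 1 s and cut on second boundaries —
makes the band power of distinct epochs statistically independent. This
matters: if oscillator amplitudes were constant over a trial, all 30 epochs
of a trial would share one amplitude draw, epoch-level test statistics would
be computed on strongly dependent samples, and the channel-selection t-tests
would be badly anti-conservative.

**Anxiety effect.** On the six effect channels (AF3, AF4, FC5, FC6, P7, P8)
the θ and β oscillator *power* is multiplied by `effect_size**level`
(amplitude by its square root), `effect_size` ≥ 1, default 1.5. Both members
of each homologous pair are scaled equally, so MP features carry the class
signal while RASM/AI do not — asymmetry features act as realistic
distractors. One known artifact of the sinusoidal model: an oscillator's
Hamming-windowed spectrum leaks ~18 % of its power into the adjacent 2 Hz
bin, so a θ effect bleeds weakly into the δ and α bands; analyses that
compare band subsets on generator output will see faint genuine signal in
bands adjacent to the effect bands.

**Scores.** Each subject receives one HAM-A total drawn uniformly inside the
level's bin ([0,12], [13,20], [21,25], [26,56]); each trial receives SAM
valence/arousal drawn strictly inside the level's labeling region, so with
`sam_jitter=0` (the default) relabeling the emitted scores recovers the
latent level for 100 % of trials. Positive jitter blurs scores across label
boundaries. SAM regions follow the printed label ranges (Severe valence
starts at 0) even though the SAM instrument is a 1–9 scale.

**Artifacts.** Optional and seeded: raised-cosine blink transients (0.5 s,
~80 µV, frontal channels; spectral content < 4 Hz), broadband > 30 Hz EMG
bursts (0.5 s, ~20 µV, random channel subsets), and a 50 Hz line-noise
sinusoid with per-channel random phase. Zero rates reproduce the clean
signal exactly, and the clean latent level is always retained, so artifact
injection is testable against before/after spectral oracles.

**What the generator does not model:** volume conduction and inter-channel
correlation, eye-movement hemispheric symmetry, non-stationary baseline
drift, subject-specific spectral fingerprints, or any SAM-answering-period
EEG (only the 30 s analysis window is produced). Consequently, passing
recovery tests on synthetic data demonstrates that the pipeline's inference
machinery is correct and calibrated — not that real anxiety produces these
effect sizes, nor that real EEG satisfies the independence assumptions the
generator deliberately provides.

## Preprocessing

The bandpass is the study's printed specification: order 15 (16 taps),
4–45 Hz, Hanning windowed sinc, designed with `scipy.signal.firwin` and
applied as a single forward pass. A 16-tap filter at 128 Hz has a ~25 Hz
transition band; its measured DC gain is |H(0)| ≈ 0.55 and the 4 Hz edge is
barely attenuated. We implement the filter exactly as specified and document
the measured response rather than silently increasing the order; the < 4 Hz
suppression claimed for this stage is therefore partial, which is why blink
rejection also exists as an explicit epoch-level option.

Group delay is compensated by trimming `order // 2` = 7 samples from the
full convolution (output length = input length, edges implicitly
zero-padded). A single pass was chosen over zero-phase double filtering
because the reference pipeline specifies one FIR application; the residual
half-sample delay of the even-length filter is irrelevant for band-power
features.

Epochs are non-overlapping 1-s windows cut from the start of each trial;
a trailing partial window is dropped (with a warning) rather than
zero-padded so that all epochs are identically distributed. The EMG
rejection option removes epochs whose channel-averaged fraction of PSD mass
above 30 Hz exceeds `power_ratio_threshold` (default 0.5, disabled by
default — the reference analysis used an external source-separation tool
whose parameters are unpublished; this power-ratio rule mirrors its
criterion at epoch granularity). Component-level blind-source-separation
EOG/EMG removal is out of scope.

## Spectral features

Welch PSD inside each 1-s epoch: 64-sample segments, 50 % overlap, periodic
Hamming taper — three segments and 2 Hz resolution, the largest segment
count obtainable at this epoch length that still puts at least one bin in
every band. Density scaling, no detrending; `welch_psd` is verified against
a hand-rolled averaged-periodogram oracle and a Parseval check. With 2 Hz
bins and inclusive band edges, θ (5–7 Hz) contains only the 6 Hz bin, and δ
(2–4 Hz) the 2 and 4 Hz bins; this is a direct consequence of the epoch
length and is asserted in tests rather than smoothed over.

Band power is the arithmetic mean of PSD values at bins whose center lies in
[low, high]. The min–max normalization `(x − min)/(max − min) × 14` used for
channel-level PSD visualization maps the minimum to 0 and maximum to 14
exactly and rejects constant input.

The asymmetry index is implemented as the bounded normalized difference
(P_L − P_R)/(P_L + P_R); the log-ratio variant ln P_L − ln P_R is available
via `ai_mode="log"`. The left-hemisphere channel is always the numerator /
minuend. Column names (`MP_AF3_beta`, `RASM_AF3-AF4_theta`, `AI_P7-P8_beta`)
are part of the public contract: band-subset selection parses them.

## Channel selection

Per-epoch broadband power (mean PSD over 4–45 Hz) is compared across classes
with the classical pooled-variance two-sample t-test (two classes) or one-way
ANOVA (more classes), per channel, at α = 0.05, without multiple-testing
correction — matching the reference analysis, which reports raw per-channel
p-values. Both a Welch-t option (`equal_var=False`) and a Bonferroni option
are exposed. Band powers are approximately log-normal, so analyses that need
calibrated tail behaviour (e.g. the recovery simulations) log-transform the
power summaries first; the raw-power default reproduces the reference
procedure. The sampling unit is the epoch; the reference study does not
state whether its tests used epochs or trials.

## Band-subset search and RFE

All 31 non-empty subsets of the five bands are scored by the mean accuracy
of `n_repeats` seeded stratified 5-fold cross-validations restricted to that
subset's columns. The original algorithm description iterates the procedure
1000 times; `n_repeats` is a parameter (desk-scale default 10) because the
repeat count trades runtime against score noise, not correctness. The
default winner is the strict argmax with ties broken toward fewer bands and
canonical band order (δ<θ<α<β<γ). An opt-in parsimony rule
(`one_se_rule=True`, `se_factor` standard errors) instead returns the
smallest subset whose score is within `se_factor` SE of the best. The
rationale: CV subset comparison on a fixed dataset is systematically
optimistic for supersets — noise columns correlate with the labels by chance
at the ~1/√n scale in train *and* test folds — and no number of repeats
removes that bias; the SE window must cover it. Inner CV is stratified
5-fold rather than leave-one-out because LOO × 31 subsets × repeats is
computationally disproportionate for a model-comparison step; final reported
models use LOO/LOSO.

RFE starts from all columns, scores the current set by seeded 5-fold CV
accuracy, removes the least important feature (estimator-native importances
when available, otherwise drop-one accuracy loss), and repeats down to one
feature; the returned subset maximizes CV accuracy along the path, with ties
going to the smaller subset — so duplicated features collapse to a single
column. The full (removed feature, accuracy) trajectory is recorded.

## Classification and metrics

Classifier defaults are the study's tuned values: kNN k=5; decision tree
depth 32; random forest 500 trees × depth 32; MLP with four hidden ReLU
layers, Adam; RBF-SVM. Unstated values were fixed as: MLP hidden sizes
(64, 32, 16, 8); MLP learning rate 1e-3 (the printed 0.4 is selectable but
generally diverges under Adam; the printed momentum 0.3 is stored and used
only when the optimizer is switched to SGD, as Adam has no momentum
parameter); SVM C=1 with γ = 1/(d·var). Features are standardized inside
each training fold only; no resampling or class weighting is applied, so
class imbalance affects the classifiers exactly as in the reference setting.

Cross-validation plans: leave-one-instance-out (fold count = instance
count — the default, matching the stated fold arithmetic) and
leave-one-subject-out (no subject in both train and test — matching the
stated subject separation; the two statements are mutually inconsistent for
1-s epochs, so both modes exist and the choice is explicit). A training fold
missing a class raises an error naming the fold.

Confusion matrices use rows = predicted, columns = true, mirroring the
published table layout. Metrics: accuracy = trace/total (reported in %);
per-class precision TP/(TP+FP) along the predicted-class row and recall
TP/(TP+FN) along the true-class column (the published tables appear to swap
the two headers; the formulas here are implemented literally); F as their
harmonic mean; Cohen's κ with chance agreement from the products of row and
column marginals. Zero-denominator rates are reported as 0 and the class is
flagged. κ is verified against an independent implementation and satisfies
the transpose-invariance and independence identities.

Recomputing the published two-level HAM-A matrix reproduces its printed
accuracy (3929/4140 = 94.90 %) and κ (0.8791 → 0.88) exactly; two of the
other published matrices disagree with their own printed accuracies in the
second decimal (e.g. 3840/4140 = 92.75 vs a printed 92.74), so exact
assertions are limited to quantities whose printed arithmetic is internally
consistent.

## Pipeline

`run_pipeline` executes simulate → filter → segment → (optional EMG
rejection) → label → channel selection → feature table → band selection →
RFE → per-classifier evaluation for every requested scheme × granularity,
persisting labels, selection evidence and the metrics report under the
output directory with SHA-256 digests in a run manifest; identical config
and seed reproduce identical digests. By default the selection stages run
once on the full dataset and the chosen features are then cross-validated —
this mirrors the reference study's sequential procedure and is optimistic
for generalization, since test epochs influenced selection. `nested=True`
refits channel, band and feature selection inside each training fold of the
final CV; it is the statistically honest mode and is proportionally more
expensive.

Desk-scale defaults (selection RF with 100 trees, a handful of band-search
repeats, LOSO) keep a full synthetic run in the minutes range; study-scale
settings (500-tree forests, LOIO over 4140 epochs, 1000 repeats) are reached
by configuration alone.

## Known limitations

* The generator's independence structure is *more* benign than real EEG
  (no cross-channel correlation, no within-trial dependence); calibration
  results transfer to real data only insofar as epochs are exchangeable.
* The 16-tap bandpass leaves substantial sub-4 Hz residual; treat the
  filtering stage as the specified component, not as a state-of-the-art
  artifact remover.
* Non-nested selection inflates downstream CV accuracy; use `nested=True`
  when an unbiased generalization estimate matters.
* EDF support writes a minimal 16-bit EDF (single 1-s record blocks,
  integer sampling rates, whole seconds) sufficient for interoperability
  round trips, not a full EDF+ implementation.
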