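# anxeeg

EEG-based **state-anxiety classification**: a tested, reusable implementation
of a spectral-feature pipeline for 14-channel consumer EEG (Emotiv EPOC
layout, 128 Hz), from raw multi-channel recordings through preprocessing,
labeling, feature extraction and selection, to multi-classifier evaluation.

It is aimed at affective-computing and neurophysiology researchers who want
to reproduce, probe or extend this family of analyses without access to the
original clinical recordings: a synthetic-data module generates datasets with
the same shape as the DASPS exposure-therapy protocol (23 subjects × 6 trials
× 30 s of analyzed EEG), with a controllable anxiety effect and realistic
artifacts, so every stage is testable end to end.

## The analysis

1. **Preprocessing** — FIR bandpass 4–45 Hz (order 15, Hanning windowed sinc),
   single pass with group-delay compensation; segmentation into 1-s epochs
   (the classification instance); optional epoch-level EMG rejection by
   \>30 Hz power ratio.
2. **Labeling** — two schemes × two granularities:
   * SAM valence/arousal regions → {Normal, Light, Moderate, Severe}
     (e.g. V ∈ [0,2] ∧ A ∈ [7,9] → Severe);
   * HAM-A total → bins [0,12], (12,20], (20,25], (25,56];
   * two-level merge {Normal, Light} → *Light Anxiety*,
     {Moderate, Severe} → *Severe Anxiety*.
3. **Features** — Welch PSD (64-sample segments, 50 % overlap, Hamming) per
   1-s epoch; band powers over δ (2–4), θ (5–7), α (8–12), β (13–29),
   γ (30–45) Hz; per channel and band the **mean power** MP, and per
   homologous pair (AF3/AF4, FC5/FC6, P7/P8) the **rational asymmetry**
   RASM = P_L/P_R and **asymmetry index** AI = (P_L−P_R)/(P_L+P_R).
   Six channels × 5 bands gives the full 60-column table (30 MP + 15 RASM +
   15 AI).
4. **Selection** — channels by two-sample *t*-test (2 classes) or one-way
   ANOVA (4 classes) on per-epoch broadband power at α = 0.05; frequency
   bands by exhaustive search over all 31 non-empty band subsets scored by
   repeated stratified CV; features by accuracy-driven recursive feature
   elimination.
5. **Evaluation** — kNN (k=5), decision tree (depth 32), random forest
   (500 trees, depth 32), MLP (4 hidden ReLU layers, Adam) and RBF-SVM under
   leave-one-instance-out or leave-one-subject-out CV, with per-fold
   standardization; confusion matrices (rows = predicted), accuracy,
   per-class precision/recall/F, and Cohen's kappa
   κ = (P_obs − P_chance)/(1 − P_chance).

Selection stages expose sklearn-style estimators
(`StatisticalChannelSelector`, `BandSubsetSelector`, `AccuracyRFE`) with
`fit`/`transform`/`get_support`, so they compose with sklearn pipelines.

## Worked example

```python
import numpy as np
import anxeeg as ax

cfg = ax.GeneratorConfig(n_subjects=6, n_trials=2, trial_seconds=8.0,
                         class_prevalence=(0.25, 0.25, 0.25, 0.25),
                         effect_size=2.0, seed=7)
recs = ax.generate_dataset(cfg)
spec = ax.design_bandpass_fir(4, 45, 15, "hanning", 128)
epochs = ax.concat_epochs([ax.segment_epochs(ax.apply_fir(r, spec))
                           for r in recs])

labels = np.array(ax.expand_trial_labels(
    {(r.subject_id, r.trial_id): ax.label_trial(r.scores, "HAM-A", 2)
     for r in recs},
    provenance=epochs.provenance, scheme="HAM-A", granularity=2).labels)

power = np.log(ax.channel_power_summary(epochs))
results = ax.select_channels(power, labels, epochs.channels, bonferroni=True)
sel = [r.channel for r in results if r.significant]

table = ax.build_feature_table(
    epochs, channels=sel,
    pairs=[(l, r) for l, r in ax.PAIRS if l in sel and r in sel])
cm, rep = ax.evaluate(table, labels,
                      ax.ClassifierConfig(kind="rf", rf_n_trees=100, seed=0),
                      ax.loso_plan(epochs.subject_ids()))
print(sel)
print(f"accuracy {rep.accuracy_pct:.2f}%  kappa {rep.kappa:.3f}")
```

prints

```
['AF3', 'FC5', 'P7', 'P8', 'FC6', 'AF4']
accuracy 79.17%  kappa 0.455
```

The six significant channels are exactly the generator's effect channels
(the class effect was planted on AF3/AF4/FC5/FC6/P7/P8), and the
leave-one-subject-out random-forest accuracy of 79 % on 96 one-second epochs
reflects a strong but noisy two-level effect — subject-held-out scores are
lower than leave-one-instance-out scores because no subject appears in both
train and test folds.

The same flow is available from the shell:

```bash
anxeeg simulate --subjects 6 --trials 2 --trial-seconds 8 --seed 7 --out ds/
anxeeg preprocess --in ds/ --out epochs.npz
anxeeg label --in ds/ --out labels.csv
anxeeg evaluate --features features.csv --epochs epochs.npz \
    --labels labels.csv --classifier rf --cv loso --out eval.json
anxeeg run --seed 7 --out full_run/   # the whole pipeline
```

## Layout

```
src/anxeeg/
  synth.py          synthetic DASPS-shaped EEG generator
  preprocessing.py  FIR bandpass, segmentation, EMG-epoch rejection
  labeling.py       SAM / HAM-A labeling and the two-level merge
  spectral.py       Welch PSD, band powers, MP/RASM/AI feature table
  stats_select.py   t-test / ANOVA channel selection
  subset_select.py  band-subset search and accuracy-RFE
  evaluation.py     classifiers, CV plans, confusion matrices, metrics
  pipeline.py       end-to-end orchestration with hashed run manifests
  io.py             CSV/JSON dataset I/O, minimal EDF writer, mne EDF reader
  cli.py            click CLI (`anxeeg ...`)
docs/methods.md     models, assumptions, parameter choices, limitations
```

See `docs/methods.md` for the generator's signal model, the numerical
choices (Welch segmentation, filter delay handling, tie-breaking rules) and
what synthetic-data results do and do not imply about real recordings.
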