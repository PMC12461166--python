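# longicog

Long-horizon prediction of cognitive status — Control, amnestic mild
cognitive impairment (aMCI), or Alzheimer's disease dementia (AD) — from
longitudinal clinical visit data.

Most machine-learning work on AD progression predicts 1–3 years ahead.
`longicog` implements a pipeline for the much harder 3–10-year horizon:
given a patient's earlier visits, predict their diagnostic status at a
visit 3–10 years past the last observed one.  It is aimed at researchers
working with registry-style longitudinal cohorts (multi-year records of
per-visit neuropsychological scores plus largely static health/history
variables, with pervasive missingness).  Because such registries are
restricted-access, the package ships a seeded synthetic cohort simulator
that reproduces their structure, so the entire pipeline is runnable and
testable out of the box.

## Method

**Data preparation.** Patients need ≥ 2 dated visits with a first-to-last
span of 3–10 years; records that progress to a non-AD dementia are
excluded, and transitions to a *less* severe label (reversions,
Control < aMCI < AD) are dropped pair-wise.  Classes are balanced by
uniform draws without replacement down to the smallest class.  Training
uses prefix augmentation: a record x₁,…,x_t yields the t−1 pairs
({xᵢ | i ∈ 1…j−1}, x_j) for j = 2…t, i.e. every visit prefix predicts the
next visit's label.  Evaluation uses exactly one pair per patient — target
= last visit, prefix = all visits 3–10 years before it — with no
augmentation.  Cross-validation folds partition *patients*, never pairs.

**Feature engineering.** Two views per sample, each with an explicit
missingness mask φ:

- *baseline* — the latest prefix visit z-scored against the cognitively
  normal population of the training split (held-out data is scored with
  the same training statistics);
- *change* — each prefix visit as the ratio to the patient's first visit,
  x′_j(t) = x_j(t)/x_j(1), capturing intrapersonal decline; features that
  are static within a patient are masked out of this view.

**Model.** Raw values are strictly positive, so missing cells are set to a
−1 sentinel, making missingness linearly separable.  The baseline vector
is encoded by one of two missing-data encoders: stacked masked multi-head
self-attention over features (softmax(Q·Kᵀ/√d_k) restricted to observed
positions), or a lighter *linear attention*: per-feature scores
f(x) = S·ϕ·T(x) normalised to weights w_k = s_k/Σᵢsᵢ that reweight the
inputs, x′_k = x_k·w_k, followed by a single projection.  The change matrix
runs through a 3-layer LSTM (zero-initialised; final hidden state h).  A
bias-free scalar gate δ = w·h mixes the two encodings,
δ·Temporal + (1−δ)·Baseline, so a single-visit patient (empty change
sequence, h = 0) falls back exactly onto the baseline path.  A
dropout → linear → ReLU → linear head and softmax produce the three class
probabilities, trained with mean cross-entropy under AdamW
(weight decay 0.01, batch 64, ≤ 55 epochs, early stopping on dev
accuracy).

**Evaluation.** Per-fold 3×3 confusion matrices; overall accuracy;
per-class one-vs-rest (OvR) precision, recall, accuracy and rank-based
AUC; aggregates reported as mean ± t₀.₉₇₅,k₋₁·sd/√k over the k folds.

No deep-learning framework is required: the encoders, LSTM, fusion head
and AdamW run on a small reverse-mode autodiff core (`longicog.nn`) over
numpy, in float64, fully seeded.

## Worked example

```bash
printf 'n_patients: 300\neffect_size: 2.0\n' > sim.yaml
longicog simulate --config sim.yaml --out cohort.csv --seed 7
# wrote 300 patients to cohort.csv

longicog prepare --in cohort.csv --folds 3 --seed 7 --out pairs/
# 231 patients after preparation; 909 training pairs, 231 eval pairs -> pairs/pairs.csv

longicog crossval --in cohort.csv --folds 3 --seed 7 \
    --imputation linear_attention --hidden-size 32 \
    --learning-rate 0.01 --max-epochs 55 --out cv/
```

which prints (elided):

```
AD_ovr_accuracy: 0.8225 ± 0.0812
Control_ovr_accuracy: 0.7446 ± 0.2464
aMCI_ovr_accuracy: 0.7403 ± 0.1118
overall_accuracy: 0.6537 ± 0.2148
ovr_auc_macro: 0.8895 ± 0.0566
report -> cv/report.json
```

Each line is a cross-fold mean with its 95% t-confidence half-width over
the 3 folds.  With a 2-SD first-to-last cognitive decline for AD
converters (half that for aMCI) the model recovers about two-thirds of
held-out labels against a chance level of 1/3, with AD the easiest class —
the ordering expected when aMCI trajectories sit between stable controls
and AD converters.  The same pipeline is available
programmatically via `simulate_cohort`, `prepare_pairs`,
`BaselineChangeFeaturizer` (sklearn transformer) and `FusionClassifier`
(sklearn estimator: `fit` / `predict` / `predict_proba`).

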