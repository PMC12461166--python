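# Methods

This note documents the models, the synthetic data, the numerical
choices, and the places where the design was genuinely open.

## Task and data model

A cohort is a set of patients, each a strictly date-ordered sequence of
visits.  A visit carries a diagnosis label (Control < aMCI < AD;
OtherDementia marks exclusion) and a sparse vector of strictly positive
raw feature values split into two groups: per-visit *cognition* scores and
*health*/history variables, some of which are static within a patient.
The prediction problem: from the visits 3–10 years before a patient's
final visit, predict the final visit's label.

### Eligibility and pair construction

- Eligibility: ≥ 2 visits and a first-to-last span within [3, 10] years.
  Spans are fractional years at 365.25 days/year; the convention matters
  only at day resolution.
- Patients with any non-AD-dementia label are removed whole; *pairs*
  whose target is less severe than the last prefix label (reversions) are
  removed individually, so a patient with one aberrant transition keeps
  their other transitions.
- Class balancing draws uniformly without replacement down to the
  smallest class, at the patient level, on the final label, before
  augmentation.
- Training pairs: every prefix→next-visit transition (t−1 pairs from a
  t-visit record).  Their horizons span roughly 1–10 years even though
  evaluation targets 3–10; the temporal encoder is horizon-agnostic and
  benefits from the extra transitions.  Evaluation pairs (one per
  patient, no augmentation) use only visits 3–10 years before the final
  visit, so every evaluation prefix is a subset of what training saw.
- Folds: patients (never pairs) are sorted by id, shuffled with the given
  seed, and dealt round-robin into k folds; all of a patient's pairs
  inherit the patient's fold, which is what makes the train/validation
  patient sets provably disjoint.

## Feature engineering

Two views per pair, with explicit 0/1 observation masks throughout:

- **baseline**: the *latest* prefix visit, z-scored per feature against
  the training split's control visits (mean and n−1 sd over observed
  values; features with < 2 observed control values or zero variance are
  flagged and passed through as missing).  Held-out data is always scored
  with the training statistics.  Which prefix visit should feed the
  baseline view was an open choice; the latest visit is the most
  informative single visit for a forward prediction.
- **change**: ratios x_j(t)/x_j(1) on raw (pre-standardisation) values —
  a ratio of z-scores is ill-defined near zero.  A zero or missing
  first-visit denominator masks the feature's whole row rather than
  producing infinities.  Static features are masked out of this view
  entirely (their ratio is identically 1).  A single-visit prefix yields
  an *empty* change sequence rather than the lone all-ones column: the
  constant column carries no information, and the empty sequence is what
  lets the gate bypass (below) hold exactly.

The −1 sentinel for missing values is injected inside the encoders, after
engineering, so correctness never depends on engineered values remaining
positive (z-scores are not); the explicit mask is authoritative and the
sentinel is a representation the model can exploit.

## Encoders

Both encoders first substitute the sentinel for missing cells and embed
each feature scalar with a shared 1→H linear map.  Because the stored
value of a masked cell is replaced before any computation, both encoders
are exactly (bit-for-bit) invariant to whatever a masked cell contains.

**Masked attention encoder** ("transformer" arm): 3 layers of 4-head
scaled-dot-product self-attention over the K feature positions with a
residual connection per layer.  Masked positions receive −∞ logits as
keys, so each feature's representation is a weighted average over
*observed* features only.  The printed form of the attention equation in
the source literature has inconsistent subscripts; it is implemented as
standard masked attention (query k attends over i, output Σᵢ α_{k,i} Vᵢ),
the only standard reading consistent with a "rolling average across other
features".  After the last layer the observed positions are mean-pooled
into one H-vector (the pooling rule was unstated; mean over observed
positions matches the masking semantics).  An all-missing input returns
the zero vector rather than NaN.

**Linear attention encoder** ("no transformers" arm): per-feature scores
through f(x) = S·ϕ·T(x) with S, T ∈ R^{H×H} and ϕ = ReLU, reduced to a
scalar by the mean over the H components and passed through exp, so the
scores are strictly positive and the weight normalisation
w_k = s_k / Σᵢ sᵢ can never divide by zero; weights sum to 1 by
construction.  The reweighted scalars x_k·w_k are mapped K→H by a single
projection.  The scalar-reduction and the positivity transform were open
choices (the source describes "normalized scores" without a normaliser).
This arm has roughly 5× fewer parameters than the attention stack at
equal hidden size (2,656 vs 12,736 at H = 32, K = 16).

## Fusion model

The change matrix (masked cells as 0, concatenated with the mask → 2K
channels per timestep) runs through a 3-layer LSTM with hidden size H,
zero-initialised; padded timesteps beyond a sample's length do not
advance the state, and the hidden state at each sample's own last
timestep is taken.  The gate δ = w·h is a bias-free linear functional of
the *raw* LSTM state, deliberately neither squashed nor clamped: a
sigmoid would map h = 0 to δ = 0.5, breaking the single-visit bypass.
Consequently δ·Temporal + (1−δ)·Baseline is an affine, not convex, mix.
The temporal encoding entering the mix is an H→H projection of h (the
literal table in the source lists a features→hidden projection here,
which cannot follow an LSTM hidden state; the H→H reading is used).  With
an empty change sequence h = 0 exactly, hence δ = 0 and the fused vector
equals the baseline encoding bit-for-bit (0·x = ±0 and ±0 + y = y in
IEEE arithmetic).  Head: Dropout(0.5, training only) → Linear(H,H) →
ReLU → Linear(H,3), softmax; loss is mean cross-entropy computed from
logits via a shifted log-sum-exp.

All tensors are float64 on a hand-rolled reverse-mode autodiff core
(`longicog.nn`) — elementwise ops, broadcast-aware matmul, reductions,
masked softmax — validated against central finite differences at 1e-5
(agreement to ~1e-11 absolute).  Runs are deterministic for a fixed seed
on a single thread.

## Training protocol

AdamW (decoupled weight decay 0.01), batch size 64, up to 55 epochs,
early stopping on dev-set accuracy with patience 10 and min-delta 0
(the patience was unstated; 10 epochs is a conventional choice), restoring
the best-dev weights.  The dev set is the held-out fold itself — the
protocol names no third split — which makes the early-stopping choice
mildly optimistic on the held-out metric; this is a known limitation of
the protocol, not of the implementation.  Predicted class = argmax
probability, ties toward the lower index.  The published learning rates
(5e-5 for the attention arm at hidden 512, 5e-6 for the linear arm at
hidden 2048) remain the constructor defaults; they pair with full-scale
data and do not move a small model, so the desk-scale experiments in this
package pass hidden 32 with 1e-2 (linear arm) / 3e-3 (attention arm),
picked by a small first-fold sweep in the same spirit as the original
protocol's sweep.

## Metrics

One-vs-rest extraction from the 3×3 confusion matrix treats predicting
the class under test as positive and anything else as negative; division
by zero yields NaN ("flagged undefined") rather than raising.  OvR AUC is
the rank statistic (Mann–Whitney with midrank ties), checked in the tests
against both exhaustive pair enumeration and scikit-learn.  Cross-fold
aggregates are mean ± t_{0.975,k−1}·sd/√k.  Overall accuracy is computed
per fold and then banded (pooling predictions across folds is the
alternative reading; per-fold matches the ± reporting format).

## Synthetic cohort generator

The generator emulates the *structure* of registry data, not its variable
dictionary: 2–8 visits per patient, record spans drawn from 2–11 years
(straddling the 3–10 eligibility window so filtering has work to do),
roughly annual visits (relative gap variation from a uniform [0.8, 1.5]
convention, rescaled to the drawn span), 10 cognition + 6 health features
of which 4 are static, 10% MCAR missingness, and three trajectories mixed
1:1:1.

Values are shifted log-normal, guaranteeing positivity with realistic
right skew.  On the log scale each patient carries a stable trait plus
visit noise; `reliability` (ICC, default 0.75) fixes their variance split
at a constant population marginal, emulating the test–retest reliability
of neuropsychological instruments.  This matters: with i.i.d. visit noise
at the full population SD, within-person change is unlearnable and the
method's change pathway would have nothing to detect.

Converters carry a preclinical signal in the dynamic cognition features:
their first-visit mean sits 0.5·effect below the control mean (cognitive
decline precedes the diagnostic label by years — converters in real
registries often already present impaired at entry), and they decline
linearly in time so the mean first-to-last drop equals `effect_size`
population SDs.  aMCI converters receive half the AD effect, placing
their trajectories between stable controls and AD converters.  Decline is
floored at 5% of the population mean to preserve positivity.  The
diagnostic label flips at a change-point visit drawn uniformly within the
record (AD records pass through aMCI when there is room) — later than the
feature decline begins, which is exactly what makes future status
predictable from earlier visits.  `null_cohort` re-runs the identical
draw with the effect forced to zero: labels, dates and health features
are unchanged and the feature marginals are exchangeable across groups.

What the simulator does **not** reproduce: real covariance between test
scores, learning/practice effects, informative (non-MCAR) missingness
beyond the optional per-patient feature blocks, demographic confounders,
label noise, and irregular assessment-battery versions.  Passing tests
therefore demonstrate that the pipeline recovers the signal its design
targets under clean conditions; they say nothing about accuracy on real
registry data.

## Scaled-down experiment sizes

The end-to-end checks run 300 patients, hidden size 32, a 3-fold split
with one evaluated fold, and ≤ 55 epochs — sizes chosen so the full suite
completes in minutes on one CPU while leaving the protocol (balancing,
augmentation, patient-level splitting, early stopping) identical to the
full-scale recipe.  At these sizes the held-out accuracy of the
linear-attention arm is typically 0.60–0.72 against a chance level of
1/3, and the zero-effect null cohort stays inside the 95% binomial CI of
1/3.  Fold-level metrics at n ≈ 70 evaluation pairs carry binomial noise
of about ±0.06, which dominates the differences between the two
imputation arms at this scale.

## Known limitations

- The dev set doubles as the held-out fold (see Training protocol).
- The gate is unbounded; nothing prevents δ outside [0, 1] (by design,
  to keep the exact zero bypass).
- Variable-length change sequences are padded and masked rather than
  packed; cost is negligible at ≤ 8 visits.
- `balance_classes` assumes all three classes are present and errors
  otherwise, by contract.
- The per-sample loop in the LSTM is O(T²) in the number of timesteps
  because timestep extraction uses mask-sums; irrelevant at T ≤ 8.
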