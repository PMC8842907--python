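# Methods

This note documents the modelling choices, the synthetic data model, the
numerical decisions, and the limits of what the shipped experiments
demonstrate.

## Data model and labeling

A cohort is a set of patient timelines: ordered, dated visits, each a
set of medical codes in four modalities (diagnosis ICD-9/ICD-10,
medication NDC, procedure CPT/ICD, lab LOINC).  ICD codes are
normalized by uppercasing and dot-stripping; all prefix matching happens
on the flat form.  The delivery outcome is read off the ICD-9 codes of
the delivery visit — the *last* visit carrying any labeling code:
codes under 644.2x (prefix `6442`) label preterm; 645.xx (prefix `645`)
or exactly `6498`, `650`, `6525` label full term.  Preterm takes
precedence when both families co-occur, because the positive class is
the rarer, clinically critical one.  Cohort inclusion requires at least
two visits; timelines longer than 200 visits keep their most recent 200.

Serialization is JSON Lines (one patient per line: id, visits with date
and codes, delivery date, optional pregnancy start, label) and a TSV
vocabulary (index, system, value, modality, train frequency).  Codes are
written in sorted order, so identical cohorts serialize byte-identically.

## Prediction points and data windows

All slicing is anchored on the delivery date, not on gestational age
(which EHR data rarely states reliably).  A prediction point of *m*
months keeps visits with `date <= delivery − m × days_per_month`; a
month defaults to 30 days (calendar-month subtraction is available) and
the comparison is **inclusive** — the source protocol does not state the
boundary convention, so the inclusive choice is documented here and
frozen.  The delivery visit itself is always excluded from model input:
its codes define the label, and including them would leak the outcome.
Records with fewer than two surviving visits are dropped from that task,
so task cohorts shrink as the offset grows.  The short-term window
additionally discards visits before the pregnancy start date; the data
model treats that date as caller-supplied, and the synthetic generator
fixes it at 270 days before delivery for every patient — the simplest
defensible convention given that real pregnancy-start derivation is
unspecified upstream.

## Models

Three families share one training harness.

**Code-attention network** (the primary model).  Visit multi-hot vectors
are embedded (`v_i = σ(W_emb x_i + b_x)`), a bidirectional LSTM over the
embeddings produces hidden states from which per-visit, per-dimension
attention weights `β_j = tanh(W_β h_j + b_β)` are computed, the context
is the attention-gated sum `c = Σ_j β_j ⊙ v_j`, and a single logit
`s = w·c + b` gives the preterm probability through a logistic link.  A
`reversed` direction option runs a single LSTM in reversed time instead
of the BiLSTM (then `W_β` maps from q rather than 2q dimensions).

Two head conventions differ deliberately from a literal reading of the
architecture description:

* *Single-logit head.*  A two-class softmax with a weight vector in
  R^m and scalar bias is algebraically a logistic output; implementing
  it as one logit makes the additive attribution identity exact rather
  than defined up to the softmax normalizer.
* *Linear embedding by default.*  The attribution derivation substitutes
  `v_j = Σ_k x_{j,k} W_emb[:,k]`, which silently assumes an identity
  activation and no embedding bias.  With ReLU the per-code split of a
  visit's contribution is not exact.  The package therefore defaults to
  `embedding_activation="linear"`, `embedding_bias=False`; relu/sigmoid
  (+bias) are available for prediction-only use, and the attribution
  module refuses them rather than report an approximate decomposition as
  exact.  The network remains nonlinear through the LSTM and tanh
  attention.

**RETAIN baseline.**  Adds a second reversed-time LSTM producing scalar
visit weights `α_j` (softmax-normalized over unmasked visits); the
context becomes `Σ_j α_j β_j ⊙ v_j`.  Its attributions carry the α
factor: `ω = α_j · w·(β_j ⊙ W_emb[:,k]) · x_{j,k}`, and the additive
identity holds in the same exact form.

**MLP baseline.**  One hidden ReLU layer on per-patient code counts
(code in three visits counts three); visit order is discarded by
construction.

All models are numpy with hand-written backpropagation — no deep
learning framework is a dependency.  The masked LSTM carries hidden and
cell state through padded steps unchanged in both directions, so
appending padding never changes any output (asserted to 1e-6 in tests);
the backward pass mirrors the gating exactly and is validated against
central finite differences (smooth activations; ReLU's kink at
exactly-zero pre-activations makes a numerical probe invalid there).

## Training

Mini-batch Adam on binary cross-entropy, dense multi-hot batches padded
to the batch's longest sequence with mask-gated sums, global-norm
gradient clipping at 5.  Patients are split 70/10/20 into
train/validation/test, stratified by outcome with largest-remainder
quotas (every split's class count within one patient of its target);
vocabularies are built from training records only, and out-of-vocabulary
codes at encode time are dropped and counted.  Reference defaults follow
the 200/200/32 embedding/hidden/batch setup with a 200-visit cap.

Four numerical choices matter and are defaults because they measurably
close the gap to the generator's closed-form oracle at desk scale:

1. **Coupled L2** on weight matrices (never biases), added to the
   gradients.  With Adam, a decoupled decay is normalized away on sparse
   high-dimensional code inputs; the coupled penalty behaves like
   sklearn's penalized logistic regression and controls memorization of
   rare-code patterns.
2. **Output-bias initialization** at the log-odds of the training base
   rate, so early epochs learn discrimination rather than calibration
   under 8% prevalence.
3. **Zero-initialized attention head** (`W_β = 0`, `b_β = 0.5`): β
   starts uniform at tanh(0.5) on every dimension of every visit, so
   optimization starts from a plain visit-summing linear classifier and
   attention structure grows only where the data demands it.
4. **Checkpoint selection on validation loss** (step lr decay ×0.3 at
   60% of the epoch budget).  PR-AUC and ROC-AUC remain available as
   selection metrics, but with ~16 positives in a 10% validation split
   at desk scale their estimates are noisy enough to select
   near-arbitrary checkpoints; validation loss tracks held-out ranking
   quality far more stably.

Class imbalance is handled by plain cross-entropy with an optional
positive-class weight (default 1).  Since a well-regularized model under
8% prevalence rarely emits probabilities above 0.5, sensitivity and
specificity are reported at a stated threshold — 0.5 by default, with a
Youden-optimal threshold selected on validation data as the informative
alternative (the experiments report the latter).

## Synthetic cohort generator

The generator emulates the structure of a delivery-anchored claims
cohort at desk scale.  Defaults: 870 codes (diagnosis 500, medication
100, procedure 150, lab 120 — a scaled-down echo of a diagnosis-
dominated clinical vocabulary), 8% preterm prevalence, Poisson visit
counts (mean 11, minimum 2) on distinct days uniform over a 3-year
history, 1+Poisson(3) codes per visit drawn Zipf (exponent 1.2) within
each modality, and a delivery visit carrying the appropriate ICD-9
labeling code.

Risk is planted through **exposures**: each of three default risk codes
(diagnosis codes at Zipf ranks 50/130/210 — rare enough that background
draws add little noise, common enough to appear in every split) has an
independent exposure probability of 0.25 per patient, a log-odds effect
of 2.5, and an active window of 90 days before delivery.  Labels are
drawn from `P(preterm) = logistic(b0 + Σ effects of exposures)` with the
intercept solved numerically on the realized exposures to hit the target
prevalence.  An exposed patient's code is placed in a random existing
visit inside the window, or in a newly created visit there — never by
moving an existing visit, which would leave an exposure trace in the
post-cutoff timeline.  Under these defaults the Bayes-optimal classifier
on the exposure count has a closed-form ROC-AUC of ≈0.89, which is the
ceiling against which the trained models are judged.

What the generator does **not** emulate: real code semantics and
co-occurrence structure, comorbidity trajectories, per-patient visit
seasonality, coding-system migration, measurement values for labs, and
multiple deliveries per mother.  Passing the shipped experiments
demonstrates that the implementation recovers planted, time-localized
additive risk under realistic sparsity and imbalance — not clinical
validity on real EHR data.

## Canonical experiments (`ptbrisk.experiments`)

Problem sizes are chosen so each experiment runs in minutes on one CPU:
cohorts of 2,000 (recovery/null) or 3,000 (trends) patients and a 32/32
embedding/hidden configuration with the recipe above (L2 2e-2, lr 1e-2,
50 epochs).

* **Signal recovery** — default generator, all pre-delivery history
  (offset 0): held-out ROC-AUC and whether all three planted codes rank
  in the top decile of mean positive-class contribution.  At a 1-month
  offset the 30-day cut removes about a third of the 90-day planted
  window and the attainable AUC falls to ~0.76, so the recovery check is
  run at offset 0 where the oracle is ~0.89.
* **Null control** — identical generator with all effects zero; held-out
  ROC-AUC should sit near 0.5 (the null sampling band at 400 test
  patients is roughly ±0.05).
* **Trends** — signal active only in the last 60 days.  Slicing three
  months out removes the whole signal window, so the 1-month model
  should dominate the 3-month model.  For the window comparison, the
  cohort is first restricted to short-window-eligible patients (≥2
  visits inside pregnancy) and both windows are trained on that common
  population, so the cells differ only in whether pre-pregnancy noise
  visits are included; comparing across differently-composed cohorts
  would confound the window effect.  n = 3,000 because at half that size
  the short-window cell is statistically unlearnable by any method
  (a converged L2 logistic regression reaches ~0.51 versus an oracle of
  ~0.69).

## Known limitations

* Degenerate inputs: visits with only out-of-vocabulary codes encode as
  zero vectors and stay in the sequence; empty visit sets are invalid.
* Ties in attribution rankings break by ascending code index; ROC ties
  count half (Mann–Whitney convention).
* The additive attribution is on the logit scale, where it is exact; the
  probability is reported alongside but probability-scale shares are not
  additive.
* Training determinism holds for a fixed seed, platform and BLAS; across
  BLAS implementations results may differ in the last few bits.
* No ICD-9↔ICD-10 mapping, no gestational-age estimation, no grouping of
  multiple deliveries of the same mother, and no significance testing
  between models.
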