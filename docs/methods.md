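# Methods

## Problem setting

Survivors of in-hospital cardiac arrest (IHCA) face high 30-day mortality
and readmission risk, but the task of predicting outcomes *after the
cardiac-arrest record itself* is extremely imbalanced: in national claims
data the CA-mortality label is positive for roughly half a percent of
CA records. This package implements (a) the hierarchical visit-sequence
model that turns a patient's claims history into per-record risk scores,
(b) the two counter-measures that make training on such imbalance viable —
cosine-gated multitask learning and person upsampling with CA record
weighting — and (c) a synthetic cohort generator that reproduces the
statistical structure of the problem, since the underlying national claims
databases are access-restricted and no public substitute exists.

## Data model and labels

A clinical record is one dated inpatient/outpatient visit with codes in
five categories (diagnosis, procedure, medication, test, other), care-site
attributes, per-category costs and counts, and a hospital-stay duration.
Dates are integer day indices from a cohort epoch; same-day records are
ordered by record id so recurrent processing is total and reproducible.
A record is a CA record iff it carries an ICD-9 resuscitation procedure
code (default set {99.60, 99.63}).

Per-record targets use inclusive integer windows:

* **mortality_30d** — a record is positive iff the person's mortality event
  (the single record flagged dead-or-discharged-critical) occurs 1–30 days
  later. The mortality record itself is always negative. This anti-leakage
  convention exists because terminal-record features trivially encode death;
  a model exploiting them scores well and is clinically useless. A config
  flag (`drop_mortality_records`) implements the stricter alternative of
  removing those records altogether; keeping them as negatives is the
  default.
* **readmission_30d** — defined for inpatient records only: positive iff a
  later inpatient admission starts 1–30 days after the discharge day
  (date + stay). Outpatient records have no discharge day and are excluded
  (NA), not zero-filled. Overlapping stays yield a warning and count as
  non-readmission.

Four task subsets follow: ALL-/CA-mortality and ALL-/CA-readmission, the
CA variants being the same labels masked to CA records.

## Synthetic cohort generator

A single scalar latent severity s ~ N(0,1) per person drives every
observable channel, which is the minimal structure under which "codes
predict outcomes" can hold and be recovered:

* codes are drawn from a per-category Poisson count; each code comes from
  the severe fifth of the vocabulary with probability sigmoid(s − 1);
* inpatient records (30% of visits) carry a CA procedure code with a
  severity-tilted probability;
* after each record the person dies with hazard sigmoid(c + β·s)
  (β = `severity_effect`); a death appends a terminal flagged record 1–30
  days after discharge and ends the sequence;
* after each inpatient record, the next visit is an inpatient admission
  1–30 days from discharge with probability sigmoid(c_r + β·s); otherwise
  the next visit starts 31–120 days later, so accidental readmissions
  cannot occur and the readmission rate is exactly the configured Bernoulli
  parameter among non-terminal inpatient records;
* costs are lognormal with log-mean increasing in severity and code count,
  giving the cost-regression heads a learnable target; inpatient stays are
  1 + Poisson(3) days.

**Calibration.** All intercepts are solved deterministically (80-node
Gauss–Hermite quadrature + Brent root-finding) so that *marginal* rates hit
their configured values: the per-record CA rate, the non-CA and CA
per-record death hazards, and the readmission probability. The CA-record
hazard is calibrated against the severity-tilted distribution of CA
records. Because death truncates sequences, the nominal geometric
visit-count parameter is likewise solved from the closed-form expectation
E[records | s] = (1 + q(s)) / (1 − (1−p)(1−q(s))) so the *realized* mean
records per person (terminal records included) matches the configured mean.
A readmission forces the next record to be inpatient, so the free inpatient
probability is set per person to β_in = π(1−r)/(1−πr), keeping the
stationary inpatient fraction at π = 0.3.

**Defaults as study conditions.** mean 9.3 records/person, CA-record rate
11%, CA-mortality hazard 0.53% — the regime reported for the real cohort —
with severity_effect 1.5, base mortality hazard 2% and base readmission
rate 30% chosen as realistic mid-range values; demographics (37.9% male,
age 68.7 ± 19.0) follow the published population table. Generation is a
pure function of the config including its seed.

**What the generator does not emulate:** real ICD-9 semantics or
co-occurrence structure, care-site taxonomies, coding drift over years,
multi-dimensional comorbidity (severity is one scalar), or realistic cost
scales. Passing tests therefore certify the *machinery* — labeling,
featurization, optimization, evaluation, and the direction of the
imbalance-handling effects — not clinical performance on real claims.

## Featurization

The 707-dim record vector concatenates, in fixed order: five 128-dim
code-category sums, claim type (2), age (1), gender (2), care-site type /
specialization / rank (21/5/17), hospital stay (1), per-category costs (5)
and counts (5), and 3/6/12/24-month history features (4 stay-day sums + 4
admission counts over windows strictly before the record date).

Code embeddings are deterministic hashed standard-normal vectors keyed by
(seed, category, code): the architecture only requires a fixed code→vector
map, and the synthetic signal lives in code identity, which random
embeddings preserve. No semantic-similarity structure is claimed; swapping
in any pretrained clinical code embedding is a drop-in replacement.
Codes are summed in sorted order so featurization is exactly
permutation-invariant.

Scalar features are z-scored with statistics fitted on the training split
only (costs log1p-transformed first); the scaler freezes after fitting, so
validation/test featurization can never leak statistics.

## Model

Record encoder: one fully-connected layer, tanh, output 200 (dropout 0.5 on
its output during training). Person state: LSTM with 128 hidden units,
standard gates, forget-gate bias initialized to 1, state reset to zeros per
person. Eight affine heads read the person vector: mortality and
readmission logits, three reconstructions partitioning the 707-dim input
(codes 640 / context 48 / statistics+history 19), current- and next-record
cost (log1p total cost, standardized; next-record target is 0 — the mean —
for the last record, the minimal well-defined "future cost" horizon), and
the CA-record classifier. Classification losses are binary cross-entropy
from logits; reconstructions and regressions are mean-squared error.

The implementation is NumPy with hand-written backpropagation. The
backward pass takes the per-task head gradients as a stacked tensor and
propagates all tasks through the shared encoder/LSTM in one vectorized
pass, returning one flat gradient vector per task. Gradient arithmetic
runs in single precision (the dominant contractions are ~2× faster and
first-order optimizers are insensitive to 1e-7 relative gradient noise);
the forward pass is double precision, so prediction contracts (causality,
step-vs-batch equivalence) hold at full precision. Hyperparameter defaults:
visit embedding 200, recurrent output 128, learning rate 1e-3, dropout 0.5,
L2 weight 0.01 (applied to weight matrices, not biases, and added to the
main-task gradient), code embedding 128.

## Training

One model is trained per main task (mortality or readmission); the other
main head exists in the architecture but receives no gradient. In
multitask mode the six auxiliary gradients are gated independently against
the main gradient G:

    direction = G + Σ_i max(0, cos(G, V_i)) · V_i,

with cos of a zero vector defined as 0, and the parameters updated by Adam
(β = 0.9/0.999) at the configured learning rate. In ~4·10⁵-dimensional
parameter space the cosines are small early in training (|cos| ≲ 0.05), so
the gate admits auxiliary influence conservatively; empirically the
multitask and single-task trajectories stay close on the synthetic cohorts
while conflicting gradients are provably excluded (a property test pins
this exactly).

Batches are sets of persons; sequences are processed full length with
per-person state reset. For padding efficiency persons are grouped into
batches by sequence length and batch order is shuffled per epoch.
Upsampling replicates, within each training batch, every person holding at
least one CA record positive for the main task, `upsampling_rate` times;
replicas get independent dropout. Record weighting multiplies each
per-record loss by w_pos on CA records (w_neg = 1 otherwise), normalized by
the total weight so the effective learning rate is comparable across weight
settings. Both mechanisms apply to the training split only.

Splits are person-level 70/15/15 by seeded permutation. Early stopping
monitors main-task validation AUROC with patience 5 and restores the best
epoch; if the validation metric is undefined (single-class), training runs
to the epoch cap. Training is bitwise reproducible given the config seed
and init seed.

## Evaluation

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative, ties at 1/2, computed via average ranks. F1/precision/
recall use a fixed 0.5 probability threshold by default, with an optional
validation-maximizing threshold mode; degenerate confusion-matrix corners
follow the precision = 0 / recall = 0 conventions. Single-class inputs
raise an undefined-metric error and surface as NA, never 0. CA-task
metrics mask the same trained model's scores to CA records (one model, two
masks). The grid harness trains each (config, seed) cell, records
failures without aborting, and summarizes mean ± sd over seeds in the
layout of the upsampling-rate × event-weight study.

## Scales used in the shipped checks

The direction-of-effect study runs on 5,000 generated persons
(~46,000 records), 5 seeds and 2 epochs per arm, comparing single-task,
multitask, and multitask + upsampling(10) on CA-mortality test AUROC; the
orderings are asserted within the overlap tolerance of the across-seed
spread (the claim is directional, not an absolute value). The acceptance
script uses the same scale but reports, per arm, one cross-validated AUROC:
each record is scored whenever it falls in the held-out 30% across the five
split seeds and the scores are averaged per record, so the CA metric rests
on all of the cohort's few dozen rare positives rather than the handful in
any single test split. These sizes keep a full run on a single CPU in
minutes; even so, CA-task metrics on any one generated cohort carry
substantial sampling noise — which is the phenomenon under study.

## Known limitations

* The cosine-scaled gate admits only small auxiliary influence in very
  high-dimensional parameter spaces; with near-orthogonal task gradients,
  multitask and single-task training coincide to within seed noise. The
  binary-gate variant (add V whenever cos > 0) would transfer more
  auxiliary signal but is not the rule implemented here.
* "Future cost" is next-record cost; cumulative-horizon variants are not
  implemented.
* One scalar severity latent cannot represent competing risks or
  condition-specific trajectories; absolute AUROCs on the synthetic cohorts
  are not comparable to values obtainable on real claims.
* No calibration of predicted probabilities, decision-curve analysis, or
  interpretability tooling.
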