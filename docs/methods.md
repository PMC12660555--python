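# Methods

## Problem setting and data model

A cohort is a set of patients, each an ordered visit sequence. Timestamps
are float hours from an arbitrary per-cohort epoch; no calendar or timezone
logic exists anywhere (all derived quantities are differences, so the
representation is translation-invariant, and a property test pins this).
Visits carry diagnosis codes (opaque strings — mapping raw ICD codes into
condition groups is left to an upstream grouping table, since grouping
conventions vary by site), four canonical note sections, and lab rows
(item id, value, unit, abnormal flag). Cohorts serialize as one JSON object
per line; loading re-validates every invariant (strictly increasing
admissions, discharge ≥ admission, unique patient ids) and write→load is
the identity on validated cohorts.

Prediction instances are built one per patient: history = all visits except
the last, target = the last visit's label vector. This matches patient-level
sample counting; an expanding-window mode (one instance per visit prefix) is
available behind `RunConfig.expanding_window` for studies that want
visit-level counts.

## Temporal features

For visit *t*: duration = d_t − a_t and gap = a_t − d_{t−1}. The first
visit has no predecessor; its gap is set to 0, a neutral value under
min-max scaling. Overlapping admissions (negative gaps) occur in real EHRs;
they are clamped to 0 with a logged warning rather than rejected. Sequences
longer than `max_len` = 16 keep the most recent 16 visits — recency
dominates chronic-care prediction — and when the true first visit is
dropped, the first retained row keeps its real gap to the dropped
predecessor rather than being zeroed, preserving information. Padding rows
are all-zero with a false mask bit, and every downstream computation is
masked so padding can never influence a result (tested: the temporal
embedding is bit-identical under layer norm, and equal to 1e-6 under the
masked batch-norm mode, when trailing padding is appended).

## Semantic stream

Abnormal lab rows become templated sentences
(`These are abnormal results recorded: ITEMID<id>: <value> <unit>; ...;`);
normal rows are dropped, and zero abnormal rows yield the empty string so
no constant token stream leaks into every document. Lab values pass through
verbatim — no unit normalization or rounding, since source conventions
differ. Per instance, the document concatenates each history visit's
non-empty sections in the fixed order Chief Complaint, Current Illness,
Medical History, Admission Medication, then that visit's lab text, with
`[SEC]`/`[VISIT]` delimiter tokens. A whitespace-token budget (default 64)
drops whole visits oldest-first — the newest clinical state matters most —
and hard-truncates only when the newest visit alone exceeds the budget.

The encoder contract is the reusable piece: document → fixed-dimension
vector *h_a*, then the trainable affine projection *z_a = W h_a + b* into
disease-logit space. The default compact encoder hashes whitespace tokens
into 2048 buckets (a fixed blake2 hash — deterministic, no tokenizer model
to ship), adds sinusoidal positions, and runs a small post-norm transformer
stack, pooling the last non-pad token to mirror the final hidden state of
an autoregressive decoder (mean pooling by config). Its default geometry —
d_llm 32, 1 layer, 2 heads, 64-token budget — was sized so that full
training runs complete in seconds on one CPU core; the dimensions are
config-exposed and the contract is unchanged at any size. External
encoders (e.g. a hosted fine-tuned clinical LLM) plug in through
`EncoderAdapter`: declare `d_llm` and `trainable`, return one vector per
document, honor the pooling contract. A `FixedVectorEncoder` stub serves
conformance tests and offline-embedding workflows.

## Temporal stream

Durations and gaps are min-max scaled with statistics fitted on the
training split only (fitting globally would leak test-set range
information). Test-time values outside the training range clip to [0, 1];
constant features map to 0. The encoder follows the published geometry:
d_model 64, 8 heads, 3 layers, FFN 256, dropout 0.10, max length 16, GELU
activation, with scaled dot-product attention `softmax(QKᵀ/√d_k)V` and a
padding mask that excludes invalid keys before the softmax (each attention
row is therefore a probability distribution over valid keys; a fully
masked query row is defined as zero context rather than NaN).

Two normalization modes exist because the two natural choices genuinely
differ for clinical timelines: `batch` (default) computes batch-norm-style
per-feature statistics, taken per sequence over valid positions only so
padding cannot leak and results do not depend on batch composition;
`layer` is the standard transformer choice. Residual connections wrap both
sublayers (post-norm placement, as in the original encoder design) — a
3-layer encoder does not train reliably without them. The sequence is
aggregated by masked mean-pooling (a learned-token alternative was
considered and rejected as extra machinery with no measurable benefit at
this scale), then mapped by the output affine z_b = W_o z̃ + b_o.

A single-layer, single-head configuration is verified against a
straight-line dense-math reimplementation to 1e-5 in the test suite, for
both norm modes and both activations.

## Fusion, prediction, training

z_in = [z_a ‖ z_b] feeds an MLP with one ReLU hidden layer of width
d_model (extra depth config-gated), then an affine map to one logit per
target label. Note the dimension bookkeeping: z_a lives in label space
(d_a = number of diseases) while z_b lives in model space (d_b = 64); the
fused vector has d_a + d_b entries. Probabilities are elementwise sigmoid;
decisions threshold at 0.5 with the boundary assigned to the positive
class (so an untrained zero-logit model predicts positive — pinned by a
test). Either modality can be absent, which is exactly how the no-text /
no-temporal ablations run through the identical code path.

The objective is α·BCE + (1−α)·hinge with α = 0.95. BCE sums over labels
and, by default, averages over patients so α keeps a batch-size-independent
meaning (the literal unreduced patient sum is available as
`reduction="paper-sum"`). The hinge term sums max(0, 1 − (ŝ_i − ŝ_j)) over
(positive, negative) label pairs per patient and divides by the patient
count — not the pair count, so patients with many labels weigh more; this
literal normalization is kept deliberately. Scores ŝ are pre-sigmoid
logits by default: on the probability scale the unit margin is unattainable
(differences of sigmoids are < 1) and the loss could never reach zero; a
probability-scale mode is retained for literal fidelity. Probabilities are
clamped at 1e-7 for log stability. Both losses' analytic gradients match
finite differences to 1e-4 in tests.

Training is mini-batch Adam — the optimizer is a deliberate default since
none is dictated by the architecture — over all parameters jointly
(encoder, projection, TST, MLP), batch size 8, 10 epochs, with the
best-validation-loss checkpoint retained. The default learning rate is
1e-4, appropriate for fine-tuning a large pretrained encoder; the
scaled-down synthetic experiments train the compact encoder from scratch
and use 3e-3, a standard from-scratch Adam rate — at 1e-4 the randomly
initialized model cannot leave the all-negative-prediction regime within
the 10-epoch budget. Splits are always at patient level: 80/20 train/test,
the train side re-split 4:1 (net 64/16/20), floor-rounded
(test = ⌊0.2n⌋, train = ⌊0.8(n − test)⌋, remainder to validation), and a
leakage assertion runs on every training and evaluation call. All
randomness (split, initialization, batch order, dropout) derives from
`split_seed`/`init_seed`, and the whole stack is float64 single-threaded
numpy, so identical configurations reproduce metric reports bitwise.

The heart-failure task is the d_out = 1 head whose target is the CHF
component of the next visit's labels; with a single label the hinge term
has no (positive, negative) pairs and contributes exactly 0, so training
reduces to BCE automatically.

## Metrics

Per-label confusion metrics (precision, recall, F1; macro and
support-weighted averages) are delegated to scikit-learn; reported
precision/recall are macro-averaged, and labels with zero predicted
positives score 0. Multilabel "accuracy" is the per-cell rate — the
fraction of correct label decisions over all sample × label cells — which
sits above macro-F1 under imbalance, as expected for this family of
models; subset accuracy is available by flag. Recall@k and NDCG@k follow
the standard definitions with binary relevance; ranking ties break by
ascending label index for reproducibility, patients with no positive label
are excluded from the averages (their denominators are undefined), k > d
clamps to d with a warning, and the ideal DCG truncates at
min(k, #positives). Both are verified against brute-force enumeration
oracles on 200 random fixtures to 1e-9.

## Synthetic cohorts

The generator reproduces the statistical structure the model assumes, not
clinical realism. Each of d = 10 conditions (named after the ten most
prevalent chronic conditions in critical-care cohorts: HTN, ARRHY, DM,
VALVE, CHF, CHRNLUNG, LYTES, NEURO, RENLFAIL, HTNCX) evolves independently
as a two-state Markov chain: initial activation probabilities spread
linearly from 0.40 to 0.08 (mimicking the skewed prevalence of top-10
condition lists), onset 0.05, persistence 0.95 — so conditions behave
chronically, which is what makes history predictive of the next visit.
Visit counts are uniform on 2..8 (every patient passes the ≥ 2-visit
filter by construction).

Observable channels: note sections emit an indicative token per active
disease with probability 0.65 (0.03 spuriously for inactive ones) plus
background tokens; each disease's lab item is abnormal with probability
0.90 when active versus 0.03 background; stay duration has gamma mean
36·(1 + 0.8·k) hours and the next gap gamma mean 2400/(1 + 1.5·k) hours,
k = active-condition count — sicker patients stay longer and return
sooner, the qualitative pattern the temporal stream is designed to read.
Scenario presets decouple the channels: `text-only-signal` flattens the
temporal laws, `time-only-signal` flattens text and labs, `null` flattens
both; `mixed-signal` keeps all.

What the generator does *not* emulate: comorbidity coupling between
conditions (a correlation hook exists but defaults to independence), real
clinical language, ICD code semantics, measurement error in timestamps, or
the marginal statistics of any real dataset. Passing tests therefore show
that the pipeline recovers signal *where the generative assumptions hold*;
they say nothing about performance on real clinical data.

Closed forms used by tests: occupancy of the two-state chain
p_{t+1} = p_t·persist + (1 − p_t)·onset with p_1 = init, averaged over the
visit-count law for last-visit prevalence; and the no-skill baseline — a
predictor flipping each label with its prevalence p has expected precision
= recall = p, hence expected F1 = p, so the baseline macro-F1 is the mean
prevalence.

## Scaled-down study sizes

The signal-recovery experiments (acceptance tests and
`scripts/acceptance.py`) use cohorts of 500 patients, d = 10, three seeds,
with the compact encoder at learning rate 3e-3 — sizes at which the full
3-ablation × 3-seed sweep completes in a few minutes on one CPU core while
leaving clear separation between the full model, its ablations, and the
no-skill baseline.

## Known limitations

- The compact encoder is a contract-faithful stand-in, not a clinical
  language model; absolute metric values on synthetic data do not transfer.
- The hinge normalization (per patient, not per pair) makes many-label
  patients weigh more; kept literally, flagged here.
- No probability calibration or per-label thresholds; the single 0.5
  threshold is used throughout.
- Ingestion stops at the documented JSONL cohort schema; parsing raw
  hospital table extracts (admissions, note events, lab events) into that
  schema is left to site-specific adapters.
- Batch-norm mode uses per-sequence statistics; with very short sequences
  (one visit) the variance estimate degenerates and the epsilon floor
  dominates — layer norm is the safer choice for such cohorts.
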