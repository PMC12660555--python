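# ehrfusion

Multimodal chronic-disease prediction from longitudinal electronic health
records (EHRs), for clinical-informatics researchers who want a tested,
CPU-scale reference implementation of the lab-to-text / time-series-fusion
modeling recipe — and a synthetic cohort generator to exercise it where the
real credentialed datasets cannot be shared.

## The model

A patient is a sequence of visits. Visit *t* carries admission and discharge
timestamps *a_t*, *d_t* (hours), a set of diagnosis codes, four free-text
note sections (Chief Complaint, Current Illness, Medical History, Admission
Medication) and structured lab results. Given visits 1..*T*, the task is to
predict the multilabel diagnosis vector **y** ∈ {0,1}^d of visit *T*+1 over
the *d* = 10 most prevalent chronic conditions (a binary heart-failure
variant uses the CHF component alone).

Two representation streams are learned jointly:

- **Semantic stream.** Abnormal lab rows are templated into text
  (`These are abnormal results recorded: ITEMID<id>: <value> <unit>; ...;`),
  concatenated with the note sections of every history visit, and encoded to
  a hidden vector *h_a*; an affine projection maps it into disease-logit
  space, *z_a = W h_a + b*. The encoder is pluggable: the default is a
  compact trainable transformer over hashed tokens (so everything runs on a
  laptop CPU); an adapter protocol accepts externally hosted large language
  models.
- **Temporal stream.** Each visit contributes two features: duration
  δ_visit = *d_t* − *a_t* and inter-visit gap δ_gap = *a_t* − *d_{t−1}*
  (long stays flag severity; short gaps flag instability). After min-max
  scaling fitted on the training split, a masked time-series transformer
  encoder (input projection *u_t = W_p x̃_t + b_p*, fixed sinusoidal
  positions, scaled dot-product self-attention `softmax(QKᵀ/√d_k)V` with a
  padding mask, FFN, post-norm residual blocks) is mean-pooled over valid
  positions into the temporal embedding *z_b = W_o z̃ + b_o*.

The fused vector *z_in = [z_a ‖ z_b]* passes through an MLP
(*h* = ReLU(W₁ z_in + b₁), *z* = W_out h + b_out); probabilities are
σ(*z*), dichotomized at 0.5. Training minimizes the hybrid objective

    L = α·L_BCE + (1−α)·L_hinge,        α = 0.95,

where L_hinge sums max(0, 1 − (ŝ_i − ŝ_j)) over each patient's
(positive i, negative j) label pairs, rewarding correct label *ranking* on
top of per-label calibration. Evaluation reports macro/weighted F1,
precision, recall, accuracy, and the ranking metrics Recall@k and NDCG@k
(DCG@k = Σ (2^rel_i − 1)/log₂(i+1), normalized by the ideal DCG).

All neural components run on a small numpy reverse-mode autodiff core
(`ehrfusion.nn`) — no deep-learning framework required.

## Worked example

```python
from ehrfusion import RunConfig, evaluate, generate_cohort, scenario, train
from ehrfusion.synthetic import no_skill_macro_f1

config = scenario("mixed-signal", n_patients=500, seed=1)   # labels drive text AND timing
cohort, truth = generate_cohort(config)
ckpt = train(cohort, RunConfig(lr=3e-3, split_seed=1, init_seed=1))
report = evaluate(ckpt, cohort, "test")
print(round(report.f1_macro, 4), round(report.accuracy, 4),
      round(report.recall_at_k[3], 4), round(no_skill_macro_f1(config), 4))
```

prints

```
0.4625 0.757 0.5517 0.3256
```

— the full model reaches macro-F1 0.4625 on held-out patients against a
no-skill (prevalence-matched random predictor) baseline of 0.3256, places
55% of true diagnoses in its top 3 (Recall@3 0.5517), and gets 75.7% of
label decisions right. Dropping lab text (`ablation="no-labtext"`) falls to
macro-F1 ≈ 0.33 and dropping all text (`ablation="no-text"`, timing only)
collapses further — the same qualitative ordering the modeling recipe
predicts.

The same pipeline is scriptable from the shell:

```bash
ehrfusion simulate --scenario mixed-signal --n 500 --seed 1 -o cohort.jsonl
ehrfusion train --cohort cohort.jsonl --config run.yaml -o ckpt.npz
ehrfusion evaluate --ckpt ckpt.npz --cohort cohort.jsonl --split test
ehrfusion ablate --cohort cohort.jsonl --config run.yaml
ehrfusion predict --ckpt ckpt.npz --cohort cohort.jsonl -o predictions.jsonl
```

## Layout

- `src/ehrfusion/ehr_data.py` — data model, JSONL cohort I/O, temporal features
- `src/ehrfusion/text_assembly.py` — lab-to-text templating, document assembly
- `src/ehrfusion/text_encoder.py` — compact semantic encoder + adapter protocol
- `src/ehrfusion/tst_encoder.py` — masked time-series transformer
- `src/ehrfusion/fusion.py` — embedding fusion, MLP head, prediction
- `src/ehrfusion/objectives.py` — BCE, multilabel hinge, hybrid loss
- `src/ehrfusion/metrics.py` — classification + Recall@k / NDCG@k
- `src/ehrfusion/synthetic.py` — Markov-chain cohort generator, scenarios
- `src/ehrfusion/pipeline.py` — splits, training loop, evaluation, ablations
- `src/ehrfusion/nn.py` — numpy autodiff core
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
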