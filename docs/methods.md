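# Methods

## Overview

`ehrgpt` treats a longitudinal electronic health record as a sentence: a
patient is a sequence of visits, each visit a bag of coded clinical
events (ICD-10-style diagnoses, RxNorm-style medications, CPT-style
procedures, LOINC-style labs) linearized into tokens, and a small
decoder-only transformer is trained to predict the next token given
everything before it.  On top of that single pretrained model the
package implements two evaluation protocols — stepwise visit-level
forecasting, and zero-shot prediction of a future diagnosis from a
censored history — plus a frozen-backbone linear probe as the supervised
comparator, and attention/embedding interpretability.

## Token grammar

A record is rendered as

```
SEX:·  AGE:·  [V1]  SEP  t_k  [V2]  SEP  …  t_k  [VL]  SEP
```

* **Demographics prefix** — one sex token and one age token (5-year
  buckets, age at first visit; bucket width configurable).
* **Time tokens** — every visit except the first opens with one of
  `t0/t1/t2/t3` encoding the gap to the previous visit: ≤ 91 days,
  92–182, 183–365, > 365.  The boundaries are fixed day counts (a
  rolling reading of "same quarter"), so the partition of [0, ∞) is
  exhaustive and deterministic.
* **Visit body** — a visit-type token (`VT:outpatient/inpatient/emergency`),
  the event tokens, and for inpatient visits an optional discharge-type
  token (`DT:·`).  Every visit, including the last, is terminated by the
  separator `SEP`; generation uses `SEP` as the visit terminator.
* **Intra-visit order** — events within a visit frequently share one
  timestamp, so a canonical order (timestamp, then domain
  diagnosis→procedure→medication→lab, then code) is imposed.  The order
  is artificial but deterministic, which makes tokenization and training
  reproducible.
* **Truncation** — sequences longer than the 512-token context window
  drop whole oldest visits (never part of one); the demographics prefix
  is always kept and the earliest retained visit is re-rendered without
  a time token, so truncated sequences remain grammatical.

## Vocabulary

Diagnosis codes are first passed through an optional user-supplied
source→target code table (e.g. an ICD-9→ICD-10 equivalence map; the
table is a total function with identity fallback), then grouped to the
≤ 3 characters before the decimal (`E11.9 → E11`).  Codes carried by
fewer than 0.1% of patients are removed; the count is per patient (a
code billed in ten visits of one patient counts once), which makes the
filter robust to repeat billing, and exactly-at-threshold codes are
retained (strictly-below removal).

Lab values are discretized per lab code into ten bins by the empirical
CDF of the training split: the nine boundaries are the type-1
(left-continuous inverse eCDF) 10th…90th percentiles,
`b_k = sorted[⌈k·n/10⌉ − 1]`, and a value's bin is the number of
boundaries strictly below it.  Out-of-range values at inference clip to
bins 0/9; a lab with fewer than 10 training values is excluded, and an
all-identical lab degenerates to a single bin with a warning.  Each
(lab code, bin) pair is one vocabulary entry.

Ids are assigned deterministically: a fixed structural token list first
(PAD, SEP, time tokens, visit/discharge types, sex, age buckets), then
all retained clinical tokens in lexicographic order.  The vocabulary
serializes to a single JSON file and carries a content hash that
checkpoints verify at load time.

## Model and training

The network is a pre-norm GPT stack written directly in NumPy (causal
multi-head self-attention, GELU MLPs, learned positional embeddings,
untied output head) with a hand-derived backward pass, verified against
numerical differentiation, and Adam.  Defaults are desk-scale — 2
layers, 2 heads, 128 hidden units, context window 512 — chosen to train
on one CPU core in minutes; width, depth and dropout are configurable.
Training minimizes mean next-token negative log-likelihood with PAD
positions excluded, uses a patient-level 90/10 train/validation split,
fixed learning rate, and early stopping on validation loss (best
weights restored).  Batches are length-bucketed to limit padding waste;
all randomness (init, shuffling, dropout, splits) flows through seeded
generators, so identically seeded trainings are bit-reproducible.
Computation is float32.

Greedy decoding takes the arg-max at each step with ties broken toward
the lowest token id; `top_n_candidates` orders by probability then id,
so candidate sets are nested in N.

## Visit-level forecasting metric

For each patient with L ≥ 2 visits and each k < L, the model receives
the demographics prefix plus visits 1..k and greedy-decodes until it
emits SEP (or a 64-token cap).  The generated and true token sets for
visit k+1 are compared; only SEP is excluded from either set, so time,
visit-type and discharge tokens participate symmetrically.  Precision is
|∩|/|generated| (0 when nothing is generated), recall |∩|/|truth|, and
the aggregate is micro-averaged over all compared visits.

## Zero-shot censored-window protocol

For a target diagnosis token (or an ICD chapter range, where any member
token counts):

* **Positives** — patients whose first target occurrence leaves at least
  `min_history_visits` visits strictly before *first target date −
  window*; the input is the history censored at that point and is
  verified target-free by an automated scan.
* **Negatives** — patients never carrying the target, censored at a
  seeded random visit boundary with at least one window of recorded
  follow-up afterwards.  The protocol under evaluation does not define a
  negative arm beyond "not diagnosed", so this construction guarantees
  label correctness and reproducibility.
* **Windows** — 3 months = 91 days, 6 months = 182 days, consistent with
  the time-token boundaries.

The model then extends the censored prefix greedily.  At every
event-forecast step — a step whose greedy token is a clinical event —
the top-N candidate set is checked for the target.  Steps that emit
structural tokens (time token, visit type, SEP) are not candidate
checks: there the model is predicting sequence structure, and the tail
ordering of the distribution over clinical codes merely mirrors their
marginal frequency, so including those steps lets any common target
enter small candidate sets for every patient and erases the
positive/negative contrast (verified empirically on diagnostic
rollouts; the target can genuinely be forecast only where an event is
being emitted).  Elapsed time is accumulated from *generated* time
tokens at their range midpoints (t0→45, t1→137, t2→274, t3→548 days),
the only temporal signal the token stream carries, and the rollout
stops once elapsed time exceeds the window, 10 future visits have been
generated, or a visit stalls past 64 tokens.  A patient is
predicted-positive at N if the target entered the top-N set at any
in-window event step.  Because candidate sets are nested, one greedy
pass per patient serves all N (the hit is recorded at the smallest
containing N), and TP@N / FP@N are non-decreasing in N by construction.
TP/FN percentages are over the positive arm, FP/TN over the negative
arm.  A vectorized lock-step implementation of the rollout produces
identical per-patient results to the scalar reference (tested) and is
what the cohort evaluation uses.

## Frozen-backbone probe

Embeddings are the mean over sequence positions of the final-layer
(post-LayerNorm) hidden states; the backbone is never updated, which the
tests assert byte-for-byte on the serialized weights.  A single linear
head with input dropout (default 0.1) is trained with Adam at learning
rate 1e-4 and class-balanced weighted sampling, early-stopped on
held-out log-loss.  Sensitivity is reported as TP% at a matched FP%:
the threshold sweep picks the smallest threshold whose FP% does not
exceed the requested target (predictions are `score > threshold`), which
is conservative — it never overstates sensitivity at the stated
specificity — and equals exhaustive enumeration over all distinct-score
thresholds (tested).

## Interpretability

In a decoder-only model the "attention to the target" is read from
causal self-attention: when the model's top-1 forecast at a step equals
the target, the final-layer, head-averaged attention row of the
predicting position is taken over all prior positions; the top-15
inputs (ties toward earlier positions) are collected per patient, each
code counted once per patient, and the 10 most frequent codes reported
with max-normalized frequencies (ties at the cutoff are all included and
flagged).  Structural and demographic tokens are eligible and reported
like any other input.  For embedding geometry, the input-embedding table
(context-free, one vector per code) is exported per diagnosis code with
its ICD chapter label among the 14 tracked chapter ranges; 2-D
projection is delegated to an external UMAP implementation via the CLI
rather than re-implemented.

## Synthetic cohorts and what they do (not) show

The generator emulates the *shape* of a multi-visit EHR corpus:
demographics, four event domains, per-visit Bernoulli code emission,
log-normal lab values (skewed positive, which stresses the decile
discretization), gap mixtures spanning all four time-token ranges, and
visit counts 1 + Poisson.  Patient-level heterogeneity is modelled by
per-code carrier fractions: a code with carrier fraction f is emitted
only by a fraction f of patients (its chronic prevalence), at the
per-visit background rate within carriers.

Injected precursor→target rules carry the known conditional structure:
among patients emitting the precursor, the rule fires once with the
configured probability and plants the target 10–80 days (configurable)
after the *last* precursor occurrence — anchoring late so that earlier
recurrences of a chronic precursor remain in the censored history, as
chronic conditions do in real records.  The realized conditional
frequency is reported per rule and converges to the configured
probability (±3 binomial SE, tested at n = 2000).

The reference study conditions (`zero_shot_study_config`) are 2 000
patients, a chronic precursor with prevalence 0.5 re-billed in ~60% of a
carrier's visits, and a target that occurs only through the rule
(probability 0.8).  Because the target has no background rate, the
negative arm is label-perfect; its lower bound on FP is set by carriers
in whom the rule did not fire (~17% of negatives), which look identical
to positives at censor time.

What passing these tests shows: the pipeline is internally consistent
(grammar invertible, metrics equal independent oracles) and the
model+protocol can recover a planted temporal dependency from censored
histories.  What they do not show: performance on real EHR data, whose
code correlations, visit dynamics, noise and label ambiguity are far
richer than per-visit Bernoulli emissions; the synthetic forecasting
precision/recall numbers characterize the generator, not any clinical
corpus.

## Numerical and scale choices

* Problem sizes: acceptance-style runs use 2 000 patients / ~150 tokens
  of vocabulary / a 2-layer model, which completes the whole pipeline in
  a few minutes on one CPU core; examples use 300–600 patients.
* The reference study trains with dropout 0.1 for ~20 epochs: without
  regularization, whether the model learns that the *absence* of the
  chronic precursor in a history suppresses its emission is unstable
  across training seeds, and a model that misses it hallucinates the
  precursor during greedy rollouts and then conditions on its own
  hallucination, inflating the false-positive arm.
* Degenerate inputs: empty records, single-class labels, empty cohort
  arms, unknown codes and malformed token streams raise typed errors;
  unknown events during tokenization are dropped with a logged count.
* Distribution sums, attention rows and probability checks use 1e-5
  tolerances (float32 compute).
* Tie-breaks are everywhere deterministic: lowest token id in decoding,
  earliest position in attention, lexicographic order in vocabularies.
* Calibration checks report the model's *expected* per-token loss under
  the known branch law (e.g. −(0.9·ln p_B + 0.1·ln p_X) on a
  Bernoulli(0.9) grammar) rather than the empirical NLL over sampled
  branches: the expectation estimates the same converged quantity
  without the branch-sampling noise, which at a few hundred evaluation
  positions would dominate the comparison against the closed-form
  entropy (0.325 nats).
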