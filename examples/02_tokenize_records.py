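"""Turn patient records into the visit-grammar token stream.

Shows the vocabulary pipeline (3-character diagnosis grouping, <0.1%
rare-code filter, per-lab eCDF deciles) and the linearized sequence of
one patient: demographics prefix, per-visit blocks opened by a relative
time token (t0..t3) and closed by the separator.
"""

from ehrgpt import build_sequence, build_vocabulary, decode_sequence, generate_cohort
from ehrgpt.synthetic import zero_shot_study_config

records, _ = generate_cohort(zero_shot_study_config(n_patients=300, seed=0))
vocab = build_vocabulary(records)

n_lab = sum(1 for t in vocab.id_to_token if t.startswith("LAB:"))
print(f"vocabulary: {len(vocab)} tokens "
      f"({len(vocab.diagnosis_tokens())} diagnosis, {n_lab} lab-decile)")
code = next(iter(vocab.lab_deciles))
print(f"lab {code} decile boundaries: "
      + ", ".join(f"{b:.2f}" for b in vocab.lab_deciles[code]))

rec = max(records, key=lambda r: len(r.visits))
seq = build_sequence(rec, vocab)
toks = [vocab.decode(i) for i in seq.token_ids]
print(f"\nperson {rec.person_id}: {len(rec.visits)} visits -> "
      f"{len(seq)} tokens (truncated: {seq.truncated})")
print("first 25 tokens:", " ".join(toks[:25]))

visits = decode_sequence(seq, vocab)
print(f"decoded back into {len(visits)} visit blocks; "
      f"first gap token of visit 2: {visits[1].time_token}")
# Every visit after the first opens with t0 (gap ≤3 mo), t1 (3-6 mo),
# t2 (6-12 mo) or t3 (>1 y); decode inverts the grammar exactly.
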