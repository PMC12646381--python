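"""Attention-based attribution and code-embedding export.

When the model forecasts a target diagnosis as its top-1 choice at some
step, the final-layer, head-averaged self-attention row of that
predicting position says which history tokens it leaned on.  Aggregating
the per-patient top-k attended codes across a cohort gives a
max-normalized frequency profile of the inputs that drive a given
diagnostic forecast.  Separately, the model's input-embedding table can
be exported per diagnosis code with its ICD chapter label for external
2-D projection (e.g. UMAP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vocab import Vocabulary

#: the 14 higher-level ICD-10 chapter ranges used for category-level tasks
CHAPTER_RANGES: tuple[tuple[str, str], ...] = (
    ("A00", "B99"), ("C00", "D49"), ("D50", "D89"), ("E00", "E89"),
    ("F01", "F99"), ("G00", "G99"), ("H00", "H59"), ("H60", "H95"),
    ("I00", "I99"), ("J00", "J99"), ("K00", "K95"), ("L00", "L99"),
    ("M00", "M99"), ("N00", "N99"),
)


def code_chapter(code: str) -> str | None:
    """ICD chapter label ("C00-D49") for a 3-character code stem, if any."""
    for lo, hi in CHAPTER_RANGES:
        if lo <= code <= hi:
            return f"{lo}-{hi}"
    return None


@dataclass
class AttendedToken:
    position: int
    token: str
    weight: float


def attended_tokens(model, prefix: list[int], step_index: int,
                    target_id: int, vocab: Vocabulary,
                    k: int = 15) -> list[AttendedToken]:
    """Top-k attended input positions for a target forecast at one step.

    ``step_index`` is the predicting position: the model's top-1 forecast
    given ``prefix[:step_index+1]`` must equal ``target_id`` (precondition
    checked).  Attention is the final layer averaged over heads; ties
    break toward earlier positions.  Structural and demographics tokens
    are eligible and reported like any other input.
    """
    if not 0 <= step_index < len(prefix):
        raise ValueError("step_index out of range")
    probs = model.next_token_distribution(list(prefix[:step_index + 1]))
    if int(np.argmax(probs)) != target_id:
        raise ValueError(
            f"top-1 forecast at step {step_index} is not the target code")
    att = model.final_attention(list(prefix[:step_index + 1]))
    row = att[step_index, :step_index + 1]
    order = sorted(range(len(row)), key=lambda i: (-row[i], i))[:k]
    return [AttendedToken(i, vocab.decode(prefix[i]), float(row[i])) for i in order]


@dataclass
class AttentionSummary:
    """Cohort-level profile of the most attended input codes."""

    target: str
    codes: list[str]
    counts: dict[str, int]
    normalized: dict[str, float]
    tie_at_cutoff: bool
    n_patients: int


def aggregate_attention(per_patient: list[list[AttendedToken]], target: str,
                        top: int = 10) -> AttentionSummary:
    """Count each code once per patient it is attended for; max-normalize.

    Returns the ``top`` most frequent codes; ties at the cutoff rank are
    all included and flagged.
    """
    if not per_patient:
        raise ValueError("no contributing patients")
    counts: dict[str, int] = {}
    for toks in per_patient:
        for code in {t.token for t in toks}:
            counts[code] = counts.get(code, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    tie = False
    if len(ranked) > top:
        cutoff = ranked[top - 1][1]
        keep = [kv for kv in ranked if kv[1] > cutoff]
        tied = [kv for kv in ranked if kv[1] == cutoff]
        if len(keep) + len(tied) > top:
            tie = True
        ranked = keep + tied
    mx = ranked[0][1]
    return AttentionSummary(
        target=target,
        codes=[c for c, _ in ranked],
        counts=dict(ranked),
        normalized={c: n / mx for c, n in ranked},
        tie_at_cutoff=tie,
        n_patients=len(per_patient),
    )


def collect_attention_summary(model, cohort_prefixes: list[list[int]],
                              target_id: int, vocab: Vocabulary,
                              k: int = 15, top: int = 10,
                              max_steps: int = 200) -> AttentionSummary | None:
    """Scan greedy rollouts of a cohort for top-1 target forecasts.

    For each patient, the prefix is extended greedily; whenever the top-1
    forecast equals the target, the attended tokens at that step are
    collected (first such step per patient).  Returns None when no
    patient ever forecasts the target top-1.
    """
    per_patient: list[list[AttendedToken]] = []
    for prefix in cohort_prefixes:
        cur = list(prefix)
        for _ in range(max_steps):
            probs = model.next_token_distribution(cur)
            tok = int(np.argmax(probs))
            if tok == target_id:
                per_patient.append(
                    attended_tokens(model, cur, len(cur) - 1, target_id, vocab, k=k))
                break
            cur.append(tok)
            if len(cur) >= model.config.context_window:
                break
    if not per_patient:
        return None
    return aggregate_attention(per_patient, vocab.decode(target_id), top=top)


def export_code_embeddings(model, vocab: Vocabulary,
                           chapters: tuple[tuple[str, str], ...] | None = None
                           ) -> pd.DataFrame:
    """Input-embedding matrix for diagnosis codes with chapter labels.

    One row per retained diagnosis code whose stem falls in one of the
    requested chapter ranges (default: all 14); columns are ``code``,
    ``chapter`` and the embedding dimensions.  Deterministic for a fixed
    checkpoint.
    """
    chapters = chapters or CHAPTER_RANGES
    rows = []
    for tok in vocab.diagnosis_tokens():
        code = tok[3:]
        label = None
        for lo, hi in chapters:
            if lo <= code <= hi:
                label = f"{lo}-{hi}"
                break
        if label is None:
            continue
        emb = model.input_embedding(vocab.encode(tok))
        rows.append({"code": code, "chapter": label,
                     **{f"e{i}": float(x) for i, x in enumerate(emb)}})
    if not rows:
        raise ValueError("no diagnosis codes fall in the requested chapters")
    return pd.DataFrame(rows)
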