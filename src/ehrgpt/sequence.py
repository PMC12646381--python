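"""Linearize patient records into the visit-grammar token stream.

A record becomes ``[SEX, AGE, V1…, SEP, t_k, V2…, SEP, …]``: a
demographics prefix, then one block per visit terminated by the
separator.  Every visit except the first opens with a relative time
token (t0: gap ≤ 3 months, t1: 3–6 months, t2: 6–12 months, t3: > 1
year), followed by the visit-type token, the events in canonical order
(timestamp, then domain, then code), and an optional discharge-type
token.  Sequences longer than the context window are truncated by
dropping whole oldest visits; the demographics prefix is always kept and
the earliest retained visit is re-rendered without a time token.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import pathlib
from dataclasses import dataclass, field

from .records import DOMAINS, PatientRecord, Visit
from .vocab import (
    SEP,
    TIME_TOKENS,
    UnknownTokenError,
    Vocabulary,
    age_bucket_token,
    sex_token,
)

log = logging.getLogger(__name__)

_T_BOUNDS = (91, 182, 365)  # day boundaries between t0/t1/t2/t3


class EmptySequenceError(ValueError):
    """Record has no events mappable to the vocabulary."""


class StructuralError(ValueError):
    """Token stream violates the visit grammar."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def assign_time_token(gap_days: int) -> str:
    """Map an inter-visit gap (days) to its time token.

    Partitions [0, ∞): t0 ≤ 91 < t1 ≤ 182 < t2 ≤ 365 < t3.
    """
    if gap_days < 0:
        raise ValueError(f"gap_days must be non-negative, got {gap_days}")
    for tok, bound in zip(TIME_TOKENS, _T_BOUNDS):
        if gap_days <= bound:
            return tok
    return TIME_TOKENS[3]


@dataclass
class TokenSequence:
    """A linearized record with per-token visit provenance.

    ``visit_index`` is −1 for the demographics prefix and the 0-based
    ordinal of the (retained) visit for every other token, including its
    terminating SEP.
    """

    person_id: int
    token_ids: list[int]
    visit_index: list[int]
    visit_dates: list[dt.date]
    n_dropped_events: int = 0
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def n_visits(self) -> int:
        return len(self.visit_dates)

    def prefix_through_visit(self, k: int) -> list[int]:
        """Token ids of demographics + visits 0..k inclusive (ends after SEP)."""
        return [t for t, vi in zip(self.token_ids, self.visit_index) if vi <= k]

    def visit_token_ids(self, k: int, *, include_sep: bool = False) -> list[int]:
        ids = [t for t, vi in zip(self.token_ids, self.visit_index) if vi == k]
        return ids if include_sep else ids[:-1]


@dataclass
class VisitStruct:
    """Decoded structure of one visit block."""

    time_token: str | None
    visit_type: str | None
    event_tokens: list[str] = field(default_factory=list)
    discharge: str | None = None


def _visit_event_tokens(visit: Visit, vocab: Vocabulary) -> tuple[list[str], int]:
    """Event tokens of one visit in canonical order; returns (tokens, dropped)."""
    keyed = []
    dropped = 0
    for e in visit.events:
        try:
            tok = vocab.event_token(e.domain, e.code, e.value)
        except (UnknownTokenError, ValueError):
            dropped += 1
            continue
        if tok not in vocab:
            dropped += 1
            continue
        keyed.append(((e.date, DOMAINS.index(e.domain), e.code), tok))
    keyed.sort(key=lambda kv: kv[0])
    return [tok for _, tok in keyed], dropped


def _render(record: PatientRecord, visits: list[Visit], vocab: Vocabulary,
            event_cache: dict[int, list[str]]) -> tuple[list[str], list[int]]:
    tokens = [sex_token(record.sex),
              age_bucket_token(record.age_at_first_visit(), vocab.age_bucket_width)]
    vidx = [-1, -1]
    prev_date: dt.date | None = None
    for i, v in enumerate(visits):
        block: list[str] = []
        if prev_date is not None:
            block.append(assign_time_token((v.date - prev_date).days))
        block.append(f"VT:{v.visit_type}")
        block.extend(event_cache[id(v)])
        if v.discharge:
            block.append(f"DT:{v.discharge}")
        block.append(SEP)
        tokens.extend(block)
        vidx.extend([i] * len(block))
        prev_date = v.date
    return tokens, vidx


def build_sequence(record: PatientRecord, vocab: Vocabulary,
                   max_len: int = 512) -> TokenSequence:
    """Linearize a record, truncating oldest visits to fit ``max_len``.

    Events whose codes are absent from the vocabulary are dropped with a
    logged count; a record with zero mappable events raises
    :class:`EmptySequenceError`.
    """
    if not record.visits:
        raise ValueError(f"person {record.person_id}: record has no visits")
    cache: dict[int, list[str]] = {}
    dropped = 0
    n_events = 0
    for v in record.visits:
        toks, d = _visit_event_tokens(v, vocab)
        cache[id(v)] = toks
        dropped += d
        n_events += len(toks)
    if dropped:
        log.info("person %d: dropped %d events not in vocabulary",
                 record.person_id, dropped)
    if n_events == 0:
        raise EmptySequenceError(
            f"person {record.person_id}: no events mappable to vocabulary")

    start = 0
    visits = record.visits
    tokens, vidx = _render(record, visits, vocab, cache)
    while len(tokens) > max_len and start < len(record.visits) - 1:
        start += 1
        visits = record.visits[start:]
        tokens, vidx = _render(record, visits, vocab, cache)
    if len(tokens) > max_len:
        raise ValueError(
            f"person {record.person_id}: single visit exceeds max_len={max_len}")
    return TokenSequence(
        person_id=record.person_id,
        token_ids=[vocab.encode(t) for t in tokens],
        visit_index=vidx,
        visit_dates=[v.date for v in visits],
        n_dropped_events=dropped,
        truncated=start > 0,
    )


def decode_sequence(tokens: TokenSequence | list[int],
                    vocab: Vocabulary) -> list[VisitStruct]:
    """Parse a token stream back into visit structures.

    Splits on SEP after skipping the demographics prefix; a time token
    anywhere but the head of a non-initial visit block is a
    :class:`StructuralError` reported at its index.
    """
    ids = tokens.token_ids if isinstance(tokens, TokenSequence) else list(tokens)
    toks = [vocab.decode(i) for i in ids]

    pos = 0
    while pos < len(toks) and (toks[pos].startswith("SEX:") or toks[pos].startswith("AGE:")):
        pos += 1

    visits: list[VisitStruct] = []
    block_start = pos
    current = VisitStruct(time_token=None, visit_type=None)
    i = pos
    for i in range(pos, len(toks)):
        t = toks[i]
        if t == SEP:
            visits.append(current)
            current = VisitStruct(time_token=None, visit_type=None)
            block_start = i + 1
            continue
        if t in TIME_TOKENS:
            if i != block_start or not visits:
                raise StructuralError(f"unexpected time token {t!r}", i)
            current.time_token = t
        elif t.startswith("VT:"):
            if current.visit_type is not None:
                raise StructuralError("duplicate visit-type token", i)
            current.visit_type = t[3:]
        elif t.startswith("DT:"):
            current.discharge = t[3:]
        elif t.startswith(("SEX:", "AGE:")):
            raise StructuralError(f"demographics token {t!r} inside a visit", i)
        else:
            current.event_tokens.append(t)
    if current.visit_type is not None or current.event_tokens or current.time_token:
        visits.append(current)  # unterminated trailing block
    return visits


# ---------------------------------------------------------------------------
# Tokenized corpus I/O


def save_corpus(sequences: list[TokenSequence], path: str | pathlib.Path) -> None:
    """One record per line: ``person_id<TAB>space-separated token ids``.

    A companion ``<path>.index.json`` stores per-sequence visit dates and
    per-token visit ordinals.
    """
    path = pathlib.Path(path)
    with path.open("w") as fh:
        for s in sequences:
            fh.write(f"{s.person_id}\t{' '.join(map(str, s.token_ids))}\n")
    index = [
        {
            "person_id": s.person_id,
            "visit_index": s.visit_index,
            "visit_dates": [d.isoformat() for d in s.visit_dates],
            "truncated": s.truncated,
        }
        for s in sequences
    ]
    path.with_suffix(path.suffix + ".index.json").write_text(json.dumps(index))


def load_corpus(path: str | pathlib.Path) -> list[TokenSequence]:
    path = pathlib.Path(path)
    index_path = path.with_suffix(path.suffix + ".index.json")
    index = json.loads(index_path.read_text()) if index_path.exists() else None
    out: list[TokenSequence] = []
    for lineno, ln in enumerate(path.read_text().splitlines()):
        pid_s, ids_s = ln.split("\t", 1)
        ids = [int(x) for x in ids_s.split()]
        meta = index[lineno] if index else None
        out.append(
            TokenSequence(
                person_id=int(pid_s),
                token_ids=ids,
                visit_index=meta["visit_index"] if meta else [0] * len(ids),
                visit_dates=[dt.date.fromisoformat(d) for d in meta["visit_dates"]]
                if meta else [],
                truncated=meta["truncated"] if meta else False,
            )
        )
    return out
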