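"""Evaluation protocols: visit-level forecasting and censored-window zero-shot.

Two ways of scoring the pretrained model without task-specific training:

* **Visit-level forecasting** — for each patient, visits 1..k are fed in
  and visit k+1 is greedy-decoded; the generated and true token sets are
  compared (precision = |∩|/|generated|, recall = |∩|/|truth|), with only
  the separator excluded from either set, and micro-averaged over all
  compared visits.

* **Censored-window diagnostics** — for a target diagnosis code (or an
  ICD chapter range), positive patients are censored 3 or 6 months
  before their first target occurrence and negatives (never-diagnosed,
  with enough follow-up) at a seeded random visit boundary.  The model
  then rolls out greedily from the censored history; the patient counts
  as predicted-positive at candidate-set size N if the target enters the
  top-N next-token candidates at any decoding step while the simulated
  elapsed time — accumulated from generated time tokens at their range
  midpoints (45/137/274/548 days) — is still inside the window.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np

from .records import PatientRecord
from .sequence import TokenSequence, build_sequence
from .vocab import TIME_TOKENS, Vocabulary

log = logging.getLogger(__name__)

WINDOW_DAYS = {3: 91, 6: 182}
#: midpoint day-count contributed by each generated time token
TIME_TOKEN_MIDPOINT_DAYS = {"t0": 45, "t1": 137, "t2": 274, "t3": 548}

DEFAULT_NS = (1, 5, 10, 20)


# ---------------------------------------------------------------------------
# Visit-level forecasting


@dataclass
class ForecastScores:
    precision: float
    recall: float
    n_visits_compared: int
    per_visit: list[tuple[float, float]] = field(default_factory=list)
    n_skipped_single_visit: int = 0


def _score_sets(generated: set[int], truth: set[int]) -> tuple[float, float]:
    inter = len(generated & truth)
    precision = inter / len(generated) if generated else 0.0
    recall = inter / len(truth) if truth else 0.0
    return precision, recall


def visit_level_forecast_eval(model, sequences: list[TokenSequence],
                              max_visit_tokens: int = 64) -> ForecastScores:
    """Stepwise generate-next-visit evaluation, micro-averaged.

    For every sequence with ≥2 visits and every k, the model greedy-
    decodes visit k+1 from the demographics prefix plus visits 1..k; the
    separator is excluded from both the generated and true token sets.
    Single-visit sequences are skipped with a logged count.
    """
    tp = n_gen = n_truth = 0
    per_visit: list[tuple[float, float]] = []
    skipped = 0
    for seq in sequences:
        if seq.n_visits < 2:
            skipped += 1
            continue
        for k in range(seq.n_visits - 1):
            prefix = seq.prefix_through_visit(k)
            gen, _ = model.generate_visit(prefix, max_visit_tokens=max_visit_tokens)
            g = set(gen) - {model.sep_id}
            t = set(seq.visit_token_ids(k + 1)) - {model.sep_id}
            per_visit.append(_score_sets(g, t))
            tp += len(g & t)
            n_gen += len(g)
            n_truth += len(t)
    if skipped:
        log.info("forecast eval: skipped %d single-visit sequences", skipped)
    return ForecastScores(
        precision=tp / n_gen if n_gen else 0.0,
        recall=tp / n_truth if n_truth else 0.0,
        n_visits_compared=len(per_visit),
        per_visit=per_visit,
        n_skipped_single_visit=skipped,
    )


# ---------------------------------------------------------------------------
# Censored-window cohorts


class EmptyCohortError(ValueError):
    pass


@dataclass
class CohortMember:
    person_id: int
    censor_date: dt.date
    prefix_ids: list[int]


@dataclass
class CohortSpec:
    """Positive/negative arms for one target, one prediction window."""

    target_tokens: tuple[str, ...]
    target_ids: tuple[int, ...]
    window_months: int
    positives: list[CohortMember]
    negatives: list[CohortMember]


def expand_target(target: str | tuple[str, str], vocab: Vocabulary) -> list[str]:
    """Target spec → diagnosis tokens: a single code or an (lo, hi) range."""
    if isinstance(target, str):
        tok = f"DX:{target}"
        return [tok] if tok in vocab else []
    lo, hi = target
    return [t for t in vocab.diagnosis_tokens() if lo <= t[3:] <= hi]


def _censored_record(record: PatientRecord, n_visits: int) -> PatientRecord:
    return PatientRecord(person_id=record.person_id, sex=record.sex,
                         birth_year=record.birth_year,
                         visits=record.visits[:n_visits])


def build_diagnostic_cohort(records: list[PatientRecord], vocab: Vocabulary,
                            target: str | tuple[str, str], window_months: int,
                            min_history_visits: int = 1, seed: int = 0,
                            max_len: int = 512) -> CohortSpec:
    """Assemble the censored positive/negative arms for one target.

    Positives: first target occurrence exists and ≥ ``min_history_visits``
    visits fall strictly before (first target date − window); input is the
    history censored there, verified target-free.  Negatives: patients
    never carrying the target, censored at a seeded random visit boundary
    that leaves ≥ one window of recorded follow-up.
    """
    if window_months not in WINDOW_DAYS:
        raise ValueError(f"window_months must be one of {sorted(WINDOW_DAYS)}")
    target_tokens = expand_target(target, vocab)
    if not target_tokens:
        raise EmptyCohortError(f"target {target!r} has no tokens in vocabulary")
    target_ids = tuple(vocab.encode(t) for t in target_tokens)
    tset = set(target_tokens)
    window = dt.timedelta(days=WINDOW_DAYS[window_months])
    rng = np.random.default_rng(seed)

    def visit_has_target(visit) -> bool:
        for e in visit.events:
            try:
                if vocab.event_token(e.domain, e.code, e.value) in tset:
                    return True
            except Exception:
                continue
        return False

    positives: list[CohortMember] = []
    negatives: list[CohortMember] = []
    for rec in records:
        first = None
        for v in rec.visits:
            if visit_has_target(v):
                first = v.date
                break
        if first is not None:
            cutoff = first - window
            n_hist = sum(1 for v in rec.visits if v.date < cutoff)
            if n_hist < min_history_visits:
                continue
            cens = _censored_record(rec, n_hist)
            assert not any(visit_has_target(v) for v in cens.visits), \
                "positive input contains the target token"
            try:
                seq = build_sequence(cens, vocab, max_len=max_len)
            except Exception:
                continue
            positives.append(CohortMember(rec.person_id, cutoff, seq.token_ids))
        else:
            last = rec.visits[-1].date
            eligible = [
                i for i in range(min_history_visits, len(rec.visits))
                if last - rec.visits[i - 1].date >= window
            ]
            if not eligible:
                continue
            i = int(rng.choice(eligible))
            cens = _censored_record(rec, i)
            try:
                seq = build_sequence(cens, vocab, max_len=max_len)
            except Exception:
                continue
            negatives.append(
                CohortMember(rec.person_id, rec.visits[i - 1].date, seq.token_ids))

    if not positives:
        raise EmptyCohortError(f"no eligible positives for target {target!r}")
    return CohortSpec(tuple(target_tokens), target_ids, window_months,
                      positives, negatives)


def check_censoring(cohort: CohortSpec, vocab: Vocabulary) -> None:
    """Assert no positive input carries the target; raises on violation."""
    tids = set(cohort.target_ids)
    for m in cohort.positives:
        if tids.intersection(m.prefix_ids):
            raise AssertionError(
                f"positive {m.person_id}: target token in censored input")


# ---------------------------------------------------------------------------
# Window-bounded greedy rollout


@dataclass
class WindowPrediction:
    hit: bool
    first_hit_step: int | None
    best_rank: int | None  # smallest N whose candidate set ever held the target
    n_steps: int
    elapsed_days: int


def _target_rank(probs: np.ndarray, target_ids: tuple[int, ...]) -> int:
    """1-based rank of the best target id under (prob desc, id asc) order."""
    best = None
    for t in target_ids:
        pt = probs[t]
        rank = 1 + int(np.sum(probs > pt)) + int(np.sum(probs[:t] == pt))
        if best is None or rank < best:
            best = rank
    return best


def rollout_best_rank(model, prefix: list[int], target_ids: tuple[int, ...],
                      window_months: int, vocab: Vocabulary,
                      max_future_visits: int = 10,
                      max_visit_tokens: int = 64) -> WindowPrediction:
    """Greedy rollout recording the best top-N rank of the target in-window.

    One pass serves every N because candidate sets are nested: the target
    is in the top-N set at some step iff its best in-window rank ≤ N.
    The rank is evaluated at event-forecast steps — steps whose greedy
    token is a clinical event — since only there is the model forecasting
    a medical concept; at structural steps (time token, visit type, SEP)
    the tail ordering of the distribution carries no conditioning signal.
    """
    window_days = WINDOW_DAYS[window_months]
    midpoints = {tid: TIME_TOKEN_MIDPOINT_DAYS[tok]
                 for tok, tid in zip(TIME_TOKENS, vocab.time_token_ids)}
    structural = vocab.structural_ids()
    cur = list(prefix)
    elapsed = 0
    visits = 0
    tokens_in_visit = 0
    best_rank: int | None = None
    first_hit_step: int | None = None
    step = 0
    max_steps = max_future_visits * max_visit_tokens
    while step < max_steps:
        probs = model.next_token_distribution(cur)
        tok = int(np.argmax(probs))
        if elapsed <= window_days and tok not in structural:
            rank = _target_rank(probs, target_ids)
            if best_rank is None or rank < best_rank:
                best_rank = rank
                first_hit_step = step
        cur.append(tok)
        step += 1
        if tok in midpoints:
            elapsed += midpoints[tok]
            if elapsed > window_days:
                break
        if tok == model.sep_id:
            visits += 1
            tokens_in_visit = 0
            if visits >= max_future_visits:
                break
        else:
            tokens_in_visit += 1
            if tokens_in_visit > max_visit_tokens:
                break  # stalled inside one visit
    return WindowPrediction(hit=False, first_hit_step=first_hit_step,
                            best_rank=best_rank, n_steps=step,
                            elapsed_days=elapsed)


def rollout_best_rank_batch(model, prefixes: list[list[int]],
                            target_ids: tuple[int, ...], window_months: int,
                            vocab: Vocabulary, max_future_visits: int = 10,
                            max_visit_tokens: int = 64,
                            chunk_size: int = 64) -> list[WindowPrediction]:
    """Vectorized counterpart of :func:`rollout_best_rank`.

    Runs many greedy rollouts in lock-step batches (right-padded; each
    row's distribution is read at its own last position, which causal
    masking leaves unaffected by the padding).  Produces exactly the same
    per-patient results as the scalar rollout.
    """
    from .transformer import softmax

    if not hasattr(model, "net"):  # scripted/test models: scalar path
        return [rollout_best_rank(model, p, target_ids, window_months, vocab,
                                  max_future_visits=max_future_visits,
                                  max_visit_tokens=max_visit_tokens)
                for p in prefixes]

    window_days = WINDOW_DAYS[window_months]
    midpoints = {tid: TIME_TOKEN_MIDPOINT_DAYS[tok]
                 for tok, tid in zip(TIME_TOKENS, vocab.time_token_ids)}
    structural = vocab.structural_ids()
    ctx = model.config.context_window
    max_steps = max_future_visits * max_visit_tokens
    results: list[WindowPrediction | None] = [None] * len(prefixes)

    order = sorted(range(len(prefixes)), key=lambda i: len(prefixes[i]))
    for c0 in range(0, len(order), chunk_size):
        rows = order[c0:c0 + chunk_size]
        bufs = [list(prefixes[i]) for i in rows]
        elapsed = [0] * len(rows)
        visits = [0] * len(rows)
        in_visit = [0] * len(rows)
        best_rank: list[int | None] = [None] * len(rows)
        first_hit: list[int | None] = [None] * len(rows)
        steps = [0] * len(rows)
        active = list(range(len(rows)))
        step = 0
        while active and step < max_steps:
            tails = [bufs[r][-ctx:] for r in active]
            T = max(len(t) for t in tails)
            X = np.full((len(active), T), model.pad_id, dtype=np.int64)
            for j, t in enumerate(tails):
                X[j, :len(t)] = t
            logits, _, _, _ = model.net.forward(X)
            still = []
            for j, r in enumerate(active):
                probs = softmax(logits[j, len(tails[j]) - 1])
                tok = int(np.argmax(probs))
                if elapsed[r] <= window_days and tok not in structural:
                    rank = _target_rank(probs, target_ids)
                    if best_rank[r] is None or rank < best_rank[r]:
                        best_rank[r] = rank
                        first_hit[r] = steps[r]
                bufs[r].append(tok)
                steps[r] += 1
                alive = True
                if tok in midpoints:
                    elapsed[r] += midpoints[tok]
                    if elapsed[r] > window_days:
                        alive = False
                if tok == model.sep_id:
                    visits[r] += 1
                    in_visit[r] = 0
                    if visits[r] >= max_future_visits:
                        alive = False
                else:
                    in_visit[r] += 1
                    if in_visit[r] > max_visit_tokens:
                        alive = False
                if alive:
                    still.append(r)
            active = still
            step += 1
        for r, i in enumerate(rows):
            results[i] = WindowPrediction(
                hit=False, first_hit_step=first_hit[r], best_rank=best_rank[r],
                n_steps=steps[r], elapsed_days=elapsed[r])
    return results  # type: ignore[return-value]


def predict_within_window(model, prefix: list[int],
                          target_ids: tuple[int, ...], n: int,
                          window_months: int, vocab: Vocabulary,
                          max_future_visits: int = 10) -> tuple[bool, int | None]:
    """Does the target enter the top-``n`` candidates inside the window?"""
    wp = rollout_best_rank(model, prefix, target_ids, window_months, vocab,
                           max_future_visits=max_future_visits)
    hit = wp.best_rank is not None and wp.best_rank <= n
    return hit, (wp.first_hit_step if hit else None)


# ---------------------------------------------------------------------------
# Confusion at N


@dataclass
class ConfusionAtN:
    """TP/FP/TN/FN percentages per candidate-set size N.

    TP/FN are percentages of the positive arm; FP/TN of the negative arm.
    """

    ns: tuple[int, ...]
    tp: dict[int, float]
    fp: dict[int, float]
    tn: dict[int, float]
    fn: dict[int, float]
    n_positives: int
    n_negatives: int
    positive_ranks: list[int | None] = field(default_factory=list)
    negative_ranks: list[int | None] = field(default_factory=list)
    positive_first_hit_steps: list[int | None] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "Ns": list(self.ns),
            "TP": {str(n): self.tp[n] for n in self.ns},
            "FP": {str(n): self.fp[n] for n in self.ns},
            "TN": {str(n): self.tn[n] for n in self.ns},
            "FN": {str(n): self.fn[n] for n in self.ns},
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
        }


def confusion_at_n(model, cohort: CohortSpec, vocab: Vocabulary,
                   ns: tuple[int, ...] = DEFAULT_NS,
                   max_future_visits: int = 10) -> ConfusionAtN:
    """Run the window-bounded rollout on both arms and tally confusion.

    A single generation pass per patient is reused across every N (the
    hit is recorded at the smallest N containing the target).
    """
    if not cohort.positives:
        raise EmptyCohortError("positive arm is empty")
    if not cohort.negatives:
        raise EmptyCohortError("negative arm is empty")

    def arm_ranks(members):
        wps = rollout_best_rank_batch(
            model, [m.prefix_ids for m in members], cohort.target_ids,
            cohort.window_months, vocab, max_future_visits=max_future_visits)
        return [w.best_rank for w in wps], [w.first_hit_step for w in wps]

    pos_ranks, pos_steps = arm_ranks(cohort.positives)
    neg_ranks, _ = arm_ranks(cohort.negatives)

    tp, fp, tn, fn = {}, {}, {}, {}
    for n in ns:
        p_hit = sum(1 for r in pos_ranks if r is not None and r <= n)
        n_hit = sum(1 for r in neg_ranks if r is not None and r <= n)
        tp[n] = 100.0 * p_hit / len(pos_ranks)
        fn[n] = 100.0 - tp[n]
        fp[n] = 100.0 * n_hit / len(neg_ranks)
        tn[n] = 100.0 - fp[n]
    return ConfusionAtN(tuple(ns), tp, fp, tn, fn,
                        len(pos_ranks), len(neg_ranks),
                        pos_ranks, neg_ranks, pos_steps)
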