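"""Evaluation protocols: forecast metrics, cohort censoring, window rollout."""

import datetime as dt

import numpy as np
import pytest

from ehrgpt import (
    EmptyCohortError,
    build_diagnostic_cohort,
    build_sequence,
    build_vocabulary,
    check_censoring,
    confusion_at_n,
    predict_within_window,
    visit_level_forecast_eval,
)
from ehrgpt.records import Event, PatientRecord, Visit
from ehrgpt.sequence import TokenSequence
from ehrgpt.zeroshot import (
    WINDOW_DAYS,
    expand_target,
    rollout_best_rank,
    rollout_best_rank_batch,
)

from conftest import ScriptedModel

SEP = 1


def _seq(person_id, visit_tokens):
    """TokenSequence from per-visit token id lists (SEP appended)."""
    ids, vidx = [], []
    for k, toks in enumerate(visit_tokens):
        ids.extend(toks + [SEP])
        vidx.extend([k] * (len(toks) + 1))
    d0 = dt.date(2020, 1, 1)
    return TokenSequence(person_id, ids, vidx,
                         [d0 + dt.timedelta(days=30 * k)
                          for k in range(len(visit_tokens))])


def _scripted(generated_by_prefix, vocab_size=20):
    table = {}
    for prefix, gen in generated_by_prefix.items():
        cur = list(prefix)
        for tok in list(gen) + [SEP]:
            p = np.zeros(vocab_size)
            p[tok] = 1.0
            table[tuple(cur)] = p
            cur.append(tok)
    return ScriptedModel(vocab_size, SEP, table=table)


def test_forecast_precision_recall_set_arithmetic():
    truth = _seq(1, [[10, 11], [12, 13, 14]])  # generated {10,11,15} vs {12,13,14}
    model = _scripted({(10, 11, SEP): [12, 13, 15]})
    scores = visit_level_forecast_eval(model, [truth])
    assert scores.n_visits_compared == 1
    assert scores.precision == pytest.approx(2 / 3)
    assert scores.recall == pytest.approx(2 / 3)


def test_forecast_perfect_prediction():
    truth = _seq(1, [[10], [12, 13]])
    model = _scripted({(10, SEP): [12, 13]})
    scores = visit_level_forecast_eval(model, [truth])
    assert scores.precision == 1.0 and scores.recall == 1.0


def test_forecast_empty_generation_convention():
    truth = _seq(1, [[10], [12]])
    model = _scripted({(10, SEP): []})  # immediately emits SEP
    scores = visit_level_forecast_eval(model, [truth])
    assert scores.precision == 0.0 and scores.recall == 0.0


def test_forecast_skips_single_visit_sequences():
    model = _scripted({})
    scores = visit_level_forecast_eval(model, [_seq(1, [[10]])])
    assert scores.n_visits_compared == 0
    assert scores.n_skipped_single_visit == 1


def test_forecast_matches_bruteforce_on_randomized_pairs():
    rng = np.random.default_rng(11)
    total_tp = total_gen = total_truth = 0
    seqs, model_table = [], {}
    for pid in range(20):
        v1 = sorted(set(rng.integers(5, 20, size=3).tolist()))
        v2 = sorted(set(rng.integers(5, 20, size=4).tolist()))
        gen = sorted(set(rng.integers(5, 20, size=rng.integers(0, 5)).tolist()))
        seqs.append(_seq(pid, [v1, v2]))
        model_table[tuple(v1 + [SEP])] = gen
        total_tp += len(set(gen) & set(v2))
        total_gen += len(gen)
        total_truth += len(v2)
    model = _scripted(model_table)
    scores = visit_level_forecast_eval(model, seqs)
    assert scores.precision == pytest.approx(total_tp / total_gen)
    assert scores.recall == pytest.approx(total_tp / total_truth)


# ---------------------------------------------------------------------------
# Cohort construction


def _target_record(pid, target_day, n_before, spacing=30, follow_up=0):
    d0 = dt.date(2020, 1, 1)
    visits = []
    for i in range(n_before):
        day = target_day - spacing * (n_before - i)
        visits.append(Visit(i + 1, d0 + dt.timedelta(days=day),
                            events=[Event("diagnosis", "D01",
                                          d0 + dt.timedelta(days=day))]))
    visits.append(Visit(99, d0 + dt.timedelta(days=target_day),
                        events=[Event("diagnosis", "I50",
                                      d0 + dt.timedelta(days=target_day))]))
    for j in range(follow_up):
        day = target_day + spacing * (j + 1)
        visits.append(Visit(200 + j, d0 + dt.timedelta(days=day),
                            events=[Event("diagnosis", "D01",
                                          d0 + dt.timedelta(days=day))]))
    return PatientRecord(pid, "F", 1980, visits)


@pytest.fixture(scope="module")
def cohort_vocab():
    records = [_target_record(pid, 300, 8) for pid in range(1, 4)]
    return build_vocabulary(records)


def test_positive_censored_one_window_before_target(cohort_vocab):
    # target at day 300, window 3 months → cutoff day 209; visits ≥ that excluded
    rec = _target_record(1, 300, n_before=8, spacing=30)
    cohort = build_diagnostic_cohort([rec], cohort_vocab, "I50", 3)
    assert len(cohort.positives) == 1
    m = cohort.positives[0]
    assert m.censor_date == dt.date(2020, 1, 1) + dt.timedelta(days=300 - 91)
    target_id = cohort_vocab.encode("DX:I50")
    assert target_id not in m.prefix_ids
    # visits at days 270/240/210 fall inside the window and are excluded:
    # 8 pre-target visits at 60..270 → only 60..180 (5 visits) remain
    assert sum(1 for t in m.prefix_ids if t == cohort_vocab.sep_id) == 5


def test_patient_with_history_only_inside_window_is_ineligible(cohort_vocab):
    rec = _target_record(1, 300, n_before=2, spacing=30)  # visits at 240, 270
    with pytest.raises(EmptyCohortError):
        build_diagnostic_cohort([rec], cohort_vocab, "I50", 3)


def test_negative_requires_follow_up_after_censor(cohort_vocab):
    d0 = dt.date(2020, 1, 1)
    mk = lambda pid, days: PatientRecord(pid, "M", 1970, [
        Visit(i + 1, d0 + dt.timedelta(days=d),
              events=[Event("diagnosis", "D01", d0 + dt.timedelta(days=d))])
        for i, d in enumerate(days)])
    pos = _target_record(1, 300, n_before=8)
    long_neg = mk(2, [0, 30, 60, 500])      # ≥91 d follow-up exists
    short_neg = mk(3, [0, 30, 60])          # nothing ≥91 d after any boundary
    cohort = build_diagnostic_cohort([pos, long_neg, short_neg],
                                     cohort_vocab, "I50", 3, seed=0)
    assert [m.person_id for m in cohort.negatives] == [2]
    check_censoring(cohort, cohort_vocab)


def test_chapter_range_targets_expand_to_member_tokens(cohort_vocab):
    toks = expand_target(("I00", "I99"), cohort_vocab)
    assert toks == ["DX:I50"]
    assert expand_target(("A00", "B99"), cohort_vocab) == []


# ---------------------------------------------------------------------------
# Window-bounded rollout


def _uniformish(vocab_size, favorite, p=0.9):
    probs = np.full(vocab_size, (1 - p) / (vocab_size - 1))
    probs[favorite] = p
    return probs


def _window_vocab():
    """A vocabulary whose time-token ids are needed by the rollout."""
    records = [_target_record(pid, 300, 8) for pid in range(1, 4)]
    return build_vocabulary(records)


def test_target_as_immediate_argmax_is_positive_at_n1(cohort_vocab):
    v = cohort_vocab
    target = v.encode("DX:I50")
    model = ScriptedModel(len(v), v.sep_id,
                          default=_uniformish(len(v), target))
    hit, step = predict_within_window(model, [10, 11], (target,), 1, 3, v)
    assert hit and step == 0


def test_n_equal_vocab_size_is_always_positive(cohort_vocab):
    v = cohort_vocab
    target = v.encode("DX:I50")
    other = v.encode("DX:D01")
    model = ScriptedModel(len(v), v.sep_id, default=_uniformish(len(v), other))
    hit, step = predict_within_window(model, [10, 11], (target,), len(v), 3, v)
    assert hit and step == 0


def test_immediate_t3_exceeds_window_and_is_negative(cohort_vocab):
    v = cohort_vocab
    target = v.encode("DX:I50")
    t3 = v.encode("t3")
    model = ScriptedModel(len(v), v.sep_id, default=_uniformish(len(v), t3, p=0.99))
    hit, _ = predict_within_window(model, [10, 11], (target,), 1, 3, v)
    assert not hit
    wp = rollout_best_rank(model, [10, 11], (target,), 3, v)
    assert wp.elapsed_days == 548 and wp.n_steps == 1


def test_batch_rollout_matches_scalar_on_trained_model(tiny_model, small_vocab,
                                                       small_sequences):
    # compare at float64 so the two execution orders cannot straddle a tie
    from ehrgpt.model import TrainedModel
    from ehrgpt.transformer import TransformerLM

    m32, _ = tiny_model
    cfg = m32.config
    net = TransformerLM(cfg.vocab_size, cfg.context_window, cfg.n_layers,
                        cfg.n_heads, cfg.hidden_dim, dtype=np.float64)
    net.params = {k: v.astype(np.float64) for k, v in m32.net.params.items()}
    model = TrainedModel(net, cfg, m32.vocab_hash, m32.pad_id, m32.sep_id)
    target = (small_vocab.encode("DX:D11"),)
    prefixes = [s.prefix_through_visit(0) for s in small_sequences[:25]]
    scalar = [rollout_best_rank(model, p, target, 3, small_vocab)
              for p in prefixes]
    batch = rollout_best_rank_batch(model, prefixes, target, 3, small_vocab)
    for s, b in zip(scalar, batch):
        assert (s.best_rank, s.first_hit_step, s.n_steps, s.elapsed_days) == \
               (b.best_rank, b.first_hit_step, b.n_steps, b.elapsed_days)


def test_confusion_counts_and_monotonicity(small_cohort, small_vocab, tiny_model):
    records, _ = small_cohort
    model, _ = tiny_model
    cohort = build_diagnostic_cohort(records, small_vocab, "D11", 3, seed=0)
    check_censoring(cohort, small_vocab)
    # negatives never carry the target at all
    tid = small_vocab.encode("DX:D11")
    neg_ids = {m.person_id for m in cohort.negatives}
    for rec in records:
        if rec.person_id in neg_ids:
            assert not rec.has_code("diagnosis", "D11")
    res = confusion_at_n(model, cohort, small_vocab)
    for n in res.ns:
        assert res.tp[n] + res.fn[n] == pytest.approx(100.0)
        assert res.fp[n] + res.tn[n] == pytest.approx(100.0)
    tps = [res.tp[n] for n in res.ns]
    fps = [res.fp[n] for n in res.ns]
    assert tps == sorted(tps)   # non-decreasing in N (nested candidate sets)
    assert fps == sorted(fps)


def test_three_month_window_never_simulates_more_time_than_six(
        small_cohort, small_vocab, tiny_model):
    records, _ = small_cohort
    model, _ = tiny_model
    cohort3 = build_diagnostic_cohort(records, small_vocab, "D11", 3, seed=0)
    for m in cohort3.positives[:10]:
        w3 = rollout_best_rank(model, m.prefix_ids,
                               (small_vocab.encode("DX:D11"),), 3, small_vocab)
        w6 = rollout_best_rank(model, m.prefix_ids,
                               (small_vocab.encode("DX:D11"),), 6, small_vocab)
        assert w3.n_steps <= w6.n_steps
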