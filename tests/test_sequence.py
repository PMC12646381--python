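"""Sequence grammar: time tokens, linearization, truncation, decoding."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrgpt import (
    EmptySequenceError,
    StructuralError,
    assign_time_token,
    build_sequence,
    build_vocabulary,
    decode_sequence,
    generate_cohort,
    load_corpus,
    save_corpus,
)
from ehrgpt.records import Event, PatientRecord, Visit
from ehrgpt.vocab import SEP, TIME_TOKENS

from conftest import small_config


@pytest.mark.parametrize(
    "gap, expected",
    [(0, "t0"), (45, "t0"), (91, "t0"), (92, "t1"), (120, "t1"), (182, "t1"),
     (183, "t2"), (365, "t2"), (366, "t3"), (400, "t3"), (10000, "t3")],
)
def test_time_token_partition(gap, expected):
    assert assign_time_token(gap) == expected


def test_negative_gap_rejected():
    with pytest.raises(ValueError):
        assign_time_token(-1)


@given(st.integers(0, 5000))
@settings(deadline=None, max_examples=200)
def test_time_token_total_function(gap):
    assert assign_time_token(gap) in TIME_TOKENS


def _record(visit_specs, pid=1, sex="F", birth_year=1980):
    visits = []
    for i, (date, codes) in enumerate(visit_specs):
        visits.append(Visit(visit_id=i + 1, date=date,
                            events=[Event("diagnosis", c, date) for c in codes]))
    return PatientRecord(pid, sex, birth_year, visits)


@pytest.fixture(scope="module")
def toy_vocab():
    d0 = dt.date(2020, 1, 1)
    records = [
        _record([(d0, ["D00", "D01"]), (d0 + dt.timedelta(days=400), ["D02"])],
                pid=i)
        for i in range(1, 4)
    ]
    return build_vocabulary(records)


def test_single_visit_shape_no_time_token(toy_vocab):
    d0 = dt.date(2020, 1, 1)
    seq = build_sequence(_record([(d0, ["D00"])]), toy_vocab)
    toks = [toy_vocab.decode(i) for i in seq.token_ids]
    assert toks == ["SEX:F", "AGE:40-44", "VT:outpatient", "DX:D00", SEP]
    assert seq.visit_index == [-1, -1, 0, 0, 0]


def test_time_token_precedes_second_visit(toy_vocab):
    d0 = dt.date(2020, 1, 1)
    seq = build_sequence(
        _record([(d0, ["D00"]), (d0 + dt.timedelta(days=400), ["D02"])]),
        toy_vocab)
    toks = [toy_vocab.decode(i) for i in seq.token_ids]
    second_block = toks[toks.index(SEP) + 1:]
    assert second_block[0] == "t3"


def test_zero_mappable_events_raises(toy_vocab):
    d0 = dt.date(2020, 1, 1)
    with pytest.raises(EmptySequenceError):
        build_sequence(_record([(d0, ["ZZZ"])]), toy_vocab)


def test_unknown_events_dropped_but_sequence_builds(toy_vocab):
    d0 = dt.date(2020, 1, 1)
    seq = build_sequence(_record([(d0, ["D00", "ZZZ"])]), toy_vocab)
    assert seq.n_dropped_events == 1
    assert "DX:D00" in [toy_vocab.decode(i) for i in seq.token_ids]


def test_truncation_keeps_demographics_and_recent_visits(toy_vocab):
    d0 = dt.date(2020, 1, 1)
    specs = [(d0 + dt.timedelta(days=100 * i), ["D00", "D01", "D02"])
             for i in range(12)]
    rec = _record(specs)
    seq = build_sequence(rec, toy_vocab, max_len=30)
    assert len(seq) <= 30
    assert seq.truncated
    toks = [toy_vocab.decode(i) for i in seq.token_ids]
    assert toks[0].startswith("SEX:") and toks[1].startswith("AGE:")
    # a contiguous suffix of visits is kept, most recent last
    assert seq.visit_dates == [v.date for v in rec.visits[-len(seq.visit_dates):]]
    # grammar stays valid: decodes cleanly and no visit is split
    visits = decode_sequence(seq, toy_vocab)
    assert len(visits) == seq.n_visits
    assert visits[0].time_token is None
    assert all(v.visit_type is not None for v in visits)
    assert all(len(v.event_tokens) == 3 for v in visits)


def test_decode_splits_on_sep(toy_vocab):
    d0 = dt.date(2020, 1, 1)
    rec = _record([(d0, ["D00"]), (d0 + dt.timedelta(days=50), ["D01"]),
                   (d0 + dt.timedelta(days=300), ["D02"])])
    seq = build_sequence(rec, toy_vocab)
    assert sum(1 for t in seq.token_ids if t == toy_vocab.sep_id) == 3
    visits = decode_sequence(seq, toy_vocab)
    assert len(visits) == 3
    assert visits[0].time_token is None
    assert visits[1].time_token == "t0"
    assert visits[2].time_token == "t2"


def test_stray_time_token_raises_structural_error_with_position(toy_vocab):
    d0 = dt.date(2020, 1, 1)
    seq = build_sequence(_record([(d0, ["D00", "D01"])]), toy_vocab)
    ids = list(seq.token_ids)
    ids.insert(4, toy_vocab.encode("t1"))  # inside the first visit block
    with pytest.raises(StructuralError) as exc:
        decode_sequence(ids, toy_vocab)
    assert exc.value.position == 4


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=10)
def test_round_trip_identity_on_random_cohorts(seed):
    cfg = small_config(seed=seed)
    cfg.n_patients = 6
    records, _ = generate_cohort(cfg)
    vocab = build_vocabulary(records)
    for rec in records:
        try:
            seq = build_sequence(rec, vocab)
        except EmptySequenceError:
            continue
        if seq.truncated:
            continue
        visits = decode_sequence(seq, vocab)
        assert len(visits) == len(rec.visits)
        for v_struct, v in zip(visits, rec.visits):
            assert v_struct.visit_type == v.visit_type
            assert v_struct.discharge == v.discharge
            expected = set()
            for e in v.events:
                try:
                    tok = vocab.event_token(e.domain, e.code, e.value)
                except Exception:
                    continue
                if tok in vocab:
                    expected.add(tok)
            assert set(v_struct.event_tokens) == expected
        # rebuild: re-encoding the decoded structure reproduces the ids
        seq2 = build_sequence(rec, vocab)
        assert seq2.token_ids == seq.token_ids


def test_corpus_save_load_round_trip(small_sequences, tmp_path):
    path = tmp_path / "corpus.txt"
    save_corpus(small_sequences, path)
    back = load_corpus(path)
    assert len(back) == len(small_sequences)
    for a, b in zip(small_sequences, back):
        assert a.person_id == b.person_id
        assert a.token_ids == b.token_ids
        assert a.visit_index == b.visit_index
        assert a.visit_dates == b.visit_dates
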