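"""Vocabulary: normalization, filtering, eCDF deciles, bijectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrgpt import (
    CodeMapping,
    apply_code_mapping,
    build_vocabulary,
    compute_code_frequencies,
    filter_rare_codes,
    fit_lab_deciles,
    normalize_diagnosis_code,
)
from ehrgpt.records import Event, PatientRecord, Visit
from ehrgpt.vocab import Vocabulary, UnknownTokenError, lab_bin
import datetime as dt


@pytest.mark.parametrize(
    "code, expected",
    [
        ("E11.9", "E11"),
        ("I50", "I50"),
        ("C25.0", "C25"),
        ("e11.9", "E11"),
        ("M0612", "M06"),  # no decimal: truncate to the 3-char stem
        ("I1", "I1"),
    ],
)
def test_normalize_diagnosis_code(code, expected):
    assert normalize_diagnosis_code(code) == expected


def test_normalize_empty_code_rejected():
    with pytest.raises(ValueError):
        normalize_diagnosis_code("")


def test_apply_code_mapping_is_total_with_identity_fallback():
    m = CodeMapping({"250.00": "E11.9", "401.9": "I10"})
    assert apply_code_mapping("250.00", m) == "E11.9"
    assert apply_code_mapping("401.9", m) == "I10"
    assert apply_code_mapping("E11.9", CodeMapping()) == "E11.9"


def test_mapping_file_round_trip(tmp_path):
    p = tmp_path / "gem.csv"
    p.write_text("# source,target\n250.00,E11.9\n4019 I10\n")
    m = CodeMapping.from_file(p)
    assert m("250.00") == "E11.9" and m("4019") == "I10"


def _one_code_record(pid, code, n_visits):
    d0 = dt.date(2020, 1, 1)
    visits = [
        Visit(visit_id=pid * 100 + i, date=d0 + dt.timedelta(days=100 * i),
              events=[Event("diagnosis", code, d0 + dt.timedelta(days=100 * i))])
        for i in range(n_visits)
    ]
    return PatientRecord(pid, "F", 1980, visits)


def test_frequencies_count_each_patient_once():
    records = [
        _one_code_record(1, "E11.9", 3),  # repeated across 3 visits: counts 1
        _one_code_record(2, "E11.9", 1),
        _one_code_record(3, "I10", 1),
        _one_code_record(4, "I10", 2),
    ]
    freq = compute_code_frequencies(records)
    assert freq["DX:E11"] == 2
    assert freq["DX:I10"] == 2
    assert "DX:C25" not in freq


def test_filter_rare_codes_strict_below_removed():
    freq = {"a": 1, "b": 10, "c": 2}
    kept = filter_rare_codes(freq, n_patients=2000, threshold=0.001)
    assert "a" not in kept            # 0.05% < 0.1% → removed
    assert "b" in kept                # 0.5% → retained
    assert "c" in kept                # exactly 0.1% → retained
    with pytest.raises(ValueError):
        filter_rare_codes(freq, 0)


@given(st.floats(0.0005, 0.5), st.floats(0.0005, 0.5))
@settings(deadline=None, max_examples=30)
def test_filter_monotone_in_threshold(t1, t2):
    freq = {f"c{i}": i for i in range(1, 30)}
    lo, hi = sorted((t1, t2))
    assert filter_rare_codes(freq, 1000, hi) <= filter_rare_codes(freq, 1000, lo)


def _oracle_deciles(values):
    # independent route: numpy's inverse-eCDF quantile
    return list(np.quantile(np.asarray(values, dtype=float),
                            np.arange(1, 10) / 10, method="inverted_cdf"))


@pytest.mark.parametrize("n", [10, 37, 100, 1000])
def test_decile_boundaries_match_quantile_oracle(n):
    rng = np.random.default_rng(n)
    values = list(rng.lognormal(1.0, 0.7, n))
    got = fit_lab_deciles({"L": values})["L"]
    assert np.allclose(got, _oracle_deciles(values))


def test_uniform_1_to_100_boundaries_and_bin():
    values = [float(x) for x in range(1, 101)]
    bounds = fit_lab_deciles({"L": values})["L"]
    assert bounds == [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0]
    assert lab_bin(55.0, bounds) == 5
    assert lab_bin(0.5, bounds) == 0
    assert lab_bin(1e9, bounds) == 9


def test_ten_distinct_values_each_get_their_own_bin():
    values = [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    bounds = fit_lab_deciles({"L": values})["L"]
    assert [lab_bin(v, bounds) for v in values] == list(range(10))


def test_degenerate_identical_values_all_bin_zero(caplog):
    with caplog.at_level("WARNING"):
        bounds = fit_lab_deciles({"L": [5.0] * 25})["L"]
    assert bounds == [5.0] * 9
    assert lab_bin(5.0, bounds) == 0
    assert any("identical" in r.message for r in caplog.records)


def test_too_few_values_excluded_with_warning(caplog):
    with caplog.at_level("WARNING"):
        out = fit_lab_deciles({"L": [1.0] * 9, "M": list(range(12))})
    assert "L" not in out and "M" in out


def test_bin_coverage_between_5_and_15_percent():
    rng = np.random.default_rng(0)
    values = list(rng.normal(size=2000))
    bounds = fit_lab_deciles({"L": values})["L"]
    bins = np.array([lab_bin(v, bounds) for v in values])
    frac = np.bincount(bins, minlength=10) / len(values)
    assert np.all(frac >= 0.05) and np.all(frac <= 0.15)


def test_vocabulary_bijective_and_round_trips(small_vocab, tmp_path):
    v = small_vocab
    for i in range(len(v)):
        assert v.encode(v.decode(i)) == i
    path = tmp_path / "vocab.json"
    v.save(path)
    w = Vocabulary.load(path)
    assert w.id_to_token == v.id_to_token
    assert w.lab_deciles == v.lab_deciles
    assert w.content_hash() == v.content_hash()


def test_build_vocabulary_deterministic_and_filters(small_cohort):
    records, _ = small_cohort
    v1 = build_vocabulary(records)
    v2 = build_vocabulary(records)
    assert v1.id_to_token == v2.id_to_token
    # raising the threshold can only shrink the clinical token set
    v3 = build_vocabulary(records, threshold=0.5)
    assert set(v3.id_to_token) <= set(v1.id_to_token)


def test_discretize_unknown_lab_raises(small_vocab):
    with pytest.raises(UnknownTokenError):
        small_vocab.discretize_lab("NOPE", 1.0)


def test_lab_tokens_are_code_bin_compounds(small_vocab):
    tok = small_vocab.discretize_lab("L00", 1e-9)
    assert tok == "LAB:L00:0"
    assert tok in small_vocab
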