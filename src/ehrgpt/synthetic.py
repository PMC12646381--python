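"""Synthetic OMOP-style longitudinal cohorts with known conditional structure.

The generator emulates the shape of a real multi-visit EHR corpus —
demographics, four event domains, continuous lab values, inter-visit gaps
covering every time-token range — while injecting precursor→target rules
with *known* conditional probabilities.  Those rules are the ground truth
against which the downstream tokenizer, language model and censored-window
evaluation protocol are validated.

Rule semantics
--------------
A rule ``(precursor, target, p, min_lag, max_lag)`` fires (per patient, at
most once) with probability ``p`` among patients that emit the precursor at
least once.  When it fires, the target code is planted in (or as) a visit
``min_lag..max_lag`` days after the *last* precursor occurrence, so earlier
recurrences of a chronic precursor remain in the visible pre-target history.
Per-code ``carrier_fractions`` gate background emission at the patient
level, which is how chronic, patient-specific codes (prevalence < 1) are
modelled on top of the per-visit background rates.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import DISCHARGE_TYPES, DOMAINS, Event, PatientRecord, Visit

log = logging.getLogger(__name__)


def _event_key(e: Event) -> tuple:
    return (DOMAINS.index(e.domain), e.code, e.value if e.value is not None else 0.0)

#: inter-visit gap ranges (days, inclusive) matching the four time tokens
GAP_RANGES = ((1, 91), (92, 182), (183, 365), (366, 730))

_OMOP_TABLES = (
    "person",
    "visit_occurrence",
    "condition_occurrence",
    "drug_exposure",
    "procedure_occurrence",
    "measurement",
)

_EVENT_TABLE = {
    "diagnosis": "condition_occurrence",
    "medication": "drug_exposure",
    "procedure": "procedure_occurrence",
    "lab": "measurement",
}


class ConfigError(ValueError):
    """A generator configuration field is invalid."""


@dataclass(frozen=True)
class PrecursorRule:
    precursor: str
    target: str
    probability: float
    min_lag_days: int
    max_lag_days: int


def _default_pools() -> dict[str, list[str]]:
    dx = [f"D{i:02d}" for i in range(40)]
    rx = [f"R{i:02d}" for i in range(15)]
    px = [f"P{i:02d}" for i in range(10)]
    lab = [f"L{i:02d}" for i in range(5)]
    return {"diagnosis": dx, "medication": rx, "procedure": px, "lab": lab}


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic cohort.

    Defaults describe a desk-scale corpus: 2 000 patients averaging 8
    visits, ~40+15+10 coded concepts plus 5 continuous labs, gap mixture
    dominated by same-quarter returns, log-normal lab values.
    """

    n_patients: int = 2000
    code_pools: dict[str, list[str]] = field(default_factory=_default_pools)
    visit_count_mean: float = 8.0
    gap_mixture: tuple[float, float, float, float] = (0.55, 0.20, 0.15, 0.10)
    lab_value_distributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    precursor_rules: list[PrecursorRule] = field(default_factory=list)
    background_rates: dict[str, float] = field(default_factory=dict)
    default_background_rate: float = 0.08
    carrier_fractions: dict[str, float] = field(default_factory=dict)
    epoch_start: dt.date = dt.date(2015, 1, 1)
    epoch_days: int = 1460
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.visit_count_mean < 1:
            raise ConfigError("visit_count_mean must be >= 1")
        if len(self.gap_mixture) != 4:
            raise ConfigError("gap_mixture must have 4 weights")
        if any(w < 0 for w in self.gap_mixture):
            raise ConfigError("gap_mixture weights must be non-negative")
        if abs(sum(self.gap_mixture) - 1.0) > 1e-9:
            raise ConfigError("gap_mixture weights must sum to 1")
        pools = self.code_pools
        seen: set[str] = set()
        for domain, codes in pools.items():
            dup = seen.intersection(codes)
            if dup:
                raise ConfigError(f"code_pools not disjoint across domains: {sorted(dup)}")
            seen.update(codes)
        for code, p in self.background_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"background_rates[{code!r}] must be in [0,1]")
        for code, f in self.carrier_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"carrier_fractions[{code!r}] must be in [0,1]")
        for rule in self.precursor_rules:
            if not 0.0 <= rule.probability <= 1.0:
                raise ConfigError(f"precursor_rules[{rule.precursor}->{rule.target}]: "
                                  "probability must be in [0,1]")
            if rule.min_lag_days < 0 or rule.max_lag_days < rule.min_lag_days:
                raise ConfigError(f"precursor_rules[{rule.precursor}->{rule.target}]: "
                                  "bad lag range")
        for code, (mu, sigma) in self.lab_value_distributions.items():
            if sigma <= 0:
                raise ConfigError(f"lab_value_distributions[{code!r}]: sigma must be > 0")

    def rate(self, code: str) -> float:
        return self.background_rates.get(code, self.default_background_rate)

    def lab_params(self, code: str) -> tuple[float, float]:
        # log-normal by default: skewed positive values typical of labs
        return self.lab_value_distributions.get(code, (1.0, 0.5))


@dataclass
class RuleOutcome:
    person_id: int
    precursor_onset_date: dt.date
    target_code: str
    fired: bool


@dataclass
class GroundTruth:
    """Per-rule realized outcomes of the injected conditional structure."""

    outcomes: dict[str, list[RuleOutcome]]  # keyed "precursor->target"
    realized_frequencies: dict[str, float]
    configured_probabilities: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "realized_frequencies": self.realized_frequencies,
            "configured_probabilities": self.configured_probabilities,
            "outcomes": {
                key: [
                    {
                        "person_id": o.person_id,
                        "precursor_onset_date": o.precursor_onset_date.isoformat(),
                        "target_code": o.target_code,
                        "fired": o.fired,
                    }
                    for o in outs
                ]
                for key, outs in self.outcomes.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def zero_shot_study_config(n_patients: int = 2000, probability: float = 0.8,
                           seed: int = 0) -> GeneratorConfig:
    """Study conditions for censored-window signal recovery.

    A chronic precursor diagnosis ("D00", carried by half the population
    and re-billed in ~60% of a carrier's visits) triggers the target
    diagnosis ("D40") with the given conditional probability 10–80 days
    after its last occurrence.  The target never occurs at background, so
    never-diagnosed patients form a clean negative arm; the recurring
    precursor leaves signal in the history even after the prediction
    window is censored away.
    """
    cfg = GeneratorConfig(n_patients=n_patients, seed=seed)
    cfg.code_pools["diagnosis"].append("D40")
    cfg.background_rates = {"D00": 0.6, "D40": 0.0}
    cfg.carrier_fractions = {"D00": 0.5}
    cfg.precursor_rules = [
        PrecursorRule(precursor="D00", target="D40", probability=probability,
                      min_lag_days=10, max_lag_days=80)
    ]
    return cfg


def _sample_gap(rng: np.random.Generator, mixture: tuple[float, ...]) -> int:
    k = rng.choice(4, p=np.asarray(mixture, dtype=float))
    lo, hi = GAP_RANGES[k]
    return int(rng.integers(lo, hi + 1))


def _gen_patient(pid: int, cfg: GeneratorConfig, rng: np.random.Generator,
                 carrier: dict[str, np.ndarray], pidx: int) -> PatientRecord:
    sex = "F" if rng.random() < 0.5 else "M"
    birth_year = int(rng.integers(1940, 2006))
    n_visits = 1 + int(rng.poisson(max(cfg.visit_count_mean - 1.0, 0.0)))
    start = cfg.epoch_start + dt.timedelta(days=int(rng.integers(0, cfg.epoch_days)))

    dates = [start]
    for _ in range(n_visits - 1):
        dates.append(dates[-1] + dt.timedelta(days=_sample_gap(rng, cfg.gap_mixture)))

    visits: list[Visit] = []
    for i, d in enumerate(dates):
        u = rng.random()
        vtype = "outpatient" if u < 0.8 else ("inpatient" if u < 0.9 else "emergency")
        discharge = None
        if vtype == "inpatient":
            discharge = DISCHARGE_TYPES[int(rng.choice(3, p=[0.85, 0.12, 0.03]))]
        events: list[Event] = []
        for domain, codes in cfg.code_pools.items():
            for code in codes:
                if not carrier[code][pidx]:
                    continue
                if rng.random() < cfg.rate(code):
                    value = None
                    if domain == "lab":
                        mu, sigma = cfg.lab_params(code)
                        value = float(rng.lognormal(mu, sigma))
                    events.append(Event(domain=domain, code=code, date=d, value=value))
        visits.append(Visit(visit_id=0, date=d, visit_type=vtype,
                            discharge=discharge, events=events))
    return PatientRecord(person_id=pid, sex=sex, birth_year=birth_year, visits=visits)


def _apply_rule(record: PatientRecord, rule: PrecursorRule,
                rng: np.random.Generator) -> RuleOutcome | None:
    """Fire ``rule`` on one patient; returns the outcome or None if no precursor."""
    precursor_dates = [
        v.date for v in record.visits
        if any(e.code == rule.precursor for e in v.events)
    ]
    if not precursor_dates:
        return None
    anchor = precursor_dates[-1]
    fired = bool(rng.random() < rule.probability)
    if fired:
        lag = int(rng.integers(rule.min_lag_days, rule.max_lag_days + 1))
        target_date = anchor + dt.timedelta(days=lag)
        lo = anchor + dt.timedelta(days=rule.min_lag_days)
        hi = anchor + dt.timedelta(days=rule.max_lag_days)
        host = None
        best = None
        for v in record.visits:
            if lo <= v.date <= hi:
                gap = abs((v.date - target_date).days)
                if best is None or gap < best:
                    host, best = v, gap
        if host is None:
            host = Visit(visit_id=0, date=target_date, visit_type="outpatient")
            record.visits.append(host)
            record.visits.sort(key=lambda v: v.date)
        host.events.append(
            Event(domain="diagnosis", code=rule.target, date=host.date)
        )
    return RuleOutcome(record.person_id, anchor, rule.target, fired)


def generate_cohort(config: GeneratorConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a seeded cohort plus the realized rule outcomes.

    Deterministic: an identical config (including seed) reproduces the
    cohort exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    all_codes = [c for codes in config.code_pools.values() for c in codes]
    carrier = {
        code: rng.random(config.n_patients) < config.carrier_fractions.get(code, 1.0)
        for code in all_codes
    }

    records = [
        _gen_patient(1 + i, config, rng, carrier, i) for i in range(config.n_patients)
    ]

    outcomes: dict[str, list[RuleOutcome]] = {}
    for rule in config.precursor_rules:
        key = f"{rule.precursor}->{rule.target}"
        outs = []
        for rec in records:
            o = _apply_rule(rec, rule, rng)
            if o is not None:
                outs.append(o)
        outcomes[key] = outs

    # renumber visit ids globally after any rule-driven insertions, and put
    # each visit's events into the canonical (domain, code, value) order so
    # the OMOP round trip is exact
    vid = 1
    for rec in records:
        for v in rec.visits:
            v.visit_id = vid
            v.events.sort(key=_event_key)
            vid += 1

    realized: dict[str, float] = {}
    configured: dict[str, float] = {}
    for rule in config.precursor_rules:
        key = f"{rule.precursor}->{rule.target}"
        configured[key] = rule.probability
        outs = outcomes[key]
        if outs:
            hits = 0
            by_id = {r.person_id: r for r in records}
            for o in outs:
                rec = by_id[o.person_id]
                lo = o.precursor_onset_date + dt.timedelta(days=rule.min_lag_days)
                hi = o.precursor_onset_date + dt.timedelta(days=rule.max_lag_days)
                if any(
                    lo <= v.date <= hi and any(e.code == rule.target for e in v.events)
                    for v in rec.visits
                ):
                    hits += 1
            realized[key] = hits / len(outs)
        else:
            realized[key] = float("nan")

    return records, GroundTruth(outcomes, realized, configured)


# ---------------------------------------------------------------------------
# OMOP table round trip


def write_omop_tables(records: list[PatientRecord], directory: str | pathlib.Path,
                      ground_truth: GroundTruth | None = None) -> None:
    """Write the minimal OMOP CDM table subset as comma-delimited text.

    Emits person, visit_occurrence and the four event-domain tables with
    header rows (empty domains still produce a header-only file), plus
    ``ground_truth.json`` when provided.
    """
    if not records:
        raise ValueError("records must be non-empty")
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    person = pd.DataFrame(
        [
            {"person_id": r.person_id, "gender_source_value": r.sex,
             "year_of_birth": r.birth_year}
            for r in records
        ]
    )
    visit_rows, cond, drug, proc, meas = [], [], [], [], []
    eid = {t: 1 for t in _EVENT_TABLE.values()}
    for r in records:
        for v in r.visits:
            visit_rows.append(
                {"visit_occurrence_id": v.visit_id, "person_id": r.person_id,
                 "visit_start_date": v.date.isoformat(),
                 "visit_source_value": v.visit_type,
                 "discharge_to_source_value": v.discharge or ""}
            )
            for e in v.events:
                table = _EVENT_TABLE[e.domain]
                row = {"person_id": r.person_id, "visit_occurrence_id": v.visit_id}
                if e.domain == "diagnosis":
                    row |= {"condition_occurrence_id": eid[table],
                            "condition_start_date": e.date.isoformat(),
                            "condition_source_value": e.code}
                    cond.append(row)
                elif e.domain == "medication":
                    row |= {"drug_exposure_id": eid[table],
                            "drug_exposure_start_date": e.date.isoformat(),
                            "drug_source_value": e.code}
                    drug.append(row)
                elif e.domain == "procedure":
                    row |= {"procedure_occurrence_id": eid[table],
                            "procedure_date": e.date.isoformat(),
                            "procedure_source_value": e.code}
                    proc.append(row)
                else:
                    row |= {"measurement_id": eid[table],
                            "measurement_date": e.date.isoformat(),
                            "measurement_source_value": e.code,
                            "value_as_number": repr(e.value) if e.value is not None else ""}
                    meas.append(row)
                eid[table] += 1

    _HEADERS = {
        "person": ["person_id", "gender_source_value", "year_of_birth"],
        "visit_occurrence": ["visit_occurrence_id", "person_id", "visit_start_date",
                             "visit_source_value", "discharge_to_source_value"],
        "condition_occurrence": ["condition_occurrence_id", "person_id",
                                 "visit_occurrence_id", "condition_start_date",
                                 "condition_source_value"],
        "drug_exposure": ["drug_exposure_id", "person_id", "visit_occurrence_id",
                          "drug_exposure_start_date", "drug_source_value"],
        "procedure_occurrence": ["procedure_occurrence_id", "person_id",
                                 "visit_occurrence_id", "procedure_date",
                                 "procedure_source_value"],
        "measurement": ["measurement_id", "person_id", "visit_occurrence_id",
                        "measurement_date", "measurement_source_value",
                        "value_as_number"],
    }
    frames = {
        "person": person,
        "visit_occurrence": pd.DataFrame(visit_rows),
        "condition_occurrence": pd.DataFrame(cond),
        "drug_exposure": pd.DataFrame(drug),
        "procedure_occurrence": pd.DataFrame(proc),
        "measurement": pd.DataFrame(meas),
    }
    for name, df in frames.items():
        cols = _HEADERS[name]
        if df.empty:
            df = pd.DataFrame(columns=cols)
        df = df[cols]
        df.to_csv(directory / f"{name}.csv", index=False, lineterminator="\n")

    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(ground_truth.to_json())


def read_omop_tables(directory: str | pathlib.Path) -> list[PatientRecord]:
    """Read the table set back into patient records.

    Events are joined to visits by ``visit_occurrence_id`` and inherit the
    visit date; orphan event rows (no matching visit) are logged and
    skipped, and patients with zero visits are dropped with a logged count.
    """
    directory = pathlib.Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name in _OMOP_TABLES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
        tables[name] = pd.read_csv(path, dtype=str, keep_default_na=False)

    visits: dict[int, Visit] = {}
    visit_owner: dict[int, int] = {}
    for row in tables["visit_occurrence"].itertuples(index=False):
        vid = int(row.visit_occurrence_id)
        visits[vid] = Visit(
            visit_id=vid,
            date=dt.date.fromisoformat(row.visit_start_date),
            visit_type=row.visit_source_value,
            discharge=row.discharge_to_source_value or None,
        )
        visit_owner[vid] = int(row.person_id)

    orphans = 0
    spec = (
        ("condition_occurrence", "diagnosis", "condition_source_value", None),
        ("drug_exposure", "medication", "drug_source_value", None),
        ("procedure_occurrence", "procedure", "procedure_source_value", None),
        ("measurement", "lab", "measurement_source_value", "value_as_number"),
    )
    for table, domain, code_col, val_col in spec:
        for row in tables[table].itertuples(index=False):
            vid = int(getattr(row, "visit_occurrence_id"))
            v = visits.get(vid)
            if v is None:
                orphans += 1
                continue
            value = None
            if val_col is not None:
                raw = getattr(row, val_col)
                value = float(raw) if raw != "" else None
            v.events.append(Event(domain=domain, code=getattr(row, code_col),
                                  date=v.date, value=value))
    if orphans:
        log.warning("skipped %d orphan event rows with no matching visit", orphans)

    records: list[PatientRecord] = []
    dropped = 0
    for row in tables["person"].itertuples(index=False):
        pid = int(row.person_id)
        own = sorted(
            (v for vid, v in visits.items() if visit_owner[vid] == pid),
            key=lambda v: (v.date, v.visit_id),
        )
        if not own:
            dropped += 1
            continue
        for v in own:
            v.events.sort(key=_event_key)
        records.append(
            PatientRecord(person_id=pid, sex=row.gender_source_value,
                          birth_year=int(row.year_of_birth), visits=own)
        )
    if dropped:
        log.info("dropped %d patients with zero visits", dropped)
    return records
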