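"""Token vocabulary: code normalization, rare-code filtering, lab deciles.

The clinical token set mirrors how EHR foundation-model corpora are
usually built: diagnosis codes are collapsed to their 3-character stem
(``E11.9 → E11``), codes carried by fewer than 0.1% of patients are
dropped, and each lab's continuous values are discretized into ten bins
by the empirical CDF of the training split (one compound token per
(lab code, decile) pair).  Structural tokens — PAD, the visit separator,
the four relative time tokens, visit-/discharge-type tokens and the
demographics tokens — occupy the low ids in a fixed order so that id
assignment is deterministic across runs.
"""

from __future__ import annotations

import json
import logging
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .records import DISCHARGE_TYPES, PatientRecord, VISIT_TYPES

log = logging.getLogger(__name__)

PAD = "[PAD]"
SEP = "[SEP]"
TIME_TOKENS = ("t0", "t1", "t2", "t3")
SEXES = ("F", "M", "U")

_DOMAIN_PREFIX = {"diagnosis": "DX:", "medication": "RX:", "procedure": "PX:",
                  "lab": "LAB:"}


class UnknownTokenError(KeyError):
    pass


def special_tokens(age_bucket_width: int = 5, max_age: int = 100) -> list[str]:
    """The fixed structural token list, lowest ids first (PAD is id 0)."""
    toks = [PAD, SEP, *TIME_TOKENS]
    toks += [f"VT:{v}" for v in VISIT_TYPES]
    toks += [f"DT:{d}" for d in DISCHARGE_TYPES]
    toks += [f"SEX:{s}" for s in SEXES]
    for lo in range(0, max_age, age_bucket_width):
        toks.append(f"AGE:{lo}-{lo + age_bucket_width - 1}")
    toks.append(f"AGE:{max_age}+")
    return toks


def age_bucket_token(age: int, width: int = 5, max_age: int = 100) -> str:
    age = max(0, age)
    if age >= max_age:
        return f"AGE:{max_age}+"
    lo = (age // width) * width
    return f"AGE:{lo}-{lo + width - 1}"


def sex_token(sex: str) -> str:
    return f"SEX:{sex}" if sex in SEXES else "SEX:U"


# ---------------------------------------------------------------------------
# Code normalization / mapping


def normalize_diagnosis_code(code: str) -> str:
    """Collapse a diagnosis code to the (≤3) characters before the decimal.

    ``E11.9 → E11``; codes without a decimal are truncated to 3 chars.
    """
    if not code:
        raise ValueError("empty diagnosis code")
    return code.split(".", 1)[0][:3].upper()


class CodeMapping:
    """A source→target code table (e.g. ICD-9 → ICD-10 equivalence maps).

    Acts as a total function: codes absent from the table map to
    themselves.
    """

    def __init__(self, table: dict[str, str] | None = None):
        self.table = dict(table or {})

    def __call__(self, code: str) -> str:
        return self.table.get(code, code)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_file(cls, path: str | pathlib.Path, delimiter: str | None = None) -> "CodeMapping":
        """Load a two-column delimited text file (source, target)."""
        table = {}
        for ln in pathlib.Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split(delimiter) if delimiter else ln.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"mapping line needs two columns: {ln!r}")
            table[parts[0]] = parts[1]
        return cls(table)


def apply_code_mapping(code: str, mapping: CodeMapping) -> str:
    return mapping(code)


# ---------------------------------------------------------------------------
# Frequencies and filtering


def event_base_token(domain: str, code: str, mapping: CodeMapping | None = None) -> str:
    """Domain-qualified base token for an event code (lab bins not applied)."""
    if domain == "diagnosis":
        if mapping is not None:
            code = mapping(code)
        code = normalize_diagnosis_code(code)
    return _DOMAIN_PREFIX[domain] + code


def compute_code_frequencies(records: list[PatientRecord],
                             mapping: CodeMapping | None = None) -> dict[str, int]:
    """Patient-level counts: each code counted once per patient carrying it."""
    if not records:
        raise ValueError("records must be non-empty")
    freq: dict[str, int] = {}
    for rec in records:
        seen = {
            event_base_token(e.domain, e.code, mapping)
            for v in rec.visits
            for e in v.events
        }
        for tok in seen:
            freq[tok] = freq.get(tok, 0) + 1
    return freq


def filter_rare_codes(frequencies: dict[str, int], n_patients: int,
                      threshold: float = 0.001) -> set[str]:
    """Retain codes carried by ≥ ``threshold`` of patients.

    Codes strictly below the threshold are removed; exactly-at-threshold
    codes are kept.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    return {tok for tok, c in frequencies.items() if c / n_patients >= threshold}


# ---------------------------------------------------------------------------
# Lab eCDF deciles


def fit_lab_deciles(lab_values: dict[str, list[float]],
                    min_values: int = 10) -> dict[str, list[float]]:
    """Fit per-lab decile boundaries on training values.

    Boundaries are the type-1 (left-continuous inverse eCDF) 10th…90th
    percentiles: ``b_k = sorted[⌈k·n/10⌉ − 1]``.  Labs with fewer than
    ``min_values`` training values are excluded with a warning; an
    all-identical lab degenerates to nine equal boundaries (every value
    lands in bin 0).
    """
    out: dict[str, list[float]] = {}
    for code, values in lab_values.items():
        vals = [float(x) for x in values if x is not None and math.isfinite(x)]
        n = len(vals)
        if n < min_values:
            log.warning("lab %s: only %d training values (<%d), excluded",
                        code, n, min_values)
            continue
        srt = sorted(vals)
        bounds = [srt[math.ceil(k * n / 10) - 1] for k in range(1, 10)]
        if srt[0] == srt[-1]:
            log.warning("lab %s: all training values identical, degenerate bins", code)
        assert all(a <= b for a, b in zip(bounds, bounds[1:]))
        out[code] = bounds
    return out


def lab_bin(value: float, boundaries: list[float]) -> int:
    """Bin index = number of boundaries strictly below ``value`` (0..9)."""
    return int(sum(b < value for b in boundaries))


# ---------------------------------------------------------------------------
# Vocabulary


@dataclass
class Vocabulary:
    """Bijective token↔id registry with per-lab decile boundaries.

    Ids are assigned deterministically: the fixed structural token list
    first, then all retained clinical tokens in lexicographic order.
    """

    id_to_token: list[str]
    lab_deciles: dict[str, list[float]]
    frequencies: dict[str, int]
    threshold: float
    n_patients: int
    age_bucket_width: int = 5
    code_mapping: dict[str, str] = field(default_factory=dict)
    token_to_id: dict[str, int] = field(init=False, repr=False)

    SCHEMA_VERSION = 1

    def __post_init__(self) -> None:
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("duplicate tokens in vocabulary")
        for code, bounds in self.lab_deciles.items():
            if len(bounds) != 9 or any(not math.isfinite(b) for b in bounds):
                raise ValueError(f"lab {code}: need 9 finite boundaries")
            if any(a > b for a, b in zip(bounds, bounds[1:])):
                raise ValueError(f"lab {code}: boundaries must be non-decreasing")

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode(self, token: str) -> int:
        try:
            return self.token_to_id[token]
        except KeyError:
            raise UnknownTokenError(token) from None

    def decode(self, token_id: int) -> str:
        return self.id_to_token[token_id]

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    # structural ids -------------------------------------------------------
    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def time_token_ids(self) -> tuple[int, ...]:
        return tuple(self.token_to_id[t] for t in TIME_TOKENS)

    def structural_ids(self) -> frozenset[int]:
        """Ids of all non-clinical tokens (PAD, SEP, time, VT/DT, demographics)."""
        if not hasattr(self, "_structural_ids"):
            specials = set(special_tokens(self.age_bucket_width))
            self._structural_ids = frozenset(
                i for i, t in enumerate(self.id_to_token) if t in specials)
        return self._structural_ids

    def mapping(self) -> CodeMapping:
        return CodeMapping(self.code_mapping)

    # lab helpers ----------------------------------------------------------
    def discretize_lab(self, lab_code: str, value: float) -> str:
        """Compound token ``LAB:<code>:<bin>`` for a continuous lab value."""
        if lab_code not in self.lab_deciles:
            raise UnknownTokenError(f"no fitted deciles for lab {lab_code!r}")
        return f"LAB:{lab_code}:{lab_bin(value, self.lab_deciles[lab_code])}"

    def event_token(self, domain: str, code: str, value: float | None = None) -> str:
        """Vocabulary token string for an event (may be absent from vocab)."""
        if domain == "lab":
            if value is None:
                raise ValueError(f"lab event {code!r} has no value")
            return self.discretize_lab(code, value)
        return event_base_token(domain, code, self.mapping())

    def diagnosis_tokens(self) -> list[str]:
        return [t for t in self.id_to_token if t.startswith("DX:")]

    # serialization --------------------------------------------------------
    def save(self, path: str | pathlib.Path) -> None:
        payload = {
            "schema_version": self.SCHEMA_VERSION,
            "special_tokens": special_tokens(self.age_bucket_width),
            "tokens": self.id_to_token,
            "lab_deciles": self.lab_deciles,
            "frequencies": self.frequencies,
            "threshold": self.threshold,
            "n_patients": self.n_patients,
            "age_bucket_width": self.age_bucket_width,
            "code_mapping": self.code_mapping,
        }
        pathlib.Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "Vocabulary":
        payload = json.loads(pathlib.Path(path).read_text())
        return cls(
            id_to_token=payload["tokens"],
            lab_deciles=payload["lab_deciles"],
            frequencies=payload["frequencies"],
            threshold=payload["threshold"],
            n_patients=payload["n_patients"],
            age_bucket_width=payload.get("age_bucket_width", 5),
            code_mapping=payload.get("code_mapping", {}),
        )

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update("\x00".join(self.id_to_token).encode())
        for code in sorted(self.lab_deciles):
            h.update(code.encode())
            h.update(np.asarray(self.lab_deciles[code], dtype=np.float64).tobytes())
        return h.hexdigest()


def build_vocabulary(records: list[PatientRecord],
                     mapping: CodeMapping | None = None,
                     threshold: float = 0.001,
                     age_bucket_width: int = 5) -> Vocabulary:
    """Full pipeline: mapping → normalization → rare-code filter → deciles.

    ``records`` should be the training split: both the frequency filter
    and the lab decile boundaries are fitted on what is passed here.
    """
    mapping = mapping or CodeMapping()
    freq = compute_code_frequencies(records, mapping)
    retained = filter_rare_codes(freq, len(records), threshold)
    if not retained:
        raise ValueError("vocabulary empty after rare-code filtering")

    lab_values: dict[str, list[float]] = {}
    for rec in records:
        for v in rec.visits:
            for e in v.events:
                if e.domain == "lab" and e.value is not None:
                    base = event_base_token("lab", e.code)
                    if base in retained:
                        lab_values.setdefault(e.code, []).append(e.value)
    deciles = fit_lab_deciles(lab_values)

    clinical: list[str] = []
    for tok in sorted(retained):
        if tok.startswith("LAB:"):
            code = tok[len("LAB:"):]
            if code in deciles:
                clinical.extend(f"LAB:{code}:{b}" for b in range(10))
        else:
            clinical.append(tok)
    tokens = special_tokens(age_bucket_width) + sorted(clinical)
    return Vocabulary(
        id_to_token=tokens,
        lab_deciles=deciles,
        frequencies=freq,
        threshold=threshold,
        n_patients=len(records),
        age_bucket_width=age_bucket_width,
        code_mapping=dict(mapping.table),
    )
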