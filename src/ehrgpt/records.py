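"""Core in-memory containers for longitudinal patient records.

A :class:`PatientRecord` holds one person's demographics plus a
time-ordered list of visits; each visit carries typed clinical events
(diagnosis, medication, procedure, lab).  These containers are the
hand-off format between the synthetic cohort generator, the OMOP table
reader/writer and the tokenizer.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

#: canonical event domains, in the fixed intra-visit serialization order
DOMAINS = ("diagnosis", "procedure", "medication", "lab")

VISIT_TYPES = ("outpatient", "inpatient", "emergency")
DISCHARGE_TYPES = ("home", "snf", "expired")


@dataclass(frozen=True)
class Event:
    """A single coded clinical event.

    ``value`` is the continuous measurement result and is only set for
    lab events.  ``date`` is the event timestamp; events inherit their
    visit's date when no finer timestamp exists.
    """

    domain: str
    code: str
    date: dt.date
    value: float | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown event domain: {self.domain!r}")


@dataclass
class Visit:
    visit_id: int
    date: dt.date
    visit_type: str = "outpatient"
    discharge: str | None = None
    events: list[Event] = field(default_factory=list)

    def codes(self, domain: str | None = None) -> list[str]:
        return [e.code for e in self.events if domain is None or e.domain == domain]


@dataclass
class PatientRecord:
    person_id: int
    sex: str
    birth_year: int
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        dates = [v.date for v in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"person {self.person_id}: visit dates must be strictly increasing"
            )

    @property
    def first_visit_date(self) -> dt.date:
        return self.visits[0].date

    def age_at_first_visit(self) -> int:
        return self.first_visit_date.year - self.birth_year

    def has_code(self, domain: str, code: str) -> bool:
        return any(e.domain == domain and e.code == code for v in self.visits for e in v.events)

    def first_occurrence(self, domain: str, code: str) -> dt.date | None:
        """Date of the first visit containing ``code`` in ``domain``."""
        for v in self.visits:
            if any(e.domain == domain and e.code == code for e in v.events):
                return v.date
        return None
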