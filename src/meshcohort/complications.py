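"""Peri-procedural complication detection, 30-day readmission taxonomy, and
long-term mesh-related event extraction.

Conventions (the readmission clock):

* the clock starts at the *discharge* date of the index spell — a readmission
  cannot overlap the index stay;
* the 30-day window covers days 1–30 inclusive;
* a 30-day readmission is a COMPLICATION when its primary diagnosis is a
  complication code, or is qualified by one (a qualifier-section code later in
  the same episode's diagnosis list);
* long-term complications are admissions with a genitourinary-device
  complication diagnosis (T83 section) or any diagnosis qualified by an
  adverse-device-incident code (Y73 section);
* further mesh surgery is sub-typed removal / repair / insertion / renewal
  from procedure codes; a further-surgery admission already counted as a
  30-day complication is not emitted again (no double counting);
* several qualifying codes in one admission collapse to one event per kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .codesets import CodeRegistry
from .cohort import Spell

WITHIN_30D = "WITHIN_30D"
LONG_TERM = "LONG_TERM"

COMPLICATION = "COMPLICATION"
FURTHER_SURGERY = "FURTHER_SURGERY"
ROUTINE = "ROUTINE"

#: subtype priority when one admission carries several surgery codes
_SURGERY_SUBTYPES = (
    ("REMOVAL", "mesh_removal"),
    ("REPAIR", "mesh_repair"),
    ("RENEWAL", "mesh_renewal"),
    ("INSERTION", "mesh_insertion"),
)

ATTRIBUTION_CLASSES = ("PROCEDURAL", "DEVICE", "URINARY", "OTHER")


@dataclass(frozen=True)
class FollowUpEvent:
    patient_id: str
    admission_date: pd.Timestamp
    days_since_index: int
    kind: str                      # COMPLICATION | FURTHER_SURGERY
    surgery_subtype: str | None    # set iff kind == FURTHER_SURGERY
    window: str                    # WITHIN_30D | LONG_TERM

    def __post_init__(self):
        if (self.kind == FURTHER_SURGERY) != (self.surgery_subtype is not None):
            raise ValueError("surgery_subtype set iff kind is FURTHER_SURGERY")
        if self.days_since_index < 0:
            raise ValueError("events cannot precede the index discharge")


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: int                 # days from index discharge
    event: bool
    censor_cause: str         # none | study_end | death

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(
                f"negative follow-up time for {self.patient_id}")
        if self.event and self.censor_cause != "none":
            raise ValueError("observed events carry no censoring cause")


def detect_periproc(index_spell: Spell,
                    registry: CodeRegistry) -> frozenset[str] | None:
    """Attribution classes of any in-spell complication coding, or None.

    A spell may carry several classes (class percentages can sum past 100).
    Codes without a configured attribution fall into OTHER.
    """
    cs = registry["periproc_complication"]
    classes = set()
    for c in index_spell.all_diagnoses:
        if cs.matches_value(c):
            classes.add(cs.attribution_for(c) or "OTHER")
    return frozenset(classes) if classes else None


def _primary_qualified(spell: Spell, registry: CodeRegistry,
                       qualifier_set: str) -> bool:
    """True if a qualifier-section code follows the primary diagnosis within
    the same episode's diagnosis list."""
    for diags in spell.episode_diagnoses:
        for c in diags[1:]:
            if registry.matches(qualifier_set, c):
                return True
    return False


def _surgery_subtype(spell: Spell, registry: CodeRegistry) -> str | None:
    for subtype, set_name in _SURGERY_SUBTYPES:
        if spell.has_any(registry, set_name):
            return subtype
    return None


def classify_30day(spell: Spell, registry: CodeRegistry) -> set[str]:
    """Labels for one readmission spell within 30 days of index discharge.

    Returns a subset of {COMPLICATION, FURTHER_SURGERY}, or {ROUTINE}; one
    spell may be both a complication and further surgery.
    """
    labels: set[str] = set()
    primary = spell.primary_diagnosis
    if primary is not None and (
            registry.matches("thirty_day_complication", primary)
            or _primary_qualified(spell, registry, "complication_qualifiers")):
        labels.add(COMPLICATION)
    if _surgery_subtype(spell, registry) is not None:
        labels.add(FURTHER_SURGERY)
    return labels or {ROUTINE}


def _longterm_complication(spell: Spell, registry: CodeRegistry) -> bool:
    return (spell.has_any(registry, "longterm_complication", procedures=False)
            or _primary_qualified(spell, registry, "longterm_qualifiers"))


def extract_followup_events(
    spells: list[Spell],
    index_spell: Spell,
    registry: CodeRegistry,
) -> list[FollowUpEvent]:
    """All mesh-related readmission events after the index discharge.

    Spells in days 1–30 follow the 30-day taxonomy; later spells follow the
    long-term rules.  A further-surgery admission that was already counted as
    a 30-day complication is suppressed to avoid double counting.
    """
    events: list[FollowUpEvent] = []
    for s in spells:
        days = int((s.admission_date - index_spell.discharge_date).days)
        if days < 1:
            continue
        window = WITHIN_30D if days <= 30 else LONG_TERM
        if window == WITHIN_30D:
            labels = classify_30day(s, registry)
            if COMPLICATION in labels:
                events.append(FollowUpEvent(
                    s.patient_id, s.admission_date, days, COMPLICATION,
                    None, window))
                # double-counting rule: its surgery is not emitted again
                continue
            if FURTHER_SURGERY in labels:
                events.append(FollowUpEvent(
                    s.patient_id, s.admission_date, days, FURTHER_SURGERY,
                    _surgery_subtype(s, registry), window))
        else:
            if _longterm_complication(s, registry):
                events.append(FollowUpEvent(
                    s.patient_id, s.admission_date, days, COMPLICATION,
                    None, window))
            subtype = _surgery_subtype(s, registry)
            if subtype is not None:
                events.append(FollowUpEvent(
                    s.patient_id, s.admission_date, days, FURTHER_SURGERY,
                    subtype, window))
    return events


def extract_longterm(
    spells: list[Spell],
    index_spell: Spell,
    registry: CodeRegistry,
) -> list[FollowUpEvent]:
    """Long-term (after day 30) mesh-related events only.

    The 30-day taxonomy is still evaluated internally so the double-counting
    suppression behaves identically to :func:`extract_followup_events`.
    """
    return [e for e in extract_followup_events(spells, index_spell, registry)
            if e.window == LONG_TERM]


def first_event_time(
    events: list[FollowUpEvent],
    index_spell: Spell,
    study_end: date,
    death_date: pd.Timestamp | None = None,
) -> SurvivalRecord:
    """Time to first mesh-related readmission, censored at study end or death."""
    pid = index_spell.patient_id
    if events:
        t = min(e.days_since_index for e in events)
        return SurvivalRecord(pid, t, True, "none")
    end = pd.Timestamp(study_end)
    if death_date is not None and death_date <= end:
        t = int((pd.Timestamp(death_date) - index_spell.discharge_date).days)
        return SurvivalRecord(pid, t, False, "death")
    t = int((end - index_spell.discharge_date).days)
    return SurvivalRecord(pid, max(t, 0), False, "study_end")


def events_frame(events: list[FollowUpEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.patient_id, e.admission_date, e.days_since_index, e.kind,
          e.surgery_subtype or "", e.window) for e in events],
        columns=["patient_id", "admission_date", "days_since_index",
                 "kind", "surgery_subtype", "window"])


def survival_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.time, r.event, r.censor_cause) for r in records],
        columns=["patient_id", "time", "event", "censor_cause"])
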