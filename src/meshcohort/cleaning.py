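"""Deduplication and exclusion rules with an auditable attrition trail.

Rules applied, in order:

1. exact-duplicate removal, keyed on the full administrative field tuple
   (patient, admission date & method, discharge date, destination & method,
   hospital, sex, age and all diagnosis/procedure codes — episode start/end
   dates are deliberately not part of the key);
2. patient-level removal where any admission is not coded female;
3. patient-level removal where age is missing or under 18;
4. episode-level removal of invalid or missing admission method;
5. episode-level removal of missing admission date;
6. episode-level removal of episodes admitted after a recorded in-hospital
   death (death date taken as the discharge date of the earliest episode
   whose discharge method codes death).

Every run logs, per rule, episodes removed and patients fully removed, and
the identity episodes_in − Σ removals == episodes_out is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .synthetic import (
    DIAG_COLS,
    DISMETH_DIED,
    OPERTN_COLS,
    SEX_FEMALE,
)

#: the exact-duplicate key (administrative fields + all clinical codes)
DEDUP_KEY = (
    ["patient_id", "admidate", "admimeth", "disdate", "disdest", "dismeth",
     "procode", "sex", "age"] + DIAG_COLS + OPERTN_COLS
)

#: admission-method codes accepted as valid (HES admimeth dictionary)
VALID_ADMIMETH = {
    "11", "12", "13",
    "21", "22", "23", "24", "25", "28", "2A", "2B", "2C", "2D",
    "31", "32", "81", "82", "83",
}

ELECTIVE_ADMIMETH = {"11", "12", "13"}


@dataclass
class AttritionEntry:
    rule: str
    episodes_removed: int
    patients_removed: int


@dataclass
class AttritionLog:
    """Ordered record of what each cleaning rule removed."""

    entries: list[AttritionEntry] = field(default_factory=list)

    def add(self, rule: str, episodes_removed: int, patients_removed: int) -> None:
        self.entries.append(
            AttritionEntry(rule, int(episodes_removed), int(patients_removed)))

    @property
    def total_episodes_removed(self) -> int:
        return sum(e.episodes_removed for e in self.entries)

    def verify(self, n_in: int, n_out: int) -> None:
        if n_in - self.total_episodes_removed != n_out:
            raise AssertionError(
                f"attrition identity violated: {n_in} in − "
                f"{self.total_episodes_removed} removed != {n_out} out")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.rule, e.episodes_removed, e.patients_removed)
             for e in self.entries],
            columns=["rule", "episodes_removed", "patients_removed"])

    def __str__(self) -> str:
        lines = ["Attrition log:"]
        for e in self.entries:
            lines.append(f"  {e.rule}: -{e.episodes_removed} episodes"
                         f" ({e.patients_removed} patients fully removed)")
        lines.append(f"  total removed: {self.total_episodes_removed}")
        return "\n".join(lines)


def _patients_lost(before: pd.DataFrame, after: pd.DataFrame) -> int:
    return len(set(before["patient_id"]) - set(after["patient_id"]))


def deduplicate(episodes: pd.DataFrame) -> tuple[pd.DataFrame, AttritionEntry]:
    """Drop exact duplicates on the full field tuple, keeping first occurrence."""
    keep = ~episodes.duplicated(subset=DEDUP_KEY, keep="first")
    out = episodes[keep].reset_index(drop=True)
    entry = AttritionEntry("exact_duplicates", int((~keep).sum()),
                           _patients_lost(episodes, out))
    return out, entry


def apply_exclusions(episodes: pd.DataFrame) -> tuple[pd.DataFrame, AttritionLog]:
    """Apply the demographic and validity exclusions to deduplicated episodes."""
    log = AttritionLog()
    n_in = len(episodes)
    df = episodes

    # patients with any admission not coded female
    bad = set(df.loc[df["sex"] != SEX_FEMALE, "patient_id"])
    nxt = df[~df["patient_id"].isin(bad)].reset_index(drop=True)
    log.add("sex_not_female", len(df) - len(nxt), len(bad))
    df = nxt

    # patients with age missing or under 18
    age = pd.to_numeric(df["age"], errors="coerce")
    bad = set(df.loc[age.isna() | (age < 18), "patient_id"])
    nxt = df[~df["patient_id"].isin(bad)].reset_index(drop=True)
    log.add("age_missing_or_under_18", len(df) - len(nxt), len(bad))
    df = nxt

    # episodes with invalid or missing admission method
    keep = df["admimeth"].isin(VALID_ADMIMETH)
    nxt = df[keep].reset_index(drop=True)
    log.add("invalid_admission_method", int((~keep).sum()),
            _patients_lost(df, nxt))
    df = nxt

    # episodes with missing admission date
    keep = df["admidate"].notna()
    nxt = df[keep].reset_index(drop=True)
    log.add("missing_admission_date", int((~keep).sum()),
            _patients_lost(df, nxt))
    df = nxt

    # episodes admitted after recorded in-hospital death
    died = df[df["dismeth"] == DISMETH_DIED]
    if len(died):
        death_date = died.groupby("patient_id")["disdate"].min()
        dd = df["patient_id"].map(death_date)
        keep = dd.isna() | (df["admidate"] <= dd)
        nxt = df[keep].reset_index(drop=True)
        log.add("episodes_after_death", int((~keep).sum()),
                _patients_lost(df, nxt))
        df = nxt
    else:
        log.add("episodes_after_death", 0, 0)

    log.verify(n_in, len(df))
    return df, log


def clean(episodes: pd.DataFrame) -> tuple[pd.DataFrame, AttritionLog]:
    """Full cleaning pass: deduplicate, then apply all exclusion rules."""
    n_in = len(episodes)
    df, dup_entry = deduplicate(episodes)
    df, log = apply_exclusions(df)
    log.entries.insert(0, dup_entry)
    log.verify(n_in, len(df))
    return df, log
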