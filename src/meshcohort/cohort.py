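"""Spell construction, index-spell selection and cohort classification.

A *spell* is one hospital admission: the contiguous episodes sharing a
patient, admission date and hospital.  The *index spell* is the earliest
in-window admission containing a first-time mesh-insertion procedure code,
with no disqualifying concomitant codes (pelvic organ prolapse surgery, mesh
repair/removal/renewal) and no earlier mesh-surgery admission; it must carry
a coded or implied diagnosis of urinary incontinence.

Patients whose index spell contains only concomitant procedures judged
unlikely to affect outcomes (or rescue procedures, or the endoscopy /
catheterisation descriptors) form the *unconfounded* cohort; the rest are
*confounded*.  Insertion of two distinct mesh types in one spell is a
*combination* procedure and is always treated as confounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .cleaning import ELECTIVE_ADMIMETH
from .codesets import CodeRegistry, normalize_code, CodeFormatError, ICD10, OPCS4
from .synthetic import DIAG_COLS, DISMETH_DIED, OPERTN_COLS

MESH_TYPE_BY_CODE = {"M533": "TVT", "M536": "TOT", "M521": "SS"}

EXCLUDED_NONE = "none"
EXCLUDED_NO_DIAGNOSIS = "no_incontinence_diagnosis"
EXCLUDED_PRIOR = "prior_or_concomitant_mesh_surgery"
EXCLUDED_NO_INSERTION = "no_mesh_insertion_spell"

_MESH_SURGERY_SETS = ("mesh_insertion", "mesh_repair", "mesh_removal",
                      "mesh_renewal")
_DISQUALIFYING_SETS = ("pop_surgery", "mesh_repair", "mesh_removal",
                       "mesh_renewal")
_BENIGN_SETS = ("benign_concomitant", "rescue_procedures", "endoscopy",
                "catheterisation")


def _row_code_lists(df: pd.DataFrame, cols: list[str],
                    scheme: str) -> list[list[str]]:
    """Per-row normalised code lists from the wide code columns; unusable
    code positions are skipped, not fatal."""
    arr = df[cols].to_numpy(dtype=object)
    out: list[list[str]] = []
    for row in arr:
        lst = []
        for v in row:
            if isinstance(v, str) and v:
                try:
                    lst.append(normalize_code(v, scheme).value)
                except CodeFormatError:
                    continue
        out.append(lst)
    return out


@dataclass
class Spell:
    """One hospital admission (>=1 contiguous episodes)."""

    patient_id: str
    admission_date: pd.Timestamp
    discharge_date: pd.Timestamp
    hospital_id: str
    n_episodes: int
    all_procedures: list[str]
    all_diagnoses: list[str]
    episode_diagnoses: list[list[str]] = field(default_factory=list)
    is_elective: bool = False
    died: bool = False
    age: float | None = None

    @property
    def primary_diagnosis(self) -> str | None:
        first = self.episode_diagnoses[0] if self.episode_diagnoses else []
        return first[0] if first else None

    @property
    def length_of_stay(self) -> int:
        return int((self.discharge_date - self.admission_date).days)

    def has_any(self, registry: CodeRegistry, set_name: str,
                procedures: bool = True) -> bool:
        codes = self.all_procedures if procedures else self.all_diagnoses
        return any(registry.matches(set_name, c) for c in codes)


def build_all_spells(episodes: pd.DataFrame) -> dict[str, list[Spell]]:
    """Group a cleaned episode table into spells for every patient at once.

    Spell key is (patient, admission date, hospital); episodes are ordered by
    episode start within each spell.  One pass over the sorted table.
    """
    out: dict[str, list[Spell]] = {}
    if episodes.empty:
        return out
    df = episodes.sort_values(
        ["patient_id", "admidate", "procode", "epistart"],
        kind="stable").reset_index(drop=True)
    procs = _row_code_lists(df, OPERTN_COLS, OPCS4)
    diags = _row_code_lists(df, DIAG_COLS, ICD10)
    pid = df["patient_id"].astype(str).to_numpy()
    adm = df["admidate"].to_numpy()
    hosp = df["procode"].astype(str).to_numpy()
    dis = df["disdate"].to_numpy()
    admim = df["admimeth"].astype(str).to_numpy()
    dmeth = df["dismeth"].astype(str).to_numpy()
    age = df["age"].to_numpy()

    n = len(df)
    i = 0
    while i < n:
        j = i + 1
        while (j < n and pid[j] == pid[i] and adm[j] == adm[i]
               and hosp[j] == hosp[i]):
            j += 1
        all_p: list[str] = []
        all_d: list[str] = []
        ep_d: list[list[str]] = []
        for k in range(i, j):
            all_p.extend(procs[k])
            all_d.extend(diags[k])
            ep_d.append(diags[k])
        out.setdefault(pid[i], []).append(Spell(
            patient_id=pid[i],
            admission_date=pd.Timestamp(adm[i]),
            discharge_date=pd.Timestamp(max(dis[i:j])),
            hospital_id=hosp[i],
            n_episodes=j - i,
            all_procedures=all_p,
            all_diagnoses=all_d,
            episode_diagnoses=ep_d,
            is_elective=admim[i] in ELECTIVE_ADMIMETH,
            died=any(dmeth[k] == DISMETH_DIED for k in range(i, j)),
            age=float(age[i]) if pd.notna(age[i]) else None,
        ))
        i = j
    return out


def build_spells(episodes: pd.DataFrame) -> list[Spell]:
    """Group one patient's cleaned episodes into spells.

    Overlapping admissions at different hospitals are kept as separate
    spells with a warning.
    """
    grouped = build_all_spells(episodes)
    if len(grouped) > 1:
        raise ValueError("build_spells expects episodes of a single patient; "
                         "use build_all_spells for a full table")
    spells = next(iter(grouped.values()), [])
    for a, b in zip(spells, spells[1:]):
        if b.admission_date <= a.discharge_date and b.hospital_id != a.hospital_id:
            warnings.warn(
                f"patient {a.patient_id}: overlapping admissions at "
                f"{a.hospital_id} and {b.hospital_id}; kept separate",
                stacklevel=2)
    return spells


def find_index_spell(
    spells: list[Spell],
    registry: CodeRegistry,
    study_start: date | pd.Timestamp,
    study_end: date | pd.Timestamp,
) -> tuple[Spell | None, str]:
    """Select the patient's index spell, or explain the exclusion.

    Returns (spell, "none") on success, else (None, reason).
    """
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)

    def has_insertion(s: Spell) -> bool:
        return s.has_any(registry, "mesh_insertion")

    def disqualified(s: Spell) -> bool:
        return any(s.has_any(registry, name) for name in _DISQUALIFYING_SETS)

    def mesh_surgery(s: Spell) -> bool:
        return any(s.has_any(registry, name) for name in _MESH_SURGERY_SETS)

    in_window = [s for s in spells
                 if start <= s.admission_date <= end and has_insertion(s)]
    if not any(has_insertion(s) for s in spells) or not in_window:
        return None, EXCLUDED_NO_INSERTION

    candidates = [s for s in in_window if not disqualified(s)]
    if not candidates:
        # only insertions with concomitant POP / mesh-revision surgery
        return None, EXCLUDED_PRIOR
    cand = candidates[0]
    if any(mesh_surgery(s) for s in spells
           if s.admission_date < cand.admission_date):
        return None, EXCLUDED_PRIOR

    has_diagnosis = any(
        registry.matches("incontinence_diagnosis", c)
        or registry.matches("implied_incontinence", c)
        for c in cand.all_diagnoses)
    if not has_diagnosis:
        return None, EXCLUDED_NO_DIAGNOSIS
    return cand, EXCLUDED_NONE


def classify_mesh_type(index_spell: Spell, registry: CodeRegistry) -> str:
    """TVT / TOT / SS from the insertion code; two distinct codes -> COMBINATION."""
    present = sorted({c for c in index_spell.all_procedures
                      if registry.matches("mesh_insertion", c)})
    if not present:
        raise ValueError("index spell contains no mesh-insertion code")
    if len(present) >= 2:
        return "COMBINATION"
    return MESH_TYPE_BY_CODE.get(present[0], present[0])


def classify_confounding(index_spell: Spell, registry: CodeRegistry,
                         mesh_type: str | None = None) -> str:
    """UNCONFOUNDED iff every non-insertion procedure is benign, rescue, or an
    endoscopy/catheterisation descriptor; combination meshes are always
    CONFOUNDED."""
    if mesh_type is None:
        mesh_type = classify_mesh_type(index_spell, registry)
    if mesh_type == "COMBINATION":
        return "CONFOUNDED"
    for c in index_spell.all_procedures:
        if registry.matches("mesh_insertion", c):
            continue
        if any(registry.matches(name, c) for name in _BENIGN_SETS):
            continue
        return "CONFOUNDED"
    return "UNCONFOUNDED"


def index_descriptors(index_spell: Spell, registry: CodeRegistry) -> dict:
    """Descriptor flags reported per index admission."""
    return {
        "endoscopy": index_spell.has_any(registry, "endoscopy"),
        "catheterisation": index_spell.has_any(registry, "catheterisation"),
        "elective": index_spell.is_elective,
        "length_of_stay": index_spell.length_of_stay,
        "age_at_index": index_spell.age,
        "died_in_index": index_spell.died,
        "hospital_id": index_spell.hospital_id,
    }


ASSIGNMENT_COLS = [
    "patient_id", "index_admidate", "index_disdate", "mesh_type", "cohort",
    "excluded_reason", "age_at_index", "elective", "endoscopy",
    "catheterisation", "length_of_stay", "died_in_index", "hospital_id",
]


def assign_cohorts(
    episodes: pd.DataFrame,
    registry: CodeRegistry,
    study_start: date,
    study_end: date,
) -> tuple[pd.DataFrame, dict[str, list[Spell]]]:
    """Per-patient cohort assignment over a cleaned episode table.

    Returns (assignments, spells_by_patient); excluded patients appear in the
    assignments frame with their exclusion reason and empty classification.
    """
    records = []
    spells_by_patient = build_all_spells(episodes)
    for pid in sorted(spells_by_patient):
        spells = spells_by_patient[pid]
        index_spell, reason = find_index_spell(
            spells, registry, study_start, study_end)
        rec = {c: None for c in ASSIGNMENT_COLS}
        rec["patient_id"] = str(pid)
        rec["excluded_reason"] = reason
        if index_spell is not None:
            mesh = classify_mesh_type(index_spell, registry)
            rec.update(
                index_admidate=index_spell.admission_date,
                index_disdate=index_spell.discharge_date,
                mesh_type=mesh,
                cohort=classify_confounding(index_spell, registry, mesh),
            )
            desc = index_descriptors(index_spell, registry)
            rec.update(
                age_at_index=desc["age_at_index"],
                elective=desc["elective"],
                endoscopy=desc["endoscopy"],
                catheterisation=desc["catheterisation"],
                length_of_stay=desc["length_of_stay"],
                died_in_index=desc["died_in_index"],
                hospital_id=desc["hospital_id"],
            )
        records.append(rec)
    return pd.DataFrame(records, columns=ASSIGNMENT_COLS), spells_by_patient
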