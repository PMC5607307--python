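"""Hand-built episode rows and an independent brute-force phenotyping oracle.

The oracle deliberately re-implements spell grouping and index-spell
selection with plain string/set logic mirroring the shipped default code
configuration, so it shares no code with the package implementation.
"""

from __future__ import annotations

import pandas as pd

from meshcohort.synthetic import COLUMNS, DIAG_COLS, OPERTN_COLS


def ep(pid="P1", admidate="2010-01-01", disdate=None, epistart=None,
       epiend=None, admimeth="11", dismeth="1", disdest="19", procode="H001",
       sex="2", age=50.0, procs=(), diags=()):
    """One wide episode row with sensible defaults."""
    row = {c: "" for c in COLUMNS}
    disdate = disdate or admidate
    row.update(
        patient_id=pid,
        admidate=pd.Timestamp(admidate) if admidate else pd.NaT,
        disdate=pd.Timestamp(disdate),
        epistart=pd.Timestamp(epistart or admidate or disdate),
        epiend=pd.Timestamp(epiend or disdate),
        admimeth=admimeth, dismeth=dismeth, disdest=disdest,
        procode=procode, sex=sex, age=age,
    )
    for i, c in enumerate(procs):
        row[OPERTN_COLS[i]] = c
    for i, c in enumerate(diags):
        row[DIAG_COLS[i]] = c
    return row


def frame(*rows) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=COLUMNS)
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# brute-force oracle (default configuration, hardcoded)

INSERTION = {"M533", "M536", "M521"}
POP = {"P242", "P245", "P246", "P236", "P237", "Q544", "Q545", "Q546"}
REVISION = {"M537", "M538", "M539"}           # removal / repair / renewal
SUI_EXACT = {"N393", "N394"}
IMPLIED = {"T831", "T834", "T835", "T836", "T838", "T839", "Z466"}
CATH = {"M302", "M382", "M471", "M474", "M478", "M479", "M481"}
BENIGN_PREFIX = ("Q55", "M73", "M45", "M77")  # benign, rescue, endoscopy


def brute_spells(rows: list[dict]) -> list[dict]:
    """Group raw rows into spells on (admidate, hospital); one patient."""
    groups: dict[tuple, list[dict]] = {}
    for r in rows:
        groups.setdefault((r["admidate"], r["procode"]), []).append(r)
    spells = []
    for (adm, hosp), grp in sorted(groups.items(),
                                   key=lambda kv: (kv[0][0], kv[0][1])):
        grp = sorted(grp, key=lambda r: r["epistart"])
        procs = [r[c] for r in grp for c in OPERTN_COLS if r[c]]
        diags = [r[c] for r in grp for c in DIAG_COLS if r[c]]
        spells.append(dict(admidate=adm, hospital=hosp,
                           disdate=max(r["disdate"] for r in grp),
                           n_episodes=len(grp), procs=procs, diags=diags))
    return spells


def brute_index(rows: list[dict], start, end) -> tuple[dict | None, str]:
    """Exhaustive index-spell selection; returns (spell, reason)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    spells = brute_spells(rows)

    def has_insertion(s):
        return any(p in INSERTION for p in s["procs"])

    def disqualified(s):
        return any(p in POP or p in REVISION for p in s["procs"])

    def mesh_surgery(s):
        return any(p in INSERTION or p in REVISION for p in s["procs"])

    in_window = [s for s in spells
                 if start <= s["admidate"] <= end and has_insertion(s)]
    if not in_window:
        return None, "no_mesh_insertion_spell"
    candidates = [s for s in in_window if not disqualified(s)]
    if not candidates:
        return None, "prior_or_concomitant_mesh_surgery"
    cand = min(candidates, key=lambda s: (s["admidate"], s["hospital"]))
    if any(mesh_surgery(s) for s in spells
           if s["admidate"] < cand["admidate"]):
        return None, "prior_or_concomitant_mesh_surgery"
    ok = any(d in SUI_EXACT or d.startswith("R32") or d in IMPLIED
             for d in cand["diags"])
    if not ok:
        return None, "no_incontinence_diagnosis"
    return cand, "none"


def brute_mesh_type(spell: dict) -> str:
    present = sorted({p for p in spell["procs"] if p in INSERTION})
    if len(present) >= 2:
        return "COMBINATION"
    return {"M533": "TVT", "M536": "TOT", "M521": "SS"}[present[0]]


def brute_cohort(spell: dict) -> str:
    if brute_mesh_type(spell) == "COMBINATION":
        return "CONFOUNDED"
    for p in spell["procs"]:
        if p in INSERTION or p in CATH:
            continue
        if any(p.startswith(pre) for pre in BENIGN_PREFIX):
            continue
        return "CONFOUNDED"
    return "UNCONFOUNDED"
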