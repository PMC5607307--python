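"""Spell construction, index-spell selection, cohort classification, and
equivalence with a brute-force phenotyping oracle on random small patients."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from meshcohort import cohort
from meshcohort.synthetic import COLUMNS

from helpers import (
    brute_cohort,
    brute_index,
    brute_mesh_type,
    brute_spells,
    ep,
    frame,
)

START, END = date(2007, 4, 1), date(2015, 3, 31)


class TestBuildSpells:
    def test_single_episode(self):
        spells = cohort.build_spells(frame(ep(procs=("M533",), diags=("N393",))))
        assert len(spells) == 1
        s = spells[0]
        assert s.admission_date == s.discharge_date
        assert s.all_procedures == ["M533"]
        assert s.length_of_stay == 0

    def test_two_abutting_episodes_one_spell(self):
        df = frame(
            ep(admidate="2010-01-01", disdate="2010-01-04",
               epistart="2010-01-01", epiend="2010-01-02",
               procs=("M533",), diags=("N393", "T812")),
            ep(admidate="2010-01-01", disdate="2010-01-04",
               epistart="2010-01-02", epiend="2010-01-04", diags=("N393",)))
        spells = cohort.build_spells(df)
        assert len(spells) == 1
        s = spells[0]
        assert s.n_episodes == 2
        assert s.discharge_date == pd.Timestamp("2010-01-04")
        assert s.episode_diagnoses == [["N393", "T812"], ["N393"]]
        assert s.primary_diagnosis == "N393"

    def test_different_admission_dates_two_spells(self):
        df = frame(ep(admidate="2010-01-01"), ep(admidate="2010-02-01"))
        assert len(cohort.build_spells(df)) == 2

    def test_overlapping_hospitals_warn_but_kept(self):
        df = frame(
            ep(admidate="2010-01-01", disdate="2010-01-05", procode="H001"),
            ep(admidate="2010-01-03", procode="H002"))
        with pytest.warns(UserWarning, match="overlapping"):
            spells = cohort.build_spells(df)
        assert len(spells) == 2


class TestFindIndexSpell:
    def _index(self, df, registry):
        return cohort.find_index_spell(
            cohort.build_spells(df), registry, START, END)

    def test_simple_index(self, registry):
        s, reason = self._index(
            frame(ep(procs=("M533",), diags=("N393",))), registry)
        assert reason == "none" and s is not None

    def test_concomitant_pop_excluded(self, registry):
        s, reason = self._index(
            frame(ep(procs=("M533", "P245"), diags=("N393",))), registry)
        assert s is None
        assert reason == "prior_or_concomitant_mesh_surgery"

    def test_no_incontinence_diagnosis(self, registry):
        s, reason = self._index(
            frame(ep(procs=("M533",), diags=("D259",))), registry)
        assert s is None and reason == "no_incontinence_diagnosis"

    def test_implied_diagnosis_accepted(self, registry):
        s, reason = self._index(
            frame(ep(procs=("M533",), diags=("Z466",))), registry)
        assert reason == "none"

    def test_prior_mesh_surgery_excludes(self, registry):
        df = frame(
            ep(admidate="2008-01-01", procs=("M538",), diags=("N393",)),
            ep(admidate="2010-01-01", procs=("M533",), diags=("N393",)))
        s, reason = self._index(df, registry)
        assert s is None and reason == "prior_or_concomitant_mesh_surgery"

    def test_out_of_window_insertion_not_index(self, registry):
        df = frame(ep(admidate="2006-01-01", procs=("M533",),
                      diags=("N393",)))
        s, reason = self._index(df, registry)
        assert s is None and reason == "no_mesh_insertion_spell"

    def test_earliest_candidate_selected(self, registry):
        df = frame(
            ep(admidate="2012-01-01", procs=("M533",), diags=("N393",)),
            ep(admidate="2010-01-01", procs=("M536",), diags=("N393",)))
        s, reason = self._index(df, registry)
        assert reason == "none"
        assert s.admission_date == pd.Timestamp("2010-01-01")


class TestClassification:
    def _spell(self, registry, procs, diags=("N393",)):
        return cohort.build_spells(frame(ep(procs=procs, diags=diags)))[0]

    @pytest.mark.parametrize("procs, expected", [
        (("M533",), "TVT"),
        (("M536",), "TOT"),
        (("M521",), "SS"),
        (("M533", "M536"), "COMBINATION"),
        (("M521", "M521"), "SS"),        # repetition is not a combination
    ])
    def test_mesh_type(self, registry, procs, expected):
        assert cohort.classify_mesh_type(
            self._spell(registry, procs), registry) == expected

    def test_mesh_type_requires_insertion(self, registry):
        with pytest.raises(ValueError):
            cohort.classify_mesh_type(self._spell(registry, ("M538",)),
                                      registry)

    @pytest.mark.parametrize("procs, expected", [
        (("M533",), "UNCONFOUNDED"),
        (("M533", "Q071"), "CONFOUNDED"),       # hysterectomy confounds
        (("M533", "M536"), "CONFOUNDED"),       # combination forced
        (("M533", "Q551"), "UNCONFOUNDED"),     # benign concomitant
        (("M533", "M731"), "UNCONFOUNDED"),     # rescue procedure
        (("M533", "M451", "M302"), "UNCONFOUNDED"),  # descriptors don't confound
    ])
    def test_confounding(self, registry, procs, expected):
        assert cohort.classify_confounding(
            self._spell(registry, procs), registry) == expected

    def test_descriptors(self, registry):
        s = self._spell(registry, ("M533", "M451", "M302"))
        d = cohort.index_descriptors(s, registry)
        assert d["endoscopy"] and d["catheterisation"]
        assert d["length_of_stay"] == 0 and d["elective"]


def _random_patients(n_cases, seed):
    """Random ≤5-episode patients over a small date/code pool."""
    rng = np.random.default_rng(seed)
    proc_pool = ["", "M533", "M536", "M521", "P245", "M537", "M538",
                 "Q071", "Q551", "M451", "M731", "M302"]
    diag_pool = ["", "N393", "R322", "D259", "T835", "Z466"]
    dates = pd.date_range("2006-06-01", "2015-03-01", freq="ME")
    rows = []
    for i in range(n_cases):
        pid = f"C{i:06d}"
        n_ep = rng.integers(1, 6)
        adm_choices = rng.choice(len(dates), n_ep)
        for k in range(n_ep):
            admidate = dates[adm_choices[k]]
            procs = [p for p in rng.choice(proc_pool, 2) if p]
            diags = [d for d in rng.choice(diag_pool, 2) if d] or ["R104"]
            rows.append(ep(
                pid=pid, admidate=admidate,
                disdate=admidate + pd.Timedelta(days=int(rng.integers(0, 3))),
                epistart=admidate + pd.Timedelta(days=k),  # distinct in-spell
                procode=f"H{rng.integers(0, 2)}",
                procs=tuple(procs), diags=tuple(diags)))
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["age"] = pd.to_numeric(df["age"])
    return df, rows


def test_oracle_equivalence_random_small_patients(registry):
    """Spell grouping and index selection agree with the brute-force
    enumerator across thousands of randomized ≤5-episode patients."""
    df, rows = _random_patients(2000, seed=42)
    assignments, spells_by_patient = cohort.assign_cohorts(
        df, registry, START, END)
    by_pid: dict[str, list[dict]] = {}
    for r in rows:
        by_pid.setdefault(r["patient_id"], []).append(r)

    assignments = assignments.set_index("patient_id")
    for pid, prows in by_pid.items():
        expect_spells = brute_spells(prows)
        got_spells = spells_by_patient[pid]
        assert [(s.admission_date, s.hospital_id, s.n_episodes)
                for s in got_spells] == \
            [(s["admidate"], s["hospital"], s["n_episodes"])
             for s in expect_spells]

        b_spell, b_reason = brute_index(prows, START, END)
        a = assignments.loc[pid]
        assert a["excluded_reason"] == b_reason, pid
        if b_reason == "none":
            assert a["index_admidate"] == b_spell["admidate"]
            assert a["mesh_type"] == brute_mesh_type(b_spell)
            assert a["cohort"] == brute_cohort(b_spell)


def test_partition_invariant(registry):
    """Every non-excluded patient is in exactly one cohort and stratum."""
    df, _ = _random_patients(500, seed=7)
    assignments, _ = cohort.assign_cohorts(df, registry, START, END)
    inc = assignments[assignments["excluded_reason"] == "none"]
    assert inc["cohort"].isin(["UNCONFOUNDED", "CONFOUNDED"]).all()
    assert inc["mesh_type"].isin(
        ["TVT", "TOT", "SS", "COMBINATION"]).all()
    assert len(assignments) == assignments["patient_id"].nunique()
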