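"""Cohort-level report tables and the end-to-end pipeline driver.

Outputs mirror the shape of a national mesh-procedure audit: per-stratum
index-admission descriptors (table 1), the per-patient readmission-count
distribution (table 2), readmission reasons with crude incidence rates and
the five-year event-free percentage (table 3), an attrition flow, and annual
activity counts binned by NHS financial year (April–March).

Every percentage and rate cell is computed directly from the numerator and
denominator cells that accompany it, and :func:`audit_report` re-checks that
identity plus the partition invariants on each run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleaning, cohort, complications, survival
from .codesets import CodeRegistry, load_codesets
from .synthetic import SimulationConfig, generate_cohort

MESH_STRATA = ("TVT", "TOT", "SS", "COMBINATION")


def _median_iqr(x: pd.Series) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation."""
    if len(x) == 0:
        return (np.nan, np.nan, np.nan)
    q = np.percentile(pd.to_numeric(x).dropna(), [25, 50, 75])
    return float(q[1]), float(q[0]), float(q[2])


def _pct(k: int, n: int) -> float:
    return round(100.0 * k / n, 1) if n else 0.0


def table1(assignments: pd.DataFrame) -> pd.DataFrame:
    """Index-admission descriptors per (cohort, mesh type) stratum."""
    rows = []
    inc = assignments[assignments["excluded_reason"] == "none"]
    for coh in ("UNCONFOUNDED", "CONFOUNDED"):
        for mesh in MESH_STRATA:
            g = inc[(inc["cohort"] == coh) & (inc["mesh_type"] == mesh)]
            n = len(g)
            row = {"cohort": coh, "mesh_type": mesh, "patients": n,
                   "empty_stratum": n == 0}
            if n == 0:
                rows.append(row)
                continue
            elect = int(g["elective"].sum())
            endo = int(g["endoscopy"].sum())
            cath = int(g["catheterisation"].sum())
            med, q1, q3 = _median_iqr(g["age_at_index"])
            lmed, lq1, lq3 = _median_iqr(g["length_of_stay"])
            compl = g["periproc_classes"].fillna("") != ""
            ncomp = int(compl.sum())
            row.update(
                elective=elect, elective_pct=_pct(elect, n),
                hospitals=int(g["hospital_id"].nunique()),
                age_median=med, age_q1=q1, age_q3=q3,
                endoscopy=endo, endoscopy_pct=_pct(endo, n),
                catheterisation=cath, catheterisation_pct=_pct(cath, n),
                los_median=lmed, los_q1=lq1, los_q3=lq3,
                deaths=int(g["died_in_index"].sum()),
                complications=ncomp, complications_pct=_pct(ncomp, n),
            )
            for cls in complications.ATTRIBUTION_CLASSES:
                k = int(g["periproc_classes"].fillna("")
                        .str.contains(cls, regex=False).sum())
                row[f"attr_{cls.lower()}"] = k
                row[f"attr_{cls.lower()}_pct"] = _pct(k, ncomp) if ncomp else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def table2(events: pd.DataFrame, assignments: pd.DataFrame,
           cohort_label: str = "UNCONFOUNDED") -> pd.DataFrame:
    """Readmission-count distribution (0/1/2/3+ and maximum) per stratum.

    One readmission = one distinct admission date among a patient's
    mesh-related events (an admission that is both a complication and further
    surgery counts once).
    """
    inc = assignments[(assignments["excluded_reason"] == "none")
                      & (assignments["cohort"] == cohort_label)]
    per_patient = (events.groupby("patient_id")["admission_date"].nunique()
                   if len(events) else pd.Series(dtype=int))
    rows = []
    strata = [m for m in MESH_STRATA
              if (inc["mesh_type"] == m).any()] + ["All"]
    for mesh in strata:
        g = inc if mesh == "All" else inc[inc["mesh_type"] == mesh]
        counts = g["patient_id"].map(per_patient).fillna(0).astype(int)
        n = len(g)
        row = {
            "mesh_type": mesh, "patients": n,
            "readmit_0": int((counts == 0).sum()),
            "readmit_1": int((counts == 1).sum()),
            "readmit_2": int((counts == 2).sum()),
            "readmit_3plus": int((counts >= 3).sum()),
            "max_readmissions": int(counts.max()) if n else 0,
        }
        for k in ("readmit_0", "readmit_1", "readmit_2", "readmit_3plus"):
            row[f"{k}_pct"] = _pct(row[k], n)
        rows.append(row)
    return pd.DataFrame(rows)


def table3(events: pd.DataFrame, surv: pd.DataFrame,
           assignments: pd.DataFrame,
           cohort_label: str = "UNCONFOUNDED") -> pd.DataFrame:
    """Readmission reasons, crude rates and 5-year event-free % per stratum.

    ``surv`` must carry per-patient ``time`` (to first event or censoring),
    ``event``, ``censor_cause`` and ``total_followup_days``.
    """
    inc = assignments[(assignments["excluded_reason"] == "none")
                      & (assignments["cohort"] == cohort_label)]
    surv = surv.merge(inc[["patient_id", "mesh_type"]], on="patient_id")
    ev = events.merge(inc[["patient_id", "mesh_type"]], on="patient_id")

    rows = []
    strata = [m for m in MESH_STRATA
              if (inc["mesh_type"] == m).any()] + ["All"]
    for mesh in strata:
        g = inc if mesh == "All" else inc[inc["mesh_type"] == mesh]
        e = ev if mesh == "All" else ev[ev["mesh_type"] == mesh]
        s = surv if mesh == "All" else surv[surv["mesh_type"] == mesh]
        n = len(g)
        py = survival.person_years(s["total_followup_days"]) if n else 0.0

        surg = e[e["kind"] == complications.FURTHER_SURGERY]
        comp = e[e["kind"] == complications.COMPLICATION]
        spells_any = e.drop_duplicates(["patient_id", "admission_date"])
        row = {
            "mesh_type": mesh, "patients": n,
            "person_years": round(py, 1),
            "deaths": int((s["censor_cause"] == "death").sum()),
            "surgery_total": len(surg),
            "surgery_patients": int(surg["patient_id"].nunique()),
            "complication_total": len(comp),
            "complication_patients": int(comp["patient_id"].nunique()),
            "any_total": len(spells_any),
            "any_patients": int(e["patient_id"].nunique()),
        }
        for sub in ("REMOVAL", "REPAIR", "INSERTION", "RENEWAL"):
            ss = surg[surg["surgery_subtype"] == sub]
            row[f"surgery_{sub.lower()}_total"] = len(ss)
            row[f"surgery_{sub.lower()}_patients"] = int(
                ss["patient_id"].nunique())
        row["surgery_patients_pct"] = _pct(row["surgery_patients"], n)
        row["complication_patients_pct"] = _pct(row["complication_patients"], n)
        row["any_patients_pct"] = _pct(row["any_patients"], n)
        if py > 0:
            row["surgery_rate_per_1000py"] = survival.crude_incidence(
                row["surgery_total"], py).rate_1dp
            row["complication_rate_per_1000py"] = survival.crude_incidence(
                row["complication_total"], py).rate_1dp
            row["any_rate_per_1000py"] = survival.crude_incidence(
                row["any_total"], py).rate_1dp
        if n:
            est = survival.km_fit(s["time"], s["event"])
            t5 = min(5.0, est.max_time / survival.DAYS_PER_YEAR)
            pct, lo, hi = survival.km_free_at(est, t5)
            row["free_5y_pct"] = round(pct, 1)
            row["free_5y_lo"] = round(lo, 1)
            row["free_5y_hi"] = round(hi, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def annual_activity(assignments: pd.DataFrame) -> pd.DataFrame:
    """Index procedures per NHS financial year (April–March) and mesh type."""
    inc = assignments[assignments["excluded_reason"] == "none"].copy()
    ad = pd.to_datetime(inc["index_admidate"])
    fy_start = ad.dt.year - (ad.dt.month < 4).astype(int)
    inc["financial_year"] = (fy_start.astype(str) + "/"
                             + ((fy_start + 1) % 100).astype(str).str.zfill(2))
    out = (inc.groupby(["financial_year", "mesh_type"])
           .size().unstack(fill_value=0))
    out["total"] = out.sum(axis=1)
    return out.reset_index()


def audit_report(bundle: "ReportBundle") -> None:
    """Self-consistency audit: partitions and percentage identities."""
    t2 = bundle.table2
    for _, row in t2.iterrows():
        cells = (row["readmit_0"] + row["readmit_1"] + row["readmit_2"]
                 + row["readmit_3plus"])
        if cells != row["patients"]:
            raise AssertionError(
                f"table2 {row['mesh_type']}: buckets sum {cells} != "
                f"{row['patients']} patients")
        for k in ("readmit_0", "readmit_1", "readmit_2", "readmit_3plus"):
            if row[f"{k}_pct"] != _pct(row[k], row["patients"]):
                raise AssertionError(f"table2 {k} percentage mismatch")
    t1 = bundle.table1
    inc = bundle.assignments[bundle.assignments["excluded_reason"] == "none"]
    if int(t1["patients"].sum()) != len(inc):
        raise AssertionError("table1 strata do not partition the cohort")
    t3 = bundle.table3
    for _, row in t3.iterrows():
        if not (row["any_patients"] <= row["surgery_patients"]
                + row["complication_patients"]):
            raise AssertionError("table3 union bound violated")
    ann = bundle.annual_activity
    if len(ann) and int(ann["total"].sum()) != len(inc):
        raise AssertionError("annual activity does not partition the cohort")


@dataclass
class ReportBundle:
    attrition: pd.DataFrame
    assignments: pd.DataFrame
    events: pd.DataFrame
    survival_records: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    annual_activity: pd.DataFrame
    km_curve: pd.DataFrame
    hazard_curve: pd.DataFrame
    ground_truth: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("attrition", "assignments", "events",
                     "survival_records", "table1", "table2", "table3",
                     "annual_activity", "km_curve", "hazard_curve"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        if self.ground_truth is not None:
            self.ground_truth.to_csv(out / "ground_truth.csv", index=False)


def extract_all_events(
    cleaned: pd.DataFrame,
    assignments: pd.DataFrame,
    spells_by_patient: dict,
    registry: CodeRegistry,
    study_end: date,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Follow-up events, survival records and peri-procedural findings for
    every assigned patient.

    Returns (events, survival_records, assignments-with-periproc); survival
    records carry ``total_followup_days`` (to study end or death, ignoring
    events) for crude-rate denominators.
    """
    end = pd.Timestamp(study_end)
    ev_rows: list[complications.FollowUpEvent] = []
    sr_rows = []
    periproc_col = {}
    for _, a in assignments.iterrows():
        if a["excluded_reason"] != "none":
            continue
        pid = a["patient_id"]
        spells = spells_by_patient[pid]
        index_spell = next(
            s for s in spells
            if s.admission_date == a["index_admidate"]
            and s.hospital_id == a["hospital_id"])
        pp = complications.detect_periproc(index_spell, registry)
        periproc_col[pid] = "|".join(sorted(pp)) if pp else ""

        death_dates = [s.admission_date for s in spells if s.died]
        death = min(death_dates) if death_dates else None

        followups = [s for s in spells
                     if s.admission_date > index_spell.discharge_date]
        events = complications.extract_followup_events(
            followups, index_spell, registry)
        ev_rows.extend(events)
        rec = complications.first_event_time(
            events, index_spell, study_end, death)
        total = int(((death if death is not None else end)
                     - index_spell.discharge_date).days)
        sr_rows.append((rec.patient_id, rec.time, rec.event,
                        rec.censor_cause, max(total, 0)))

    events_df = complications.events_frame(ev_rows)
    surv_df = pd.DataFrame(
        sr_rows, columns=["patient_id", "time", "event", "censor_cause",
                          "total_followup_days"])
    assignments = assignments.copy()
    assignments["periproc_classes"] = assignments["patient_id"].map(
        periproc_col)
    return events_df, surv_df, assignments


def run_pipeline(
    config: SimulationConfig | None = None,
    episodes: pd.DataFrame | None = None,
    registry: CodeRegistry | None = None,
    study_start: date | None = None,
    study_end: date | None = None,
    bandwidth_years: float = 0.5,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """End-to-end run: simulate (or take episodes), clean, assign, extract
    events, estimate survival, and assemble all report tables."""
    if (config is None) == (episodes is None):
        raise ValueError("provide exactly one of config or episodes")
    registry = registry or load_codesets()
    truth = None
    if config is not None:
        episodes, truth = generate_cohort(config)
        study_start = study_start or config.study_start
        study_end = study_end or config.study_end
    if study_start is None or study_end is None:
        raise ValueError("study_start and study_end are required with episodes")

    cleaned, log = cleaning.clean(episodes)
    assignments, spells = cohort.assign_cohorts(
        cleaned, registry, study_start, study_end)
    events, surv, assignments = extract_all_events(
        cleaned, assignments, spells, registry, study_end)

    uncon = assignments[(assignments["excluded_reason"] == "none")
                        & (assignments["cohort"] == "UNCONFOUNDED")]
    s_uncon = surv[surv["patient_id"].isin(uncon["patient_id"])]
    if len(s_uncon):
        km = survival.km_fit(s_uncon["time"], s_uncon["event"])
        km_curve = pd.DataFrame({
            "time_days": km.times, "survival": km.survival,
            "ci_lower": km.ci_lower, "ci_upper": km.ci_upper})
        hz = survival.kernel_hazard(
            s_uncon["time"], s_uncon["event"], bandwidth_years=bandwidth_years)
        hazard_curve = hz.to_frame()
    else:
        km_curve = pd.DataFrame(
            columns=["time_days", "survival", "ci_lower", "ci_upper"])
        hazard_curve = pd.DataFrame(columns=["time_years", "hazard_per_1000py"])

    ev_uncon = events[events["patient_id"].isin(uncon["patient_id"])]
    bundle = ReportBundle(
        attrition=log.to_frame(),
        assignments=assignments,
        events=events,
        survival_records=surv,
        table1=table1(assignments),
        table2=table2(ev_uncon, assignments),
        table3=table3(ev_uncon, surv, assignments),
        annual_activity=annual_activity(assignments),
        km_curve=km_curve,
        hazard_curve=hazard_curve,
        ground_truth=truth,
    )
    audit_report(bundle)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
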