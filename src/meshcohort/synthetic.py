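"""Synthetic HES-like episode tables with known ground truth.

The generator emits one row per finished consultant episode in the admitted-
patient-care schema (wide diagnosis/procedure columns), emulating the features
the downstream pipeline must survive: exact duplicate rows, invalid
demographics, multi-episode admissions, concomitant-procedure mixes,
peri-procedural complication coding, readmissions driven by a configurable
piecewise-constant hazard, in-hospital deaths, and administrative censoring at
the study end date.

Every patient also gets one ground-truth row (index spell, mesh type, cohort
label, uncensored event times, censoring cause) so recovery by the pipeline
can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import integrate

DIAG_COLS = [f"diag_{i:02d}" for i in range(1, 21)]
OPERTN_COLS = [f"opertn_{i:02d}" for i in range(1, 25)]
COLUMNS = [
    "patient_id", "epistart", "epiend", "admidate", "disdate",
    "admimeth", "dismeth", "disdest", "procode", "sex", "age",
] + DIAG_COLS + OPERTN_COLS

DATE_COLS = ["epistart", "epiend", "admidate", "disdate"]

#: HES coding conventions used throughout.
SEX_FEMALE, SEX_MALE = "2", "1"
DISMETH_NORMAL, DISMETH_DIED = "1", "4"
ADMIMETH_ELECTIVE, ADMIMETH_EMERGENCY, ADMIMETH_INVALID = "11", "21", "99"

DAYS_PER_YEAR = 365.25

MESH_CODE = {"TVT": "M533", "TOT": "M536", "SS": "M521"}
SURGERY_CODE = {
    "REMOVAL": "M537", "REPAIR": "M538", "RENEWAL": "M539", "INSERTION": "M533",
}
PERIPROC_CODE = {
    "PROCEDURAL": "T812", "URINARY": "R33", "DEVICE": "T833", "OTHER": "T881",
}


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard in events per person-year.

    ``breaks`` are left interval edges in years (first must be 0); the last
    rate extends to infinity.
    """

    breaks: tuple[float, ...] = (0.0,)
    rates: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.rates) or not self.breaks:
            raise ValueError("breaks and rates must have equal nonzero length")
        if self.breaks[0] != 0.0 or list(self.breaks) != sorted(self.breaks):
            raise ValueError("breaks must be sorted and start at 0")
        if any(r < 0 for r in self.rates):
            raise ValueError("hazard rates must be non-negative")

    @classmethod
    def constant(cls, rate: float) -> "PiecewiseHazard":
        return cls((0.0,), (float(rate),))

    def rate_at(self, t: float) -> float:
        i = np.searchsorted(self.breaks, t, side="right") - 1
        return self.rates[max(i, 0)]

    def cumulative(self, t: float) -> float:
        """Integrated hazard H(t)."""
        if t <= 0:
            return 0.0
        h = 0.0
        for i, (a, r) in enumerate(zip(self.breaks, self.rates)):
            b = self.breaks[i + 1] if i + 1 < len(self.breaks) else math.inf
            if t <= a:
                break
            h += r * (min(t, b) - a)
        return h

    def sample(self, u: np.ndarray) -> np.ndarray:
        """Inverse-transform sampling of event times from uniforms in (0,1).

        Returns np.inf where the target exceeds the total integrable hazard
        (possible when the final rate is 0).
        """
        targets = -np.log1p(-np.asarray(u, dtype=float))
        out = np.full(targets.shape, np.inf)
        edges = list(self.breaks) + [math.inf]
        done = np.zeros(targets.shape, dtype=bool)
        cumh = 0.0
        for i, r in enumerate(self.rates):
            a, b = edges[i], edges[i + 1]
            if r <= 0:
                continue
            top = cumh + r * (b - a) if math.isfinite(b) else math.inf
            hit = ~done & (targets <= top)
            out[hit] = a + (targets[hit] - cumh) / r
            done |= hit
            if math.isinf(top):
                break
            cumh = top
        return out

    def plus(self, other: "PiecewiseHazard") -> "PiecewiseHazard":
        """Pointwise sum of two piecewise hazards."""
        breaks = tuple(sorted(set(self.breaks) | set(other.breaks)))
        rates = tuple(self.rate_at(b) + other.rate_at(b) for b in breaks)
        return PiecewiseHazard(breaks, rates)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the published English national cohort: an 8-year study
    window, mesh-type mix from the printed totals, roughly a quarter of index
    spells confounded by concomitant procedures, a peri-procedural
    complication rate near 2.4%, and mesh-related readmission hazards
    concentrated in the first two years with an overall first-event scale of
    about 16 per 1000 person-years.
    """

    n_patients: int = 1000
    study_start: date = date(2007, 4, 1)
    study_end: date = date(2015, 3, 31)
    p_confounded: float = 0.263
    mesh_type_weights: dict = field(default_factory=lambda: {
        "TVT": 56648 / 92246, "TOT": 34704 / 92246,
        "SS": 834 / 92246, "COMBINATION": 60 / 92246,
    })
    p_elective: float = 0.998
    p_endoscopy: float = 0.25
    p_catheterisation: float = 0.02
    p_periproc_complication: dict = field(default_factory=lambda: {
        "PROCEDURAL": 0.013, "URINARY": 0.007, "DEVICE": 0.0015, "OTHER": 0.003,
    })
    complication_hazard: PiecewiseHazard = PiecewiseHazard((0.0, 2.0), (0.009, 0.004))
    surgery_hazard: PiecewiseHazard = PiecewiseHazard((0.0, 2.0), (0.020, 0.008))
    surgery_subtype_weights: dict = field(default_factory=lambda: {
        "REMOVAL": 0.47, "REPAIR": 0.18, "INSERTION": 0.3485, "RENEWAL": 0.0015,
    })
    p_death_per_year: float = 0.0019
    p_multi_episode: float = 0.08
    p_routine_readmission_30d: float = 0.05
    p_no_sui_diagnosis: float = 0.05
    p_prior_mesh_surgery: float = 0.015
    p_duplicate_row: float = 0.003
    p_invalid_demographics: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for name in ("p_confounded", "p_elective", "p_endoscopy",
                     "p_catheterisation", "p_multi_episode",
                     "p_routine_readmission_30d", "p_no_sui_diagnosis",
                     "p_prior_mesh_surgery", "p_duplicate_row",
                     "p_invalid_demographics"):
            _check_prob(name, getattr(self, name))
        for k, v in self.p_periproc_complication.items():
            _check_prob(f"p_periproc_complication[{k}]", v)
        if self.p_death_per_year < 0:
            raise ValueError("p_death_per_year must be >= 0")

    def clean(self, **overrides) -> "SimulationConfig":
        """A copy with all noise and exclusion-generating rates set to zero
        (every patient then has a recoverable index spell)."""
        base = dict(
            p_duplicate_row=0.0, p_invalid_demographics=0.0,
            p_no_sui_diagnosis=0.0, p_prior_mesh_surgery=0.0,
        )
        base.update(overrides)
        return replace(self, **base)

    @property
    def window_years(self) -> float:
        return (self.study_end - self.study_start).days / DAYS_PER_YEAR

    @property
    def total_hazard(self) -> PiecewiseHazard:
        return self.complication_hazard.plus(self.surgery_hazard)


def _day(t_years: float) -> int:
    """Event time in whole days since index discharge (at least 1)."""
    return max(1, int(round(t_years * DAYS_PER_YEAR)))


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (episode table, ground truth) for the configured cohort.

    Deterministic for a fixed seed.  The episode table's ``attrs`` carry the
    noise counters ``n_injected_duplicates`` and ``n_corrupted_rows``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    if n == 0:
        episodes = pd.DataFrame(columns=COLUMNS)
        episodes.attrs["n_injected_duplicates"] = 0
        episodes.attrs["n_corrupted_rows"] = 0
        return episodes, pd.DataFrame(columns=_TRUTH_COLS)

    window_days = (cfg.study_end - cfg.study_start).days
    mesh_names = list(cfg.mesh_type_weights)
    mesh_p = np.array([cfg.mesh_type_weights[m] for m in mesh_names], float)
    mesh_p = mesh_p / mesh_p.sum()
    sub_names = list(cfg.surgery_subtype_weights)
    sub_p = np.array([cfg.surgery_subtype_weights[s] for s in sub_names], float)
    sub_p = sub_p / sub_p.sum()

    # bulk randomness (one array per decision keeps the per-patient loop lean)
    offs = rng.integers(0, window_days + 1, n)
    mesh_idx = rng.choice(len(mesh_names), n, p=mesh_p)
    confounded = rng.random(n) < cfg.p_confounded
    elective = rng.random(n) < cfg.p_elective
    endoscopy = rng.random(n) < cfg.p_endoscopy
    cath = rng.random(n) < cfg.p_catheterisation
    multiep = rng.random(n) < cfg.p_multi_episode
    benign_draw = rng.random(n)
    ages = np.clip(np.round(rng.normal(51, 10, n)), 18, 90).astype(int)
    hospitals = rng.integers(0, 170, n)
    los_draw = rng.choice([0, 1, 1, 2], n)
    los_conf_extra = rng.choice([0, 1, 1, 2, 3], n)
    periproc_draws = {
        cls: rng.random(n) < p for cls, p in cfg.p_periproc_complication.items()
    }
    no_sui = rng.random(n) < cfg.p_no_sui_diagnosis
    prior_mesh = rng.random(n) < cfg.p_prior_mesh_surgery
    prior_lag = rng.integers(30, 720, n)
    sui_code = rng.choice(
        ["N393", "N393", "N393", "N394", "R32", "Z466"], n)
    t_comp = cfg.complication_hazard.sample(rng.random(n))
    t_surg = cfg.surgery_hazard.sample(rng.random(n))
    sub_idx = rng.choice(len(sub_names), n, p=sub_p)
    comp_primary = rng.random(n) < 0.8   # else complication via qualifier route
    surg_has_comp_diag = rng.random(n) < 0.35
    if cfg.p_death_per_year > 0:
        t_death = rng.exponential(1.0 / cfg.p_death_per_year, n)
    else:
        t_death = np.full(n, np.inf)
    routine = rng.random(n) < cfg.p_routine_readmission_30d
    routine_day = rng.integers(1, 31, n)
    event_los = rng.choice([0, 1, 2], n)

    rows: list[dict] = []
    truth: list[dict] = []

    def blank_row() -> dict:
        return {c: "" for c in COLUMNS}

    def emit(pid, hosp, admidate, disdate, admim, dismeth, age, procs, diags,
             epistart=None, epiend=None):
        r = blank_row()
        r.update(
            patient_id=pid, epistart=epistart or admidate,
            epiend=epiend or disdate, admidate=admidate, disdate=disdate,
            admimeth=admim, dismeth=dismeth,
            disdest="79" if dismeth == DISMETH_DIED else "19",
            procode=hosp, sex=SEX_FEMALE, age=age,
        )
        for j, c in enumerate(procs[: len(OPERTN_COLS)]):
            r[OPERTN_COLS[j]] = c
        for j, c in enumerate(diags[: len(DIAG_COLS)]):
            r[DIAG_COLS[j]] = c
        rows.append(r)

    for i in range(n):
        pid = f"P{i:07d}"
        hosp = f"H{hospitals[i]:03d}"
        mesh = mesh_names[mesh_idx[i]]
        admidate = cfg.study_start + timedelta(days=int(offs[i]))
        los = int(los_draw[i] + (los_conf_extra[i] if confounded[i] else 0))
        los = min(los, (cfg.study_end - admidate).days)
        disdate = admidate + timedelta(days=los)
        admim = ADMIMETH_ELECTIVE if elective[i] else ADMIMETH_EMERGENCY

        if mesh == "COMBINATION":
            procs = ["M533", "M536"]
        else:
            procs = [MESH_CODE[mesh]]
        is_conf = bool(confounded[i]) or mesh == "COMBINATION"
        if confounded[i]:
            procs.append("Q071")
        elif benign_draw[i] < 0.2:
            procs.append("Q551")
        elif benign_draw[i] < 0.3:
            procs.append("M731")
        if endoscopy[i]:
            procs.append("M451")
        if cath[i]:
            procs.append("M302")

        diags = ["D259"] if no_sui[i] else [str(sui_code[i])]
        periproc = [c for c in periproc_draws if periproc_draws[c][i]]
        diags += [PERIPROC_CODE[c] for c in periproc]

        if prior_mesh[i]:
            pad = admidate - timedelta(days=int(prior_lag[i]))
            emit(pid, hosp, pad, pad, ADMIMETH_ELECTIVE, DISMETH_NORMAL,
                 int(ages[i]), ["M538"], ["N393"])

        if multiep[i] and los >= 1:
            mid = admidate + timedelta(days=max(1, los // 2))
            emit(pid, hosp, admidate, disdate, admim, DISMETH_NORMAL,
                 int(ages[i]), procs, diags, epistart=admidate, epiend=mid)
            emit(pid, hosp, admidate, disdate, admim, DISMETH_NORMAL,
                 int(ages[i]), [], diags[:1], epistart=mid, epiend=disdate)
        else:
            emit(pid, hosp, admidate, disdate, admim, DISMETH_NORMAL,
                 int(ages[i]), procs, diags)

        # --- follow-up ---------------------------------------------------
        censor_day = max(0, (cfg.study_end - disdate).days)
        death_day = _day(t_death[i]) if math.isfinite(t_death[i]) else None
        if death_day is not None and death_day > censor_day:
            death_day = None

        comp_day = _day(t_comp[i]) if math.isfinite(t_comp[i]) else None
        surg_day = _day(t_surg[i]) if math.isfinite(t_surg[i]) else None
        if comp_day is not None and surg_day == comp_day:
            surg_day += 1
        subtype = sub_names[sub_idx[i]]

        def _observed(d):
            if d is None or d > censor_day:
                return None
            if death_day is not None and d >= death_day:
                return None
            return d

        comp_obs, surg_obs = _observed(comp_day), _observed(surg_day)
        if comp_obs is not None:
            ad = disdate + timedelta(days=comp_obs)
            dd = ad + timedelta(days=int(event_los[i]))
            if comp_primary[i]:
                ediags = ["T835"]
            else:
                ediags = ["N390", "Y731"]
            emit(pid, hosp, ad, min(dd, cfg.study_end), ADMIMETH_EMERGENCY,
                 DISMETH_NORMAL, int(ages[i]), [], ediags)
        if surg_obs is not None:
            ad = disdate + timedelta(days=surg_obs)
            dd = ad + timedelta(days=int(event_los[i]))
            ediags = ["N393"] + (["T836"] if surg_has_comp_diag[i] else [])
            emit(pid, hosp, ad, min(dd, cfg.study_end), ADMIMETH_ELECTIVE,
                 DISMETH_NORMAL, int(ages[i]), [SURGERY_CODE[subtype]], ediags)

        if routine[i]:
            rd = int(routine_day[i])
            if (_observed(rd) is not None and rd not in (comp_obs, surg_obs)
                    and rd != (death_day or -1)):
                ad = disdate + timedelta(days=rd)
                emit(pid, hosp, ad, ad, ADMIMETH_EMERGENCY, DISMETH_NORMAL,
                     int(ages[i]), [], ["R104"])

        first_obs = min((d for d in (comp_obs, surg_obs) if d is not None),
                        default=None)
        if death_day is not None and (first_obs is None):
            ad = disdate + timedelta(days=death_day)
            emit(pid, hosp, ad, ad, ADMIMETH_EMERGENCY, DISMETH_DIED,
                 int(ages[i]), [], ["I219"])
        elif death_day is not None and first_obs is not None and death_day > first_obs:
            ad = disdate + timedelta(days=death_day)
            emit(pid, hosp, ad, ad, ADMIMETH_EMERGENCY, DISMETH_DIED,
                 int(ages[i]), [], ["I219"])

        if no_sui[i]:
            reason = "no_incontinence_diagnosis"
        elif prior_mesh[i]:
            reason = "prior_or_concomitant_mesh_surgery"
        else:
            reason = "none"
        true_first = min((d for d in (comp_day, surg_day) if d is not None),
                         default=None)
        if comp_obs is not None and (surg_obs is None or comp_obs <= surg_obs):
            kind = "COMPLICATION"
        elif surg_obs is not None:
            kind = "FURTHER_SURGERY"
        else:
            kind = ""
        truth.append(dict(
            patient_id=pid,
            index_admidate=admidate, index_disdate=disdate,
            mesh_type=mesh,
            cohort="CONFOUNDED" if is_conf else "UNCONFOUNDED",
            excluded_reason=reason,
            age=int(ages[i]),
            elective=bool(elective[i]),
            periproc_classes="|".join(periproc),
            true_comp_day=comp_day, true_surg_day=surg_day,
            true_first_event_day=true_first,
            event_day=first_obs,
            event_observed=first_obs is not None,
            first_event_kind=kind,
            censor_day=death_day if (first_obs is None and death_day is not None)
            else censor_day,
            censor_cause=("death" if (first_obs is None and death_day is not None)
                          else "study_end") if first_obs is None else "none",
            death_day=death_day,
        ))

    episodes = pd.DataFrame(rows, columns=COLUMNS)

    # --- noise: corruption then verbatim duplication ---------------------
    n_corrupt = 0
    episodes["age"] = episodes["age"].astype(float)
    if cfg.p_invalid_demographics > 0:
        corrupt_mask = rng.random(len(episodes)) < cfg.p_invalid_demographics
        fields = rng.integers(0, 4, len(episodes))
        for ri in np.nonzero(corrupt_mask)[0]:
            f = fields[ri]
            if f == 0:
                episodes.iat[ri, episodes.columns.get_loc("sex")] = SEX_MALE
            elif f == 1:
                episodes.iat[ri, episodes.columns.get_loc("age")] = np.nan
            elif f == 2:
                episodes.iat[ri, episodes.columns.get_loc("admidate")] = ""
            else:
                episodes.iat[ri, episodes.columns.get_loc("admimeth")] = ADMIMETH_INVALID
            n_corrupt += 1

    n_dup = 0
    if cfg.p_duplicate_row > 0:
        dup_mask = rng.random(len(episodes)) < cfg.p_duplicate_row
        pieces = []
        for ri in range(len(episodes)):
            pieces.append(episodes.iloc[[ri]])
            if dup_mask[ri]:
                pieces.append(episodes.iloc[[ri]])
                n_dup += 1
        episodes = pd.concat(pieces, ignore_index=True)

    for c in DATE_COLS:
        episodes[c] = pd.to_datetime(episodes[c], errors="coerce")
    episodes["age"] = pd.to_numeric(episodes["age"], errors="coerce")

    episodes.attrs["n_injected_duplicates"] = n_dup
    episodes.attrs["n_corrupted_rows"] = n_corrupt

    truth_df = pd.DataFrame(truth, columns=_TRUTH_COLS)
    for c in ("index_admidate", "index_disdate"):
        truth_df[c] = pd.to_datetime(truth_df[c])
    return episodes, truth_df


_TRUTH_COLS = [
    "patient_id", "index_admidate", "index_disdate", "mesh_type", "cohort",
    "excluded_reason", "age", "elective", "periproc_classes",
    "true_comp_day", "true_surg_day", "true_first_event_day",
    "event_day", "event_observed", "first_event_kind",
    "censor_day", "censor_cause", "death_day",
]


# --------------------------------------------------------------------------
# closed-form expectations for the configured event process

def _piece_edges(h: PiecewiseHazard) -> list[tuple[float, float, float]]:
    edges = list(h.breaks) + [math.inf]
    return [(edges[i], edges[i + 1], h.rates[i]) for i in range(len(h.rates))]


def _event_integral(h: PiecewiseHazard, mu: float, c: float) -> float:
    """∫_0^c h(t)·exp(−H(t)−μt) dt, exact per piece."""
    total, cumh = 0.0, 0.0
    for a, b, r in _piece_edges(h):
        if c <= a:
            break
        x = min(c, b)
        lam = r + mu
        sa = math.exp(-cumh - mu * a)
        if lam > 0:
            sx = math.exp(-(cumh + r * (x - a)) - mu * x)
            total += r / lam * (sa - sx)
        cumh += r * (x - a) if math.isfinite(x) else 0.0
        if x == c:
            break
    return total


def _surv_integral(h: PiecewiseHazard, mu: float, c: float) -> float:
    """∫_0^c exp(−H(t)−μt) dt (event- and death-free person-time)."""
    total, cumh = 0.0, 0.0
    for a, b, r in _piece_edges(h):
        if c <= a:
            break
        x = min(c, b)
        lam = r + mu
        sa = math.exp(-cumh - mu * a)
        if lam > 0:
            sx = math.exp(-(cumh + r * (x - a)) - mu * x)
            total += (sa - sx) / lam
        else:
            total += sa * (x - a)
        cumh += r * (x - a)
        if x == c:
            break
    return total


def expected_event_count(config: SimulationConfig) -> float:
    """Expected number of observed first events before censoring.

    Index dates are uniform over the study window, so the administrative
    censoring time is uniform on [0, W] years; in-hospital death acts as a
    competing exponential censoring process.  Only patients who receive an
    index assignment (no exclusion flags) contribute.
    """
    h = config.total_hazard
    mu = config.p_death_per_year
    w = config.window_years
    n_eff = (config.n_patients
             * (1 - config.p_no_sui_diagnosis)
             * (1 - config.p_prior_mesh_surgery))
    if w <= 0 or n_eff == 0:
        return 0.0
    pts = [b for b in h.breaks if 0 < b < w]
    val, _ = integrate.quad(lambda c: _event_integral(h, mu, c), 0, w,
                            points=pts, limit=200)
    return n_eff * val / w


def expected_person_years(config: SimulationConfig) -> float:
    """Expected person-years at risk (to first event, death or study end)."""
    h = config.total_hazard
    mu = config.p_death_per_year
    w = config.window_years
    n_eff = (config.n_patients
             * (1 - config.p_no_sui_diagnosis)
             * (1 - config.p_prior_mesh_surgery))
    if w <= 0 or n_eff == 0:
        return 0.0
    pts = [b for b in h.breaks if 0 < b < w]
    val, _ = integrate.quad(lambda c: _surv_integral(h, mu, c), 0, w,
                            points=pts, limit=200)
    return n_eff * val / w


def write_episodes_csv(episodes: pd.DataFrame, path) -> None:
    out = episodes.copy()
    for c in DATE_COLS:
        out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_episodes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in
                                  ["patient_id", "admimeth", "dismeth",
                                   "disdest", "procode", "sex"]
                                  + DIAG_COLS + OPERTN_COLS},
                     keep_default_na=False, na_values=[""])
    for c in DATE_COLS:
        df[c] = pd.to_datetime(df[c], errors="coerce")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    for c in DIAG_COLS + OPERTN_COLS + ["admimeth", "dismeth", "disdest",
                                        "sex", "procode", "patient_id"]:
        df[c] = df[c].fillna("")
    return df
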