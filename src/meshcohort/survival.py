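"""Person-time, crude incidence, proportion CIs, Kaplan–Meier estimation and
kernel-smoothed hazard rates.

Times are recorded in days and converted to years at 365.25 days/year.
Proportions use Wilson score intervals.  Kaplan–Meier estimation is
delegated to lifelines; Greenwood's variance and a log-scale 95% CI are
derived from the fitted risk table.  The instantaneous hazard is an
Epanechnikov-kernel smoothing of the Nelson–Aalen increments with a
renormalisation boundary correction near 0 and the largest observed time,
reported in events per 1000 person-years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.stats.proportion import proportion_confint

DAYS_PER_YEAR = 365.25
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class IncidenceRate:
    events: int
    person_years: float

    @property
    def rate(self) -> float:
        """Events per 1000 person-years (exact: rate·py/1000 == events)."""
        return 1000.0 * self.events / self.person_years

    @property
    def rate_1dp(self) -> float:
        return round(self.rate, 1)


def person_years(times_days) -> float:
    """Total follow-up in person-years (Σ days / 365.25)."""
    t = np.asarray(times_days, dtype=float)
    if t.size and (t < 0).any():
        raise ValueError("negative follow-up times")
    return float(t.sum() / DAYS_PER_YEAR)


def crude_incidence(n_events: int, py: float) -> IncidenceRate:
    """Crude rate per 1000 person-years."""
    if py <= 0:
        raise ValueError("person-years must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    return IncidenceRate(int(n_events), float(py))


def proportion_ci(k: int, n: int) -> tuple[float, float, float]:
    """Percentage with Wilson score 95% CI: (percent, lower, upper)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("numerator must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return 100.0 * k / n, 100.0 * lo, 100.0 * hi


@dataclass
class KMEstimate:
    """Product-limit survival estimate on the distinct event-time grid.

    Ties are handled by the usual convention that events at t precede
    censorings at t.  CI is on the log-survival scale, clipped to [0, 1].
    """

    times: np.ndarray            # days, including 0
    survival: np.ndarray
    variance: np.ndarray         # Greenwood
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_subjects: int
    max_time: float

    def survival_at(self, t_days: float) -> tuple[float, float, float]:
        """Right-continuous step evaluation: (S(t), lower, upper)."""
        if t_days > self.max_time:
            import warnings
            warnings.warn(
                f"t={t_days} beyond last observed time {self.max_time}; "
                "returning the last estimate", stacklevel=2)
            t_days = self.max_time
        i = int(np.searchsorted(self.times, t_days, side="right") - 1)
        i = max(i, 0)
        return (float(self.survival[i]), float(self.ci_lower[i]),
                float(self.ci_upper[i]))


def km_fit(durations_days, events) -> KMEstimate:
    """Fit the Kaplan–Meier product-limit estimator."""
    durations = np.asarray(durations_days, dtype=float)
    observed = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("at least one record is required")
    if (durations < 0).any():
        raise ValueError("negative durations")
    if not observed.any():
        import warnings
        warnings.warn("no observed events: survival is identically 1",
                      stacklevel=2)

    kmf = KaplanMeierFitter()
    kmf.fit(durations, observed)
    table = kmf.event_table  # index: time; removed/observed/censored/at_risk

    ev = table[table["observed"] > 0]
    times = np.concatenate([[0.0], ev.index.to_numpy(dtype=float)])
    d = ev["observed"].to_numpy(dtype=float)
    y = ev["at_risk"].to_numpy(dtype=float)

    surv = np.concatenate([[1.0], np.cumprod(1.0 - d / y)])
    # Greenwood: Var(S) = S^2 Σ d / (y (y − d))
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(y > d, d / (y * (y - d)), np.inf)
    gsum = np.concatenate([[0.0], np.cumsum(incr)])
    var = surv ** 2 * gsum
    var = np.where(np.isfinite(var), var, 0.0)

    # log-scale CI: exp(log S ± z·se(log S)), se(log S) = se(S)/S
    with np.errstate(divide="ignore", invalid="ignore"):
        se_log = np.where(surv > 0, np.sqrt(var) / surv, 0.0)
        lower = np.where(surv > 0, surv * np.exp(-_Z95 * se_log), 0.0)
        upper = np.where(surv > 0, surv * np.exp(_Z95 * se_log), 0.0)
    lower = np.clip(lower, 0.0, 1.0)
    upper = np.clip(upper, 0.0, 1.0)

    return KMEstimate(
        times=times, survival=surv, variance=var,
        ci_lower=lower, ci_upper=upper,
        n_subjects=int(durations.size),
        max_time=float(durations.max()),
    )


def km_free_at(estimate: KMEstimate, t_years: float) -> tuple[float, float, float]:
    """Percent of patients event-free at *t_years*: (percent, lower, upper)."""
    s, lo, hi = estimate.survival_at(t_years * DAYS_PER_YEAR)
    return 100.0 * s, 100.0 * lo, 100.0 * hi


@dataclass
class HazardEstimate:
    grid_years: np.ndarray
    hazard: np.ndarray           # events per 1000 person-years
    kernel: str
    bandwidth_years: float
    boundary_corrected: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_years": self.grid_years,
                             "hazard_per_1000py": self.hazard})


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u ** 2), 0.0)


def _epanechnikov_mass(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """∫_a^b K(u) du on clipped [-1, 1]."""
    a = np.clip(a, -1.0, 1.0)
    b = np.clip(b, -1.0, 1.0)
    F = lambda u: 0.75 * (u - u ** 3 / 3.0) + 0.5
    return np.maximum(F(b) - F(a), 0.0)


def kernel_hazard(
    durations_days,
    events,
    bandwidth_years: float = 0.5,
    grid_years: np.ndarray | None = None,
    boundary_correction: bool = True,
) -> HazardEstimate:
    """Kernel-smoothed instantaneous hazard, per 1000 person-years.

    ĥ(t) = (1/b) Σ_i K((t − t_i)/b) · d_i / Y(t_i) over distinct event times,
    with the kernel mass renormalised where its support is truncated by the
    observation boundaries (t < b or t > t_max − b).
    """
    if bandwidth_years <= 0:
        raise ValueError("bandwidth must be positive")
    durations = np.asarray(durations_days, dtype=float) / DAYS_PER_YEAR
    observed = np.asarray(events, dtype=bool)
    if grid_years is None:
        grid_years = np.linspace(0.0, 8.0, 161)
    grid = np.asarray(grid_years, dtype=float)

    if durations.size == 0 or not observed.any():
        return HazardEstimate(grid, np.zeros_like(grid), "epanechnikov",
                              bandwidth_years, boundary_correction)

    order = np.argsort(durations)
    t_sorted = durations[order]
    e_sorted = observed[order]
    ev_times, d_counts, at_risk = [], [], []
    n = t_sorted.size
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    for t0, i0 in zip(uniq, first_idx):
        same = t_sorted == t0
        d = int(e_sorted[same].sum())
        if d > 0:
            ev_times.append(t0)
            d_counts.append(d)
            at_risk.append(n - i0)
    ti = np.asarray(ev_times)
    da = np.asarray(d_counts, dtype=float) / np.asarray(at_risk, dtype=float)

    b = float(bandwidth_years)
    tmax = float(t_sorted.max())
    u = (grid[:, None] - ti[None, :]) / b
    h = (_epanechnikov(u) * da[None, :]).sum(axis=1) / b
    if boundary_correction:
        mass = _epanechnikov_mass((grid - tmax) / b, grid / b)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(mass > 0, h / mass, 0.0)
    return HazardEstimate(grid, 1000.0 * h, "epanechnikov",
                          b, boundary_correction)
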