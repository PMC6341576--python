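"""Incidence, baseline characterisation, one-year mortality and survival.

Person-time conventions: one year is 365 days and one month 30.4375 days
(365.25/12) for all rate denominators.  Rate confidence intervals use the
log-normal approximation exp(log r +/- 1.96/sqrt(events)); a zero-event
rate gets the exact upper Poisson bound 3.69/person-time.  The
Kaplan-Meier product-limit estimator is implemented directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LinkageError

__all__ = [
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "RateEstimate",
    "rate_estimate",
    "incidence_rate",
    "survival_records",
    "mortality_summary",
    "KMCurve",
    "km_estimate",
    "baseline_table",
]

DAYS_PER_YEAR = 365.0
DAYS_PER_MONTH = 30.4375

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class RateEstimate:
    """An event rate per ``scale`` units of person-time, with 95% CI."""

    events: int
    person_time: float
    unit: str
    scale: float
    rate: float
    ci_low: float
    ci_high: float


def rate_estimate(events: int, person_time: float, scale: float = 10_000,
                  unit: str = "person-years") -> RateEstimate:
    """Point estimate and log-normal 95% CI for an incidence-type rate."""
    if person_time <= 0:
        raise ValueError("person_time must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    rate = events / person_time * scale
    if events == 0:
        low, high = 0.0, 3.69 / person_time * scale
    else:
        se_log = _Z95 / math.sqrt(events)
        low, high = rate * math.exp(-se_log), rate * math.exp(se_log)
    return RateEstimate(events, person_time, unit, scale, rate, low, high)


def incidence_rate(events: int, person_years: float,
                   scale: float = 10_000) -> RateEstimate:
    """Incident cases per ``scale`` person-years."""
    return rate_estimate(events, person_years, scale, unit="person-years")


# ---------------------------------------------------------------------------
# one-year mortality follow-up

AGE_BANDS_MORTALITY = ((0, 59, "<60"), (60, 69, "60-69"),
                       (70, 79, "70-79"), (80, 200, ">=80"))


def _age_band(age: np.ndarray, bands=AGE_BANDS_MORTALITY) -> np.ndarray:
    out = np.full(len(age), "", dtype=object)
    for lo, hi, label in bands:
        out[(age >= lo) & (age <= hi)] = label
    return out


def survival_records(bundle, cases: pd.DataFrame, study_end=None,
                     horizon_months: float = 12.0) -> pd.DataFrame:
    """Build the one-year mortality follow-up table for the final case set.

    ``cases`` needs ``patient_id`` and ``final_event_date``.  Follow-up
    runs from the final event date to death, data end (registration_end),
    ``study_end`` or ``horizon_months``, whichever is first; ``event`` is
    True when death closes the interval.  Cases whose record ends on or
    before their event date are excluded (no mortality follow-up possible).
    """
    if cases["final_event_date"].isna().any():
        raise LinkageError("case without a final event date")
    pats = bundle.patients.set_index("patient_id")
    missing = set(cases["patient_id"]) - set(pats.index)
    if missing:
        raise LinkageError(f"case(s) absent from patients table: "
                           f"{sorted(missing)[:3]}")
    sub = pats.loc[cases["patient_id"].to_numpy()]
    start = pd.to_datetime(cases["final_event_date"]).to_numpy()
    death = sub["death_date"].to_numpy()
    reg_end = sub["registration_end"].to_numpy()
    far = np.datetime64("2200-01-01")
    death_f = np.where(pd.isna(death), far, death)
    end_cap = np.where(pd.isna(reg_end), far, reg_end)
    if study_end is not None:
        end_cap = np.minimum(end_cap, np.datetime64(pd.Timestamp(study_end)))
    # hour resolution keeps the horizon at exactly horizon_months months
    horizon = start + np.timedelta64(1, "h") * int(
        round(horizon_months * DAYS_PER_MONTH * 24))
    end = np.minimum(np.minimum(death_f, end_cap), horizon)
    event = (death_f <= end_cap) & (death_f <= horizon)
    keep = end > start
    days = (end - start) / np.timedelta64(1, "D")
    age = ((start - sub["birth_date"].to_numpy())
           / np.timedelta64(1, "D") / 365.25).astype(int)
    out = pd.DataFrame({
        "patient_id": cases["patient_id"].to_numpy(),
        "sex": sub["sex"].to_numpy(),
        "age": age,
        "age_band": _age_band(age),
        "time_months": np.minimum(days / DAYS_PER_MONTH, horizon_months),
        "event": event,
    })
    return out[keep].reset_index(drop=True)


def _mortality_row(label: str, grp: pd.DataFrame) -> dict:
    at_risk = len(grp)
    deaths = int(grp["event"].sum())
    pm = float(grp["time_months"].sum())
    row = {"stratum": label, "at_risk": at_risk, "deaths": deaths,
           "person_months": pm}
    if at_risk == 0 or pm <= 0:
        row.update(crude_pct=np.nan, rate_per_100pm=np.nan,
                   ci_low=np.nan, ci_high=np.nan)
        return row
    est = rate_estimate(deaths, pm, scale=100, unit="person-months")
    row.update(crude_pct=100.0 * deaths / at_risk, rate_per_100pm=est.rate,
               ci_low=est.ci_low, ci_high=est.ci_high)
    return row


def mortality_summary(records: pd.DataFrame) -> pd.DataFrame:
    """One-year all-cause mortality: total, by sex, by age band.

    Columns: stratum, at_risk, deaths, crude_pct, person_months,
    rate_per_100pm, ci_low, ci_high (rates per 100 person-months).
    """
    rows = [_mortality_row("total", records)]
    for sex in ("M", "F"):
        rows.append(_mortality_row(sex, records[records["sex"] == sex]))
    for _, _, label in AGE_BANDS_MORTALITY:
        rows.append(_mortality_row(label,
                                   records[records["age_band"] == label]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier product-limit estimator (implemented directly)


@dataclass
class KMCurve:
    """Product-limit survival estimate at each distinct event time."""

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray

    @property
    def median_survival(self) -> float | None:
        """First time survival drops to <= 0.5; None if never reached."""
        hit = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[hit[0]]) if len(hit) else None

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_months": self.times, "n_risk": self.n_risk,
            "n_event": self.n_event, "n_censored": self.n_censored,
            "survival": self.survival,
        })


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate from ``time_months``/``event`` records.

    Ties are handled with the standard convention that subjects censored
    at time t remain at risk for the deaths occurring at t.
    """
    times = np.asarray(records["time_months"], dtype=float)
    events = np.asarray(records["event"], dtype=bool)
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    n = len(times)
    uniq = np.unique(times)
    t_out, r_out, d_out, c_out, s_out = [], [], [], [], []
    surv = 1.0
    at_risk = n
    for t in uniq:
        sel = times == t
        d = int(events[sel].sum())
        c = int((~events[sel]).sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
            t_out.append(t)
            r_out.append(at_risk)
            d_out.append(d)
            c_out.append(c)
            s_out.append(surv)
        at_risk -= d + c
    return KMCurve(np.asarray(t_out), np.asarray(r_out, dtype=int),
                   np.asarray(d_out, dtype=int), np.asarray(c_out, dtype=int),
                   np.asarray(s_out))


# ---------------------------------------------------------------------------
# baseline characterisation

AGE_BANDS_BASELINE = ((0, 49, "<50"), (50, 59, "50-59"), (60, 69, "60-69"),
                      (70, 79, "70-79"), (80, 89, "80-89"), (90, 200, ">=90"))

LIFESTYLE_FACTORS = {
    "smoking": {
        "LIFE_SMOK_NEVER": "never", "LIFE_SMOK_CURRENT": "current",
        "LIFE_SMOK_FORMER": "former",
    },
    "bmi": {
        "LIFE_BMI_15_19": "15-19", "LIFE_BMI_20_24": "20-24",
        "LIFE_BMI_25_29": "25-29", "LIFE_BMI_GE30": ">=30",
    },
    "alcohol": {
        "LIFE_ALC_NONE": "none", "LIFE_ALC_LOW": "1-9",
        "LIFE_ALC_MOD": "10-20", "LIFE_ALC_HIGH": ">20",
    },
}


def baseline_table(bundle, cases: pd.DataFrame,
                   comorbidity_codes: set[str] | None = None,
                   drug_classes: tuple[str, ...] = (
                       "beta2_agonist", "opioid", "ppi", "nsaid",
                       "oral_steroid", "antiplatelet"),
                   ) -> pd.DataFrame:
    """Characterise the case set at diagnosis.

    Rules: lifestyle status is the most recent record on or before the
    diagnosis date ('unknown' if none); a comorbidity counts if ever coded
    before diagnosis; a medication is current when the most recent
    prescription issued on or before diagnosis still had supply running on
    the diagnosis date or ending within the preceding 365 days.

    Returns a long table with columns factor, category, n, pct.
    """
    if cases["final_event_date"].isna().any():
        raise LinkageError("case without a final event date")
    n_cases = len(cases)
    pats = bundle.patients.set_index("patient_id")
    diag = pd.Series(pd.to_datetime(cases["final_event_date"]).to_numpy(),
                     index=cases["patient_id"].to_numpy())

    rows: list[tuple[str, str, int, float]] = []

    def _add(factor: str, counts: dict[str, int]) -> None:
        for cat, k in counts.items():
            rows.append((factor, cat, int(k),
                         100.0 * k / n_cases if n_cases else np.nan))

    sub = pats.loc[diag.index]
    _add("sex", sub["sex"].value_counts().to_dict())
    age = ((diag.to_numpy() - sub["birth_date"].to_numpy())
           / np.timedelta64(1, "D") / 365.25).astype(int)
    _add("age_band", pd.Series(_age_band(age, AGE_BANDS_BASELINE))
         .value_counts().to_dict())

    ev = bundle.events[["patient_id", "event_date", "code"]].merge(
        diag.rename("diag_date"), left_on="patient_id", right_index=True)
    before = ev[ev["event_date"] <= ev["diag_date"]]

    for factor, mapping in LIFESTYLE_FACTORS.items():
        sub_ev = before[before["code"].isin(mapping)]
        latest = (sub_ev.sort_values(["patient_id", "event_date"],
                                     kind="mergesort")
                  .groupby("patient_id")["code"].last())
        cats = latest.map(mapping).reindex(diag.index).fillna("unknown")
        _add(factor, cats.value_counts().to_dict())

    if comorbidity_codes is None:
        comorbidity_codes = {c for c in before["code"].unique()
                             if str(c).startswith("COM_")}
    for code in sorted(comorbidity_codes):
        k = before.loc[before["code"] == code, "patient_id"].nunique()
        _add("comorbidity", {code: k})

    rx = bundle.prescriptions.merge(
        diag.rename("diag_date"), left_on="patient_id", right_index=True)
    rx = rx[rx["issue_date"] <= rx["diag_date"]]
    latest_rx = (rx.sort_values(["patient_id", "issue_date"], kind="mergesort")
                 .groupby(["patient_id", "drug_class"]).last().reset_index())
    supply_end = latest_rx["issue_date"] + pd.to_timedelta(
        latest_rx["supply_days"], unit="D")
    latest_rx = latest_rx.assign(
        current=supply_end >= latest_rx["diag_date"] - pd.Timedelta(days=365))
    for cls in drug_classes:
        k = int(latest_rx.loc[(latest_rx["drug_class"] == cls)
                              & latest_rx["current"], "patient_id"].nunique())
        _add("medication_current", {cls: k})

    return pd.DataFrame(rows, columns=["factor", "category", "n", "pct"])
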