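"""Cohort eligibility, start dates, follow-up intervals and person-time.

A person enters the cohort on the earliest date within the study window at
which all of the following hold: age 18-89 (whole-year age), registration
status permanent or died, at least two years since registration, at least
two years since the first recorded prescription, at least one clinical
event in the preceding two years, and no prior lung-cancer or small-cell
code.  Follow-up runs from that start date to the earliest of the first
qualifying cancer code, death, or the end of the study.

Conventions: "2 years" is exactly 730 days; follow-up is half-open
[start, end), so an index code recorded on the start date itself counts as
an event during follow-up with zero person-time contributed.  Follow-up is
not truncated when a participant later turns 90 — the age band is an entry
criterion.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .codelists import CodeList

__all__ = ["LinkageError", "eligible_cohort", "total_person_years"]

DAYS_PER_YEAR = 365.0


class LinkageError(ValueError):
    """A table row references a patient absent from the patients table."""


_FAR_FUTURE = pd.Timestamp("2200-01-01")


def eligible_cohort(
    bundle,
    study_start: date,
    study_end: date,
    codelists: CodeList,
    *,
    enrolment_days: int = 730,
    prescription_days: int = 730,
    encounter_days: int = 730,
    age_min: int = 18,
    age_max: int = 89,
) -> pd.DataFrame:
    """Apply the eligibility rules and return one follow-up row per entrant.

    Returns a DataFrame with columns ``patient_id, start_date, end_date,
    end_reason, person_days``; patients never eligible are absent.
    """
    if not study_start < study_end:
        raise ValueError("study_start must precede study_end")
    s0, s1 = pd.Timestamp(study_start), pd.Timestamp(study_end)

    pats = bundle.patients
    orphan = set(bundle.events["patient_id"]) - set(pats["patient_id"])
    if orphan:
        raise LinkageError(
            f"events reference patient(s) absent from patients table, "
            f"e.g. {sorted(orphan)[:3]}"
        )

    pats = pats[pats["registration_status"].isin(["permanent", "died"])].copy()
    if pats.empty:
        return _empty_followups()

    first_rx = bundle.prescriptions.groupby("patient_id")["issue_date"].min()
    pats = pats.merge(first_rx.rename("first_rx"), on="patient_id", how="inner")
    if pats.empty:
        return _empty_followups()

    birth = pd.DatetimeIndex(pats["birth_date"])
    adult = birth + pd.DateOffset(years=age_min)
    age_cap = birth + pd.DateOffset(years=age_max + 1)  # exclusive

    base = pd.concat(
        [
            pd.Series(adult, index=pats.index),
            pats["registration_start"] + pd.Timedelta(days=enrolment_days),
            pats["first_rx"] + pd.Timedelta(days=prescription_days),
        ],
        axis=1,
    ).max(axis=1).clip(lower=s0)
    pats = pats.assign(base=base, age_cap=pd.Series(age_cap, index=pats.index))

    ev = bundle.events[["patient_id", "event_date", "code"]].merge(
        pats[["patient_id", "base"]], on="patient_id", how="inner"
    )
    recent = ev[ev["event_date"] >= ev["base"] - pd.Timedelta(days=encounter_days)]
    first_recent = recent.groupby("patient_id")["event_date"].min()

    cancer_codes = codelists.cancer
    cancer = ev[ev["code"].isin(cancer_codes)]
    first_cancer = cancer.groupby("patient_id")["event_date"].min()

    pats = pats.merge(first_recent.rename("first_recent"), on="patient_id", how="inner")
    pats = pats.merge(first_cancer.rename("first_cancer"), on="patient_id", how="left")

    start = pats[["base", "first_recent"]].max(axis=1)
    death = pats["death_date"].fillna(_FAR_FUTURE)
    cancer_date = pats["first_cancer"].fillna(_FAR_FUTURE)

    ok = (
        (start <= s1)
        & (start < pats["age_cap"])
        & (death >= start)
        & ~(cancer_date < start)  # prevalent cancer excludes the patient
    )
    pats, start = pats[ok], start[ok]
    death, cancer_date = death[ok], cancer_date[ok]

    end = pd.concat([cancer_date, death, pd.Series(s1, index=pats.index)], axis=1
                    ).min(axis=1)
    reason = np.where(
        cancer_date <= end, "index_code",
        np.where(death <= end, "death", "study_end"),
    )
    out = pd.DataFrame({
        "patient_id": pats["patient_id"].to_numpy(),
        "start_date": start.to_numpy(),
        "end_date": end.to_numpy(),
        "end_reason": reason,
        "person_days": (end - start).dt.days.to_numpy(),
    })
    return out.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def _empty_followups() -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": pd.Series(dtype=object),
        "start_date": pd.Series(dtype="datetime64[ns]"),
        "end_date": pd.Series(dtype="datetime64[ns]"),
        "end_reason": pd.Series(dtype=object),
        "person_days": pd.Series(dtype="int64"),
    })


def total_person_years(followups: pd.DataFrame) -> float:
    """Total follow-up, in person-years of 365 days."""
    if len(followups) == 0:
        return 0.0
    return float(followups["person_days"].sum()) / DAYS_PER_YEAR
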