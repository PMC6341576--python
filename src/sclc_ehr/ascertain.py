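"""The four-step case-identification algorithm for incident SCLC.

Step 1 — detect, per cohort member, the first lung-cancer or small-cell
         cancer (SCC) code during follow-up: lung-cancer code defines
         group 1, SCC code group 2 (SCC wins a same-day tie, being the
         more specific code).
Step 2 — cross-coding: a group-1 patient with an SCC code within 90 days
         either side of the index code (and vice versa for group 2) is
         retained as a confirmed case without text review.
Step 3 — free-text search in the window from 30 days before to 90 days
         after the index code; group-1 residuals split into SCLC-text-only,
         non-text-only, both, or no-text strata; group-2 residuals into
         lung-cancer-text or no-text.
Step 4 — confirmation rates measured on small reviewed samples of each
         text stratum are extrapolated to the full stratum counts to give
         the expected number of SCLC cases.

The final event date of an expected case is backdated to the earliest
related symptom or diagnostic-procedure code within a configurable
look-back window before the recorded index code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .codelists import CodeList
from .textmine import PatternSet, match_text

__all__ = [
    "detect_index",
    "cross_code",
    "text_flags",
    "classify",
    "StepCounts",
    "extrapolate",
    "backdate_event_date",
    "assign_final_dates",
]

STRATA = (
    "cross_code_confirmed",
    "text_sclc_only",
    "text_non_only",
    "text_both",
    "text_lung",
    "no_text",
)

# strata counted as expected cases outright; text_both enters only through
# its extrapolated confirmation-rate term
_EXPECTED_STRATA = {"cross_code_confirmed", "text_sclc_only", "text_lung"}


def detect_index(bundle, followups: pd.DataFrame, codelists: CodeList) -> pd.DataFrame:
    """Step 1: earliest cancer code within follow-up defines group and date.

    Returns columns ``patient_id, group, index_code, index_date`` with
    group 1 = lung-cancer code, group 2 = SCC code.  Patients with no
    qualifying code during follow-up are absent.
    """
    if codelists.lung_cancer & codelists.scc:
        raise ValueError("lung-cancer and SCC code lists overlap")
    ev = bundle.events[["patient_id", "event_date", "code"]]
    ev = ev[ev["code"].isin(codelists.cancer)]
    ev = ev.merge(followups[["patient_id", "start_date", "end_date"]],
                  on="patient_id", how="inner")
    ev = ev[(ev["event_date"] >= ev["start_date"])
            & (ev["event_date"] <= ev["end_date"])]
    if ev.empty:
        return pd.DataFrame({
            "patient_id": pd.Series(dtype=object),
            "group": pd.Series(dtype="int64"),
            "index_code": pd.Series(dtype=object),
            "index_date": pd.Series(dtype="datetime64[ns]"),
        })
    is_scc = ev["code"].isin(codelists.scc)
    ev = ev.assign(group=np.where(is_scc, 2, 1),
                   _prio=np.where(is_scc, 0, 1))  # SCC wins same-day ties
    ev = ev.sort_values(["patient_id", "event_date", "_prio", "code"],
                        kind="mergesort")
    first = ev.groupby("patient_id", as_index=False).first()
    return first.rename(columns={"event_date": "index_date",
                                 "code": "index_code"})[
        ["patient_id", "group", "index_code", "index_date"]]


def cross_code(assignments: pd.DataFrame, bundle, codelists: CodeList,
               window_days: int = 90) -> pd.Series:
    """Step 2: complementary code within +/-``window_days`` (inclusive).

    Returns a boolean Series indexed by patient_id.
    """
    ev = bundle.events[["patient_id", "event_date", "code"]]
    flags = pd.Series(False, index=assignments["patient_id"].to_numpy())
    for group, other_codes in ((1, codelists.scc), (2, codelists.lung_cancer)):
        grp = assignments[assignments["group"] == group]
        if grp.empty:
            continue
        sub = ev[ev["code"].isin(other_codes)].merge(
            grp[["patient_id", "index_date"]], on="patient_id", how="inner")
        delta = (sub["event_date"] - sub["index_date"]).dt.days
        hit = sub.loc[delta.abs() <= window_days, "patient_id"].unique()
        flags.loc[hit] = True
    flags.index.name = "patient_id"
    return flags


def text_flags(assignments: pd.DataFrame, bundle, patterns: PatternSet,
               cross_flags: pd.Series | None = None,
               lo_days: int = -30, hi_days: int = 90) -> pd.DataFrame:
    """Step 3: per-patient OR of text-search flags over the comment window.

    Cross-code-confirmed patients skip the text search (their flags stay
    false).  Returns a DataFrame indexed by patient_id with boolean columns
    ``has_sclc_text, has_non_text, has_lung_text``.
    """
    idx = assignments["patient_id"].to_numpy()
    out = pd.DataFrame(False, index=pd.Index(idx, name="patient_id"),
                       columns=["has_sclc_text", "has_non_text", "has_lung_text"])
    todo = assignments
    if cross_flags is not None:
        keep = ~cross_flags.reindex(idx, fill_value=False).to_numpy()
        todo = assignments[keep]
    if todo.empty:
        return out
    ev = bundle.events[["patient_id", "event_date", "free_text"]]
    ev = ev[ev["free_text"].astype(bool)]
    sub = ev.merge(todo[["patient_id", "index_date"]], on="patient_id", how="inner")
    delta = (sub["event_date"] - sub["index_date"]).dt.days
    sub = sub[(delta >= lo_days) & (delta <= hi_days)]
    if sub.empty:
        return out
    # classify each distinct comment once
    cache = {t: match_text(t, patterns) for t in sub["free_text"].unique()}
    f = sub["free_text"].map(cache)
    sub = sub.assign(
        has_sclc_text=[x.has_sclc_text for x in f],
        has_non_text=[x.has_non_text for x in f],
        has_lung_text=[x.has_lung_text for x in f],
    )
    agg = sub.groupby("patient_id")[
        ["has_sclc_text", "has_non_text", "has_lung_text"]].any()
    out.loc[agg.index] = agg
    return out


def classify(assignments: pd.DataFrame, cross_flags: pd.Series,
             flags: pd.DataFrame) -> pd.DataFrame:
    """Assign each code-detected patient to a single stratum.

    Group 1 residuals split on the SCLC/non text flags; group 2 residuals
    on the lung-cancer flag.  ``is_expected_case`` marks the strata counted
    as SCLC outright (cross-confirmed, SCLC-text-only, lung-cancer-text);
    the ambiguous both-strings stratum contributes to case counts only via
    its extrapolated confirmation-rate term.
    """
    pid = assignments["patient_id"].to_numpy()
    group = assignments["group"].to_numpy()
    crossed = cross_flags.reindex(pid, fill_value=False).to_numpy()
    fl = flags.reindex(pid, fill_value=False)
    sclc_t = fl["has_sclc_text"].to_numpy()
    non_t = fl["has_non_text"].to_numpy()
    lung_t = fl["has_lung_text"].to_numpy()

    stratum = np.full(len(pid), "no_text", dtype=object)
    g1 = group == 1
    g2 = group == 2
    stratum[g1 & ~crossed & sclc_t & non_t] = "text_both"
    stratum[g1 & ~crossed & sclc_t & ~non_t] = "text_sclc_only"
    stratum[g1 & ~crossed & ~sclc_t & non_t] = "text_non_only"
    stratum[g2 & ~crossed & lung_t] = "text_lung"
    stratum[crossed] = "cross_code_confirmed"

    out = assignments[["patient_id", "group", "index_code", "index_date"]].copy()
    out["stratum"] = stratum
    out["is_expected_case"] = np.isin(stratum, sorted(_EXPECTED_STRATA))
    out["final_event_date"] = pd.NaT
    return out


# ---------------------------------------------------------------------------
# step counts and extrapolation


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class StepCounts:
    """Aggregate counts flowing through the ascertainment flowchart."""

    n_group1: int = 0
    n_group2: int = 0
    n_cross1: int = 0
    n_cross2: int = 0
    n_text_sclc_only: int = 0
    n_text_non_only: int = 0
    n_text_both: int = 0
    n_text_lung: int = 0
    confirmation_rates: dict[str, float] | None = None
    expected_cases_total: int | None = None
    expected_cases_final: int | None = None
    text_both_term: int | None = None

    def __post_init__(self) -> None:
        if self.n_cross1 > self.n_group1 or self.n_cross2 > self.n_group2:
            raise ValueError("cross-code counts cannot exceed group sizes")
        if (self.n_text_sclc_only + self.n_text_non_only + self.n_text_both
                > self.n_group1 - self.n_cross1):
            raise ValueError("group-1 text strata exceed the residual group size")
        if self.n_text_lung > self.n_group2 - self.n_cross2:
            raise ValueError("group-2 text stratum exceeds the residual group size")

    @classmethod
    def from_classifications(cls, classifications: pd.DataFrame) -> "StepCounts":
        c = classifications
        by = c.groupby(["group", "stratum"]).size()

        def n(group: int, stratum: str) -> int:
            return int(by.get((group, stratum), 0))

        return cls(
            n_group1=int((c["group"] == 1).sum()),
            n_group2=int((c["group"] == 2).sum()),
            n_cross1=n(1, "cross_code_confirmed"),
            n_cross2=n(2, "cross_code_confirmed"),
            n_text_sclc_only=n(1, "text_sclc_only"),
            n_text_non_only=n(1, "text_non_only"),
            n_text_both=n(1, "text_both"),
            n_text_lung=n(2, "text_lung"),
        )

    @property
    def n_detected(self) -> int:
        return self.n_group1 + self.n_group2

    def proportions(self) -> dict[str, float]:
        """Headline percentages: expected cases among all code-detected
        patients, and cross-coded fractions within each group."""
        out: dict[str, float] = {}
        if self.expected_cases_total is not None and self.n_detected:
            out["pct_expected_of_detected"] = (
                100.0 * self.expected_cases_total / self.n_detected)
        if self.n_group1:
            out["pct_cross_group1"] = 100.0 * self.n_cross1 / self.n_group1
        if self.n_group2:
            out["pct_cross_group2"] = 100.0 * self.n_cross2 / self.n_group2
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def extrapolate(counts: StepCounts, rates: dict[str, float]) -> StepCounts:
    """Step 4: apply stratum confirmation rates to the full stratum counts.

    ``rates`` maps ``text_sclc_only``, ``text_both`` and ``text_lung`` to
    confirmation probabilities.  Each extrapolated term is rounded to the
    nearest integer (half away from zero) before summation.  The total
    includes the ambiguous both-strings term; the final count excludes it.
    """
    for key in ("text_sclc_only", "text_both", "text_lung"):
        if key not in rates:
            raise ValueError(f"missing confirmation rate for stratum {key!r}")
        if not 0.0 <= rates[key] <= 1.0:
            raise ValueError(
                f"confirmation rate for {key!r} must be in [0, 1], got {rates[key]}")
    term_sclc = _round_half_away(rates["text_sclc_only"] * counts.n_text_sclc_only)
    term_both = _round_half_away(rates["text_both"] * counts.n_text_both)
    term_lung = _round_half_away(rates["text_lung"] * counts.n_text_lung)
    total = counts.n_cross1 + term_sclc + term_both + counts.n_cross2 + term_lung
    return StepCounts(
        n_group1=counts.n_group1,
        n_group2=counts.n_group2,
        n_cross1=counts.n_cross1,
        n_cross2=counts.n_cross2,
        n_text_sclc_only=counts.n_text_sclc_only,
        n_text_non_only=counts.n_text_non_only,
        n_text_both=counts.n_text_both,
        n_text_lung=counts.n_text_lung,
        confirmation_rates=dict(rates),
        expected_cases_total=total,
        expected_cases_final=total - term_both,
        text_both_term=term_both,
    )


# ---------------------------------------------------------------------------
# event-date backdating


def backdate_event_date(events: pd.DataFrame, codelists: CodeList,
                        recorded_date, lookback_days: int = 90):
    """Final event date: earliest related symptom/procedure code within
    ``lookback_days`` before the recorded index code; the recorded date if
    none.  Never later than the recorded date."""
    recorded = pd.Timestamp(recorded_date)
    related = codelists["symptom"] | codelists["procedure"]
    if len(events) == 0:
        return recorded
    sub = events[events["code"].isin(related)]
    lo = recorded - pd.Timedelta(days=lookback_days)
    dates = sub.loc[(sub["event_date"] >= lo) & (sub["event_date"] <= recorded),
                    "event_date"]
    return dates.min() if len(dates) else recorded


def assign_final_dates(classifications: pd.DataFrame, bundle,
                       codelists: CodeList, lookback_days: int = 90
                       ) -> pd.DataFrame:
    """Fill ``final_event_date`` for expected cases (vectorised backdating)."""
    out = classifications.copy()
    cases = out[out["is_expected_case"]]
    if cases.empty:
        return out
    related = codelists["symptom"] | codelists["procedure"]
    ev = bundle.events[["patient_id", "event_date", "code"]]
    ev = ev[ev["code"].isin(related)].merge(
        cases[["patient_id", "index_date"]], on="patient_id", how="inner")
    delta = (ev["index_date"] - ev["event_date"]).dt.days
    ev = ev[(delta >= 0) & (delta <= lookback_days)]
    earliest = ev.groupby("patient_id")["event_date"].min()
    final = cases["index_date"].to_numpy().copy()
    mapped = cases["patient_id"].map(earliest)
    final = np.where(mapped.notna(), mapped.to_numpy(), final)
    out.loc[cases.index, "final_event_date"] = final
    return out
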