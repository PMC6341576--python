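"""Manual-review validation: confirmation rates and positive predictive value.

In the real study small random samples of each text stratum were reviewed
by hand against the full patient record, and a larger 400-patient sample
(300 from the lung-cancer group, 100 from the SCC group) was reviewed to
estimate the positive predictive value of the case definition.  In the
synthetic setting the chart review is an oracle read of the gold-standard
truth table: a sampled patient is confirmed when truly an incident SCLC
case (onset on or after the follow-up start date), with an optional error
rate to model imperfect review.

Confidence intervals for proportions are exact Clopper-Pearson bounds —
preferred here because the reviewed strata are small (n = 18, 20, 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LinkageError

__all__ = [
    "PPVEstimate",
    "clopper_pearson",
    "draw_review_sample",
    "review",
    "ppv",
    "stratified_ppv",
    "confirmation_rates",
    "exclusion_tally",
]

EXCLUSION_REASONS = (
    "nsclc", "secondary_tumour", "prevalent", "unconfirmed", "other_location",
    "none",
)


@dataclass(frozen=True)
class PPVEstimate:
    """Positive predictive value with an exact 95% binomial interval."""

    n_confirmed: int
    n_reviewed: int
    ppv: float
    ci_low: float
    ci_high: float

    def as_percent(self) -> tuple[float, float, float]:
        return 100 * self.ppv, 100 * self.ci_low, 100 * self.ci_high


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence bounds for ``k`` successes in ``n`` trials."""
    if n < 1:
        raise ValueError("Clopper-Pearson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def draw_review_sample(classifications: pd.DataFrame, stratum: str,
                       size: int, seed: int) -> list[str]:
    """Simple random sample without replacement from one stratum."""
    ids = np.sort(
        classifications.loc[classifications["stratum"] == stratum, "patient_id"]
        .to_numpy()
    )
    if size < 0:
        raise ValueError("sample size must be non-negative")
    if size > len(ids):
        raise ValueError(
            f"sample size {size} exceeds stratum {stratum!r} count {len(ids)}")
    if size == 0:
        return []
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(ids, size=size, replace=False).tolist())


def review(sample_ids, truth: pd.DataFrame, followups: pd.DataFrame,
           review_error_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Oracle chart review of a sample against the truth table.

    Confirmed means true SCLC with onset on or after the follow-up start
    date; otherwise the exclusion reason is mapped from the truth label
    (NSCLC -> nsclc, other lung location -> other_location, onset before
    follow-up -> prevalent, no true disease -> unconfirmed).  With a
    non-zero ``review_error_rate`` each verdict flips independently with
    that probability.
    """
    if not 0.0 <= review_error_rate <= 1.0:
        raise ValueError("review_error_rate must be in [0, 1]")
    sample_ids = list(sample_ids)
    tr = truth.set_index("patient_id")
    missing = [p for p in sample_ids if p not in tr.index]
    if missing:
        raise LinkageError(f"sampled patient(s) lack a truth label: {missing[:3]}")
    fu = followups.set_index("patient_id")["start_date"]

    rng = np.random.default_rng(seed)
    flips = rng.random(len(sample_ids)) < review_error_rate

    rows = []
    for pid, flip in zip(sample_ids, flips):
        disease = tr.at[pid, "true_disease"]
        onset = tr.at[pid, "true_onset_date"]
        start = fu.get(pid, pd.NaT)
        if disease == "SCLC":
            if pd.notna(start) and pd.notna(onset) and onset < start:
                confirmed, reason = False, "prevalent"
            else:
                confirmed, reason = True, "none"
        elif disease == "NSCLC":
            confirmed, reason = False, "nsclc"
        elif disease == "OTHER_LUNG":
            confirmed, reason = False, "other_location"
        else:
            confirmed, reason = False, "unconfirmed"
        if flip:
            confirmed = not confirmed
            reason = "none" if confirmed else "unconfirmed"
        rows.append((pid, True, confirmed, reason))
    return pd.DataFrame(
        rows, columns=["patient_id", "reviewed", "confirmed", "exclusion_reason"])


def ppv(outcomes: pd.DataFrame) -> PPVEstimate:
    """PPV over a set of review outcomes with Clopper-Pearson 95% CI."""
    n = int(outcomes["reviewed"].sum())
    if n == 0:
        raise ValueError("PPV undefined: no reviewed patients")
    k = int(outcomes.loc[outcomes["reviewed"], "confirmed"].sum())
    low, high = clopper_pearson(k, n)
    return PPVEstimate(k, n, k / n, low, high)


def stratified_ppv(outcomes: pd.DataFrame, strata: pd.Series
                   ) -> dict[str, PPVEstimate]:
    """PPV per stratum; ``strata`` maps patient_id to a stratum label."""
    labelled = outcomes.assign(
        _stratum=outcomes["patient_id"].map(strata))
    out: dict[str, PPVEstimate] = {}
    for label, grp in labelled.groupby("_stratum"):
        out[str(label)] = ppv(grp)
    return out


def confirmation_rates(outcomes_by_stratum: dict[str, pd.DataFrame]
                       ) -> dict[str, float]:
    """Confirmed/reviewed per stratum, feeding the extrapolation step."""
    rates: dict[str, float] = {}
    for stratum, outcomes in outcomes_by_stratum.items():
        n = int(outcomes["reviewed"].sum()) if len(outcomes) else 0
        if n == 0:
            raise ValueError(
                f"confirmation rate undefined: empty review sample for "
                f"stratum {stratum!r}")
        k = int(outcomes.loc[outcomes["reviewed"], "confirmed"].sum())
        rates[stratum] = k / n
    return rates


def exclusion_tally(outcomes: pd.DataFrame) -> dict[str, int]:
    """Count non-confirmed review outcomes by exclusion reason."""
    excl = outcomes[~outcomes["confirmed"]]
    tally = {r: 0 for r in EXCLUSION_REASONS if r != "none"}
    for r, n in excl["exclusion_reason"].value_counts().items():
        tally[str(r)] = int(n)
    return tally
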