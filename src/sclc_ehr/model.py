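"""Model-style front end: build once from a bundle, ``fit()`` runs the
whole ascertainment/validation/characterisation pipeline and returns a
results object with the estimates, intervals and summary table.

    >>> from sclc_ehr import SCLCPhenotype, SimConfig, generate_bundle
    >>> bundle = generate_bundle(SimConfig(n_patients=20_000, seed=7))
    >>> res = SCLCPhenotype(bundle).fit(seed=7)
    >>> print(res.summary())
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import ascertain as asc
from . import epistats as ep
from . import validate as val
from .codelists import CodeList, default_codelists
from .cohort import eligible_cohort, total_person_years
from .synth import EHRBundle, read_bundle
from .textmine import PatternSet, default_patterns

__all__ = ["SCLCPhenotype", "SCLCPhenotypeResults"]

DEFAULT_REVIEW_SIZES = {
    "text_sclc_only": 18,
    "text_non_only": 18,
    "text_both": 20,
    "text_lung": 25,
}
DEFAULT_PPV_SAMPLE = (300, 100)  # from text_sclc_only and text_lung strata


def _child_seed(seed: int, label: str) -> int:
    # crc32 keeps the derivation stable across processes (str hash is not)
    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


class SCLCPhenotype:
    """Case-ascertainment model for incident SCLC in a primary-care bundle.

    Parameters
    ----------
    bundle : EHRBundle
        Patients, coded events (with free text), prescriptions and — for
        the simulated chart review — truth labels.
    codelists, patterns : code dictionary and text-search patterns;
        package defaults if omitted.
    study_start, study_end : study window (defaults 2000-01-01 to
        2014-12-31).
    cross_code_days : half-width of the cross-coding window (default 90).
    text_lo, text_hi : free-text window relative to the index code
        (default -30 to +90 days, both inclusive).
    backdate_lookback : look-back for the final-event-date rule (default
        90 days).
    """

    def __init__(self, bundle: EHRBundle, codelists: CodeList | None = None,
                 patterns: PatternSet | None = None,
                 study_start: date = date(2000, 1, 1),
                 study_end: date = date(2014, 12, 31),
                 cross_code_days: int = 90, text_lo: int = -30,
                 text_hi: int = 90, backdate_lookback: int = 90):
        self.bundle = bundle
        self.codelists = codelists or default_codelists()
        self.patterns = patterns or default_patterns()
        self.study_start = study_start
        self.study_end = study_end
        self.cross_code_days = cross_code_days
        self.text_lo = text_lo
        self.text_hi = text_hi
        self.backdate_lookback = backdate_lookback

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "SCLCPhenotype":
        return cls(read_bundle(path), **kwargs)

    def fit(self, review_sizes: dict[str, int] | None = None,
            ppv_sample: tuple[int, int] = DEFAULT_PPV_SAMPLE,
            confirmation_rates: dict[str, float] | None = None,
            review_error_rate: float = 0.0,
            seed: int = 0) -> "SCLCPhenotypeResults":
        """Run cohort selection, the four ascertainment steps, validation
        and the epidemiological outputs.

        ``confirmation_rates`` overrides the simulated stratum review
        (useful when rates measured elsewhere are treated as inputs);
        otherwise rates come from oracle review of stratum samples of the
        given sizes (capped at the stratum count).
        """
        bundle = self.bundle
        followups = eligible_cohort(bundle, self.study_start, self.study_end,
                                    self.codelists)
        assignments = asc.detect_index(bundle, followups, self.codelists)
        cross = asc.cross_code(assignments, bundle, self.codelists,
                               self.cross_code_days)
        flags = asc.text_flags(assignments, bundle, self.patterns, cross,
                               self.text_lo, self.text_hi)
        classifications = asc.classify(assignments, cross, flags)
        classifications = asc.assign_final_dates(
            classifications, bundle, self.codelists, self.backdate_lookback)
        counts = asc.StepCounts.from_classifications(classifications)

        sizes = dict(DEFAULT_REVIEW_SIZES)
        if review_sizes:
            sizes.update(review_sizes)

        review_outcomes: dict[str, pd.DataFrame] = {}
        if confirmation_rates is None:
            rates: dict[str, float] = {}
            for stratum in ("text_sclc_only", "text_non_only", "text_both",
                            "text_lung"):
                n_stratum = int((classifications["stratum"] == stratum).sum())
                size = min(sizes.get(stratum, 0), n_stratum)
                if size == 0:
                    if stratum != "text_non_only":
                        rates[stratum] = 0.0  # empty stratum: zero weight
                    continue
                ids = val.draw_review_sample(
                    classifications, stratum, size,
                    _child_seed(seed, f"review:{stratum}"))
                outcomes = val.review(ids, bundle.truth, followups,
                                      review_error_rate,
                                      _child_seed(seed, f"flip:{stratum}"))
                review_outcomes[stratum] = outcomes
                if stratum != "text_non_only":
                    rates[stratum] = val.confirmation_rates(
                        {stratum: outcomes})[stratum]
        else:
            rates = dict(confirmation_rates)
        counts = asc.extrapolate(counts, rates)

        # PPV validation sample: fixed split across the two review strata
        ppv_outcomes = []
        for stratum, size in zip(("text_sclc_only", "text_lung"), ppv_sample):
            n_stratum = int((classifications["stratum"] == stratum).sum())
            size = min(size, n_stratum)
            if size == 0:
                continue
            ids = val.draw_review_sample(classifications, stratum, size,
                                         _child_seed(seed, f"ppv:{stratum}"))
            out = val.review(ids, bundle.truth, followups, review_error_rate,
                             _child_seed(seed, f"ppvflip:{stratum}"))
            out = out.assign(stratum=stratum)
            ppv_outcomes.append(out)
        ppv_df = (pd.concat(ppv_outcomes, ignore_index=True) if ppv_outcomes
                  else pd.DataFrame(columns=["patient_id", "reviewed",
                                             "confirmed", "exclusion_reason",
                                             "stratum"]))
        ppv_overall = val.ppv(ppv_df) if len(ppv_df) else None
        ppv_by_group = {}
        for stratum, label in (("text_sclc_only", "group1"),
                               ("text_lung", "group2")):
            sub = ppv_df[ppv_df["stratum"] == stratum]
            if len(sub):
                ppv_by_group[label] = val.ppv(sub)

        person_years = total_person_years(followups)
        incidence = None
        incidence_total = None
        if person_years > 0 and counts.expected_cases_final is not None:
            incidence = ep.incidence_rate(counts.expected_cases_final,
                                          person_years)
            incidence_total = ep.incidence_rate(counts.expected_cases_total,
                                                person_years)

        cases = classifications[classifications["is_expected_case"]]
        records = mortality = km = baseline = None
        if len(cases):
            records = ep.survival_records(bundle, cases, self.study_end)
            if len(records):
                mortality = ep.mortality_summary(records)
                km = ep.km_estimate(records)
            baseline = ep.baseline_table(bundle, cases)

        return SCLCPhenotypeResults(
            model=self, followups=followups, classifications=classifications,
            step_counts=counts, review_outcomes=review_outcomes,
            ppv_outcomes=ppv_df, ppv_overall=ppv_overall,
            ppv_by_group=ppv_by_group, person_years=person_years,
            incidence=incidence, incidence_total=incidence_total,
            survival=records, mortality=mortality, km=km, baseline=baseline,
            seed=seed,
        )


@dataclass
class SCLCPhenotypeResults:
    """Fitted pipeline outputs: counts, rates, validation and survival."""

    model: SCLCPhenotype
    followups: pd.DataFrame
    classifications: pd.DataFrame
    step_counts: asc.StepCounts
    review_outcomes: dict[str, pd.DataFrame]
    ppv_outcomes: pd.DataFrame
    ppv_overall: val.PPVEstimate | None
    ppv_by_group: dict[str, val.PPVEstimate]
    person_years: float
    incidence: ep.RateEstimate | None
    incidence_total: ep.RateEstimate | None
    survival: pd.DataFrame | None
    mortality: pd.DataFrame | None
    km: ep.KMCurve | None
    baseline: pd.DataFrame | None
    seed: int = 0

    # -- derived -----------------------------------------------------------
    @property
    def n_cases(self) -> int | None:
        return self.step_counts.expected_cases_final

    def validation_report(self) -> dict:
        rep: dict = {"exclusion_reasons": (val.exclusion_tally(self.ppv_outcomes)
                                           if len(self.ppv_outcomes) else {})}
        if self.ppv_overall:
            rep["ppv_overall"] = self.ppv_overall.__dict__
        for label, est in self.ppv_by_group.items():
            rep[f"ppv_{label}"] = est.__dict__
        rep["confirmation_rates"] = self.step_counts.confirmation_rates
        return rep

    def summary(self) -> str:
        c = self.step_counts
        lines = [
            "SCLC case ascertainment summary",
            "=" * 46,
            f"Eligible cohort                 {len(self.followups):>12,}",
            f"Person-years of follow-up       {self.person_years:>12,.0f}",
            f"Group 1 (lung-cancer code)      {c.n_group1:>12,}",
            f"Group 2 (SCC code)              {c.n_group2:>12,}",
            f"  cross-coded, group 1          {c.n_cross1:>12,}",
            f"  cross-coded, group 2          {c.n_cross2:>12,}",
            f"  'SCLC' text only              {c.n_text_sclc_only:>12,}",
            f"  'non' text only               {c.n_text_non_only:>12,}",
            f"  both 'SCLC' and 'non'         {c.n_text_both:>12,}",
            f"  'lung cancer' text (group 2)  {c.n_text_lung:>12,}",
            f"Expected SCLC cases (total)     {c.expected_cases_total!s:>12}",
            f"Expected SCLC cases (final)     {c.expected_cases_final!s:>12}",
        ]
        if self.incidence:
            i = self.incidence
            lines.append(
                f"Incidence per 10,000 py         "
                f"{i.rate:>12.2f}  (95% CI {i.ci_low:.2f}-{i.ci_high:.2f})")
        if self.ppv_overall:
            p, lo, hi = self.ppv_overall.as_percent()
            lines.append(
                f"PPV, review sample (%)          "
                f"{p:>12.1f}  (95% CI {lo:.1f}-{hi:.1f})")
        if self.mortality is not None:
            tot = self.mortality.iloc[0]
            lines.append(
                f"1-yr crude mortality (%)        {tot['crude_pct']:>12.1f}")
            lines.append(
                f"Mortality per 100 pm            "
                f"{tot['rate_per_100pm']:>12.2f}  "
                f"(95% CI {tot['ci_low']:.2f}-{tot['ci_high']:.2f})")
        if self.km is not None:
            med = self.km.median_survival
            lines.append(
                "Median survival (months)        "
                + (f"{med:>12.2f}" if med is not None else "   undefined"))
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Write followups, classifications, step counts, validation report
        and the epidemiological tables as CSV/JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.followups.to_csv(directory / "followups.csv", index=False,
                              date_format="%Y-%m-%d")
        self.classifications.to_csv(directory / "classifications.csv",
                                    index=False, date_format="%Y-%m-%d")
        self.step_counts.to_json(directory / "step_counts.json")
        (directory / "validation_report.json").write_text(
            json.dumps(self.validation_report(), indent=2, sort_keys=True,
                       default=float))
        if self.baseline is not None:
            self.baseline.to_csv(directory / "table1.csv", index=False)
        if self.mortality is not None:
            self.mortality.to_csv(directory / "table3.csv", index=False)
        if self.km is not None:
            self.km.to_frame().to_csv(directory / "km_curve.csv", index=False)
        (directory / "summary.txt").write_text(self.summary() + "\n")
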