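"""Rates, mortality tables, Kaplan-Meier and baseline characterisation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from sclc_ehr import (SCLCPhenotype, incidence_rate, km_estimate,
                      mortality_summary, rate_estimate, survival_records)
from sclc_ehr.epistats import DAYS_PER_MONTH, DAYS_PER_YEAR, baseline_table

from conftest import mk_bundle


# ---------------------------------------------------------------------------
# rates


def test_incidence_rate_headline_value():
    est = incidence_rate(2938, 29_028_641, scale=10_000)
    assert round(est.rate, 2) == 1.01
    assert est.ci_low < est.rate < est.ci_high


def test_zero_events_uses_exact_poisson_bound():
    est = incidence_rate(0, 50_000)
    assert est.rate == 0.0 and est.ci_low == 0.0
    assert est.ci_high == pytest.approx(3.69 / 50_000 * 10_000)


def test_rate_rejects_nonpositive_person_time():
    with pytest.raises(ValueError):
        incidence_rate(10, 0.0)


def test_lognormal_ci_reproduces_printed_mortality_intervals():
    # overall: 9.95 (9.53-10.39); males: 11.05 (10.41-11.72)
    total = rate_estimate(1998, 20_073, scale=100, unit="person-months")
    assert round(total.rate, 2) == 9.95
    assert abs(total.ci_low - 9.53) <= 0.02
    assert abs(total.ci_high - 10.39) <= 0.02
    males = rate_estimate(1081, 9_787, scale=100, unit="person-months")
    assert round(males.rate, 2) == 11.05
    assert abs(males.ci_low - 10.41) <= 0.02
    assert abs(males.ci_high - 11.72) <= 0.02


def test_rate_invariant_under_unit_conversion():
    days = 1_234_567.0
    ev = 321
    per_year = rate_estimate(ev, days / DAYS_PER_YEAR, scale=10_000)
    per_month = rate_estimate(ev, days / DAYS_PER_MONTH,
                              scale=10_000 * DAYS_PER_YEAR / DAYS_PER_MONTH)
    assert per_year.rate == pytest.approx(per_month.rate, rel=1e-10)


def test_single_patient_dying_at_six_months():
    rec = pd.DataFrame({"patient_id": ["P1"], "sex": ["M"], "age": [70],
                        "age_band": ["70-79"], "time_months": [6.0],
                        "event": [True]})
    table = mortality_summary(rec)
    total = table[table["stratum"] == "total"].iloc[0]
    assert total["deaths"] == 1
    assert total["person_months"] == pytest.approx(6.0)
    assert total["rate_per_100pm"] == pytest.approx(100 / 6.0)


# ---------------------------------------------------------------------------
# mortality table structure


def _random_records(n=400, seed=23):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "sex": rng.choice(["M", "F"], n),
        "age": rng.integers(40, 95, n),
        "age_band": rng.choice(["<60", "60-69", "70-79", ">=80"], n),
        "time_months": np.round(rng.uniform(0.1, 12.0, n), 3),
        "event": rng.random(n) < 0.6,
    })


def test_strata_sum_to_totals():
    table = mortality_summary(_random_records()).set_index("stratum")
    total = table.loc["total"]
    for cols in (["M", "F"], ["<60", "60-69", "70-79", ">=80"]):
        sub = table.loc[cols]
        assert sub["deaths"].sum() == total["deaths"]
        assert sub["at_risk"].sum() == total["at_risk"]
        assert sub["person_months"].sum() == pytest.approx(
            total["person_months"])


def test_empty_stratum_row_flagged_with_nan():
    rec = _random_records(50)
    rec["sex"] = "M"
    table = mortality_summary(rec).set_index("stratum")
    assert table.loc["F", "at_risk"] == 0
    assert np.isnan(table.loc["F", "rate_per_100pm"])


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_four_even_deaths():
    rec = pd.DataFrame({"time_months": [1.0, 2.0, 3.0, 4.0],
                        "event": [True] * 4})
    km = km_estimate(rec)
    assert km.survival_at(2.5) == pytest.approx(0.5)
    assert km.median_survival == pytest.approx(2.0)


def test_km_all_censored():
    rec = pd.DataFrame({"time_months": [3.0, 6.0, 12.0],
                        "event": [False] * 3})
    km = km_estimate(rec)
    assert len(km.times) == 0
    assert km.survival_at(12.0) == 1.0
    assert km.median_survival is None


def test_km_rejects_negative_times():
    with pytest.raises(ValueError):
        km_estimate(pd.DataFrame({"time_months": [-1.0], "event": [True]}))


def _km_oracle(times, events):
    """Brute-force risk-set enumeration of the product-limit estimator."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = int((times >= t).sum())
        d = int((events & (times == t)).sum())
        s *= 1.0 - d / n_at_risk
        out[float(t)] = s
    return out


def test_km_matches_brute_force_oracle_on_500_random_records():
    rng = np.random.default_rng(47)
    n = 500
    times = np.round(rng.exponential(7.0, n), 2).clip(0.01, 12.0)
    events = rng.random(n) < 0.7
    km = km_estimate(pd.DataFrame({"time_months": times, "event": events}))
    want = _km_oracle(times, events)
    assert len(km.times) == len(want)
    for t, s in zip(km.times, km.survival):
        assert s == pytest.approx(want[float(t)], abs=0.0), t


def test_km_agrees_with_lifelines():
    rng = np.random.default_rng(53)
    n = 300
    times = np.round(rng.exponential(7.0, n), 2).clip(0.01, 12.0)
    events = rng.random(n) < 0.6
    km = km_estimate(pd.DataFrame({"time_months": times, "event": events}))
    kmf = KaplanMeierFitter().fit(times, events)
    for t, s in zip(km.times, km.survival):
        assert s == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12)


def test_without_censoring_km_complements_crude_mortality():
    rng = np.random.default_rng(59)
    n = 250
    times = np.minimum(np.round(rng.exponential(8.0, n), 2), 12.0)
    events = times < 12.0  # everyone followed a full year
    rec = pd.DataFrame({"time_months": times, "event": events})
    km = km_estimate(rec)
    crude = events.mean()
    assert 1.0 - km.survival_at(12.0) == pytest.approx(crude, abs=1e-12)


# ---------------------------------------------------------------------------
# survival records construction


def test_survival_records_truncate_and_censor():
    patients = [
        {"patient_id": "S1", "registration_status": "died",
         "death_date": "2006-01-01", "registration_end": "2006-01-01"},
        {"patient_id": "S2"},  # alive, full year
        {"patient_id": "S3", "registration_end": "2005-10-01"},  # data end
    ]
    bundle = mk_bundle(patients, [], [], [{"patient_id": p["patient_id"]}
                                          for p in patients])
    cases = pd.DataFrame({
        "patient_id": ["S1", "S2", "S3"],
        "final_event_date": pd.Timestamp("2005-07-01"),
    })
    rec = survival_records(bundle, cases).set_index("patient_id")
    assert rec.loc["S1", "event"]
    assert rec.loc["S1", "time_months"] == pytest.approx(
        184 / DAYS_PER_MONTH)
    assert not rec.loc["S2", "event"]
    assert rec.loc["S2", "time_months"] == pytest.approx(12.0)
    assert not rec.loc["S3", "event"]
    assert rec.loc["S3", "time_months"] == pytest.approx(
        92 / DAYS_PER_MONTH)


def test_case_with_record_closed_before_event_excluded():
    patients = [{"patient_id": "S1", "registration_end": "2005-06-01"}]
    bundle = mk_bundle(patients, [], [], [{"patient_id": "S1"}])
    cases = pd.DataFrame({"patient_id": ["S1"],
                          "final_event_date": pd.Timestamp("2005-07-01")})
    assert survival_records(bundle, cases).empty


# ---------------------------------------------------------------------------
# baseline characterisation


def _baseline_fixture():
    patients = [{"patient_id": "B1", "sex": "F", "birth_date": "1940-03-01"}]
    events = [
        {"patient_id": "B1", "event_date": "2001-01-01",
         "code": "LIFE_SMOK_NEVER"},
        {"patient_id": "B1", "event_date": "2004-01-01",
         "code": "LIFE_SMOK_CURRENT"},  # latest before diagnosis wins
        {"patient_id": "B1", "event_date": "2003-05-05", "code": "COM_COPD"},
    ]
    rx = [
        ("B1", "2005-06-01", "opioid", 60),     # spans diagnosis: current
        ("B1", "2003-01-01", "ppi", 28),        # ended >1y before: not current
    ]
    bundle = mk_bundle(patients, events, rx, [{"patient_id": "B1"}])
    cases = pd.DataFrame({"patient_id": ["B1"],
                          "final_event_date": pd.Timestamp("2005-07-01")})
    return bundle, cases


def test_baseline_rules_on_handcrafted_case():
    bundle, cases = _baseline_fixture()
    table = baseline_table(bundle, cases)
    t = table.set_index(["factor", "category"])["n"]
    assert t.loc[("smoking", "current")] == 1
    assert t.loc[("comorbidity", "COM_COPD")] == 1
    assert t.loc[("medication_current", "opioid")] == 1
    assert t.loc[("medication_current", "ppi")] == 0
    assert t.loc[("bmi", "unknown")] == 1


def test_medication_current_if_supply_ended_within_previous_year():
    bundle, cases = _baseline_fixture()
    # opioid issued 400 days before diagnosis with 60-day supply:
    # supply ended 340 days before diagnosis -> still "current use"
    bundle.prescriptions.loc[0, "issue_date"] = pd.Timestamp("2004-05-28")
    table = baseline_table(bundle, cases).set_index(["factor", "category"])
    assert table.loc[("medication_current", "opioid"), "n"] == 1


def test_baseline_flags_match_brute_force_scan(codelists, small_bundle):
    res = SCLCPhenotype(small_bundle).fit(seed=4)
    cases = res.classifications[res.classifications["is_expected_case"]]
    table = baseline_table(
        small_bundle, cases,
        comorbidity_codes={"COM_HTN", "COM_COPD"}).set_index(
        ["factor", "category"])
    diag = dict(zip(cases["patient_id"], cases["final_event_date"]))
    ev = small_bundle.events

    # comorbidity: any code on or before diagnosis
    for code in ("COM_HTN", "COM_COPD"):
        want = 0
        for pid, d in diag.items():
            sub = ev[(ev["patient_id"] == pid) & (ev["code"] == code)
                     & (ev["event_date"] <= d)]
            want += int(len(sub) > 0)
        assert table.loc[("comorbidity", code), "n"] == want

    # current medication by the supply rule
    rx = small_bundle.prescriptions
    for cls in ("opioid", "beta2_agonist"):
        want = 0
        for pid, d in diag.items():
            sub = rx[(rx["patient_id"] == pid) & (rx["drug_class"] == cls)
                     & (rx["issue_date"] <= d)]
            if len(sub) == 0:
                continue
            last = sub.sort_values("issue_date").iloc[-1]
            end = last["issue_date"] + pd.Timedelta(
                days=int(last["supply_days"]))
            want += int(end >= d - pd.Timedelta(days=365))
        assert table.loc[("medication_current", cls), "n"] == want
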