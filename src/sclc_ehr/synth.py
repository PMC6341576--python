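"""Synthetic primary-care EHR bundles with known ground truth.

Access-restricted UK primary-care databases (THIN, CPRD) cannot ship with a
package, so every stage of the case-ascertainment pipeline is exercised on
synthetic bundles that emulate their structure: per-patient registration
intervals, dated coded clinical events each optionally carrying a free-text
comment, dated prescriptions with supply durations, death dates, and a gold
standard truth table (which real data never has) recording each patient's
true disease, onset and death.

The generative model, briefly:

* patients register at staggered dates; routine encounters occur at
  roughly 6-18 month intervals; lifestyle status, comorbidities and
  prescriptions accrue over the record;
* lung cancers arise as competing exponential processes (SCLC hazard
  ``annual_sclc_hazard`` per person-year at risk, NSCLC at
  ``nsclc_to_sclc_ratio`` times that) once a patient has two years of
  registration inside the study window;
* a true case receives an index diagnostic code (lung-cancer or
  small-cell-cancer category) shortly after onset, may receive the
  complementary code within +/-90 days (cross-coding), and may receive a
  free-text comment drawn from configurable template sets within the
  [-30, +90]-day window around the index code — negated templates
  ("non small cell", "NSCLC") for NSCLC, ambiguous templates carrying both
  strings for a small fraction;
* survival after onset is exponential with configurable median; a fraction
  of cases have their record end shortly after diagnosis (data-end
  censoring for the mortality follow-up).

All randomness flows from a single integer seed; identical configurations
produce byte-identical CSV bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "EHRBundle",
    "BundleFormatError",
    "generate_bundle",
    "write_bundle",
    "read_bundle",
]

_EPOCH = np.datetime64("1970-01-01")
_DAY = np.timedelta64(1, "D")

PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_date", "registration_start",
    "registration_status", "registration_end", "death_date",
]
EVENT_COLUMNS = ["patient_id", "event_date", "code", "free_text"]
PRESCRIPTION_COLUMNS = ["patient_id", "issue_date", "drug_class", "supply_days"]
TRUTH_COLUMNS = [
    "patient_id", "true_disease", "true_onset_date", "true_stage",
    "true_death_date",
]

_TABLE_SPECS = {
    "patients": (PATIENT_COLUMNS, ["birth_date", "registration_start",
                                   "registration_end", "death_date"]),
    "events": (EVENT_COLUMNS, ["event_date"]),
    "prescriptions": (PRESCRIPTION_COLUMNS, ["issue_date"]),
    "truth": (TRUTH_COLUMNS, ["true_onset_date", "true_death_date"]),
}


class BundleFormatError(ValueError):
    """A bundle directory or table does not match the expected schema."""


def _default_templates() -> dict[str, list[str]]:
    return {
        "sclc": [
            "small cell lung cancer confirmed on biopsy",
            "histology: SCLC, oncology to review",
            "small-cell ca of bronchus - urgent referral",
            "likely sclc on ct findings",
        ],
        "non": [
            "non small cell lung cancer diagnosed",
            "non-small cell ca confirmed",
            "histology shows NSCLC",
        ],
        "ambiguous": [
            "small cell vs non small cell lung cancer - awaiting histology",
            "?sclc ?nsclc - review with biopsy result",
        ],
        "lung": [
            "lung cancer confirmed at mdt",
            "ca lung - referred to oncology",
            "carcinoma of lung on imaging",
        ],
        "benign": [
            "routine review",
            "viral urti, advice given",
            "medication review - no change",
        ],
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic-EHR generative model.

    Probabilities are per true case unless noted.  Defaults are set so the
    pipeline's end-to-end magnitudes (incidence near 1 case per 10,000
    person-years, ~80/20 split between lung-cancer-coded and SCC-coded true
    cases, near-complete capture by the union of cross-coding and free
    text) mirror a UK primary-care setting circa 2000-2014.
    """

    n_patients: int = 10_000
    study_start: date = date(2000, 1, 1)
    study_end: date = date(2014, 12, 31)
    annual_sclc_hazard: float = 1e-4
    nsclc_to_sclc_ratio: float = 6.0
    other_to_sclc_ratio: float = 0.3
    p_code_lung_given_sclc: float = 0.80
    p_code_scc_given_sclc: float = 0.20
    p_code_lung_given_nsclc: float = 0.95
    p_cross_code: float = 0.16
    p_cross_code_nsclc: float = 0.005
    p_text_sclc: float = 0.95
    p_text_non: float = 0.60
    p_text_lung: float = 0.90
    p_text_ambiguous: float = 0.02
    p_symptom_before: float = 0.84
    symptom_lead_days_max: int = 90
    median_survival_months: float = 7.4
    nsclc_median_survival_months: float = 11.0
    censor_dropout_rate: float = 0.05
    p_transfer: float = 0.05
    background_mortality: float = 0.01
    visit_gap_days: tuple[int, int] = (180, 540)
    seed: int = 0
    text_templates: dict[str, list[str]] = field(default_factory=_default_templates)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("SimConfig.n_patients must be >= 1")
        if not self.study_start < self.study_end:
            raise ValueError("SimConfig.study_start must precede study_end")
        for name in (
            "p_code_lung_given_sclc", "p_code_scc_given_sclc",
            "p_code_lung_given_nsclc", "p_cross_code", "p_cross_code_nsclc",
            "p_text_sclc", "p_text_non", "p_text_lung", "p_text_ambiguous",
            "p_symptom_before", "censor_dropout_rate", "p_transfer",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimConfig.{name} must be in [0, 1], got {v}")
        for name in ("annual_sclc_hazard", "background_mortality"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be >= 0")
        for name in ("nsclc_to_sclc_ratio", "other_to_sclc_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be >= 0")
        if self.p_code_lung_given_sclc + self.p_code_scc_given_sclc > 1 + 1e-12:
            raise ValueError(
                "SimConfig.p_code_lung_given_sclc + p_code_scc_given_sclc must be <= 1"
            )
        if self.symptom_lead_days_max < 1:
            raise ValueError("SimConfig.symptom_lead_days_max must be >= 1")
        if self.median_survival_months <= 0:
            raise ValueError("SimConfig.median_survival_months must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("study_start", "study_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        if "visit_gap_days" in raw:
            raw["visit_gap_days"] = tuple(raw["visit_gap_days"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["visit_gap_days"] = list(self.visit_gap_days)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class EHRBundle:
    """The four linked tables every pipeline stage consumes."""

    patients: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    truth: pd.DataFrame

    def validate(self) -> None:
        for name, (cols, _) in _TABLE_SPECS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise BundleFormatError(
                    f"table {name!r} missing column(s): {', '.join(missing)}"
                )
        pats = self.patients
        known = set(pats["patient_id"])
        for name in ("events", "prescriptions", "truth"):
            ids = set(getattr(self, name)["patient_id"])
            orphans = ids - known
            if orphans:
                raise BundleFormatError(
                    f"table {name!r} references unknown patient(s), "
                    f"e.g. {sorted(orphans)[:3]}"
                )
        has_end = pats["registration_end"].notna()
        bad = has_end & (pats["registration_end"] < pats["registration_start"])
        if bad.any():
            raise BundleFormatError("registration_end precedes registration_start")
        died = pats["registration_status"] == "died"
        if (died != pats["death_date"].notna()).any():
            raise BundleFormatError(
                "death_date must be present exactly when status is 'died'"
            )

    def equals(self, other: "EHRBundle") -> bool:
        return all(
            getattr(self, name).reset_index(drop=True).equals(
                getattr(other, name).reset_index(drop=True)
            )
            for name in _TABLE_SPECS
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EHRBundle: {len(self.patients)} patients, "
            f"{len(self.events)} events, {len(self.prescriptions)} "
            f"prescriptions>"
        )


# ---------------------------------------------------------------------------
# generation


def _day(d: date) -> int:
    return int((np.datetime64(d) - _EPOCH) / _DAY)


def _rand_int_between(rng: np.random.Generator, lo: np.ndarray,
                      hi: np.ndarray) -> np.ndarray:
    """Uniform integers in the closed per-element range [lo, hi]."""
    hi = np.maximum(hi, lo)
    return lo + (rng.random(len(lo)) * (hi - lo + 1)).astype(np.int64)


_MISSING = np.int64(-(2**40))  # sentinel day number meaning "no date"


def _to_ts(days: np.ndarray) -> pd.Series:
    """Integer day numbers (_MISSING meaning absent) to datetime64 Series."""
    days = days.astype("int64")
    safe = np.where(days == _MISSING, 0, days)
    out = pd.Series((_EPOCH + safe * _DAY).astype("datetime64[ns]"))
    out[days == _MISSING] = pd.NaT
    return out


def generate_bundle(config: SimConfig) -> EHRBundle:
    """Simulate an :class:`EHRBundle` from a :class:`SimConfig`.

    Deterministic: the same config (including seed) always yields an
    identical bundle.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    s0, s1 = _day(cfg.study_start), _day(cfg.study_end)

    # --- demographics and registration -----------------------------------
    sex = np.where(rng.random(n) < 0.51, "M", "F")
    age0 = rng.uniform(25.0, 84.0, n)  # age at study start
    birth = s0 - (age0 * 365.25).astype(np.int64)
    reg_start = rng.integers(s0 - 2920, s1 - 1095, n)

    transferred = rng.random(n) < cfg.p_transfer
    transfer_day = np.where(
        transferred,
        (reg_start + 365 + rng.random(n) * (s1 - reg_start - 365)).astype(np.int64),
        np.iinfo(np.int64).max // 4,
    )

    # --- background mortality (pre-onset) ---------------------------------
    risk_start = np.maximum(reg_start + 730, s0)
    bg_mort = max(cfg.background_mortality, 1e-12)
    bg_death = risk_start + (rng.exponential(1.0 / bg_mort, n) * 365.0).astype(np.int64)

    # --- disease onset: competing exponentials ----------------------------
    h_s = cfg.annual_sclc_hazard
    h_n = h_s * cfg.nsclc_to_sclc_ratio
    h_o = h_s * cfg.other_to_sclc_ratio
    h_tot = h_s + h_n + h_o
    horizon = np.minimum(np.minimum(s1, transfer_day), bg_death)
    if h_tot > 0:
        wait_days = (rng.exponential(1.0 / h_tot, n) * 365.0).astype(np.int64)
        onset = risk_start + wait_days
        diseased = onset <= horizon
        u = rng.random(n)
        disease = np.full(n, "NONE", dtype=object)
        disease[diseased & (u < h_s / h_tot)] = "SCLC"
        disease[diseased & (u >= h_s / h_tot) & (u < (h_s + h_n) / h_tot)] = "NSCLC"
        disease[diseased & (u >= (h_s + h_n) / h_tot)] = "OTHER_LUNG"
    else:
        onset = np.full(n, _MISSING, dtype=np.int64)
        disease = np.full(n, "NONE", dtype=object)
    is_case = disease != "NONE"
    onset = np.where(is_case, onset, _MISSING)

    # --- index coding ------------------------------------------------------
    u_code = rng.random(n)
    code_cat = np.full(n, "", dtype=object)  # "lung" | "scc" | ""
    sclc = disease == "SCLC"
    nsclc = disease == "NSCLC"
    other = disease == "OTHER_LUNG"
    code_cat[sclc & (u_code < cfg.p_code_lung_given_sclc)] = "lung"
    code_cat[sclc & (u_code >= cfg.p_code_lung_given_sclc)
             & (u_code < cfg.p_code_lung_given_sclc + cfg.p_code_scc_given_sclc)] = "scc"
    code_cat[nsclc & (u_code < cfg.p_code_lung_given_nsclc)] = "lung"
    code_cat[other & (u_code < 0.5)] = "lung"

    index_day = np.where(is_case, onset + rng.integers(0, 22, n), _MISSING)

    # --- survival ----------------------------------------------------------
    death_day = np.full(n, np.iinfo(np.int64).max // 4, dtype=np.int64)
    lam_s = np.log(2.0) / (cfg.median_survival_months * 30.4375)
    lam_n = np.log(2.0) / (cfg.nsclc_median_survival_months * 30.4375)
    surv = np.zeros(n)
    surv[sclc] = rng.exponential(1.0 / lam_s, int(sclc.sum()))
    surv[nsclc | other] = rng.exponential(1.0 / lam_n, int((nsclc | other).sum()))
    death_day[is_case] = onset[is_case] + np.maximum(surv[is_case].astype(np.int64), 1)
    death_day[~is_case] = bg_death[~is_case]
    death_day = np.minimum(death_day, bg_death)
    index_day = np.where(is_case, np.minimum(index_day, death_day), _MISSING)
    coded = is_case & (code_cat != "") & (index_day <= np.minimum(s1, transfer_day))

    # --- data-end (dropout) censoring for a fraction of coded cases -------
    dropout = coded & ~transferred & (rng.random(n) < cfg.censor_dropout_rate)
    dropout_day = np.where(
        dropout, index_day + rng.integers(30, 366, n), np.iinfo(np.int64).max // 4
    )

    data_end_cap = np.minimum(np.minimum(s1, transfer_day), dropout_day)
    death_observed = death_day <= data_end_cap
    final_end = np.where(death_observed, death_day, data_end_cap)
    final_end = np.maximum(final_end, reg_start)  # guard degenerate draws

    status = np.full(n, "permanent", dtype=object)
    status[transferred & ~ (death_observed & (death_day <= transfer_day))] = "transferred"
    status[death_observed] = "died"
    reg_end = np.full(n, _MISSING, dtype=np.int64)
    reg_end[status == "died"] = final_end[status == "died"]
    reg_end[status == "transferred"] = transfer_day[status == "transferred"]
    perm_dropout = (status == "permanent") & dropout & (dropout_day <= s1)
    reg_end[perm_dropout] = dropout_day[perm_dropout]

    pid = np.array([f"P{i:07d}" for i in range(n)], dtype=object)

    # --- event assembly ----------------------------------------------------
    ev_pid: list[np.ndarray] = []
    ev_day: list[np.ndarray] = []
    ev_code: list[np.ndarray] = []
    ev_text: list[np.ndarray] = []

    def _emit(idx: np.ndarray, day: np.ndarray, code, text=None) -> None:
        """Queue events, dropping any outside [reg_start, final_end]."""
        ok = (day >= reg_start[idx]) & (day <= final_end[idx])
        idx, day = idx[ok], day[ok]
        ev_pid.append(idx)
        ev_day.append(day)
        code_arr = (np.full(len(idx), code, dtype=object)
                    if isinstance(code, str) else np.asarray(code, dtype=object)[ok])
        ev_code.append(code_arr)
        if text is None:
            ev_text.append(np.full(len(idx), "", dtype=object))
        else:
            ev_text.append(np.asarray(text, dtype=object)[ok])

    # routine encounters
    gap_lo, gap_hi = cfg.visit_gap_days
    span = int(max(s1 - reg_start.min(), 1))
    k = span // gap_lo + 2
    gaps = rng.uniform(gap_lo, gap_hi, (n, k))
    visit_day = (reg_start[:, None] + np.cumsum(gaps, axis=1)).astype(np.int64)
    vis_idx, vis_col = np.nonzero(visit_day <= final_end[:, None])
    vdays = visit_day[vis_idx, vis_col]
    benign = rng.random(len(vdays)) < 0.05
    tmpl_benign = np.array(cfg.text_templates["benign"], dtype=object)
    vtext = np.where(
        benign, tmpl_benign[rng.integers(0, len(tmpl_benign), len(vdays))], ""
    ).astype(object)
    _emit(vis_idx, vdays, "ENC_VISIT", vtext)

    # lifestyle records (latest-before-diagnosis semantics exercised via
    # an optional later update)
    life_specs = [
        (["LIFE_SMOK_NEVER", "LIFE_SMOK_CURRENT", "LIFE_SMOK_FORMER"],
         [0.35, 0.35, 0.30], 0.95),
        (["LIFE_BMI_15_19", "LIFE_BMI_20_24", "LIFE_BMI_25_29", "LIFE_BMI_GE30"],
         [0.08, 0.35, 0.33, 0.24], 0.90),
        (["LIFE_ALC_NONE", "LIFE_ALC_LOW", "LIFE_ALC_MOD", "LIFE_ALC_HIGH"],
         [0.25, 0.45, 0.20, 0.10], 0.75),
    ]
    for codes, probs, p_have in life_specs:
        have = rng.random(n) < p_have
        choice = rng.choice(np.array(codes, dtype=object), size=n, p=probs)
        day = reg_start + rng.integers(0, 366, n)
        idx = np.nonzero(have)[0]
        _emit(idx, day[idx], choice[idx])
        upd = have & (rng.random(n) < 0.2)
        choice2 = rng.choice(np.array(codes, dtype=object), size=n, p=probs)
        day2 = day + rng.integers(365, 2000, n)
        idx2 = np.nonzero(upd)[0]
        _emit(idx2, day2[idx2], choice2[idx2])

    # comorbidities (ever-before flags)
    com_specs = [
        ("COM_HTN", 0.30), ("COM_COPD", 0.15), ("COM_ASTHMA", 0.15),
        ("COM_MI", 0.07), ("COM_STROKE", 0.04), ("COM_DEPRESSION", 0.20),
        ("COM_DYSPEPSIA", 0.18),
    ]
    for code, p in com_specs:
        have = rng.random(n) < p
        day = reg_start + (rng.random(n) * np.maximum(s1 - reg_start, 1)).astype(np.int64)
        idx = np.nonzero(have)[0]
        _emit(idx, day[idx], code)

    # index cancer codes
    coded_idx = np.nonzero(coded)[0]
    lung_codes = np.array(["LUNG_CA_1", "LUNG_CA_2", "LUNG_CA_3"], dtype=object)
    scc_codes = np.array(["SCC_1", "SCC_2"], dtype=object)
    idx_code = np.where(
        code_cat[coded_idx] == "lung",
        lung_codes[rng.integers(0, len(lung_codes), len(coded_idx))],
        scc_codes[rng.integers(0, len(scc_codes), len(coded_idx))],
    ).astype(object)
    _emit(coded_idx, index_day[coded_idx], idx_code)

    # cross-coding within +/-90 days of the index code
    p_cross = np.where(sclc, cfg.p_cross_code,
                       np.where(nsclc, cfg.p_cross_code_nsclc, 0.0))
    crossed = coded & (rng.random(n) < p_cross)
    cross_idx = np.nonzero(crossed)[0]
    # offsets capped at the record end: no coding after death/data end
    hi_c = np.minimum(90, final_end[cross_idx] - index_day[cross_idx])
    cross_day = index_day[cross_idx] + _rand_int_between(
        rng, np.full(len(cross_idx), -90), hi_c)
    cross_code_arr = np.where(
        code_cat[cross_idx] == "lung",
        scc_codes[rng.integers(0, len(scc_codes), len(cross_idx))],
        lung_codes[rng.integers(0, len(lung_codes), len(cross_idx))],
    ).astype(object)
    _emit(cross_idx, cross_day, cross_code_arr)

    # free-text comments within [-30, +90] days of the index code
    def _notes(mask: np.ndarray, template_key: str) -> None:
        idx = np.nonzero(mask)[0]
        hi = np.minimum(90, final_end[idx] - index_day[idx])
        day = index_day[idx] + _rand_int_between(
            rng, np.full(len(idx), -30), hi)
        tmpl = np.array(cfg.text_templates[template_key], dtype=object)
        text = tmpl[rng.integers(0, len(tmpl), len(idx))]
        _emit(idx, day, "ENC_VISIT", text)

    _notes(coded & sclc & (code_cat == "lung") & (rng.random(n) < cfg.p_text_sclc),
           "sclc")
    _notes(coded & sclc & (code_cat == "scc") & (rng.random(n) < cfg.p_text_lung),
           "lung")
    _notes(coded & nsclc & (rng.random(n) < cfg.p_text_non), "non")
    _notes(coded & nsclc & (rng.random(n) < cfg.p_text_ambiguous), "ambiguous")

    # pre-diagnosis symptoms and diagnostic procedures (backdating signal)
    symp = coded & (rng.random(n) < cfg.p_symptom_before)
    symp_idx = np.nonzero(symp)[0]
    symp_codes = np.array(
        ["SYMP_COUGH", "SYMP_HAEMOPTYSIS", "SYMP_CHEST_PAIN", "SYMP_DYSPNOEA",
         "SYMP_WEIGHT_LOSS", "SYMP_CHEST_INFECTION"], dtype=object)
    _emit(symp_idx,
          index_day[symp_idx]
          - rng.integers(1, cfg.symptom_lead_days_max + 1, len(symp_idx)),
          symp_codes[rng.integers(0, len(symp_codes), len(symp_idx))])
    proc = coded & (rng.random(n) < 0.7)
    proc_idx = np.nonzero(proc)[0]
    proc_codes = np.array(["PROC_CXR", "PROC_CT", "PROC_BRONCH", "PROC_BIOPSY"],
                          dtype=object)
    _emit(proc_idx, index_day[proc_idx] - rng.integers(0, 31, len(proc_idx)),
          proc_codes[rng.integers(0, len(proc_codes), len(proc_idx))])

    events = pd.DataFrame({
        "patient_id": pid[np.concatenate(ev_pid)],
        "event_date": _to_ts(np.concatenate(ev_day)),
        "code": np.concatenate(ev_code),
        "free_text": np.concatenate(ev_text),
    })
    events = events.sort_values(
        ["patient_id", "event_date", "code", "free_text"], kind="mergesort"
    ).reset_index(drop=True)

    # --- prescriptions -----------------------------------------------------
    rx_pid: list[np.ndarray] = []
    rx_day: list[np.ndarray] = []
    rx_class: list[np.ndarray] = []
    rx_supply: list[np.ndarray] = []

    def _emit_rx(idx, day, drug_class, supply) -> None:
        ok = (day >= reg_start[idx]) & (day <= final_end[idx])
        rx_pid.append(idx[ok])
        rx_day.append(day[ok])
        rx_class.append(np.asarray(drug_class, dtype=object)[ok])
        rx_supply.append(np.asarray(supply)[ok])

    first_classes = np.array(["ppi", "nsaid", "antibiotic"], dtype=object)
    all_idx = np.arange(n)
    _emit_rx(all_idx, reg_start + rng.integers(0, 61, n),
             first_classes[rng.integers(0, 3, n)], np.full(n, 28))

    routine = rng.random(len(vdays)) < 0.35
    routine_classes = np.array(
        ["beta2_agonist", "opioid", "ppi", "nsaid", "oral_steroid",
         "antiplatelet"], dtype=object)
    supplies = np.array([28, 56, 84])
    ridx = vis_idx[routine]
    _emit_rx(ridx, vdays[routine] + 1,
             routine_classes[rng.integers(0, len(routine_classes), len(ridx))],
             supplies[rng.integers(0, 3, len(ridx))])

    opi = coded & (rng.random(n) < 0.55)
    oidx = np.nonzero(opi)[0]
    _emit_rx(oidx, index_day[oidx] - rng.integers(0, 301, len(oidx)),
             np.full(len(oidx), "opioid", dtype=object),
             supplies[rng.integers(0, 3, len(oidx))])
    b2 = coded & (rng.random(n) < 0.40)
    bidx = np.nonzero(b2)[0]
    _emit_rx(bidx, index_day[bidx] - rng.integers(30, 401, len(bidx)),
             np.full(len(bidx), "beta2_agonist", dtype=object),
             supplies[rng.integers(0, 3, len(bidx))])

    prescriptions = pd.DataFrame({
        "patient_id": pid[np.concatenate(rx_pid)],
        "issue_date": _to_ts(np.concatenate(rx_day)),
        "drug_class": np.concatenate(rx_class),
        "supply_days": np.concatenate(rx_supply).astype("int64"),
    }).sort_values(
        ["patient_id", "issue_date", "drug_class"], kind="mergesort"
    ).reset_index(drop=True)

    # --- patients / truth --------------------------------------------------
    stage = np.full(n, "unknown", dtype=object)
    u_stage = rng.random(n)
    stage[sclc & (u_stage < 0.17)] = "limited"
    stage[sclc & (u_stage >= 0.17) & (u_stage < 0.87)] = "extensive"

    patients = pd.DataFrame({
        "patient_id": pid,
        "sex": sex,
        "birth_date": _to_ts(birth),
        "registration_start": _to_ts(reg_start),
        "registration_status": status,
        "registration_end": _to_ts(reg_end),
        "death_date": _to_ts(np.where(status == "died", final_end, _MISSING)),
    })
    truth = pd.DataFrame({
        "patient_id": pid,
        "true_disease": disease,
        "true_onset_date": _to_ts(onset),
        "true_stage": stage,
        # deaths projected beyond the representable horizon are left blank
        "true_death_date": _to_ts(
            np.where(death_day <= _day(date(2199, 12, 31)), death_day, _MISSING)
        ),
    })

    bundle = EHRBundle(patients, events, prescriptions, truth)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# CSV round trip


def write_bundle(bundle: EHRBundle, directory: str | Path) -> dict[str, Path]:
    """Write the four tables as RFC-4180 CSV with ISO-8601 dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in _TABLE_SPECS:
        path = directory / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False, date_format="%Y-%m-%d")
        paths[name] = path
    return paths


def read_bundle(directory: str | Path) -> EHRBundle:
    """Read a bundle directory; inverse of :func:`write_bundle`."""
    directory = Path(directory)
    tables = {}
    for name, (cols, date_cols) in _TABLE_SPECS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise BundleFormatError(f"bundle directory missing table file {name}.csv")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise BundleFormatError(
                f"table {name!r} missing column(s): {', '.join(missing)}"
            )
        df = df[cols].copy()
        for c in date_cols:
            df[c] = pd.to_datetime(df[c].where(df[c] != ""), format="%Y-%m-%d")
        if name == "prescriptions":
            df["supply_days"] = df["supply_days"].astype("int64")
        tables[name] = df
    bundle = EHRBundle(**tables)
    bundle.validate()
    return bundle
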