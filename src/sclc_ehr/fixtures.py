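"""Synthetic, deterministically engineered bundles for worked examples.

:func:`flowchart_bundle` constructs a bundle in which the ascertainment
flowchart reproduces a prescribed set of stratum counts exactly: every
patient is trivially eligible, each receives one index cancer code, and
the configured numbers of patients receive a cross code or a free-text
comment of each kind.  Useful for demonstrating the extrapolation
arithmetic at full scale without any randomness.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .synth import EHRBundle

__all__ = ["flowchart_bundle", "FLOWCHART_COUNTS"]

# stratum sizes for the bundled worked example
FLOWCHART_COUNTS = dict(
    n_group1=24_508, n_cross1=364, n_text_sclc_only=2_000,
    n_text_non_only=4_166, n_text_both=353,
    n_group2=733, n_cross2=137, n_text_lung=437,
)

_NOTE_SCLC = "small cell lung cancer confirmed on biopsy"
_NOTE_NON = "histology shows NSCLC"
_NOTE_BOTH = "small cell vs non small cell lung cancer - awaiting histology"
_NOTE_LUNG = "lung cancer confirmed at mdt"


def flowchart_bundle(
    n_group1: int = FLOWCHART_COUNTS["n_group1"],
    n_cross1: int = FLOWCHART_COUNTS["n_cross1"],
    n_text_sclc_only: int = FLOWCHART_COUNTS["n_text_sclc_only"],
    n_text_non_only: int = FLOWCHART_COUNTS["n_text_non_only"],
    n_text_both: int = FLOWCHART_COUNTS["n_text_both"],
    n_group2: int = FLOWCHART_COUNTS["n_group2"],
    n_cross2: int = FLOWCHART_COUNTS["n_cross2"],
    n_text_lung: int = FLOWCHART_COUNTS["n_text_lung"],
    index_date: date = date(2005, 7, 1),
) -> EHRBundle:
    """Bundle whose ascertainment yields exactly the given stratum counts."""
    if n_cross1 + n_text_sclc_only + n_text_non_only + n_text_both > n_group1:
        raise ValueError("group-1 strata exceed the group size")
    if n_cross2 + n_text_lung > n_group2:
        raise ValueError("group-2 strata exceed the group size")
    n = n_group1 + n_group2
    pid = np.array([f"F{i:07d}" for i in range(n)], dtype=object)
    idx_ts = pd.Timestamp(index_date)

    is_g1 = np.arange(n) < n_group1
    # positions within each group determine the stratum
    pos = np.where(is_g1, np.arange(n), np.arange(n) - n_group1)
    b1 = np.cumsum([n_cross1, n_text_sclc_only, n_text_non_only, n_text_both])
    stratum = np.full(n, "no_text", dtype=object)
    stratum[is_g1 & (pos < b1[0])] = "cross"
    stratum[is_g1 & (pos >= b1[0]) & (pos < b1[1])] = "sclc"
    stratum[is_g1 & (pos >= b1[1]) & (pos < b1[2])] = "non"
    stratum[is_g1 & (pos >= b1[2]) & (pos < b1[3])] = "both"
    stratum[~is_g1 & (pos < n_cross2)] = "cross"
    stratum[~is_g1 & (pos >= n_cross2) & (pos < n_cross2 + n_text_lung)] = "lung"

    ev_pid, ev_day, ev_code, ev_text = [], [], [], []

    def _emit(ids, day, code, text=""):
        ev_pid.append(ids)
        ev_day.append(np.full(len(ids), day))
        ev_code.append(np.full(len(ids), code, dtype=object))
        ev_text.append(np.full(len(ids), text, dtype=object))

    _emit(pid, pd.Timestamp("1999-06-01"), "ENC_VISIT")
    _emit(pid[is_g1], idx_ts, "LUNG_CA_1")
    _emit(pid[~is_g1], idx_ts, "SCC_1")
    cross = stratum == "cross"
    _emit(pid[is_g1 & cross], idx_ts + pd.Timedelta(days=60), "SCC_1")
    _emit(pid[~is_g1 & cross], idx_ts + pd.Timedelta(days=60), "LUNG_CA_1")
    note_day = idx_ts + pd.Timedelta(days=10)
    _emit(pid[stratum == "sclc"], note_day, "ENC_VISIT", _NOTE_SCLC)
    _emit(pid[stratum == "non"], note_day, "ENC_VISIT", _NOTE_NON)
    _emit(pid[stratum == "both"], note_day, "ENC_VISIT", _NOTE_BOTH)
    _emit(pid[stratum == "lung"], note_day, "ENC_VISIT", _NOTE_LUNG)
    # a pre-diagnosis symptom for the expected cases, to exercise backdating
    expected = cross | (stratum == "sclc") | (stratum == "lung")
    _emit(pid[expected], idx_ts - pd.Timedelta(days=36), "SYMP_COUGH")

    events = pd.DataFrame({
        "patient_id": np.concatenate(ev_pid),
        "event_date": pd.to_datetime(np.concatenate(ev_day)),
        "code": np.concatenate(ev_code),
        "free_text": np.concatenate(ev_text),
    }).sort_values(["patient_id", "event_date", "code"],
                   kind="mergesort").reset_index(drop=True)

    patients = pd.DataFrame({
        "patient_id": pid,
        "sex": np.where(np.arange(n) % 2 == 0, "M", "F"),
        "birth_date": pd.Timestamp("1945-06-15"),
        "registration_start": pd.Timestamp("1995-01-01"),
        "registration_status": "permanent",
        "registration_end": pd.NaT,
        "death_date": pd.NaT,
    })
    prescriptions = pd.DataFrame({
        "patient_id": pid,
        "issue_date": pd.Timestamp("1995-02-01"),
        "drug_class": "ppi",
        "supply_days": np.full(n, 28, dtype="int64"),
    })
    truth_disease = np.where(
        cross | np.isin(stratum, ["sclc", "lung"]), "SCLC", "NSCLC"
    ).astype(object)
    truth = pd.DataFrame({
        "patient_id": pid,
        "true_disease": truth_disease,
        "true_onset_date": idx_ts,
        "true_stage": np.where(truth_disease == "SCLC", "extensive",
                               "unknown").astype(object),
        "true_death_date": pd.NaT,
    })
    bundle = EHRBundle(patients, events, prescriptions, truth)
    bundle.validate()
    return bundle
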