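"""Shared fixtures: synthetic bundles and a hand-crafted bundle builder."""

from __future__ import annotations

import pandas as pd
import pytest

from sclc_ehr import (EHRBundle, SimConfig, default_codelists,
                      default_patterns, generate_bundle)

PATIENT_DEFAULTS = {
    "sex": "M",
    "birth_date": "1945-06-15",
    "registration_start": "1995-01-01",
    "registration_status": "permanent",
    "registration_end": None,
    "death_date": None,
}


def mk_bundle(patients, events=(), prescriptions=(), truth=()) -> EHRBundle:
    """Build a small bundle from row dicts, filling sensible defaults."""
    pat_rows = []
    for p in patients:
        row = {**PATIENT_DEFAULTS, **p}
        pat_rows.append(row)
    pats = pd.DataFrame(pat_rows)
    for c in ("birth_date", "registration_start", "registration_end",
              "death_date"):
        pats[c] = pd.to_datetime(pats[c])
    from sclc_ehr.synth import PATIENT_COLUMNS
    pats = pats[PATIENT_COLUMNS]

    ev_rows = [{"free_text": "", **e} for e in events]
    ev = pd.DataFrame(ev_rows, columns=["patient_id", "event_date", "code",
                                        "free_text"])
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev["free_text"] = ev["free_text"].fillna("")

    rx = pd.DataFrame(list(prescriptions),
                      columns=["patient_id", "issue_date", "drug_class",
                               "supply_days"])
    rx["issue_date"] = pd.to_datetime(rx["issue_date"])
    rx["supply_days"] = rx["supply_days"].astype("int64") if len(rx) else \
        rx["supply_days"]

    tr_rows = [{"true_disease": "NONE", "true_onset_date": None,
                "true_stage": "unknown", "true_death_date": None, **t}
               for t in truth]
    tr = pd.DataFrame(tr_rows, columns=["patient_id", "true_disease",
                                        "true_onset_date", "true_stage",
                                        "true_death_date"])
    for c in ("true_onset_date", "true_death_date"):
        tr[c] = pd.to_datetime(tr[c])
    return EHRBundle(pats, ev, rx, tr)


@pytest.fixture(scope="session")
def codelists():
    return default_codelists()


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


@pytest.fixture(scope="session")
def small_bundle():
    """2,500 patients with an inflated cancer hazard so every stratum of
    the ascertainment flowchart is populated at desk scale."""
    return generate_bundle(
        SimConfig(n_patients=2500, annual_sclc_hazard=1.5e-3, seed=11))


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_bundle(SimConfig(n_patients=150, seed=5))
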