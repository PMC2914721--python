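import numpy as np
import pandas as pd
import pytest

from dfi.codes import load_registry
from dfi.cohort import build_cohort
from dfi.io import SCHEMAS, ClaimsBundle
from dfi.outcomes import outcomes_frame
from dfi.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def registry():
    return load_registry()


def make_bundle(**tables) -> ClaimsBundle:
    """Build a small in-memory bundle from lists of row dicts."""
    frames = {}
    for name, (cols, datecols) in SCHEMAS.items():
        rows = tables.get(name, [])
        df = pd.DataFrame(rows, columns=cols)
        for c in datecols:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
        if "position" in df.columns:
            df["position"] = pd.to_numeric(df["position"]).astype("Int64")
        frames[name] = df
    return ClaimsBundle(**frames)


@pytest.fixture()
def tiny_bundle():
    """One classifiable patient with lookback history and follow-up events."""
    return make_bundle(
        patients=[
            {
                "patient_id": "P1",
                "sex": "M",
                "birth_date": "1935-06-15",
                "race": "WHITE",
                "death_date": "",
            }
        ],
        stays=[
            # non-infection stay long before index
            {"stay_id": "S0", "patient_id": "P1", "admit_date": "1999-01-10",
             "discharge_date": "1999-01-12", "care_setting": "ACUTE"},
            # index: ulcer + foot cellulitis
            {"stay_id": "S1", "patient_id": "P1", "admit_date": "2001-03-01",
             "discharge_date": "2001-03-11", "care_setting": "ACUTE"},
            # readmission with gangrene 30 days after discharge
            {"stay_id": "S2", "patient_id": "P1", "admit_date": "2001-04-10",
             "discharge_date": "2001-04-20", "care_setting": "ACUTE"},
        ],
        stay_dx=[
            {"stay_id": "S0", "position": 1, "icd9_code": "25000"},
            {"stay_id": "S1", "position": 1, "icd9_code": "70714"},
            {"stay_id": "S1", "position": 2, "icd9_code": "6827"},
            {"stay_id": "S2", "position": 1, "icd9_code": "44024"},
        ],
        stay_proc=[{"stay_id": "S2", "icd9_proc_code": "8411"}],
        visits=[
            # neuropathy coded 100 days before index (in window)
            {"visit_id": "V1", "patient_id": "P1", "visit_date": "2000-11-21",
             "care_setting": "OUTPATIENT"},
            # PVD coded 800 days before index (outside window)
            {"visit_id": "V2", "patient_id": "P1", "visit_date": "1998-12-21",
             "care_setting": "OUTPATIENT"},
        ],
        visit_dx=[
            {"visit_id": "V1", "position": 1, "icd9_code": "2506"},
            {"visit_id": "V2", "position": 1, "icd9_code": "4400"},
        ],
    )


@pytest.fixture(scope="session")
def sim_small():
    """Mid-size simulated bundle shared by round-trip tests."""
    bundle, truth = simulate(SimulationConfig(n_patients=1000, seed=7))
    return bundle, truth


@pytest.fixture(scope="session")
def sim_large():
    """Large fixed-seed run for parameter-recovery checks: bundle, truth,
    cohort and outcomes, computed once per session."""
    config = SimulationConfig(n_patients=50_000, seed=1)
    bundle, truth = simulate(config)
    registry = load_registry()
    cohort = build_cohort(bundle, registry)
    outcomes = outcomes_frame(cohort, bundle, registry)
    return {
        "config": config,
        "bundle": bundle,
        "truth": truth,
        "cohort": cohort,
        "outcomes": outcomes,
    }
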