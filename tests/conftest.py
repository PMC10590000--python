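import numpy as np
import pandas as pd
import pytest

from mafld_traj import taxonomy
from mafld_traj.synthetic import SimulationConfig, simulate_cohort


def make_participants(n=6, **overrides):
    """Minimal valid participant table with hand-set biomarkers."""
    base = {
        "participant_id": [f"P{i}" for i in range(n)],
        "age": 55.0,
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "townsend": 0.0,
        "bmi": 27.0,
        "waist": 95.0,
        "tg": 1.5,
        "hdl": 1.4,
        "ggt": 40.0,
        "ast": 25.0,
        "alt": 25.0,
        "platelets": 250.0,
        "albumin": 4.2,
        "glucose": 90.0,
        "hba1c": 5.4,
        "sbp": 120.0,
        "dbp": 75.0,
        "bp_med": 0,
        "t2d": 0,
        "alcohol": 5.0,
        "snp_mboat7": 1,
        "snp_gckr": 1,
        "snp_tm6sf2": 0,
        "snp_pnpla3": 1,
        "assessment_date": "2010-01-01",
        "censor_date": "2023-01-01",
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def participants():
    return make_participants()


@pytest.fixture
def small_cohort():
    """2,000-participant simulated cohort with planted structure."""
    cfg = SimulationConfig(
        n_participants=2000,
        seed=11,
        disease_catalog={"D10": 0.02, "D11": 0.03, "D12": 0.02, "D13": 0.015},
        exposure_hr={"D10": 3.0, "D11": 2.5},
        pair_amplification={("D10", "D11"): 4.0},
        death_cause_hazards={"I64": {"rate": 0.004,
                                     "disease_multipliers": {"D10": 3.0}}},
    )
    participants, diagnoses, deaths_raw, truth = simulate_cohort(cfg)
    mapping = taxonomy.identity_mapping(cfg.disease_catalog)
    events = taxonomy.collapse_events(diagnoses, mapping)
    scheme = taxonomy.load_death_scheme()
    deaths = taxonomy.prepare_deaths(deaths_raw, scheme)
    return {
        "config": cfg,
        "participants": participants,
        "events": events,
        "deaths": deaths,
        "truth": truth,
        "mapping": mapping,
        "scheme": scheme,
    }


def exposure_cohort(participants, truth):
    """Attach the ground-truth exposure flag as an analysis column."""
    cohort = participants.copy()
    cohort["exposed"] = cohort["participant_id"].map(truth.exposed_flags).astype(int)
    return cohort
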