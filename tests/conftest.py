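import numpy as np
import pandas as pd
import pytest

from pph_cea import costs as costs_mod
from pph_cea import daly as daly_mod
from pph_cea.records import RESOURCE_ITEMS
from pph_cea.synth import TrialScenario, generate_trial


def tiny_records() -> pd.DataFrame:
    """Three hand-written birth records covering the main field combinations."""
    base = {item: [0.0, 1.0, 2.0] for item in RESOURCE_ITEMS}
    return pd.DataFrame(
        {
            "patient_id": ["a", "b", "c"],
            "cluster_id": ["c1", "c1", "c2"],
            "country": ["kenya", "kenya", "nigeria"],
            "phase": ["baseline", "implementation", "baseline"],
            "arm": ["intervention", "intervention", "usual_care"],
            "blood_loss_ml": [300.0, 1250.0, np.nan],
            "source_verified": [True, True, False],
            "death_from_bleeding": [False, False, False],
            "age_years": [25.0, 31.0, 19.5],
            **base,
        }
    )


@pytest.fixture(scope="session")
def unit_cost_table():
    return costs_mod.default_unit_cost_table()


@pytest.fixture(scope="session")
def life_tables():
    return daly_mod.load_life_tables(costs_mod._data_path("life_tables.csv"))


@pytest.fixture(scope="session")
def daly_params():
    return daly_mod.DalyParams()


@pytest.fixture(scope="session")
def small_trial():
    """A small but structurally complete trial: 22 clusters, ~13k records."""
    scenario = TrialScenario(
        clusters_per_country_per_arm={"kenya": 3, "nigeria": 4, "south_africa": 2, "tanzania": 2},
        patients_per_cluster_per_phase=300,
        seed=20,
    )
    clusters, records = generate_trial(scenario)
    return scenario, clusters, records


@pytest.fixture(scope="session")
def small_complete(small_trial):
    _, clusters, records = small_trial
    return clusters, records[records["blood_loss_ml"].notna()]


@pytest.fixture(scope="session")
def eight_cluster_trial():
    """Two-country, 8-cluster fixture for exhaustive permutation enumeration."""
    scenario = TrialScenario(
        clusters_per_country_per_arm={"kenya": 2, "nigeria": 2, "south_africa": 0, "tanzania": 0},
        patients_per_cluster_per_phase=120,
        missing_blood_loss_rate=0.0,
        seed=8,
    )
    clusters, records = generate_trial(scenario)
    return clusters, records
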