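import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sigscore as sg

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_compendium(values, probe_ids=None, array_ids=None, entrez=None, cohort=None):
    """Build a small ExpressionCompendium from a plain array."""
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    array_ids = array_ids or [f"a{j}" for j in range(values.shape[1])]
    entrez = entrez if entrez is not None else [str(100 + i) for i in range(values.shape[0])]
    df = pd.DataFrame(
        values,
        index=pd.Index(probe_ids, name="probe_id"),
        columns=pd.Index(array_ids, name="array_id"),
    )
    feats = pd.DataFrame(
        {"gene_symbol": [f"S{i}" for i in range(values.shape[0])], "entrez_id": entrez},
        index=df.index,
    )
    return sg.ExpressionCompendium(df, feats, cohort=cohort)


def make_sample_table(array_ids, patient_ids, batches=None, **overrides):
    n = len(array_ids)
    base = {
        "array_id": list(array_ids),
        "patient_id": list(patient_ids),
        "batch": list(batches) if batches is not None else ["b1"] * n,
        "diagnosis": ["dSSc"] * n,
        "biopsy_site": ["forearm_lesional"] * n,
        "timepoint_label": ["t0"] * n,
        "mrss": [10] * n,
        "age": [50] * n,
        "sex": ["F"] * n,
        "disease_duration_years": [3.0] * n,
        "original_subset_label": [""] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def tiny_compendium():
    rng = np.random.default_rng(7)
    return make_compendium(rng.normal(size=(10, 6)))


@pytest.fixture
def default_sim():
    return sg.simulate_compendium(sg.CompendiumSimSpec(seed=11))
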