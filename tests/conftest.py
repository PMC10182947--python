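import numpy as np
import pandas as pd
import pytest

from mechtox import (
    FeatureTable,
    GeneratorConfig,
    TrainConfig,
    default_signatures,
    demo_training_design,
    generate_study,
)


def make_table(
    values,
    types=None,
    batch=None,
    injection_order=None,
    compound=None,
    concentration=None,
    mechanism_label=None,
    protein=None,
    sample_ids=None,
    feature_ids=None,
    hmdb=None,
):
    """Small hand-built feature table for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j}" for j in range(p)]
    types = types or ["treated"] * n

    def fill(x, default):
        if x is None:
            return [default] * n
        return list(x)

    samples = pd.DataFrame(
        {
            "type": types,
            "compound": fill(compound, None),
            "concentration": fill(concentration, None),
            "batch": fill(batch, 1),
            "injection_order": (
                list(injection_order) if injection_order is not None
                else list(range(1, n + 1))
            ),
            "mechanism_label": fill(mechanism_label, None),
            "protein": fill(protein, np.nan),
        },
        index=pd.Index(sample_ids),
    )
    # treated samples need compound/concentration; default them when absent
    for sid, row in samples.iterrows():
        if row["type"] == "treated":
            if row["compound"] is None:
                samples.loc[sid, "compound"] = "cmpd"
            if row["concentration"] is None:
                samples.loc[sid, "concentration"] = 10.0
    features = pd.DataFrame(
        {
            "mz": 100.0 + np.arange(p),
            "rt": 10.0 * (np.arange(p) + 1),
            "method": ["method1"] * p,
            "hmdb_id": list(hmdb) if hmdb is not None else [None] * p,
            "name": [None] * p,
        },
        index=pd.Index(feature_ids),
    )
    intens = pd.DataFrame(values, index=samples.index, columns=feature_ids)
    return FeatureTable(intens, samples, features)


@pytest.fixture(scope="session")
def small_signatures():
    return default_signatures(
        n_features=200, markers_per_mechanism=8, n_general_markers=10, seed=5
    )


@pytest.fixture(scope="session")
def small_design():
    return demo_training_design(seed=3, n_per_mechanism=3, n_nontoxic=4,
                                n_batches=2, n_controls_per_batch=6)


@pytest.fixture(scope="session")
def small_study(small_design, small_signatures):
    cfg = GeneratorConfig(n_features=200, seed=42)
    return generate_study(small_design, small_signatures, cfg)


@pytest.fixture(scope="session")
def quiet_study(small_design, small_signatures):
    """Zero drift / zero batch shift / zero noise variant of the small study."""
    cfg = GeneratorConfig(
        n_features=200, seed=42, drift_amplitude=0.0, batch_scale_sd=0.0,
        rsd_noise=0.0, protein_cv=0.0,
    )
    return generate_study(small_design, small_signatures, cfg)


@pytest.fixture(scope="session")
def fast_train_config():
    return TrainConfig(max_lv=4, k=3, repeats=3, seed=0)
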