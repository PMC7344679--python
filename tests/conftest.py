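import numpy as np
import pandas as pd
import pytest

from sensomet.preprocess import preprocess
from sensomet.synthetic import SyntheticConfig, generate_dataset
from sensomet.tables import FeatureTable, SampleMetadata


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (2 x 3 x 4 x 3 design, 2000 features)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def processed_default(default_dataset):
    table, meta, scores, db, gt = default_dataset
    processed, report = preprocess(table, meta)
    return processed, report


def make_table(intensities, mz=None, rt=None, mode="positive", sample_ids=None):
    """Small hand-built FeatureTable for unit tests."""
    arr = np.asarray(intensities, dtype=float)
    n_feat, n_samp = arr.shape
    fids = [f"f{i + 1}" for i in range(n_feat)]
    sids = sample_ids or [f"s{j + 1}" for j in range(n_samp)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(200.0, 400.0, n_feat),
            "rt": rt if rt is not None else np.linspace(1.0, 10.0, n_feat),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    return FeatureTable(
        features=features,
        intensities=pd.DataFrame(arr, index=features.index, columns=sids),
        mode=mode,
    )


def make_metadata(sample_ids, batches=None, volumes=None, seasons=None, clusters=None):
    n = len(sample_ids)
    return SampleMetadata(
        table=pd.DataFrame(
            {
                "season": seasons or ["S1"] * n,
                "cluster_type": clusters or ["i"] * n,
                "batch": batches or ["B1"] * n,
                "injection_volume": volumes or [1.0] * n,
                "biological_rep": list(range(1, n + 1)),
                "technical_rep": [1] * n,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
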