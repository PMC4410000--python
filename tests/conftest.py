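import numpy as np
import pandas as pd
import pytest

import dimorphseq as ds


@pytest.fixture(scope="session")
def small_config():
    return ds.SimulationConfig(n_autosomal=200, n_x=50, n_y=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ann = ds.simulate_annotation(small_config)
    cm, truth = ds.simulate_counts(ann, small_config)
    return ann, cm, truth


def make_count_matrix(counts: dict, sex: list[str]) -> ds.CountMatrix:
    """Build a CountMatrix from {gene: [counts...]} and per-sample sexes."""
    df = pd.DataFrame(counts).T.astype(np.int64)
    samples = [f"s{i}" for i in range(df.shape[1])]
    df.columns = samples
    meta = pd.DataFrame(
        {"sex": sex, "stage": "test"}, index=pd.Index(samples, name="sample_id")
    )
    return ds.CountMatrix(df, meta)
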