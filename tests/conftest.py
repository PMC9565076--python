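import numpy as np
import pandas as pd
import pytest

from cdwheat import SyntheticConfig, generate, generate_null


def make_frame(y, x, q):
    """Minimal regression frame for threshold-fit tests."""
    y = np.asarray(y, dtype=float)
    return pd.DataFrame({
        "sample_id": [str(i) for i in range(y.size)],
        "y": y, "x": np.asarray(x, dtype=float),
        "q": np.asarray(q, dtype=float),
    })


@pytest.fixture(scope="session")
def study_data():
    """Synthetic 22-sample survey with the default planted pH threshold."""
    return generate(SyntheticConfig(n=22, seed=1))


@pytest.fixture(scope="session")
def null_data():
    """Single-regime (no-threshold) synthetic survey, n = 200."""
    return generate_null(SyntheticConfig(n=200, seed=7))


@pytest.fixture()
def study_csv(tmp_path, study_data):
    from cdwheat import write_dataset

    path = tmp_path / "study.csv"
    write_dataset(study_data, path)
    return path
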