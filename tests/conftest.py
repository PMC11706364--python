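import numpy as np
import pandas as pd
import pytest

from lipopanel import LipidFeatureTable, SyntheticConfig, generate_dataset


def make_toy_table(n_case=5, n_control=5, n_features=4, seed=0, scale="raw"):
    """Small hand-sized table with valid metadata for unit tests."""
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    ids = [f"CG{i}" for i in range(n_control)] + [f"EG{i}" for i in range(n_case)]
    feats = [f"{j + 1}{'POS' if j % 2 else 'NEG'}" for j in range(n_features)]
    ab = pd.DataFrame(rng.uniform(10, 100, size=(n, n_features)), index=ids, columns=feats)
    if scale == "log2":
        ab = np.log2(ab)
    fm = pd.DataFrame(
        {
            "annotation": [f"lipid {f}" for f in feats],
            "lipid_class": ["PI", "PE", "TG", "PC"][: n_features] + ["other"] * max(0, n_features - 4),
            "ion_mode": ["POS" if j % 2 else "NEG" for j in range(n_features)],
        },
        index=feats,
    )
    sm = pd.DataFrame(
        {"group": ["CG"] * n_control + ["EG"] * n_case, "Age": rng.uniform(20, 35, n)},
        index=ids,
    )
    return LipidFeatureTable(ab, fm, sm, scale=scale)


@pytest.fixture
def toy_table():
    return make_toy_table()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down synthetic design for fast module tests."""
    return SyntheticConfig(
        n_case=45, n_control=15, n_features=120, n_weak=6, seed=7, missing_rate=0.02
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
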