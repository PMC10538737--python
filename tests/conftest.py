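import numpy as np
import pandas as pd
import pytest

import permfit as pf


@pytest.fixture(scope="session")
def tiny_meta():
    return [
        pf.FeatureMeta("dvt", "binary", ("No", "Yes")),
        pf.FeatureMeta("age", "continuous"),
    ]


@pytest.fixture(scope="session")
def tiny_csv(tmp_path_factory, tiny_meta):
    path = tmp_path_factory.mktemp("data") / "tiny.csv"
    pd.DataFrame(
        {
            "dvt": ["Yes", "No", "No"],
            "age": [61.5, 40.0, 55.25],
            "pe": ["positive", "negative", "positive"],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """Signal cohort small enough for fast learner fits (2 informative
    binaries + 1 continuous + nulls)."""
    rng = np.random.default_rng(7)
    n = 240
    raw = pd.DataFrame(
        {
            "b1": rng.choice(["No", "Yes"], n, p=[0.5, 0.5]),
            "b2": rng.choice(["No", "Yes"], n, p=[0.7, 0.3]),
            "x1": rng.normal(0, 1, n),
            "x_null": rng.normal(0, 1, n),
        }
    )
    meta = [
        pf.FeatureMeta("b1", "binary", ("No", "Yes")),
        pf.FeatureMeta("b2", "binary", ("No", "Yes")),
        pf.FeatureMeta("x1", "continuous"),
        pf.FeatureMeta("x_null", "continuous"),
    ]
    X, cmap, names = pf.encode_features(raw, meta)
    eta = 1.5 * X[:, cmap["b1"][0]] + 1.0 * X[:, cmap["x1"][0]] - 0.8
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pf.CohortTable(X, y, meta, cmap, names)


@pytest.fixture(scope="session")
def small_dnn_config():
    """Reduced network configuration keeping automated runs fast."""
    return pf.DnnEnsembleConfig(hidden_layers=(16, 8), n_bags=5, epochs=25, seed=0)
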