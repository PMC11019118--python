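import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chronoscreen.synth import (ActivitySimConfig, OmicsSimConfig,
                                generate_activity, generate_omics,
                                young_like_config)

settings.register_profile("repro", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def young_matrix_truth():
    """Default young-like omics matrix (159 features, 17 rhythmic, 5 reps)."""
    return generate_omics(young_like_config(seed=42))


@pytest.fixture(scope="session")
def noise_matrix():
    cfg = OmicsSimConfig(n_features=60, reps_per_group={"g": 5},
                         noise_cv={"g": 0.1}, seed=5)
    matrix, _ = generate_omics(cfg)
    return matrix


@pytest.fixture(scope="session")
def small_activity():
    cfg = ActivitySimConfig(n_flies=8, days=4, seed=2)
    return generate_activity(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-sized 4-feature, 2-ZT-rep matrix for unit checks."""
    ids = ["a", "b", "c", "d"]
    cols, meta = [], []
    rng = np.random.default_rng(0)
    vals = []
    for zt in (0, 4, 8, 12, 16, 20):
        for rep in (1, 2):
            sid = f"g_ZT{zt:02d}_rep{rep}"
            cols.append(sid)
            meta.append({"sample_id": sid, "group": "g", "zt": float(zt),
                         "replicate": rep})
            vals.append(rng.lognormal(size=4))
    from chronoscreen.synth import TimeCourseMatrix
    return TimeCourseMatrix(
        values=pd.DataFrame(np.column_stack(vals), index=ids, columns=cols),
        sample_meta=pd.DataFrame(meta),
    )
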