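import numpy as np
import pandas as pd
import pytest

import wavefuse as wf
from wavefuse.features import ModalityFeatures


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the calibrated defaults (57 subjects)."""
    return wf.generate_cohort(wf.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for pipeline tests: 29 subjects, small grid."""
    cfg = wf.CohortConfig(
        group_sizes={"HC": 12, "GAD": 10, "MD": 7},
        n_comorbid=6,
        grid_shape=(20, 24, 20),
        seed=11,
    )
    return wf.generate_cohort(cfg)


@pytest.fixture
def make_modality():
    """Factory for ad-hoc ModalityFeatures from a plain matrix."""

    def _make(X, regions=None, ids=None, modality="synthetic"):
        X = np.asarray(X, dtype=float)
        if ids is None:
            ids = [f"S{i:03d}" for i in range(X.shape[0])]
        if regions is None:
            regions = [f"f{j}" for j in range(X.shape[1])]
        return ModalityFeatures(
            modality=modality,
            matrix=X,
            subject_ids=list(ids),
            feature_meta=pd.DataFrame({"region": regions}),
        )

    return _make


def separated_clouds(n_pos=10, n_neg=10, d=3, gap=8.0, noise=1.0, seed=0):
    """Two well-separated Gaussian clouds with +/-1 labels."""
    rng = np.random.default_rng(seed)
    Xp = rng.normal(gap / 2, noise, size=(n_pos, d))
    Xn = rng.normal(-gap / 2, noise, size=(n_neg, d))
    X = np.vstack([Xp, Xn])
    y = np.array([1] * n_pos + [-1] * n_neg)
    return X, y
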