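import numpy as np
import pandas as pd
import pytest

from chromorigin import (
    BoostParams,
    ChromatinMatrix,
    ExclusionSet,
    FeatureMetadata,
    MutationProfile,
    SimConfig,
    build_windows,
    simulate_chromatin,
    simulate_mutations,
)


@pytest.fixture(scope="session")
def toy_windows():
    """3 windows of 1 Mb on one toy chromosome."""
    return build_windows({"chr1": 3_500_000}, ExclusionSet())


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-driver dataset: 300 windows, 4 tissues x 3 features."""
    cfg = SimConfig(
        n_windows=300, n_tissues=4, features_per_tissue=3, n_chromosomes=3, seed=11
    )
    X, meta, truth = simulate_chromatin(cfg)
    y = simulate_mutations(truth, cfg)
    return cfg, X, meta, truth, y


@pytest.fixture(scope="session")
def default_sim():
    """One dataset at the reference conditions (2128 windows, 8x8 features)."""
    cfg = SimConfig(seed=5)
    X, meta, truth = simulate_chromatin(cfg)
    y = simulate_mutations(truth, cfg)
    return cfg, X, meta, truth, y


@pytest.fixture
def fast_params():
    """Boost params with fewer CV folds for cheap unit tests."""
    return BoostParams(cv_folds=5, seed=2)


def make_matrix(arrays: dict, fingerprint: str = "") -> ChromatinMatrix:
    df = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in sorted(arrays.items())}
    )
    return ChromatinMatrix(df, fingerprint)


def make_meta(tissue_by_feature: dict) -> FeatureMetadata:
    return FeatureMetadata(
        pd.DataFrame(
            {
                "tissue_type": pd.Series(tissue_by_feature),
                "mark": "H3K4me1",
                "source": "synthetic",
            }
        ).rename_axis("feature_id")
    )


def make_profile(counts, sample_id="s", fingerprint="") -> MutationProfile:
    return MutationProfile(sample_id, np.asarray(counts, dtype=np.int64), fingerprint)
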