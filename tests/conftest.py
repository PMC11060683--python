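import warnings

import numpy as np
import pytest

from hapase import (
    AseBoostModel,
    BoostParams,
    SplitSpec,
    SyntheticConfig,
    generate_dataset,
)

# the single-driver benchmark scenario: one dominant planted effect on CHG
# gene-body methylation, low ratio noise, one condition (one row per pair)
DRIVER_SCENARIO = dict(
    n_pairs=5000,
    effect_sizes={"mCHG_gene": 2.5},
    ratio_noise_sd=0.1,
    frac_null_pairs=0.0,
    frac_unexpressed_pairs=0.0,
    tissues=("leaf",),
    treatments=("NH",),
)

# the zero-signal scenario: no planted effects, category driven by pure noise
NULL_SCENARIO = dict(
    n_pairs=5000,
    effect_sizes={},
    ratio_noise_sd=0.8,
    frac_null_pairs=0.0,
    frac_unexpressed_pairs=0.0,
    tissues=("leaf",),
    treatments=("NH",),
)


def driver_dataset(seed: int):
    return generate_dataset(SyntheticConfig(seed=seed, **DRIVER_SCENARIO), with_tracks=False)


def fit_model0(table, seed: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AseBoostModel.from_feature_table(
            table, "model0", params=BoostParams(seed=seed), split=SplitSpec(seed=seed)
        ).fit()


@pytest.fixture(scope="session")
def small_dataset():
    """60 pairs with all tracks emitted; shared across modules."""
    return generate_dataset(SyntheticConfig(n_pairs=60, seed=42))


@pytest.fixture(scope="session")
def driver_fit():
    """One fitted strong-signal model (used for SHAP and metric checks)."""
    ds = driver_dataset(seed=101)
    table = ds.truth_feature_table()
    return table, fit_model0(table, seed=101)
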