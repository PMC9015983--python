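import numpy as np
import pandas as pd
import pytest

from ppsbayes import (
    DesignConfig,
    EffectConfig,
    aggregate_cell_means,
    filter_trials,
    generate_under_hypothesis,
    normalize_vt,
)


@pytest.fixture(scope="session")
def default_design() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def small_design() -> DesignConfig:
    return DesignConfig(n_participants=6)


@pytest.fixture(scope="session")
def default_effects() -> EffectConfig:
    return EffectConfig()


@pytest.fixture(scope="session")
def clean_effects() -> EffectConfig:
    """No contamination: every generated trial is analysable."""
    return EffectConfig(outlier_rate=0.0, miss_rate=0.0, catch_fa_rate=0.0)


def preprocess(trials: pd.DataFrame):
    kept, _ = filter_trials(trials)
    cells = aggregate_cell_means(kept)
    normalized, _ = normalize_vt(cells)
    vt = cells[cells["trial_type"] == "VT"].reset_index(drop=True)
    to = cells[cells["trial_type"] == "TO"].reset_index(drop=True)
    return vt, to, normalized


@pytest.fixture(scope="session")
def h2_tables(default_design, default_effects):
    """Preprocessed VT/TO/normalized tables from one default H2 simulation."""
    trials = generate_under_hypothesis("H2", default_design, default_effects, seed=123)
    return preprocess(trials)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
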