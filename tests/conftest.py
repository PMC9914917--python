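import numpy as np
import pytest

from qeegicp import (
    ProtocolConfig,
    SpectralProfile,
    extract_feature_table,
    generate_cohort,
    preprocess_subject,
)


@pytest.fixture(scope="session")
def tiny_protocol() -> ProtocolConfig:
    """Shortened two-step protocol for fast unit tests."""
    return ProtocolConfig(
        baseline_duration=60.0,
        injury_step_duration=90.0,
        icp_targets=(20.0, 30.0),
        ramp_duration=10.0,
        n_subjects=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_protocol):
    return generate_cohort(tiny_protocol, SpectralProfile(), rng_seed=11)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    """Feature table over the tiny cohort (all registry features)."""
    import pandas as pd

    frames = [extract_feature_table(preprocess_subject(rec)) for rec in tiny_cohort]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
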