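import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from sowpatterns import SimConfig, apply_inclusion_filters, feature_table, generate_cohort, zscore_columns


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sow cohort with moderate noise, drops and invalid-sow injection."""
    cfg = SimConfig(n_sows=120, seed=7, drop_event_rate=0.02, invalid_sow_rate=0.05)
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def clean_features():
    """Filtered + z-scored features of a noise-free 60-sow cohort."""
    cfg = SimConfig(
        n_sows=60, seed=3, day_noise_cv=0.0, drop_event_rate=0.0, invalid_sow_rate=0.0
    )
    lacts, _, truth = generate_cohort(cfg)
    kept, _ = apply_inclusion_filters(lacts)
    feats = feature_table(kept)
    return zscore_columns(feats), [truth[l.sow_id] for l in kept]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
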