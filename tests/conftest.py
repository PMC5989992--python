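import numpy as np
import pytest

from lcpmap import AttributeSpec, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60 x 300 cohort with a planted continuous trait, an ICV-confounded
    trait, a null trait, and a binary attribute (session-scoped: read-only)."""
    cfg = CohortConfig(n_subjects=60, n_features=300, n_latent=3, seed=7)
    specs = [
        AttributeSpec("trait", effect_axes=(0,), effect_sizes=(1.0,), noise_sd=1.0),
        AttributeSpec("icv_trait", icv_loading=1.0, noise_sd=0.2),
        AttributeSpec("null_trait", noise_sd=1.0),
        AttributeSpec("group", family="binary", class_fractions=(0.7, 0.3)),
    ]
    return generate_cohort(cfg, specs)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
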