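import numpy as np
import pytest

from dmfnet.synthetic import CohortSpec, generate_cohort_memory


@pytest.fixture(scope="session")
def small_cohort():
    """In-memory 12-subject phantom cohort at 32 px (6 positive / 6 negative)."""
    spec = CohortSpec(n_pos=6, n_neg=6, seed=11, class_separation=1.5, image_size=32)
    manifest, latents = generate_cohort_memory(spec)
    return spec, manifest, latents


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
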