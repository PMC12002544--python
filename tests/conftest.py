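import numpy as np
import pytest

from perishell import PhantomSpec, analyze_cohort, generate_cohort

#: A compact phantom that still fits 1-2 lesions with full shell families.
SMALL_GEOM = dict(
    shape=(64, 64, 64),
    brain_axes=(27.0, 28.0, 24.0),
    wm_axes=(20.0, 21.0, 17.0),
    n_lesions_range=(1, 2),
)


@pytest.fixture(scope="session")
def small_noise_free_cohort():
    """Noise-free 2 MS + 2 HC cohort plus its analyzed table (shared)."""
    spec = PhantomSpec.noise_free(**SMALL_GEOM)
    subjects = generate_cohort(spec, n_ms=2, n_hc=2, seed=11)
    table, results = analyze_cohort(subjects)
    return spec, subjects, table, results


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
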