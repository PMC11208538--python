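import numpy as np
import pytest

from fmricomplexity import SyntheticCohortSpec, generate_cohort


@pytest.fixture()
def rng():
    """Fresh, identically seeded generator per test: deterministic draws
    independent of test execution order."""
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_cohort():
    """Cohort at the acquisition design center (490 samples, TR 0.735 s),
    small enough for unit tests."""
    spec = SyntheticCohortSpec(
        n_subjects=12, n_rois=8, n_timepoints=490, seed=42
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def coupling_cohort():
    """Cohort whose continuous target is driven by the per-subject factor
    coupling strength (tracked by connectivity features) plus age."""
    spec = SyntheticCohortSpec(
        n_subjects=300,
        n_rois=10,
        n_timepoints=200,
        truth_feature="factor_coupling",
        beta_feature=1.0,
        beta_age=0.0,
        target_noise_sd=0.1,
        seed=7,
    )
    return generate_cohort(spec)
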