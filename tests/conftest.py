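import numpy as np
import pytest

from synaptoquant.simulate import CohortSpec, StedLayoutSpec, generate_profile_set, generate_sted_fixture


@pytest.fixture(scope="session")
def small_cohort():
    """20 profiles/group, two genotypes, used by several round-trip tests."""
    return generate_profile_set(
        CohortSpec(n_profiles_per_group=20, seed=11,
                   groups=(("WT", "no stim"), ("KO", "no stim")),
                   zone_scale_by_group={"KO": 0.65}, mean_pits=1.0)
    )


@pytest.fixture(scope="session")
def sted_fixture():
    """One noisy two-channel ROI with four puncta at known signed distances."""
    return generate_sted_fixture(
        StedLayoutSpec(seed=4, boundary_peak=300.0, punctum_amplitude=200.0,
                       puncta_signed_distances=(-120.0, 0.0, 150.0, 300.0))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
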