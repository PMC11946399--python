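import numpy as np
import pytest

import gaitrel as g


@pytest.fixture(scope="session")
def noiseless_subject():
    """One noiseless synthetic subject: (spec, profile, trial, truth)."""
    spec = g.CohortSpec(n_subjects=1, seed=11)
    profile = g.make_profile(spec, 0)
    trial, truth = g.synthesize_trial(profile, "test", noiseless=True)
    return spec, profile, trial, truth


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 4-subject noisy cohort written to disk (manifest + trial CSVs)."""
    out = tmp_path_factory.mktemp("cohort")
    spec = g.CohortSpec(n_subjects=4, seed=7)
    g.generate_cohort(spec, out_dir=out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
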