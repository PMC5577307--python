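import numpy as np
import pytest

from soaytel import sample_population, study_design
from soaytel.lmm import test_parental_age


@pytest.fixture(scope="session")
def design():
    return study_design()


@pytest.fixture(scope="session")
def population(design):
    return sample_population(design, seed=101)


@pytest.fixture(scope="session")
def null_lrt_sample(design):
    """1000 linear PAC likelihood-ratio statistics on null datasets drawn
    from the study design (pac_slope = 0)."""
    chisq, pvals = [], []
    for stream in np.random.SeedSequence(2024).spawn(1000):
        df = sample_population(design, seed=stream)
        res = test_parental_age(df, "pac", "linear")
        chisq.append(res.chisq)
        pvals.append(res.p_value)
    return np.asarray(chisq), np.asarray(pvals)


# A design sized for variance-component recovery rather than for mimicking
# the field study: many levels per grouping factor so each share is
# well-estimated, random-intercept fraction raised so the components stand
# clear of residual noise.
@pytest.fixture(scope="session")
def recovery_design():
    return study_design(
        random_frac=0.6,
        n_obs=10000,
        n_animals=10000,
        n_mothers=800,
        n_fathers=400,
        n_plates=400,
    )


@pytest.fixture(scope="session")
def recovery_population(recovery_design):
    return sample_population(recovery_design, seed=0)


@pytest.fixture(scope="session")
def small_power_curve(design):
    """Power estimates over a null-to-strong effect grid, 100 replicates."""
    from soaytel.power import PowerRequest, estimate_power

    req = PowerRequest(
        structure=design,
        effect_grid=(0.0, 0.006, 0.012, 0.033),
        n_reps=100,
        seed=7,
    )
    return estimate_power(req)
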