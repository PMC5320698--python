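import math

import pytest
from hypothesis import HealthCheck, settings
from scipy.special import logit

from wmhtrial.synthetic_cohort import (
    GeneratorConfig,
    apply_dropout,
    default_config,
    generate_cohort,
    simulate_followup,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def manual_config(n_patients: int = 100, seed: int = 0, **overrides) -> GeneratorConfig:
    """A cheap fully-specified config that skips the numeric calibrations."""
    defaults = dict(
        faz_cutpoints=(-1.0, 0.5, 3.0, 4.0, 6.0, 8.0),
        prog_intercept=9.0,
        resid_sd=7.0,
        dropout_intercept=float(logit(0.28)),
        dropout_age_coef=0.0,
        dropout_faz_coef=0.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(n_patients=n_patients, seed=seed, **defaults)


@pytest.fixture(scope="session")
def calibrated_config():
    """The study-condition config, calibrated once for the whole suite."""
    return default_config(n_patients=100_000, seed=1)


@pytest.fixture(scope="session")
def big_cohort(calibrated_config):
    """A 100k-patient cohort at the study conditions: baseline, pre-dropout, final."""
    baseline = generate_cohort(calibrated_config)
    pre_dropout = simulate_followup(baseline)
    final = apply_dropout(pre_dropout)
    return {"baseline": baseline, "pre_dropout": pre_dropout, "final": final}


@pytest.fixture(scope="session")
def big_ordinal_fit(big_cohort):
    from wmhtrial.cohort_analysis import fit_volume_to_fazekas

    return fit_volume_to_fazekas(big_cohort["baseline"])
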