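import numpy as np
import pytest

from ipirisk.synthetic_cohorts import (
    calibrate_generating_model,
    default_trial_config,
    simulate_trial_cohort,
)

#: marginal 3-year targets the generator is calibrated to: placebo risk and
#: relative reductions for lifestyle and metformin
TARGETS = (0.227, 0.58, 0.31)


@pytest.fixture(scope="session")
def calibrated_config():
    """Trial generating config with calibrated arm effects (n=2640)."""
    cfg = default_trial_config(n=2640, seed=11)
    return calibrate_generating_model(*TARGETS, cfg)


@pytest.fixture(scope="session")
def trial_cohort(calibrated_config):
    """One complete simulated trial cohort at the derivation sample size."""
    return simulate_trial_cohort(calibrated_config)


@pytest.fixture(scope="session")
def fitted_trial_model(trial_cohort):
    from ipirisk.cox_model import fit_model

    return fit_model(trial_cohort)


def random_survival_fixture(rng, n, p, tie_prone=False):
    """Small random survival dataset for oracle-equivalence checks."""
    X = rng.standard_normal((n, p))
    beta = rng.normal(0, 0.5, p)
    t = rng.exponential(1.0 / np.exp(X @ beta * 0.3), n)
    if tie_prone:
        t = np.round(t, 1) + 0.05
    d = (rng.random(n) < 0.7).astype(int)
    if d.sum() == 0:
        d[0] = 1
    return X, t, d
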