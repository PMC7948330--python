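"""Shared fixtures: the seeded demo cohort and its (expensive) MGRLMM fits.

The demo study conditions — 300 subjects over 3 waves with the default
generating truth, 4 chains of 1000 warmup + 1000 draws — are fixed here and
reused by every test that needs a converged fit, so the posterior is sampled
once per session.  The convention seed for all fixtures is 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mgrlmm.model import MgrlmmSpec, SamplerSettings, fit_mgrlmm
from mgrlmm.synthetic import make_default_truth, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SEED = 1
DEMO_COVARIATES = ("dqi", "age", "sex")


@pytest.fixture(scope="session")
def truth3():
    return make_default_truth(3)


@pytest.fixture(scope="session")
def demo_cohort(truth3) -> pd.DataFrame:
    return generate_cohort(truth3, n_subjects=300, seed=SEED)


@pytest.fixture(scope="session")
def demo_fit(demo_cohort):
    """The desk-scale reference fit: D=3, 4 chains x (1000 + 1000)."""
    spec = MgrlmmSpec(
        n_dims=3,
        covariates=DEMO_COVARIATES,
        sampler=SamplerSettings(chains=4, warmup=1000, draws=1000),
    )
    return spec, fit_mgrlmm(demo_cohort, spec, seed=SEED)


@pytest.fixture(scope="session")
def demo_fit_d2(demo_cohort):
    """The two-dimensional candidate on the same table (for comparison)."""
    spec = MgrlmmSpec(
        n_dims=2,
        covariates=DEMO_COVARIATES,
        sampler=SamplerSettings(chains=2, warmup=500, draws=500),
    )
    return spec, fit_mgrlmm(demo_cohort, spec, seed=SEED)


@pytest.fixture(scope="session")
def null_fit():
    """Fit to a cohort generated with zero DQI effect on every profile."""
    truth = make_default_truth(3)
    coefs = truth.structural_coefs.copy()
    coefs[:, 0] = 0.0  # dqi column
    from dataclasses import replace

    truth0 = replace(truth, structural_coefs=coefs)
    table = generate_cohort(truth0, n_subjects=150, seed=SEED)
    spec = MgrlmmSpec(
        n_dims=3,
        covariates=DEMO_COVARIATES,
        sampler=SamplerSettings(chains=2, warmup=400, draws=400),
    )
    return truth0, spec, fit_mgrlmm(table, spec, seed=SEED)
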