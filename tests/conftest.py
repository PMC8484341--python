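"""Shared fixtures: small synthetic cohorts reused across the suite."""

import warnings

import pytest

import mapsfc as m
from mapsfc.pipeline import fit_reference


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-event mixed cohort with doublets (shared, do not mutate)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.simulate_cohort(n_events=500, noise=m.default_noise(0.02), seed=7)


@pytest.fixture(scope="session")
def fitted_reference():
    """A full reference fit on a 2,500-event cohort (shared, do not mutate)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, ev, gt = m.simulate_cohort(n_events=2500, noise=m.default_noise(0.02), seed=3)
        fit = fit_reference(ds, ev, seed=3)
    return ds, gt, fit
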