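"""Shared fixtures: small synthetic bundles and a constant-rate cohort."""

import numpy as np
import pytest
from hypothesis import settings

import tfakenya as tk

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    return tk.SyntheticSpec(population_scale=1_000_000.0)


@pytest.fixture(scope="session")
def bundle(small_spec):
    return tk.generate_bundle(small_spec)


@pytest.fixture(scope="session")
def null_bundle(small_spec):
    return tk.generate_null_bundle(small_spec)


@pytest.fixture(scope="session")
def case_fatality(bundle):
    return tk.derive_case_fatality(bundle.disease)


@pytest.fixture(scope="session")
def model_result(bundle):
    return tk.run_model(bundle)


@pytest.fixture(scope="session")
def full_scale_result():
    """Deterministic run at the default 50-million population scale."""
    return tk.run_model(tk.generate_bundle())


def constant_rate_bundle(incidence, case_fatality, background_mortality,
                         init_prevalence=0.1):
    """Bundle with age-constant disease rates, epidemiologically consistent.

    The all-cause mortality input is background + f * p_ref(a), with
    p_ref from forward illness-death simulation, so the proportional
    substitution reproduces the intended background-plus-disease
    mortality and an external 3-state chain with rates
    (incidence, case fatality, background) is directly comparable.
    """
    n = tk.AGES.size
    prev_ref, _ = tk.simulate_illness_death(
        incidence, case_fatality, background_mortality, 20, 100,
        init_prevalence=init_prevalence)
    b = tk.generate_bundle(tk.SyntheticSpec(population_scale=1e6))
    for sex in tk.SEXES:
        b.demography.all_cause_mortality[sex] = (
            background_mortality + case_fatality * prev_ref)
        b.disease.ihd_incidence[sex] = np.full(n, float(incidence))
        b.disease.ihd_prevalence[sex] = prev_ref.copy()
        b.disease.ihd_csmr[sex] = case_fatality * prev_ref
        b.disease.ihd_yld_rate[sex] = 0.05 * prev_ref
    return b
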