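"""Synthetic, internally consistent input bundles.

The generator emulates the statistical structure of the study's input
set — a young adult population of ~50 million with Gompertz all-cause
mortality, IHD incidence and case fatality rising exponentially with
age, log-normal TFA intake distributions by age and sex (means around
0.2–0.35 %E, SD = mean/2), a relative risk of 1.23 per 2 %E with
log-normal uncertainty, and cost inputs at the published central
estimates.  Disease prevalence and cause-specific mortality are
produced by forward illness–death simulation from the chosen incidence
and case fatality, so the generated epidemiology is self-consistent by
construction and case-fatality recovery is exact up to solver
tolerance.

Every bundle passes the full input validation and is a pure function
of its SyntheticSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disease import simulate_illness_death
from .inputs import (AGE_MAX, AGE_MIN, AGES, EXPOSURE_BANDS,
                     FIVE_YEAR_BANDS, GOV_COST_CATEGORIES, SEXES,
                     CostInputs, DemographyInputs, DiseaseInputs,
                     EconSettings, ExposureDistribution, InputBundle,
                     RelativeRiskSchedule, expand_to_single_ages, parse_band)

#: Government implementation cost schedule, US$/year over years 1–5.
#: Human resources and administration are the ongoing monitoring
#: categories that continue beyond year 5.
DEFAULT_GOV_SCHEDULE = {
    "strategy_development": (150_000, 0, 0, 0, 0),
    "human_resources": (360_000,) * 5,
    "promotion_media": (60_000, 0, 0, 0, 0),
    "office_rent_equipment": (10_500,) * 5,
    "administration": (104_400,) * 5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study population ("kenya-like" preset).

    Defaults encode the study conditions: 50 million adults, TFA intake
    means spanning 0.20–0.35 %E (SD = mean/2), RR 1.23 per 2 %E with a
    log-SD matching a 1.11–1.37 95% CI, full elimination as the
    intervention, published cost levels, 3% discounting and WHO
    thresholds for Kenya.
    """

    population_scale: float = 50_000_000.0
    tfa_mean_range: tuple = (0.20, 0.35)
    rr_central: float = 1.23
    rr_log_sd: float = 0.0537  # from 95% CI 1.11-1.37 on the log scale
    rr_age_attenuation: float = 0.5  # oldest band keeps this excess-risk share
    # age-exponential disease shape: base rate at 20 and slope per year
    incidence_base: dict = field(default_factory=lambda: {
        "female": 3.0e-5, "male": 5.0e-5})
    incidence_slope: float = 0.085
    case_fatality_base: float = 0.015
    case_fatality_slope: float = 0.0009  # linear per year of age
    mortality_base: dict = field(default_factory=lambda: {
        "female": 0.0020, "male": 0.0028})
    mortality_slope: float = 0.075
    ihd_disability_weight: float = 0.06
    # cost levels (US$ central estimates)
    acute_event_cost: dict = field(default_factory=lambda: {
        "female": 6083.0, "male": 6283.0})
    prevalent_case_cost: float = 336.0
    component_event_costs: dict = field(default_factory=lambda: {
        "mi": 1996.0, "angina": 1237.0, "cardiac_arrest": 1026.0})
    reformulation_cost_per_product: float = 25_000.0  # source currency
    n_products: int = 99
    annual_industry_fraction: float = 0.01
    #: combined FX + inflation factor taking the source-currency
    #: per-product cost to base-year US$
    industry_cost_multiplier: float = 1.788
    intervention_intake: tuple = (0.0, 0.0)  # (mean, sd); 0 = elimination
    seed: int = 0


def _population_by_band(spec: SyntheticSpec) -> dict:
    """Young, smoothly declining age pyramid split 50/50 by sex."""
    los = np.array([parse_band(b)[0] for b in FIVE_YEAR_BANDS])
    shares = np.exp(-0.055 * (los - 20))
    shares /= shares.sum()
    per_sex = 0.5 * spec.population_scale * shares
    return {sex: dict(zip(FIVE_YEAR_BANDS, per_sex)) for sex in SEXES}


def generate_bundle(spec: SyntheticSpec | None = None) -> InputBundle:
    """Generate a complete, validated synthetic input bundle."""
    spec = spec or SyntheticSpec()
    a = AGES - AGE_MIN  # years since 20

    population = {
        sex: expand_to_single_ages(band_pop, kind="count")
        for sex, band_pop in _population_by_band(spec).items()}

    mortality = {
        sex: np.minimum(spec.mortality_base[sex]
                        * np.exp(spec.mortality_slope * a), 0.7)
        for sex in SEXES}

    case_fatality = spec.case_fatality_base + spec.case_fatality_slope * a
    incidence, prevalence, csmr = {}, {}, {}
    for sex in SEXES:
        incidence[sex] = (spec.incidence_base[sex]
                          * np.exp(spec.incidence_slope * a))
        # forward illness-death simulation guarantees self-consistency
        prev, cs = simulate_illness_death(
            incidence[sex], case_fatality, np.zeros(AGES.size),
            start_age=AGE_MIN, end_age=AGE_MAX, init_prevalence=0.0)
        prevalence[sex] = prev
        csmr[sex] = cs

    ihd_yld = {sex: spec.ihd_disability_weight * prevalence[sex]
               for sex in SEXES}
    all_yld = {sex: ihd_yld[sex] + 0.04 + 0.0015 * a for sex in SEXES}

    # intake means decline linearly with age across the 15 exposure
    # bands; males sit slightly above, females slightly below
    lo, hi = spec.tfa_mean_range
    n_bands = len(EXPOSURE_BANDS)
    midline = np.linspace(hi, lo, n_bands)
    sex_factor = {"female": 0.97, "male": 1.03}
    post_mean, post_sd = spec.intervention_intake
    exposure_ref, exposure_int = {}, {}
    for sex in SEXES:
        for k, band in enumerate(EXPOSURE_BANDS):
            mean = float(midline[k] * sex_factor[sex])
            exposure_ref[(sex, band)] = ExposureDistribution(
                mean=mean, sd=mean / 2.0)
            exposure_int[(sex, band)] = ExposureDistribution(
                mean=post_mean, sd=post_sd)

    excess = spec.rr_central - 1.0
    atten = np.linspace(1.0, spec.rr_age_attenuation, n_bands)
    rr = RelativeRiskSchedule(
        EXPOSURE_BANDS, 1.0 + excess * atten,
        np.full(n_bands, spec.rr_log_sd))

    other_pc = {sex: 40.0 + 1.2 * a for sex in SEXES}
    total_expenditure = {
        sex: (other_pc[sex]
              + incidence[sex] * spec.acute_event_cost[sex]
              + prevalence[sex] * spec.prevalent_case_cost)
        for sex in SEXES}

    gov = pd.DataFrame.from_dict(DEFAULT_GOV_SCHEDULE, orient="index",
                                 columns=[1, 2, 3, 4, 5]).astype(float)
    gov = gov.reindex(list(GOV_COST_CATEGORIES))

    costs = CostInputs(
        acute_event_cost=dict(spec.acute_event_cost),
        prevalent_case_cost=spec.prevalent_case_cost,
        event_mix={"male": {"mi": 0.35, "angina": 0.55, "cardiac_arrest": 0.10},
                   "female": {"mi": 0.20, "angina": 0.70, "cardiac_arrest": 0.10}},
        component_event_costs=dict(spec.component_event_costs),
        other_healthcare_per_capita=other_pc,
        gov_cost_schedule=gov,
        reformulation_cost_per_product=spec.reformulation_cost_per_product,
        n_products=spec.n_products,
        annual_industry_fraction=spec.annual_industry_fraction,
        industry_cost_multiplier=spec.industry_cost_multiplier,
    )

    bundle = InputBundle(
        demography=DemographyInputs(
            population=population,
            all_cause_mortality=mortality,
            total_health_expenditure=total_expenditure),
        disease=DiseaseInputs(
            ihd_incidence=incidence,
            ihd_prevalence=prevalence,
            ihd_csmr=csmr,
            ihd_yld_rate=ihd_yld,
            all_cause_yld_rate=all_yld),
        exposure_ref=exposure_ref,
        exposure_int=exposure_int,
        rr=rr,
        costs=costs,
        settings=EconSettings(),
    )
    bundle.validate()
    return bundle


def generate_null_bundle(spec: SyntheticSpec | None = None) -> InputBundle:
    """A bundle whose policy provably has zero health effect (RR = 1).

    With RR = 1 everywhere the PIF vanishes, the intervention scenario
    equals the reference exactly, and the net cost equals the
    implementation cost — the fixture for no-effect identities.
    """
    spec = spec or SyntheticSpec()
    bundle = generate_bundle(spec)
    n = len(EXPOSURE_BANDS)
    bundle.rr = RelativeRiskSchedule(EXPOSURE_BANDS, np.ones(n), np.zeros(n))
    return bundle
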