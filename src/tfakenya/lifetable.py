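"""Multiple-cohort proportional multistate life table engine.

The adult population is modelled as closed five-year cohorts (one per
sex and entry band, 32 in all), each simulated in annual cycles until
age 100.  Within each cohort an IHD illness–death submodel (incidence,
case fatality, no remission) runs alongside the main life table; the
intervention lowers IHD incidence by the stratum PIF, and the resulting
change in IHD mortality is substituted proportionally into all-cause
mortality:

    m'(a) = m(a) - f(a) p_ref(a) + f(a) p_int(a)

Morbidity is handled the same way: the health-adjusted life years of a
cycle are the person-years weighted by one minus total morbidity, where
the IHD share of the all-cause YLD rate moves with the modelled
prevalence (disability weight = YLD rate / prevalence).

Rates are constant over calendar time (base-case assumption of stable
intake and epidemiology); the intervention is in force from cycle 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disease import CaseFatalitySchedule
from .inputs import (AGE_MAX, AGE_MIN, AGES, COHORT_ENTRY_AGES, SEXES,
                     EconSettings, InputBundle)
from .pif import pif_by_single_age

logger = logging.getLogger(__name__)

HORIZONS = (5, 10, "lifetime")
#: Calendar length of the "lifetime" horizon: the youngest cohort
#: (entry 20) reaches age 100 after 80 cycles.
LIFETIME_YEARS = AGE_MAX - AGE_MIN


@dataclass
class CohortTrajectory:
    """Annual streams for one cohort under one scenario.

    ``alive`` has one extra entry (survivors at the end of the last
    cycle); all other arrays are per cycle.  Cycle ``t`` covers ages
    ``entry_age + t`` to ``entry_age + t + 1`` and calendar year
    ``t + 1`` after policy start.
    """

    sex: str
    entry_age: int
    alive: np.ndarray  # persons at start of each cycle, length n+1
    ihd_prevalence: np.ndarray  # proportion, within-cycle average
    incident_events: np.ndarray  # persons/year
    ihd_deaths: np.ndarray  # persons/year
    total_deaths: np.ndarray  # persons/year
    life_years: np.ndarray  # person-years per cycle
    halys: np.ndarray  # health-adjusted life years per cycle

    @property
    def n_cycles(self) -> int:
        return self.incident_events.size

    def ages(self) -> np.ndarray:
        """Start-of-cycle age for each cycle."""
        return self.entry_age + np.arange(self.n_cycles)

    def prevalent_case_years(self) -> np.ndarray:
        return self.life_years * self.ihd_prevalence


def run_cohort(bundle: InputBundle, cf: CaseFatalitySchedule,
               pif: np.ndarray | None, sex: str, entry_age: int,
               population: float | None = None) -> CohortTrajectory:
    """Simulate one cohort from ``entry_age`` to age 100.

    Parameters
    ----------
    pif : ndarray over the single-age grid 20..100, or None
        Proportional incidence reduction by current age.  ``None`` (or
        all zeros) is the reference scenario.
    population : float, optional
        Cohort size at entry; defaults to the bundle population summed
        over the entry five-year band.
    """
    if not AGE_MIN <= entry_age < AGE_MAX:
        raise ValueError(f"entry age {entry_age} outside [{AGE_MIN}, {AGE_MAX})")
    idx0 = entry_age - AGE_MIN
    if population is None:
        population = float(
            bundle.demography.population[sex][idx0:idx0 + 5].sum())

    mort = bundle.demography.all_cause_mortality[sex]
    inc = bundle.disease.ihd_incidence[sex]
    prev_in = bundle.disease.ihd_prevalence[sex]
    yld_all = bundle.disease.all_cause_yld_rate[sex]
    yld_ihd = bundle.disease.ihd_yld_rate[sex]
    fs = cf.for_sex(sex)

    n = AGE_MAX - entry_age
    alive = np.empty(n + 1)
    prevalence = np.empty(n)
    events = np.empty(n)
    ihd_deaths = np.empty(n)
    total_deaths = np.empty(n)
    life_years = np.empty(n)
    halys = np.empty(n)

    # Disease submodel occupancy (per person alive at entry): the
    # reference branch drives the proportional-substitution baseline,
    # the scenario branch carries the adjusted incidence.  Background
    # mortality cancels from prevalence, so it is omitted here.
    p0 = float(prev_in[idx0])
    sh_r, sd_r = 1.0 - p0, p0
    sh_s, sd_s = 1.0 - p0, p0

    alive[0] = population
    clamped = 0
    for t in range(n):
        ia = idx0 + t
        i = float(inc[ia])
        f = float(fs[ia])
        m = float(mort[ia])
        i_s = i * (1.0 - float(pif[ia])) if pif is not None else i

        tot_r = sh_r + sd_r
        tot_s = sh_s + sd_s
        p_ref0 = sd_r / tot_r if tot_r > 0 else 0.0
        p_scn0 = sd_s / tot_s if tot_s > 0 else 0.0

        # advance submodels one year (closed form, constant rates) and
        # use the within-cycle average prevalence for the substitution
        er_h = math.exp(-i)
        es_h = math.exp(-i_s)
        e_f = math.exp(-f)
        for which in (0, 1):
            if which == 0:
                ii, eh, sh, sd = i, er_h, sh_r, sd_r
            else:
                ii, eh, sh, sd = i_s, es_h, sh_s, sd_s
            delta = f - ii
            if abs(delta) > 1e-12:
                transfer = ii * sh * (eh - e_f) / delta
            else:
                transfer = ii * sh * eh
            sd_new = sd * e_f + transfer
            sh_new = sh * eh
            if which == 0:
                sh_r, sd_r = sh_new, sd_new
            else:
                sh_s, sd_s = sh_new, sd_new
        tot_r = sh_r + sd_r
        tot_s = sh_s + sd_s
        p_ref = 0.5 * (p_ref0 + (sd_r / tot_r if tot_r > 0 else 0.0))
        p_scn = 0.5 * (p_scn0 + (sd_s / tot_s if tot_s > 0 else 0.0))

        m_adj = m - f * p_ref + f * p_scn
        if m_adj < 0:
            clamped += 1
            m_adj = 0.0

        surv = math.exp(-m_adj)
        a0 = alive[t]
        a1 = a0 * surv
        alive[t + 1] = a1
        ly = 0.5 * (a0 + a1)  # trapezoidal person-years

        if prev_in[ia] > 0:
            dw = float(yld_ihd[ia]) / float(prev_in[ia])
        else:
            dw = 0.0
        morbidity = float(yld_all[ia]) - dw * p_ref + dw * p_scn
        morbidity = min(max(morbidity, 0.0), 1.0)

        prevalence[t] = p_scn
        events[t] = i_s * (1.0 - p_scn) * ly
        ihd_deaths[t] = f * p_scn * ly
        total_deaths[t] = a0 - a1
        life_years[t] = ly
        halys[t] = ly * (1.0 - morbidity)

    if clamped:
        logger.warning("cohort (%s, %d): adjusted mortality clamped at 0 in "
                       "%d cycle(s)", sex, entry_age, clamped)
    return CohortTrajectory(sex=sex, entry_age=entry_age, alive=alive,
                            ihd_prevalence=prevalence,
                            incident_events=events, ihd_deaths=ihd_deaths,
                            total_deaths=total_deaths, life_years=life_years,
                            halys=halys)


def run_population(bundle: InputBundle, cf: CaseFatalitySchedule,
                   pifs: pd.DataFrame | None):
    """Run all 32 cohorts under the reference and intervention scenarios.

    ``pifs`` is the stratum PIF table from :func:`tfakenya.pif.pif_table`
    (``None`` makes the intervention identical to the reference).

    Returns ``(reference, intervention)``, each a list of
    :class:`CohortTrajectory` in (sex, entry age) order.
    """
    pif_arrays = {}
    if pifs is not None:
        for sex in SEXES:
            try:
                pif_arrays[sex] = pif_by_single_age(pifs, sex, AGES)
            except KeyError as exc:
                raise ValueError(
                    f"missing PIF for a populated age group ({sex}): {exc}"
                ) from exc

    reference, intervention = [], []
    for sex in SEXES:
        for entry_age in COHORT_ENTRY_AGES:
            reference.append(run_cohort(bundle, cf, None, sex, entry_age))
            intervention.append(
                run_cohort(bundle, cf, pif_arrays.get(sex), sex, entry_age))
    return reference, intervention


def aggregate_by_year(trajectories, measure: str, sex: str | None = None,
                      n_years: int = LIFETIME_YEARS) -> np.ndarray:
    """Sum a per-cycle measure across cohorts by calendar year.

    Cycle ``t`` of every cohort falls in calendar year ``t + 1``; the
    returned array has ``n_years`` entries (year 1 first).
    """
    out = np.zeros(n_years)
    for traj in trajectories:
        if sex is not None and traj.sex != sex:
            continue
        vals = getattr(traj, measure)
        if callable(vals):
            vals = vals()
        k = min(vals.size, n_years)
        out[:k] += vals[:k]
    return out


def _horizon_years(horizon) -> int:
    return LIFETIME_YEARS if horizon == "lifetime" else int(horizon)


def discount_factors(n_years: int, rate: float) -> np.ndarray:
    """Per-year present-value factors; year 1 is undiscounted."""
    return (1.0 + rate) ** -np.arange(n_years)


@dataclass
class ScenarioComparison:
    """Reference-vs-intervention health outcomes by horizon and sex.

    ``table`` is indexed by (horizon, sex) where sex includes 'total';
    HALYs and life-years are discounted at the settings rate when
    ``discount_health`` is set, event and death counts never are.
    """

    table: pd.DataFrame
    settings: EconSettings = field(repr=False, default=None)

    def outcome(self, horizon, name, sex="total") -> float:
        return float(self.table.loc[(horizon, sex), name])


def compare(reference, intervention, settings: EconSettings,
            horizons=HORIZONS) -> ScenarioComparison:
    """Difference two scenario runs into cumulative outcomes per horizon."""
    rate = settings.discount_rate if settings.discount_health else 0.0
    disc = discount_factors(LIFETIME_YEARS, rate)

    streams = {}
    for sex in SEXES:
        for measure in ("incident_events", "ihd_deaths", "total_deaths",
                        "life_years", "halys"):
            ref = aggregate_by_year(reference, measure, sex)
            intv = aggregate_by_year(intervention, measure, sex)
            streams[(sex, measure, "ref")] = ref
            streams[(sex, measure, "diff")] = intv - ref

    rows = []
    for horizon in horizons:
        h = _horizon_years(horizon)
        for sex in (*SEXES, "total"):
            use = SEXES if sex == "total" else (sex,)

            def cum(measure, which="diff", weights=None):
                total = 0.0
                for s in use:
                    arr = streams[(s, measure, which)][:h]
                    total += float((arr * weights[:h]).sum()
                                   if weights is not None else arr.sum())
                return total

            events_av = -cum("incident_events")
            deaths_av = -cum("ihd_deaths")
            ref_events = cum("incident_events", "ref")
            ref_deaths = cum("ihd_deaths", "ref")
            rows.append({
                "horizon": horizon, "sex": sex,
                "events_averted": events_av,
                "deaths_averted": deaths_av,
                "total_deaths_averted": -cum("total_deaths"),
                "life_years_gained": cum("life_years", weights=disc),
                "halys_gained": cum("halys", weights=disc),
                "pct_incidence_reduction":
                    -100.0 * events_av / ref_events if ref_events else 0.0,
                "pct_deaths_reduction":
                    -100.0 * deaths_av / ref_deaths if ref_deaths else 0.0,
            })
    table = pd.DataFrame(rows).set_index(["horizon", "sex"])
    return ScenarioComparison(table=table, settings=settings)
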