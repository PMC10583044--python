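"""Cost streams, discounting, net costs, ICERs, ROI and classification.

The evaluation takes an extended health-sector perspective: incremental
healthcare costs (IHD-related and, because survivors accrue unrelated
care in added years of life, all-other healthcare) plus policy
implementation costs for government and industry.  Cost-effectiveness is
classified against WHO GDP-per-capita benchmarks; an intervention with
negative net cost is cost saving outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inputs import (AGE_MIN, GOV_COST_CATEGORIES, GOV_ONGOING_CATEGORIES,
                     SEXES, CostInputs, EconSettings)
from .lifetable import LIFETIME_YEARS, aggregate_by_year, discount_factors


def discount(amounts, rate: float):
    """Present value of a per-year stream; year 1 is undiscounted.

    Year ``t`` (1-based) is multiplied by ``(1 + rate) ** -(t - 1)``.
    """
    amounts = np.asarray(amounts, dtype=float)
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return amounts * discount_factors(amounts.size, rate)


@dataclass
class CostStream:
    """Per-calendar-year incremental cost components (US$/year).

    Component arrays are aligned on calendar years 1..n; ``total()``
    sums components, ``discounted(rate)`` returns a new stream with
    every component discounted.
    """

    components: dict = field(default_factory=dict)

    @property
    def n_years(self) -> int:
        return next(iter(self.components.values())).size

    def total(self) -> np.ndarray:
        return np.sum(list(self.components.values()), axis=0)

    def discounted(self, rate: float) -> "CostStream":
        return CostStream({k: discount(v, rate)
                           for k, v in self.components.items()})

    def cumulative(self, horizon_years: int) -> float:
        return float(self.total()[:horizon_years].sum())

    def component_cumulative(self, name: str, horizon_years: int) -> float:
        return float(self.components[name][:horizon_years].sum())

    @staticmethod
    def merge(*streams: "CostStream") -> "CostStream":
        out = {}
        for s in streams:
            out.update(s.components)
        return CostStream(out)


def pooled_incident_cost(component_costs: dict, event_mix: dict,
                         sex: str) -> float:
    """Acute-event cost pooled over MI / angina / cardiac-arrest shares."""
    mix = event_mix[sex]
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"event mix for {sex} sums to {total:g}, not 1")
    return float(sum(component_costs[k] * share for k, share in mix.items()))


def healthcare_cost_stream(reference, intervention, costs: CostInputs,
                           n_years: int = LIFETIME_YEARS) -> CostStream:
    """Incremental healthcare costs (intervention minus reference).

    Three components: acute costs of incident IHD events, annual costs
    of prevalent IHD cases, and all-other healthcare accrued in
    added/lost person-years at the age–sex per-capita rate.  Averted
    disease makes the IHD components negative (savings); longer
    survival makes the other-healthcare component positive, so total
    savings are smaller in magnitude than the IHD-specific savings.
    """
    ihd_incident = np.zeros(n_years)
    ihd_prevalent = np.zeros(n_years)
    other = np.zeros(n_years)
    for sex in SEXES:
        d_events = (aggregate_by_year(intervention, "incident_events", sex, n_years)
                    - aggregate_by_year(reference, "incident_events", sex, n_years))
        d_case_years = (
            aggregate_by_year(intervention, "prevalent_case_years", sex, n_years)
            - aggregate_by_year(reference, "prevalent_case_years", sex, n_years))
        ihd_incident += d_events * costs.acute_event_cost[sex]
        ihd_prevalent += d_case_years * costs.prevalent_case_cost
        per_capita = costs.other_healthcare_per_capita[sex]
        for ref_t, int_t in zip(
                (t for t in reference if t.sex == sex),
                (t for t in intervention if t.sex == sex)):
            d_ly = int_t.life_years - ref_t.life_years
            ages = ref_t.ages()
            k = min(d_ly.size, n_years)
            other[:k] += d_ly[:k] * per_capita[ages[:k] - AGE_MIN]
    return CostStream({"ihd_incident_costs": ihd_incident,
                       "ihd_prevalent_costs": ihd_prevalent,
                       "other_healthcare_costs": other})


def government_cost_stream(schedule: pd.DataFrame,
                           n_years: int = LIFETIME_YEARS,
                           monitoring_uplift: float = 0.0) -> CostStream:
    """Government implementation costs per calendar year.

    ``schedule`` holds the five cost categories over years 1–5.  After
    year 5 only the ongoing monitoring categories (human resources and
    administration) continue, at their year-5 level.
    ``monitoring_uplift`` scales those ongoing categories (e.g. 0.5 for
    50% greater monitoring costs) across all years.
    """
    missing = [c for c in GOV_COST_CATEGORIES if c not in schedule.index]
    if missing:
        raise ValueError(f"government schedule missing categories: {missing}")
    years_in = sorted(int(c) for c in schedule.columns)
    if years_in[: 1] != [1]:
        raise ValueError("government schedule must start at year 1")
    out = np.zeros(n_years)
    for cat in GOV_COST_CATEGORIES:
        scale = (1.0 + monitoring_uplift) if cat in GOV_ONGOING_CATEGORIES else 1.0
        row = schedule.loc[cat]
        for year in years_in:
            if year <= n_years:
                out[year - 1] += scale * float(row[year])
        if cat in GOV_ONGOING_CATEGORIES:
            carry = scale * float(row[max(years_in)])
            out[max(years_in):] += carry
    return CostStream({"gov_costs": out})


def industry_cost_stream(cost_per_product: float, n_products: int,
                         annual_fraction: float,
                         n_years: int = LIFETIME_YEARS,
                         multiplier: float = 1.0) -> CostStream:
    """Industry reformulation costs: year-1 lump plus an ongoing fraction.

    The lump is ``cost_per_product * n_products * multiplier`` (the
    multiplier carries source-currency conversion and inflation to
    base-year US$); every later year costs ``annual_fraction`` of the
    lump, a conservative allowance for reduced industry profits.
    """
    if min(cost_per_product, n_products, annual_fraction) < 0:
        raise ValueError("industry cost inputs must be non-negative")
    lump = cost_per_product * n_products * multiplier
    out = np.full(n_years, annual_fraction * lump)
    out[0] = lump
    if n_products == 0:
        out[:] = 0.0
    return CostStream({"industry_costs": out})


@dataclass
class CEResult:
    """Cost-effectiveness summary for one horizon."""

    net_cost: float  # US$ (negative = saving)
    halys: float
    icer: float | None  # US$/HALY; None when HALYs <= 0
    dominant: bool  # saves money and gains health
    roi: float | None  # healthcare savings per $ of government spend
    classification: str
    implementation_only_icer: float | None = None

    def in_ksh(self, exchange_rate: float) -> float | None:
        return None if self.icer is None else self.icer * exchange_rate


def classify(net_cost: float, icer: float | None,
             settings: EconSettings) -> str:
    if net_cost < 0:
        return "cost-saving"
    if icer is None:
        return "not cost-effective"
    if icer < settings.who_threshold_very:
        return "very cost-effective"
    if icer < settings.who_threshold_ce:
        return "cost-effective"
    return "not cost-effective"


def cost_effectiveness(net_cost: float, halys: float, gov_costs: float,
                       healthcare_savings: float,
                       settings: EconSettings,
                       implementation_cost: float | None = None) -> CEResult:
    """ICER, ROI and WHO-threshold classification.

    ``healthcare_savings`` is positive when the intervention saves
    healthcare money; ``implementation_cost`` (government + industry)
    defaults to ``net_cost + healthcare_savings`` and feeds the
    implementation-only ICER, which ignores healthcare savings.
    """
    if implementation_cost is None:
        implementation_cost = net_cost + healthcare_savings
    icer = net_cost / halys if halys > 0 else None
    impl_icer = implementation_cost / halys if halys > 0 else None
    roi = healthcare_savings / gov_costs if gov_costs > 0 else None
    return CEResult(
        net_cost=net_cost, halys=halys, icer=icer,
        dominant=bool(net_cost < 0 and halys > 0),
        roi=roi,
        classification=classify(net_cost, icer, settings),
        implementation_only_icer=impl_icer)
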