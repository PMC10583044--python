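"""End-to-end deterministic model run: PIF -> life table -> economics."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import economics
from .disease import derive_case_fatality
from .inputs import InputBundle
from .lifetable import (HORIZONS, LIFETIME_YEARS, ScenarioComparison,
                        _horizon_years, compare, run_population)
from .pif import pif_table


@dataclass
class ModelResult:
    """All outputs of one deterministic model evaluation.

    ``summary`` is a per-horizon frame holding the health outcomes,
    discounted cost aggregates (US$), ICERs, ROI and classification —
    the model's analogue of a published results table.
    """

    comparison: ScenarioComparison
    pifs: pd.DataFrame
    healthcare: economics.CostStream  # undiscounted, incremental
    government: economics.CostStream
    industry: economics.CostStream
    summary: pd.DataFrame
    ce: dict = field(default_factory=dict)  # horizon -> CEResult

    def outcome(self, horizon, name, sex="total") -> float:
        return self.comparison.outcome(horizon, name, sex)


def run_model(bundle: InputBundle, horizons=HORIZONS) -> ModelResult:
    """Run the full pipeline on central (non-drawn) inputs."""
    cf = derive_case_fatality(bundle.disease)
    pifs = pif_table(bundle)
    reference, intervention = run_population(bundle, cf, pifs)
    comparison = compare(reference, intervention, bundle.settings,
                         horizons=horizons)

    costs = bundle.costs
    healthcare = economics.healthcare_cost_stream(reference, intervention,
                                                  costs)
    government = economics.government_cost_stream(costs.gov_cost_schedule)
    industry = economics.industry_cost_stream(
        costs.reformulation_cost_per_product, costs.n_products,
        costs.annual_industry_fraction,
        multiplier=costs.industry_cost_multiplier)

    rate = bundle.settings.discount_rate
    hc_d = healthcare.discounted(rate)
    gov_d = government.discounted(rate)
    ind_d = industry.discounted(rate)

    rows, ce = [], {}
    for horizon in horizons:
        h = _horizon_years(horizon)
        halys = comparison.outcome(horizon, "halys_gained")
        d_ihd = (hc_d.component_cumulative("ihd_incident_costs", h)
                 + hc_d.component_cumulative("ihd_prevalent_costs", h))
        d_total_hc = hc_d.cumulative(h)
        gov = gov_d.cumulative(h)
        ind = ind_d.cumulative(h)
        net = gov + ind + d_total_hc
        res = economics.cost_effectiveness(
            net_cost=net, halys=halys, gov_costs=gov,
            healthcare_savings=-d_total_hc, settings=bundle.settings,
            implementation_cost=gov + ind)
        ce[horizon] = res
        rows.append({
            "horizon": horizon,
            "events_averted": comparison.outcome(horizon, "events_averted"),
            "deaths_averted": comparison.outcome(horizon, "deaths_averted"),
            "pct_incidence_reduction":
                comparison.outcome(horizon, "pct_incidence_reduction"),
            "pct_deaths_reduction":
                comparison.outcome(horizon, "pct_deaths_reduction"),
            "halys_gained": halys,
            "life_years_gained": comparison.outcome(horizon,
                                                    "life_years_gained"),
            "ihd_healthcare_costs": d_ihd,
            "total_healthcare_costs": d_total_hc,
            "gov_costs": gov,
            "industry_costs": ind,
            "total_implementation_costs": gov + ind,
            "net_costs": net,
            "icer": res.icer,
            "implementation_only_icer": res.implementation_only_icer,
            "roi": res.roi,
            "classification": res.classification,
        })
    summary = pd.DataFrame(rows).set_index("horizon")
    return ModelResult(comparison=comparison, pifs=pifs,
                       healthcare=healthcare, government=government,
                       industry=industry, summary=summary, ce=ce)
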