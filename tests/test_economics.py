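"""Cost streams, discounting, ICER/ROI and classification."""

import numpy as np
import pandas as pd
import pytest

import tfakenya as tk
from tfakenya.economics import (CostStream, classify, cost_effectiveness,
                                discount, government_cost_stream,
                                industry_cost_stream, pooled_incident_cost)
from tfakenya.inputs import GOV_COST_CATEGORIES, EconSettings

MIX = {"male": {"mi": 0.35, "angina": 0.55, "cardiac_arrest": 0.10},
       "female": {"mi": 0.20, "angina": 0.70, "cardiac_arrest": 0.10}}
COMPONENTS = {"mi": 1996.0, "angina": 1237.0, "cardiac_arrest": 1026.0}


class TestPooledIncidentCost:
    def test_male_pooling(self):
        # 0.35*1996 + 0.55*1237 + 0.10*1026
        assert pooled_incident_cost(COMPONENTS, MIX, "male") == \
            pytest.approx(1481.55)

    def test_female_pooling(self):
        assert pooled_incident_cost(COMPONENTS, MIX, "female") == \
            pytest.approx(1367.70)

    def test_degenerate_mix(self):
        mix = {"male": {"mi": 1.0, "angina": 0.0, "cardiac_arrest": 0.0}}
        assert pooled_incident_cost(COMPONENTS, mix, "male") == 1996.0

    def test_bad_mix_rejected(self):
        mix = {"male": {"mi": 0.5, "angina": 0.3, "cardiac_arrest": 0.1}}
        with pytest.raises(ValueError, match="sums to"):
            pooled_incident_cost(COMPONENTS, mix, "male")


class TestDiscount:
    def test_zero_rate_identity(self):
        x = np.array([100.0, 50.0, 25.0])
        np.testing.assert_array_equal(discount(x, 0.0), x)

    def test_year_one_undiscounted(self):
        out = discount(np.array([100.0, 100.0]), 0.03)
        assert out[0] == 100.0
        assert out[1] == pytest.approx(100 / 1.03)
        assert out.sum() == pytest.approx(197.0874, abs=1e-3)

    def test_rate_monotonicity(self):
        x = np.full(30, 100.0)
        totals = [discount(x, r).sum() for r in (0.0, 0.03, 0.06)]
        assert totals[0] > totals[1] > totals[2]


class TestGovernmentCostStream:
    def schedule(self, **rows):
        base = {c: [0.0] * 5 for c in GOV_COST_CATEGORIES}
        base.update(rows)
        return pd.DataFrame.from_dict(base, orient="index",
                                      columns=[1, 2, 3, 4, 5])

    def test_one_off_strategy_cost_stops_after_year_one(self):
        s = government_cost_stream(
            self.schedule(strategy_development=[5e5, 0, 0, 0, 0]), 20)
        total = s.total()
        assert total[0] == 5e5
        assert np.all(total[1:] == 0.0)

    def test_ongoing_categories_carry_forward(self):
        s = government_cost_stream(
            self.schedule(human_resources=[3e5] * 5), 10)
        assert s.cumulative(10) == pytest.approx(10 * 3e5)

    def test_non_ongoing_categories_stop_at_year_five(self):
        s = government_cost_stream(
            self.schedule(promotion_media=[1e5] * 5), 10)
        assert s.cumulative(10) == pytest.approx(5 * 1e5)

    def test_monitoring_uplift_scales_ongoing_categories(self):
        sched = self.schedule(human_resources=[2e5] * 5,
                              administration=[1e5] * 5,
                              promotion_media=[4e4] * 5)
        base = government_cost_stream(sched, 10)
        up = government_cost_stream(sched, 10, monitoring_uplift=0.5)
        assert up.cumulative(10) == pytest.approx(
            base.cumulative(10) + 0.5 * 10 * 3e5)

    def test_missing_category_rejected(self):
        sched = self.schedule().drop(index="administration")
        with pytest.raises(ValueError, match="administration"):
            government_cost_stream(sched, 10)


class TestIndustryCostStream:
    def test_lump_is_product_of_inputs(self):
        s = industry_cost_stream(25_000.0, 99, 0.01, 10)
        assert s.total()[0] == pytest.approx(2_475_000.0)

    def test_annual_fraction_of_lump(self):
        s = industry_cost_stream(25_000.0, 99, 0.01, 10)
        assert s.total()[1] == pytest.approx(24_750.0)
        assert np.all(s.total()[1:] == s.total()[1])

    def test_zero_products_zero_stream(self):
        s = industry_cost_stream(25_000.0, 0, 0.01, 10)
        assert np.all(s.total() == 0.0)

    def test_multiplier_applies_to_lump_and_annuity(self):
        s = industry_cost_stream(25_000.0, 99, 0.01, 5, multiplier=1.788)
        assert s.total()[0] == pytest.approx(2_475_000.0 * 1.788)
        assert s.total()[1] == pytest.approx(24_750.0 * 1.788)


class TestHealthcareCostStream:
    def test_identical_scenarios_zero_stream(self, bundle, case_fatality):
        ref, _ = tk.run_population(bundle, case_fatality, None)
        s = tk.healthcare_cost_stream(ref, ref, bundle.costs)
        assert np.all(s.total() == 0.0)

    def test_averted_prevalent_case_years_priced_directly(self):
        """1000 averted case-years at $336/case-year saves $336,000."""
        from tfakenya.lifetable import CohortTrajectory
        n = 10
        mk = lambda prev: CohortTrajectory(
            sex="male", entry_age=50,
            alive=np.full(n + 1, 1e4),
            ihd_prevalence=np.full(n, prev),
            incident_events=np.zeros(n), ihd_deaths=np.zeros(n),
            total_deaths=np.zeros(n),
            life_years=np.full(n, 1e4), halys=np.full(n, 1e4))
        ref, intv = mk(0.02), mk(0.01)  # 100 case-years/yr averted, 10 yrs
        b = tk.generate_bundle(tk.SyntheticSpec(population_scale=1e6))
        s = tk.healthcare_cost_stream([ref], [intv], b.costs, n_years=10)
        assert s.components["ihd_prevalent_costs"].sum() == \
            pytest.approx(-1000 * 336.0)
        assert s.components["other_healthcare_costs"].sum() == 0.0

    def test_added_life_years_offset_ihd_savings(self, model_result):
        """|total healthcare savings| < |IHD-specific savings|."""
        rate = 0.03
        hc = model_result.healthcare.discounted(rate)
        h = 80
        ihd = (hc.component_cumulative("ihd_incident_costs", h)
               + hc.component_cumulative("ihd_prevalent_costs", h))
        total = hc.cumulative(h)
        assert ihd < 0 and total < 0
        assert abs(total) < abs(ihd)


class TestCostEffectiveness:
    SETTINGS = EconSettings()

    def test_negative_net_cost_is_cost_saving(self):
        res = cost_effectiveness(-12.5e6, 1175.0, 2.45e6, 19.6e6,
                                 self.SETTINGS)
        assert res.classification == "cost-saving"
        assert res.dominant

    def test_implementation_only_icer_very_cost_effective(self):
        """$20.4M over 154,725 HALYs is ~$132/HALY (< 1x GDP per capita)."""
        res = cost_effectiveness(20.4e6, 154_725.0, 14.6e6, 0.0,
                                 self.SETTINGS, implementation_cost=20.4e6)
        assert res.implementation_only_icer == pytest.approx(132.0, abs=0.5)
        assert classify(res.net_cost, res.implementation_only_icer,
                        self.SETTINGS) == "very cost-effective"

    def test_roi_is_savings_per_government_dollar(self):
        res = cost_effectiveness(-17.15e6, 1175.0, 2.45e6, 19.6e6,
                                 self.SETTINGS)
        assert res.roi == pytest.approx(8.0, abs=0.1)

    def test_zero_halys_flags_icer_undefined(self):
        res = cost_effectiveness(1e6, 0.0, 1e6, 0.0, self.SETTINGS)
        assert res.icer is None
        assert res.implementation_only_icer is None

    def test_threshold_boundaries_are_half_open(self):
        s = self.SETTINGS
        assert classify(10.0, s.who_threshold_very, s) == "cost-effective"
        assert classify(10.0, s.who_threshold_very - 1e-9, s) == \
            "very cost-effective"
        assert classify(10.0, s.who_threshold_ce, s) == "not cost-effective"

    def test_net_cost_identity_to_the_cent(self, model_result, bundle):
        """net = gov + industry + delta total healthcare, per horizon."""
        rate = bundle.settings.discount_rate
        for horizon, h in ((5, 5), (10, 10), ("lifetime", 80)):
            row = model_result.summary.loc[horizon]
            recomputed = (
                model_result.government.discounted(rate).cumulative(h)
                + model_result.industry.discounted(rate).cumulative(h)
                + model_result.healthcare.discounted(rate).cumulative(h))
            assert row["net_costs"] == pytest.approx(recomputed, abs=0.01)

    def test_icer_scale_invariance_of_scaling_components(self, small_spec):
        """Healthcare cost per HALY is invariant to population scale."""
        import dataclasses
        r1 = tk.run_model(tk.generate_bundle(small_spec))
        r2 = tk.run_model(tk.generate_bundle(dataclasses.replace(
            small_spec, population_scale=3 * small_spec.population_scale)))
        ratio1 = (r1.summary.loc["lifetime", "total_healthcare_costs"]
                  / r1.summary.loc["lifetime", "halys_gained"])
        ratio2 = (r2.summary.loc["lifetime", "total_healthcare_costs"]
                  / r2.summary.loc["lifetime", "halys_gained"])
        assert ratio1 == pytest.approx(ratio2, rel=1e-9)
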