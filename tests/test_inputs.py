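"""Input model: distribution parameterisation, expansion, I/O, validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tfakenya as tk
from tfakenya.inputs import (AGES, EXPOSURE_BANDS, FIVE_YEAR_BANDS,
                             InputValidationError, expand_to_single_ages)


class TestLognormalParams:
    def test_closed_form_moment_matching(self):
        mu, sigma = tk.lognormal_params(0.25, 0.125)
        assert sigma == pytest.approx(np.sqrt(np.log(1 + 0.5**2)), abs=1e-12)
        assert mu == pytest.approx(np.log(0.25) - sigma**2 / 2, abs=1e-12)
        # sqrt(ln(1 + (0.125/0.25)^2)) = 0.4724...
        assert sigma == pytest.approx(0.4724, abs=5e-4)

    def test_zero_sd_is_degenerate_marker(self):
        mu, sigma = tk.lognormal_params(1.0, 0.0)
        assert sigma == 0.0
        assert np.exp(mu) == pytest.approx(1.0)

    @given(st.floats(0.05, 5.0), st.floats(0.0, 2.0))
    def test_analytic_moment_recovery(self, mean, sd):
        """Recovered analytic mean/SD equal the inputs to 1e-12 relative."""
        mu, sigma = tk.lognormal_params(mean, sd)
        m = np.exp(mu + sigma**2 / 2)
        v = (np.exp(sigma**2) - 1) * m**2
        assert m == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(v) == pytest.approx(sd, rel=1e-9, abs=1e-12)

    def test_monte_carlo_round_trip(self):
        """Sample mean of 1e6 draws from params(2, 1) is within 2 ± 0.01."""
        mu, sigma = tk.lognormal_params(2.0, 1.0)
        rng = np.random.default_rng(7)
        draws = rng.lognormal(mu, sigma, 1_000_000)
        assert draws.mean() == pytest.approx(2.0, abs=0.01)
        assert draws.std() == pytest.approx(1.0, abs=0.01)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            tk.lognormal_params(0.0, 0.1)
        with pytest.raises(ValueError):
            tk.lognormal_params(-1.0, 0.1)


class TestExpandToSingleAges:
    def test_piecewise_constant_for_rates(self):
        values = {b: 0.1 for b in FIVE_YEAR_BANDS}
        values["20-24"] = 0.31
        out = expand_to_single_ages(values)
        assert np.all(out[:5] == 0.31)
        assert np.all(out[5:] == 0.1)

    def test_uniform_split_for_counts(self):
        values = {b: 0.0 for b in FIVE_YEAR_BANDS}
        values["30-34"] = 1000.0
        out = expand_to_single_ages(values, kind="count")
        assert np.all(out[10:15] == 200.0)
        assert out.sum() == pytest.approx(1000.0)

    def test_band_totals_preserved_for_counts(self):
        rng = np.random.default_rng(3)
        values = dict(zip(FIVE_YEAR_BANDS, rng.uniform(100, 5000, 16)))
        out = expand_to_single_ages(values, kind="count")
        assert out.sum() == pytest.approx(sum(values.values()), rel=1e-12)

    def test_monotone_bands_stay_monotone(self):
        values = dict(zip(FIVE_YEAR_BANDS, np.linspace(0.01, 0.5, 16)))
        out = expand_to_single_ages(values)
        assert np.all(np.diff(out) >= 0)

    def test_terminal_band_extends_to_100(self):
        values = dict(zip(FIVE_YEAR_BANDS, np.arange(16, dtype=float)))
        out = expand_to_single_ages(values)
        assert out[-1] == 15.0  # age 100 inherits 95-99

    def test_gap_in_bands_rejected(self):
        values = {b: 1.0 for b in FIVE_YEAR_BANDS if b != "40-44"}
        with pytest.raises(InputValidationError, match="tile"):
            expand_to_single_ages(values)


class TestExposureDistribution:
    def test_density_integrates_to_one(self):
        from scipy import integrate
        d = tk.ExposureDistribution(0.3, 0.15)
        total, _ = integrate.quad(d.pdf, 0, d.m, limit=200)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_default_upper_bound(self):
        d = tk.ExposureDistribution(0.3, 0.15)
        assert d.m == pytest.approx(0.3 + 1.5)

    def test_invalid_upper_bound_rejected(self):
        with pytest.raises(InputValidationError):
            tk.ExposureDistribution(0.5, 0.1, upper_bound=0.4)


class TestBundleIO:
    def test_round_trip_bit_exact(self, bundle, tmp_path):
        """Saving then reloading a bundle reproduces every value exactly."""
        tk.save_bundle(bundle, tmp_path)
        loaded = tk.load_bundle(tmp_path)
        for sex in tk.SEXES:
            np.testing.assert_array_equal(
                loaded.demography.population[sex],
                bundle.demography.population[sex])
            np.testing.assert_array_equal(
                loaded.disease.ihd_prevalence[sex],
                bundle.disease.ihd_prevalence[sex])
            np.testing.assert_array_equal(
                loaded.costs.other_healthcare_per_capita[sex],
                bundle.costs.other_healthcare_per_capita[sex])
        np.testing.assert_array_equal(loaded.rr.rr, bundle.rr.rr)
        for key, d in bundle.exposure_ref.items():
            assert loaded.exposure_ref[key].mean == d.mean
            assert loaded.exposure_ref[key].sd == d.sd
        assert (loaded.costs.gov_cost_schedule.values
                == bundle.costs.gov_cost_schedule.values).all()
        assert loaded.settings == bundle.settings

    def test_thirty_exposure_strata(self, bundle, tmp_path):
        """The intake table carries 30 age-sex strata (15 bands x 2)."""
        assert bundle.n_exposure_strata() == 30
        assert len(EXPOSURE_BANDS) == 15

    def test_out_of_range_prevalence_names_row(self, bundle, tmp_path):
        out = tk.save_bundle(bundle, tmp_path)
        path = out / "ihd_prevalence.csv"
        import pandas as pd
        df = pd.read_csv(path)
        df.loc[30, "value"] = 1.2
        df.to_csv(path, index=False)
        with pytest.raises(InputValidationError, match="ihd_prevalence"):
            tk.load_bundle(tmp_path)

    def test_negative_rate_rejected_with_row_reference(self, bundle, tmp_path):
        out = tk.save_bundle(bundle, tmp_path)
        path = out / "mortality.csv"
        import pandas as pd
        df = pd.read_csv(path)
        df.loc[10, "value"] = -0.01
        df.to_csv(path, index=False)
        with pytest.raises(InputValidationError, match="row 12"):
            tk.load_bundle(tmp_path)

    def test_missing_stratum_named(self, bundle, tmp_path):
        out = tk.save_bundle(bundle, tmp_path)
        path = out / "tfa_intake_reference.csv"
        import pandas as pd
        df = pd.read_csv(path)
        df = df[~((df["sex"] == "male") & (df["age_group"] == "90-94"))]
        df.to_csv(path, index=False)
        with pytest.raises(InputValidationError, match=r"male, 90-94"):
            tk.load_bundle(tmp_path)

    def test_unknown_config_key_rejected(self, bundle, tmp_path):
        out = tk.save_bundle(bundle, tmp_path)
        cfg = out / "config.yaml"
        cfg.write_text(cfg.read_text() + "bogus_key: 1\n")
        with pytest.raises(InputValidationError, match="bogus_key"):
            tk.load_bundle(tmp_path)


class TestValidation:
    def test_csmr_above_all_cause_mortality_flagged(self, bundle):
        import copy
        b = copy.deepcopy(bundle)
        b.disease.ihd_csmr["male"][40] = \
            b.demography.all_cause_mortality["male"][40] * 2
        with pytest.raises(InputValidationError, match="ihd_csmr"):
            b.validate()

    def test_ihd_yld_cannot_exceed_all_cause(self, bundle):
        import copy
        b = copy.deepcopy(bundle)
        b.disease.ihd_yld_rate["female"][:] = \
            b.disease.all_cause_yld_rate["female"] + 0.1
        with pytest.raises(InputValidationError, match="yld"):
            b.validate()

    def test_event_mix_must_sum_to_one(self, bundle):
        import copy
        b = copy.deepcopy(bundle)
        b.costs.event_mix["male"]["mi"] = 0.5
        with pytest.raises(InputValidationError, match="event_mix"):
            b.validate()
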