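"""Probabilistic and univariate sensitivity analysis.

The probabilistic sensitivity analysis (PSA) redraws uncertain inputs
per iteration — TFA intake (log-normal), relative risks (log-normal),
healthcare and implementation costs (normal, SD = 20% of the central
estimate) — runs the full pipeline, and summarises each outcome as the
50th percentile with a 95% uncertainty interval (2.5th–97.5th
percentiles, nearest-rank).  Draws are independent across parameters
and iterations, and reproducible from ``(seed, iteration)``.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .inputs import (EXPOSURE_BANDS, SEXES, ExposureDistribution,
                     InputBundle, RelativeRiskSchedule, lognormal_params)
from .lifetable import HORIZONS
from .pipeline import ModelResult, run_model

logger = logging.getLogger(__name__)

#: Outcomes carried from each iteration into the percentile summaries.
PSA_OUTCOMES = ("events_averted", "deaths_averted", "halys_gained",
                "ihd_healthcare_costs", "total_healthcare_costs",
                "gov_costs", "industry_costs", "total_implementation_costs",
                "net_costs")


@dataclass(frozen=True)
class PSAConfig:
    """What varies in the PSA, and how often."""

    n_iterations: int = 2000
    seed: int = 0
    vary_intake: bool = True
    vary_rr: bool = True
    vary_healthcare_costs: bool = True
    vary_implementation_costs: bool = True
    cost_sd_fraction: float = 0.2  # SD as fraction of central estimate
    redraw_intake_mean: bool = True  # redraw the mean, keep SD fixed

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.cost_sd_fraction < 0:
            raise ValueError("cost_sd_fraction must be >= 0")


def nearest_rank_percentile(values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile on sorted draws; ties keep the lower index."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    rank = max(1, math.ceil(p / 100.0 * n))
    return float(values[rank - 1])


def _truncated_normal_factor(rng, sd_fraction: float) -> float:
    """Multiplicative N(1, sd_fraction) factor, truncated at 0."""
    return max(0.0, rng.normal(1.0, sd_fraction))


def draw_inputs(bundle: InputBundle, config: PSAConfig,
                iteration_index: int) -> InputBundle:
    """One perturbed bundle, reproducible from ``(seed, iteration)``.

    * intake: a draw from each stratum's log-normal replaces its mean
      (SD kept fixed); the non-degenerate intervention intake is
      redrawn the same way
    * RR per 2 %E: log-normal draw around the central RR (clipped below
      at 1, which the log-sds used here make vanishingly rare)
    * costs: independent multiplicative normal factors, truncated at 0
    """
    rng = np.random.default_rng([config.seed, iteration_index])
    out = copy.deepcopy(bundle)
    n_truncated = 0

    if config.vary_intake:
        for exp_map in (out.exposure_ref, out.exposure_int):
            for key, dist in list(exp_map.items()):
                if dist.is_degenerate or not config.redraw_intake_mean:
                    continue
                mu, sigma = lognormal_params(dist.mean, dist.sd)
                new_mean = float(rng.lognormal(mu, sigma))
                exp_map[key] = ExposureDistribution(
                    mean=new_mean, sd=dist.sd,
                    upper_bound=dist.upper_bound)

    if config.vary_rr:
        draws = np.exp(rng.normal(np.log(out.rr.rr), out.rr.log_sd))
        out.rr = RelativeRiskSchedule(out.rr.bands,
                                      np.maximum(draws, 1.0),
                                      out.rr.log_sd)

    sdf = config.cost_sd_fraction
    if config.vary_healthcare_costs and sdf > 0:
        c = out.costs
        for sex in SEXES:
            f = rng.normal(1.0, sdf)
            n_truncated += f < 0
            c.acute_event_cost[sex] *= max(0.0, f)
            g = rng.normal(1.0, sdf)
            n_truncated += g < 0
            c.other_healthcare_per_capita[sex] = (
                c.other_healthcare_per_capita[sex] * max(0.0, g))
        f = rng.normal(1.0, sdf)
        n_truncated += f < 0
        c.prevalent_case_cost *= max(0.0, f)

    if config.vary_implementation_costs and sdf > 0:
        c = out.costs
        for cat in c.gov_cost_schedule.index:
            f = rng.normal(1.0, sdf)
            n_truncated += f < 0
            c.gov_cost_schedule.loc[cat] *= max(0.0, f)
        f = rng.normal(1.0, sdf)  # initial reformulation cost
        n_truncated += f < 0
        c.reformulation_cost_per_product *= max(0.0, f)
        g = rng.normal(1.0, sdf)  # ongoing annual cost
        n_truncated += g < 0
        c.annual_industry_fraction = min(1.0, c.annual_industry_fraction
                                         * max(0.0, g))

    if n_truncated:
        logger.info("iteration %d: %d negative cost draw(s) truncated at 0",
                    iteration_index, int(n_truncated))
    return out


@dataclass
class PSASummary:
    """Percentile summaries and probability statements from a PSA."""

    draws: pd.DataFrame  # iteration x (horizon, outcome), tidy
    summary: pd.DataFrame  # (horizon, outcome) -> point, lower, upper
    probabilities: pd.DataFrame  # horizon -> P(cost saving), P(CE), ...
    n_iterations: int
    n_failures: int = 0

    def point(self, horizon, outcome) -> float:
        return float(self.summary.loc[(horizon, outcome), "point"])

    def interval(self, horizon, outcome) -> tuple[float, float]:
        row = self.summary.loc[(horizon, outcome)]
        return float(row["lower"]), float(row["upper"])


def _iteration_outcomes(result: ModelResult, horizons) -> list[dict]:
    rows = []
    for horizon in horizons:
        row = {"horizon": horizon}
        for name in PSA_OUTCOMES:
            row[name] = float(result.summary.loc[horizon, name])
        ce = result.ce[horizon]
        row["icer"] = np.nan if ce.icer is None else ce.icer
        row["implementation_only_icer"] = (
            np.nan if ce.implementation_only_icer is None
            else ce.implementation_only_icer)
        rows.append(row)
    return rows


def run_psa(bundle: InputBundle, config: PSAConfig,
            horizons=HORIZONS) -> PSASummary:
    """Monte Carlo propagation of input uncertainty through the model."""
    records = []
    failures = 0
    for it in range(config.n_iterations):
        try:
            drawn = draw_inputs(bundle, config, it)
            result = run_model(drawn, horizons=horizons)
        except Exception:  # noqa: BLE001 - recorded and bounded below
            failures += 1
            logger.exception("PSA iteration %d failed", it)
            if failures > max(1, 0.01 * config.n_iterations):
                raise RuntimeError(
                    f"more than 1% of PSA iterations failed ({failures})")
            continue
        for row in _iteration_outcomes(result, horizons):
            row["iteration"] = it
            records.append(row)
    draws = pd.DataFrame(records)

    sum_rows, prob_rows = [], []
    settings = bundle.settings
    for horizon in horizons:
        sub = draws[draws["horizon"] == horizon]
        for name in PSA_OUTCOMES:
            vals = sub[name].to_numpy()
            sum_rows.append({
                "horizon": horizon, "outcome": name,
                "point": nearest_rank_percentile(vals, 50),
                "lower": nearest_rank_percentile(vals, 2.5),
                "upper": nearest_rank_percentile(vals, 97.5),
            })
        net = sub["net_costs"].to_numpy()
        halys = sub["halys_gained"].to_numpy()
        icer = sub["icer"].to_numpy()
        impl = sub["implementation_only_icer"].to_numpy()

        def p_below(icers, threshold):
            ok = (net < 0) & (halys > 0)
            with np.errstate(invalid="ignore"):
                ok |= (halys > 0) & (icers < threshold)
            return float(np.mean(ok))

        prob_rows.append({
            "horizon": horizon,
            "prob_cost_saving": float(np.mean(net < 0)),
            "prob_very_cost_effective": p_below(icer, settings.who_threshold_very),
            "prob_cost_effective": p_below(icer, settings.who_threshold_ce),
            "prob_very_cost_effective_impl_only":
                float(np.mean((halys > 0) & (impl < settings.who_threshold_very))),
            "prob_cost_effective_impl_only":
                float(np.mean((halys > 0) & (impl < settings.who_threshold_ce))),
        })
    summary = pd.DataFrame(sum_rows).set_index(["horizon", "outcome"])
    probabilities = pd.DataFrame(prob_rows).set_index("horizon")
    return PSASummary(draws=draws, summary=summary,
                      probabilities=probabilities,
                      n_iterations=config.n_iterations, n_failures=failures)


# ---------------------------------------------------------------------------
# Univariate (deterministic) sensitivity scenarios
# ---------------------------------------------------------------------------

def _scale_exposure(bundle, factor):
    for key, d in list(bundle.exposure_ref.items()):
        bundle.exposure_ref[key] = ExposureDistribution(
            mean=d.mean * factor, sd=d.sd * factor, upper_bound=d.upper_bound)


def _set_residual_intake(bundle, mean=0.10, sd=0.01):
    bundle.exposure_int = {
        (s, b): ExposureDistribution(mean=mean, sd=sd)
        for s in SEXES for b in EXPOSURE_BANDS}


def _builtin_scenarios():
    def discount(rate):
        def apply(b):
            b.settings = replace_settings(b.settings, discount_rate=rate)
        return apply

    def replace_settings(settings, **kw):
        return replace(settings, **kw)

    def monitoring_uplift(b):
        from .inputs import GOV_ONGOING_CATEGORIES
        for cat in GOV_ONGOING_CATEGORIES:
            b.costs.gov_cost_schedule.loc[cat] *= 1.5

    def no_industry(b):
        b.costs.reformulation_cost_per_product = 0.0

    def double_products(b):
        b.costs.n_products *= 2

    return {
        "primary": lambda b: None,
        "discount_0": discount(0.0),
        "discount_6": discount(0.06),
        "residual_tfa_0.1": _set_residual_intake,
        "intake_plus50": lambda b: _scale_exposure(b, 1.5),
        "intake_minus50": lambda b: _scale_exposure(b, 0.5),
        "double_products": double_products,
        "no_industry_costs": no_industry,
        "monitoring_plus50": monitoring_uplift,
    }


def run_sensitivity_suite(bundle: InputBundle,
                          scenarios: list[str] | None = None,
                          horizons=HORIZONS) -> pd.DataFrame:
    """Deterministic one-at-a-time sensitivity runs.

    Built-in scenario names cover the published set: discount rates 0%
    and 6%, residual post-intervention intake 0.10±0.01 %E, ±50%
    pre-intervention intake, doubled product count, no industry costs
    and 50% greater monitoring costs.  Returns a tidy frame (scenario,
    horizon, net_costs, halys_gained, events/deaths averted, icer) for
    e.g. a cost-effectiveness plane.
    """
    builtins = _builtin_scenarios()
    names = list(builtins) if scenarios is None else list(scenarios)
    unknown = [n for n in names if n not in builtins]
    if unknown:
        raise ValueError(f"unknown scenario(s) {unknown}; "
                         f"valid names: {sorted(builtins)}")
    rows = []
    for name in names:
        b = copy.deepcopy(bundle)
        builtins[name](b)
        result = run_model(b, horizons=horizons)
        for horizon in horizons:
            ce = result.ce[horizon]
            rows.append({
                "scenario": name, "horizon": horizon,
                "net_costs": float(result.summary.loc[horizon, "net_costs"]),
                "halys_gained": float(result.summary.loc[horizon,
                                                         "halys_gained"]),
                "events_averted": float(result.summary.loc[horizon,
                                                           "events_averted"]),
                "deaths_averted": float(result.summary.loc[horizon,
                                                           "deaths_averted"]),
                "icer": np.nan if ce.icer is None else ce.icer,
                "classification": ce.classification,
            })
    return pd.DataFrame(rows)
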