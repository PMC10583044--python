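"""Domain types, CSV ingestion, validation and distribution parameterisation.

All model inputs are age–sex stratified.  Internally every rate-like
quantity lives on a single-year age grid (20..100); five-year bands are
accepted at the I/O boundary and expanded piecewise-constantly (counts are
split uniformly across the band's ages).

Units
-----
* rates (mortality, incidence, case fatality, YLD): events per person-year
* prevalence: proportion of the living population
* TFA intake: percentage of total energy (%E)
* costs: US$ unless stated otherwise; Ksh rendering uses the exchange rate
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Age/sex grid constants
# ---------------------------------------------------------------------------

SEXES = ("female", "male")

AGE_MIN = 20
AGE_MAX = 100
AGES = np.arange(AGE_MIN, AGE_MAX + 1)  # single years, inclusive
N_AGES = AGES.size

#: Five-year bands used by demographic and disease tables (16 bands).
FIVE_YEAR_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(20, 100, 5))

#: Exposure (TFA intake) and relative-risk tables use 15 bands per sex —
#: 30 age–sex intake groups in total; ages >= 95 inherit the terminal band.
EXPOSURE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(20, 95, 5))

#: Cohort entry ages: one five-year cohort per band and sex (32 cohorts).
COHORT_ENTRY_AGES = tuple(range(20, 100, 5))

GOV_COST_CATEGORIES = (
    "strategy_development",
    "human_resources",
    "promotion_media",
    "office_rent_equipment",
    "administration",
)
#: Categories whose year-5 cost carries forward indefinitely.
GOV_ONGOING_CATEGORIES = ("human_resources", "administration")


class InputValidationError(ValueError):
    """Raised when model inputs violate a structural or range invariant.

    Carries a list of human-readable issue strings, each naming the
    offending table, stratum (sex / age group) and, for file inputs,
    the row.
    """

    def __init__(self, issues):
        if isinstance(issues, str):
            issues = [issues]
        self.issues = list(issues)
        super().__init__("; ".join(self.issues))


def parse_band(label: str) -> tuple[int, int]:
    """Parse a band label like ``'20-24'`` (also accepts en-dash)."""
    lo, hi = label.replace("–", "-").split("-")
    return int(lo), int(hi)


def band_for_age(age: int, bands=FIVE_YEAR_BANDS) -> str:
    """Band containing *age*; ages past the last band inherit it."""
    for label in bands:
        lo, hi = parse_band(label)
        if lo <= age <= hi:
            return label
    lo_last, _ = parse_band(bands[-1])
    if age >= lo_last:
        return bands[-1]
    raise KeyError(f"age {age} not covered by bands")


# ---------------------------------------------------------------------------
# Distribution parameterisation
# ---------------------------------------------------------------------------

def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched log-normal parameters ``(log_mean, log_sd)``.

    Solves for the underlying normal parameters so that the log-normal
    has arithmetic mean ``mean`` and standard deviation ``sd``:

        log_sd   = sqrt(ln(1 + (sd/mean)^2))
        log_mean = ln(mean) - log_sd^2 / 2

    ``sd == 0`` returns ``(ln(mean), 0.0)``, the degenerate marker.
    """
    if mean <= 0:
        raise ValueError(f"lognormal mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"lognormal sd must be non-negative, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    log_sd = math.sqrt(math.log1p((sd / mean) ** 2))
    log_mean = math.log(mean) - 0.5 * log_sd**2
    return log_mean, log_sd


@dataclass(frozen=True)
class ExposureDistribution:
    """Log-normal TFA intake distribution for one age–sex stratum (%E).

    The density is truncated to ``[0, upper_bound]`` and renormalised;
    the upper bound defaults to ``mean + 10*sd``, far enough into the
    tail that truncation is numerically immaterial.  ``sd == 0`` gives a
    point mass at ``mean`` (``mean == 0`` is the fully-eliminated case).
    """

    mean: float
    sd: float
    upper_bound: float | None = None

    def __post_init__(self):
        if self.mean < 0:
            raise InputValidationError(f"intake mean must be >= 0, got {self.mean}")
        if self.sd < 0:
            raise InputValidationError(f"intake sd must be >= 0, got {self.sd}")
        m = self.m
        if m <= self.mean:
            raise InputValidationError(
                f"upper bound {m} must exceed mean {self.mean}"
            )

    @property
    def m(self) -> float:
        """Integration upper bound (defaults to mean + 10 sd)."""
        if self.upper_bound is not None:
            return self.upper_bound
        return self.mean + 1.0 if self.is_degenerate else self.mean + 10.0 * self.sd

    @property
    def is_degenerate(self) -> bool:
        # an SD below float resolution of the mean is a point mass
        return self.sd <= 1e-12 * self.mean or self.sd == 0.0

    def log_params(self) -> tuple[float, float]:
        return lognormal_params(self.mean, self.sd)

    def pdf(self, x):
        """Truncated, renormalised density on ``[0, m]`` (vectorised)."""
        from scipy.special import ndtr

        if self.is_degenerate:
            raise ValueError("degenerate distribution has no density")
        mu, sigma = self.log_params()
        norm = float(ndtr((math.log(self.m) - mu) / sigma))
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logx = np.log(np.where(x > 0, x, 1.0))
            dens = (np.exp(-((logx - mu) ** 2) / (2.0 * sigma**2))
                    / (x * sigma * math.sqrt(2.0 * math.pi)))
        out = np.where((x > 0) & (x <= self.m), dens / norm, 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class RelativeRiskSchedule:
    """Age-specific relative risk of IHD per 2 %E of TFA intake.

    ``rr`` holds the central RR per band of :data:`EXPOSURE_BANDS`;
    ``log_sd`` its log-normal uncertainty (0 = no uncertainty).  The
    continuous dose–response is ``RR(x) = rr ** (x / 2)``.
    """

    bands: tuple[str, ...]
    rr: np.ndarray
    log_sd: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rr", np.asarray(self.rr, dtype=float))
        object.__setattr__(self, "log_sd", np.asarray(self.log_sd, dtype=float))
        if len(self.bands) != self.rr.size or self.rr.size != self.log_sd.size:
            raise InputValidationError("relative risk schedule arrays misaligned")
        if np.any(self.rr < 1.0):
            raise InputValidationError("central RR per 2%E must be >= 1")
        if np.any(self.log_sd < 0):
            raise InputValidationError("RR log-sd must be >= 0")

    def rr_for_band(self, band: str) -> float:
        return float(self.rr[self.bands.index(band)])

    def rr_for_age(self, age: int) -> float:
        return self.rr_for_band(band_for_age(age, self.bands))

    @classmethod
    def constant(cls, rr: float, log_sd: float = 0.0) -> "RelativeRiskSchedule":
        n = len(EXPOSURE_BANDS)
        return cls(EXPOSURE_BANDS, np.full(n, rr), np.full(n, log_sd))


# ---------------------------------------------------------------------------
# Input containers
# ---------------------------------------------------------------------------

AgeArray = Mapping[str, np.ndarray]  # sex -> array over AGES


def _check_age_map(name: str, data: AgeArray, issues: list[str]):
    for sex in SEXES:
        if sex not in data:
            issues.append(f"{name}: missing sex '{sex}'")
            continue
        arr = np.asarray(data[sex], dtype=float)
        if arr.shape != (N_AGES,):
            issues.append(
                f"{name} ({sex}): expected {N_AGES} single-age values, got {arr.shape}"
            )


@dataclass
class DemographyInputs:
    """Population, all-cause mortality and total health expenditure."""

    population: dict  # sex -> persons per single age
    all_cause_mortality: dict  # sex -> rate per person-year
    total_health_expenditure: dict  # sex -> US$ per person-year

    def validate(self) -> list[str]:
        issues: list[str] = []
        _check_age_map("population", self.population, issues)
        _check_age_map("all_cause_mortality", self.all_cause_mortality, issues)
        _check_age_map("total_health_expenditure", self.total_health_expenditure, issues)
        if issues:
            return issues
        for sex in SEXES:
            if np.any(self.population[sex] < 0):
                issues.append(f"population ({sex}): negative count")
            mort = self.all_cause_mortality[sex]
            if np.any(mort < 0) or np.any(mort > 1.5):
                issues.append(f"all_cause_mortality ({sex}): rate outside [0, 1.5]")
            if np.any(self.total_health_expenditure[sex] < 0):
                issues.append(f"total_health_expenditure ({sex}): negative")
        return issues


@dataclass
class DiseaseInputs:
    """IHD epidemiology and YLD rates by sex and single age."""

    ihd_incidence: dict
    ihd_prevalence: dict
    ihd_csmr: dict
    ihd_yld_rate: dict
    all_cause_yld_rate: dict

    def validate(self, demography: DemographyInputs | None = None) -> list[str]:
        issues: list[str] = []
        for name in ("ihd_incidence", "ihd_prevalence", "ihd_csmr",
                     "ihd_yld_rate", "all_cause_yld_rate"):
            _check_age_map(name, getattr(self, name), issues)
        if issues:
            return issues
        for sex in SEXES:
            for name in ("ihd_incidence", "ihd_csmr", "ihd_yld_rate",
                         "all_cause_yld_rate"):
                arr = getattr(self, name)[sex]
                bad = np.flatnonzero(arr < 0)
                if bad.size:
                    issues.append(
                        f"{name} ({sex}, age {AGES[bad[0]]}): negative rate"
                    )
            prev = self.ihd_prevalence[sex]
            bad = np.flatnonzero((prev < 0) | (prev > 1))
            if bad.size:
                issues.append(
                    f"ihd_prevalence ({sex}, age {AGES[bad[0]]}): "
                    f"value {prev[bad[0]]:g} outside [0, 1]"
                )
            if np.any(self.ihd_yld_rate[sex] > self.all_cause_yld_rate[sex] + 1e-12):
                issues.append(f"ihd_yld_rate ({sex}): exceeds all_cause_yld_rate")
            if demography is not None:
                mort = demography.all_cause_mortality[sex]
                bad = np.flatnonzero(self.ihd_csmr[sex] > mort + 1e-12)
                if bad.size:
                    issues.append(
                        f"ihd_csmr ({sex}, age {AGES[bad[0]]}): exceeds "
                        "all-cause mortality"
                    )
        return issues


@dataclass
class CostInputs:
    """Healthcare and policy implementation cost inputs (US$)."""

    acute_event_cost: dict  # sex -> $ per incident IHD event
    prevalent_case_cost: float  # $ per prevalent case-year
    event_mix: dict  # sex -> {mi, angina, cardiac_arrest} shares
    component_event_costs: dict  # {mi, angina, cardiac_arrest} $ per event
    other_healthcare_per_capita: dict  # sex -> $ per person-year by age
    gov_cost_schedule: pd.DataFrame  # index: category, columns: years 1..5
    reformulation_cost_per_product: float  # source-currency units
    n_products: int
    annual_industry_fraction: float = 0.01
    industry_cost_multiplier: float = 1.0  # FX + inflation to base-year US$

    def validate(self) -> list[str]:
        issues: list[str] = []
        for sex in SEXES:
            mix = self.event_mix.get(sex, {})
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                issues.append(f"event_mix ({sex}): shares sum to {total:g}, not 1")
            if self.acute_event_cost.get(sex, 0) < 0:
                issues.append(f"acute_event_cost ({sex}): negative")
        _check_age_map("other_healthcare_per_capita",
                       self.other_healthcare_per_capita, issues)
        for cat in GOV_COST_CATEGORIES:
            if cat not in self.gov_cost_schedule.index:
                issues.append(f"gov_cost_schedule: missing category '{cat}'")
        if (self.gov_cost_schedule < 0).any().any():
            issues.append("gov_cost_schedule: negative cost")
        if self.prevalent_case_cost < 0:
            issues.append("prevalent_case_cost: negative")
        if self.reformulation_cost_per_product < 0 or self.n_products < 0:
            issues.append("industry reformulation inputs must be >= 0")
        if not 0 <= self.annual_industry_fraction <= 1:
            issues.append("annual_industry_fraction outside [0, 1]")
        return issues


@dataclass
class EconSettings:
    """Economic settings: discounting, currency and WHO thresholds."""

    discount_rate: float = 0.03  # per year
    base_year: int = 2019
    exchange_rate: float = 103.0  # Ksh per US$
    who_threshold_very: float = 1720.0  # US$/HALY (1x GDP per capita)
    who_threshold_ce: float = 5161.0  # US$/HALY (3x GDP per capita)
    discount_health: bool = True  # discount HALYs at discount_rate
    inflation_factors: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        issues = []
        if not 0 <= self.discount_rate <= 0.2:
            issues.append(f"discount_rate {self.discount_rate} outside [0, 0.2]")
        if not 0 < self.who_threshold_very < self.who_threshold_ce:
            issues.append("WHO thresholds must be positive and ordered")
        if self.exchange_rate <= 0:
            issues.append("exchange_rate must be positive")
        return issues


@dataclass
class InputBundle:
    """The complete, validated input set for one model run."""

    demography: DemographyInputs
    disease: DiseaseInputs
    exposure_ref: dict  # (sex, band) -> ExposureDistribution
    exposure_int: dict  # (sex, band) -> ExposureDistribution
    rr: RelativeRiskSchedule
    costs: CostInputs
    settings: EconSettings

    def validate(self, raise_on_error: bool = True) -> list[str]:
        issues = []
        issues += self.demography.validate()
        issues += self.disease.validate(self.demography)
        issues += self.costs.validate()
        issues += self.settings.validate()
        for which, exp in (("reference", self.exposure_ref),
                           ("intervention", self.exposure_int)):
            for sex in SEXES:
                for band in EXPOSURE_BANDS:
                    if (sex, band) not in exp:
                        issues.append(
                            f"{which} exposure: missing stratum ({sex}, {band})"
                        )
        if issues and raise_on_error:
            raise InputValidationError(issues)
        return issues

    def n_exposure_strata(self) -> int:
        return len(self.exposure_ref)


# ---------------------------------------------------------------------------
# Age-band expansion
# ---------------------------------------------------------------------------

def expand_to_single_ages(values: Mapping[str, float] | pd.Series,
                          kind: str = "rate") -> np.ndarray:
    """Expand five-year-band values to the single-age grid 20..100.

    Rates/proportions are piecewise constant (every single age inherits
    its band's value, ages >= 95 inherit the terminal band, so the band
    value itself is preserved).  Counts (``kind='count'``) are split
    uniformly across the band's nominal ages, which preserves band
    totals; age 100 receives no count at baseline.
    """
    if kind not in ("rate", "count"):
        raise ValueError(f"kind must be 'rate' or 'count', got {kind!r}")
    if isinstance(values, pd.Series):
        values = values.to_dict()
    bands = sorted(values, key=lambda b: parse_band(b)[0])
    covered = []
    for label in bands:
        lo, hi = parse_band(label)
        covered.extend(range(lo, hi + 1))
    expected_hi = parse_band(bands[-1])[1]
    if covered != list(range(AGE_MIN, expected_hi + 1)):
        raise InputValidationError(
            f"age bands {bands} do not tile {AGE_MIN}-{expected_hi} without gaps"
        )
    out = np.zeros(N_AGES)
    for label in bands:
        lo, hi = parse_band(label)
        width = hi - lo + 1
        v = float(values[label])
        sl = slice(lo - AGE_MIN, hi - AGE_MIN + 1)
        out[sl] = v / width if kind == "count" else v
    # extend the terminal band upward (rates only; counts stay 0)
    if expected_hi < AGE_MAX and kind == "rate":
        out[expected_hi - AGE_MIN + 1:] = out[expected_hi - AGE_MIN]
    return out


# ---------------------------------------------------------------------------
# CSV / YAML I/O
# ---------------------------------------------------------------------------

AGE_TABLE_FILES = {
    "population": "population.csv",
    "all_cause_mortality": "mortality.csv",
    "total_health_expenditure": "health_expenditure.csv",
    "ihd_incidence": "ihd_incidence.csv",
    "ihd_prevalence": "ihd_prevalence.csv",
    "ihd_csmr": "ihd_csmr.csv",
    "ihd_yld_rate": "ihd_yld.csv",
    "all_cause_yld_rate": "all_cause_yld.csv",
    "other_healthcare_per_capita": "other_healthcare.csv",
}


def _read_age_table(path: Path, name: str, kind: str = "rate") -> dict:
    """Read a (sex, age_group, value) CSV into per-sex single-age arrays.

    ``age_group`` may be a single age or a five-year band; banded tables
    are expanded.  Negative values are rejected with a row reference.
    """
    df = pd.read_csv(path, dtype={"age_group": str},
                     float_precision="round_trip")
    required = {"sex", "age_group", "value"}
    if not required.issubset(df.columns):
        raise InputValidationError(
            f"{path.name}: expected columns {sorted(required)}"
        )
    neg = df.index[df["value"] < 0]
    if len(neg):
        i = neg[0]
        raise InputValidationError(
            f"{path.name} row {i + 2}: negative value "
            f"({df.loc[i, 'sex']}, {df.loc[i, 'age_group']})"
        )
    out = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex]
        if sub.empty:
            raise InputValidationError(f"{path.name}: missing sex '{sex}'")
        labels = sub["age_group"].tolist()
        if any("-" in str(x) or "–" in str(x) for x in labels):
            out[sex] = expand_to_single_ages(
                dict(zip(labels, sub["value"])), kind=kind)
        else:
            series = dict(zip((int(x) for x in labels), sub["value"]))
            missing = [a for a in AGES if a not in series]
            if missing:
                raise InputValidationError(
                    f"{path.name}: missing stratum ({sex}, {missing[0]})"
                )
            out[sex] = np.array([float(series[a]) for a in AGES])
    return out


def _read_exposure(path: Path, upper_bound: float | None) -> dict:
    df = pd.read_csv(path, dtype={"age_group": str},
                     float_precision="round_trip")
    out = {}
    for _, row in df.iterrows():
        label = str(row["age_group"]).replace("–", "-")
        out[(row["sex"], label)] = ExposureDistribution(
            mean=float(row["mean"]), sd=float(row["sd"]),
            upper_bound=upper_bound)
    missing = [(s, b) for s in SEXES for b in EXPOSURE_BANDS if (s, b) not in out]
    if missing:
        sex, band = missing[0]
        raise InputValidationError(
            f"{path.name}: missing stratum ({sex}, {band})")
    return out


def load_bundle(input_dir, config_path=None) -> InputBundle:
    """Load and validate a complete input bundle from a directory of CSVs.

    Expects the file set written by :func:`save_bundle` (one CSV per
    table, plus ``config.yaml``).  Raises :class:`InputValidationError`
    naming the offending file, stratum and row on any violation.
    """
    input_dir = Path(input_dir)
    config_path = Path(config_path) if config_path else input_dir / "config.yaml"
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}

    known = {"discount_rate", "base_year", "exchange_rate", "who_threshold_very",
             "who_threshold_ce", "discount_health", "inflation_factors",
             "exposure_upper_bound", "intervention_intake_mean",
             "intervention_intake_sd"}
    unknown = set(cfg) - known
    if unknown:
        raise InputValidationError(
            f"config.yaml: unknown key(s) {sorted(unknown)}")
    settings = EconSettings(**{k: v for k, v in cfg.items()
                               if k in EconSettings.__dataclass_fields__})

    tables = {}
    for attr, fname in AGE_TABLE_FILES.items():
        path = input_dir / fname
        if not path.exists():
            raise InputValidationError(f"missing input file {fname}")
        kind = "count" if attr == "population" else "rate"
        tables[attr] = _read_age_table(path, attr, kind=kind)

    m = cfg.get("exposure_upper_bound")
    exposure_ref = _read_exposure(input_dir / "tfa_intake_reference.csv", m)
    int_path = input_dir / "tfa_intake_intervention.csv"
    if int_path.exists():
        exposure_int = _read_exposure(int_path, m)
    else:
        mean = float(cfg.get("intervention_intake_mean", 0.0))
        sd = float(cfg.get("intervention_intake_sd", 0.0))
        exposure_int = {(s, b): ExposureDistribution(mean, sd, upper_bound=m)
                        for s in SEXES for b in EXPOSURE_BANDS}

    rr_df = pd.read_csv(input_dir / "relative_risk.csv",
                        dtype={"age_group": str},
                        float_precision="round_trip")
    rr_df["age_group"] = rr_df["age_group"].str.replace("–", "-")
    rr_df = rr_df.set_index("age_group").reindex(list(EXPOSURE_BANDS))
    if rr_df["rr"].isna().any():
        band = rr_df.index[rr_df["rr"].isna()][0]
        raise InputValidationError(f"relative_risk.csv: missing band {band}")
    rr = RelativeRiskSchedule(EXPOSURE_BANDS, rr_df["rr"].to_numpy(),
                              rr_df["log_sd"].to_numpy())

    costs_df = pd.read_csv(input_dir / "costs.csv",
                           float_precision="round_trip")
    cost_map = {(row["key"], row.get("sex")): row["value"]
                for _, row in costs_df.iterrows()}

    def ckey(key, sex=None):
        k = (key, sex if sex else None)
        # pandas reads empty sex cells as NaN
        for (kk, ss), v in cost_map.items():
            if kk == key and ((sex is None and (ss is None or ss != ss or ss == ""))
                              or ss == sex):
                return float(v)
        raise InputValidationError(f"costs.csv: missing key {key} (sex={sex})")

    gov = pd.read_csv(input_dir / "government_costs.csv",
                      float_precision="round_trip")
    gov_schedule = gov.pivot_table(index="category", columns="year",
                                   values="value", aggfunc="sum")
    gov_schedule = gov_schedule.reindex(list(GOV_COST_CATEGORIES)).fillna(0.0)
    gov_schedule.columns = [int(c) for c in gov_schedule.columns]

    costs = CostInputs(
        acute_event_cost={s: ckey("acute_event_cost", s) for s in SEXES},
        prevalent_case_cost=ckey("prevalent_case_cost"),
        event_mix={s: {"mi": ckey("event_mix_mi", s),
                       "angina": ckey("event_mix_angina", s),
                       "cardiac_arrest": ckey("event_mix_cardiac_arrest", s)}
                   for s in SEXES},
        component_event_costs={"mi": ckey("component_cost_mi"),
                               "angina": ckey("component_cost_angina"),
                               "cardiac_arrest": ckey("component_cost_cardiac_arrest")},
        other_healthcare_per_capita=tables.pop("other_healthcare_per_capita"),
        gov_cost_schedule=gov_schedule,
        reformulation_cost_per_product=ckey("reformulation_cost_per_product"),
        n_products=int(ckey("n_products")),
        annual_industry_fraction=ckey("annual_industry_fraction"),
        industry_cost_multiplier=ckey("industry_cost_multiplier"),
    )

    bundle = InputBundle(
        demography=DemographyInputs(
            population=tables["population"],
            all_cause_mortality=tables["all_cause_mortality"],
            total_health_expenditure=tables["total_health_expenditure"],
        ),
        disease=DiseaseInputs(
            ihd_incidence=tables["ihd_incidence"],
            ihd_prevalence=tables["ihd_prevalence"],
            ihd_csmr=tables["ihd_csmr"],
            ihd_yld_rate=tables["ihd_yld_rate"],
            all_cause_yld_rate=tables["all_cause_yld_rate"],
        ),
        exposure_ref=exposure_ref,
        exposure_int=exposure_int,
        rr=rr,
        costs=costs,
        settings=settings,
    )
    bundle.validate()
    return bundle


def save_bundle(bundle: InputBundle, out_dir) -> Path:
    """Write a bundle to the CSV file-set :func:`load_bundle` reads.

    Age tables are written at single-age resolution (the internal
    representation), so a save/load round trip is bit-exact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def write_age_table(fname, data):
        rows = [(sex, age, data[sex][i])
                for sex in SEXES for i, age in enumerate(AGES)]
        pd.DataFrame(rows, columns=["sex", "age_group", "value"]).to_csv(
            out_dir / fname, index=False, float_format="%.17g")

    d, dis, c = bundle.demography, bundle.disease, bundle.costs
    write_age_table("population.csv", d.population)
    write_age_table("mortality.csv", d.all_cause_mortality)
    write_age_table("health_expenditure.csv", d.total_health_expenditure)
    write_age_table("ihd_incidence.csv", dis.ihd_incidence)
    write_age_table("ihd_prevalence.csv", dis.ihd_prevalence)
    write_age_table("ihd_csmr.csv", dis.ihd_csmr)
    write_age_table("ihd_yld.csv", dis.ihd_yld_rate)
    write_age_table("all_cause_yld.csv", dis.all_cause_yld_rate)
    write_age_table("other_healthcare.csv", c.other_healthcare_per_capita)

    for name, exp in (("tfa_intake_reference.csv", bundle.exposure_ref),
                      ("tfa_intake_intervention.csv", bundle.exposure_int)):
        rows = [(sex, band, e.mean, e.sd)
                for (sex, band), e in sorted(exp.items(),
                                             key=lambda kv: (kv[0][0],
                                                             parse_band(kv[0][1])))]
        pd.DataFrame(rows, columns=["sex", "age_group", "mean", "sd"]).to_csv(
            out_dir / name, index=False, float_format="%.17g")

    pd.DataFrame({"age_group": bundle.rr.bands, "rr": bundle.rr.rr,
                  "log_sd": bundle.rr.log_sd}).to_csv(
        out_dir / "relative_risk.csv", index=False, float_format="%.17g")

    cost_rows = []
    for sex in SEXES:
        cost_rows.append(("acute_event_cost", sex, c.acute_event_cost[sex]))
        for k, col in (("mi", "event_mix_mi"), ("angina", "event_mix_angina"),
                       ("cardiac_arrest", "event_mix_cardiac_arrest")):
            cost_rows.append((col, sex, c.event_mix[sex][k]))
    cost_rows += [
        ("prevalent_case_cost", "", c.prevalent_case_cost),
        ("component_cost_mi", "", c.component_event_costs["mi"]),
        ("component_cost_angina", "", c.component_event_costs["angina"]),
        ("component_cost_cardiac_arrest", "", c.component_event_costs["cardiac_arrest"]),
        ("reformulation_cost_per_product", "", c.reformulation_cost_per_product),
        ("n_products", "", c.n_products),
        ("annual_industry_fraction", "", c.annual_industry_fraction),
        ("industry_cost_multiplier", "", c.industry_cost_multiplier),
    ]
    pd.DataFrame(cost_rows, columns=["key", "sex", "value"]).to_csv(
        out_dir / "costs.csv", index=False, float_format="%.17g")

    gov_rows = [(cat, int(year), val)
                for cat, row in bundle.costs.gov_cost_schedule.iterrows()
                for year, val in row.items()]
    pd.DataFrame(gov_rows, columns=["category", "year", "value"]).to_csv(
        out_dir / "government_costs.csv", index=False, float_format="%.17g")

    s = bundle.settings
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump({
            "discount_rate": s.discount_rate,
            "base_year": s.base_year,
            "exchange_rate": s.exchange_rate,
            "who_threshold_very": s.who_threshold_very,
            "who_threshold_ce": s.who_threshold_ce,
            "discount_health": s.discount_health,
        }, fh)
    return out_dir
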