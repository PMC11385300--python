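"""Stochastic seasonal generator emulating the crop–soil–climate simulations.

The generator is a statistical emulator of a process-based crop simulator
(DSSAT/CERES-Wheat class), not a crop model: one record per cropping season
per experiment, produced by structural equations chosen for sign fidelity to
the agronomic causal story —

1. the soil-carbon stock (csom) decays faster under conventional tillage
   than under no-till and scales with the profile's organic-carbon level;
2. available water space (aws) increases with the carbon stock;
3. biomass is a saturating function of seasonal rainfall, a Gaussian
   temperature-suitability factor, and an OC fertility factor;
4. precipitation interception increases with biomass;
5. runoff is a rainfall fraction whose coefficient is larger under CT,
   decreases with aws and interception, and is amplified in extreme-rainfall
   seasons;
6. yield is harvest index x biomass, reduced by runoff stress (both the
   harvest index and biomass carry seasonal noise);
7. GHG-CO2 emissions grow with the season's carbon turnover and a CT
   multiplier.

Noise is multiplicative mean-one lognormal, giving the right-skewed seasonal
variation typical of simulated wheat series.  Default coefficients are
calibrated so per-experiment mean yields fall inside the published
2,000–6,100 kg/ha envelope for this system; magnitudes of runoff
(~2–18 mm/season), GHG (~3,500–15,000 kgCO2eqv/ha) and aws (~130–520)
are in the reported ranges.

Default grid: 3 soilscapes x (native + 4 modeled OC levels) x {NT, CT}
= 30 experiments, each run over the 48 seasons 1975–2022 = 1,440 records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .tillage import (MODELED_OC, NATIVE_OC, SOILSCAPES, experiment_id,
                      soil_id)

__all__ = ["SoilProfile", "Coefficients", "SimConfig", "default_soils",
           "weather_series", "simulate_season", "simulate_dataset",
           "calibration_report"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SoilProfile:
    """One soil profile: soilscape unit, OC level, water-capacity baseline
    (cm3 cm-3 scale) and initial carbon stock (kg/ha)."""

    soilscape: str
    oc_percent: float
    water_capacity: float
    csom_init: float

    def __post_init__(self):
        if self.oc_percent <= 0:
            raise ConfigError("oc_percent must be positive")


# Water-capacity baselines per soilscape; chalky PDPG6 holds the least.
_WC_BASE = {"PDPG6": 95.0, "PDPG7": 100.0, "PDPG8": 110.0}
# Yield potential of each soilscape relative to PDPG8.
SOILSCAPE_YIELD_FACTOR = {"PDPG6": 0.82, "PDPG7": 0.90, "PDPG8": 1.0}
_CSOM_PER_OC = 38_000.0  # kg/ha carbon stock per OC percentage point


def default_soils() -> tuple[SoilProfile, ...]:
    """The 15 default profiles: native OC (2.6/4.4/3.9 %) plus modeled
    1/3/5/7 % for each of PDPG6/7/8."""
    soils = []
    for scape in SOILSCAPES:
        for oc in sorted(set(MODELED_OC) | {NATIVE_OC[scape]}):
            soils.append(SoilProfile(scape, oc, _WC_BASE[scape],
                                     _CSOM_PER_OC * oc))
    return tuple(soils)


@dataclass(frozen=True)
class Coefficients:
    """Effect coefficients of the structural equations (see module docstring).

    Multipliers are ratios (CT relative to NT); decays are per-season
    fractions; ``noise_cv`` is the coefficient of variation of the
    multiplicative lognormal noise on biomass, runoff and GHG, and
    ``yield_noise_cv`` that of the harvest-index noise.
    """

    csom_decay_nt: float = 0.0015
    csom_decay_ct: float = 0.006
    aws_oc_coef: float = 0.5          # aws gain per effective OC point
    ct_aws_mult: float = 0.96         # CT compaction shrinks pore space
    biomass_max: float = 16_200.0     # kg/ha potential biomass
    rain_half: float = 190.0          # mm, half-saturation of rain response
    temp_opt: float = 10.5            # deg C optimum seasonal temperature
    temp_width: float = 7.0           # deg C suitability width
    fert_exp: float = 0.32            # fertility ~ (OC/4)^fert_exp
    harvest_index: float = 0.41
    stress_half: float = 90.0         # mm runoff at half of max yield stress
    interception_base: float = 0.10   # % of rainfall at zero biomass
    interception_slope: float = 0.36  # added % at potential biomass
    runoff_coef: float = 0.013        # base rainfall fraction becoming runoff
    ct_runoff_mult: float = 1.9
    runoff_aws_k: float = 1.2         # aws shelter strength
    runoff_icpt_k: float = 0.5        # interception shelter strength
    extreme_quantile: float = 0.9     # wet-season threshold (rain quantile)
    extreme_runoff_mult: float = 2.5
    extreme_yield_penalty: float = 0.20  # at OC 1 %, fading out by OC 3 %
    ghg_base: float = 3_400.0         # kgCO2eqv/ha background emission
    ghg_turnover_k: float = 1.5       # emission per kg of carbon turned over
    ct_ghg_mult: float = 1.8
    ghg_temp_k: float = 0.04          # relative emission change per deg C
    noise_cv: float = 0.25
    yield_noise_cv: float = 0.08

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if name in ("noise_cv", "yield_noise_cv"):
                if v < 0:
                    raise ConfigError(f"{name} must be >= 0")
            elif v <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; the defaults are the study conditions."""

    years: tuple[int, int] = (1975, 2022)
    soils: tuple[SoilProfile, ...] = field(default_factory=default_soils)
    tillage_systems: tuple[str, ...] = ("NT", "CT")
    rain_mean: float = 640.0  # mm/season (lowland southern England)
    rain_sd: float = 120.0
    temp_mean: float = 10.2   # deg C seasonal mean
    temp_sd: float = 0.7
    coefficients: Coefficients = field(default_factory=Coefficients)
    seed: int = 20_240_827

    def __post_init__(self):
        if self.years[1] < self.years[0]:
            raise ConfigError("years range is empty")
        if self.rain_sd < 0 or self.temp_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        self.coefficients.validate()

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def n_experiments(self) -> int:
        return len(self.soils) * len(self.tillage_systems)

    def extreme_rain_threshold(self) -> float:
        """Wet-season rainfall threshold: the configured quantile of the
        rainfall distribution (gamma with the configured mean/sd)."""
        shape = (self.rain_mean / self.rain_sd) ** 2
        scale = self.rain_sd ** 2 / self.rain_mean
        return float(stats.gamma.ppf(self.coefficients.extreme_quantile,
                                     shape, scale=scale))


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one lognormal multiplicative noise with coefficient of
    variation ``cv`` (degenerate at 1 when cv == 0)."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return rng.lognormal(-sigma ** 2 / 2, sigma, size)


def weather_series(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One (rainfall, temperature) draw per season.

    Rainfall is gamma (right-skewed, non-negative) with the configured
    mean/sd; temperature is normal.  The same series is shared by every
    experiment of a run, as a single catchment weather record would be.
    """
    years = np.arange(config.years[0], config.years[1] + 1)
    n = len(years)
    if config.rain_sd > 0:
        shape = (config.rain_mean / config.rain_sd) ** 2
        scale = config.rain_sd ** 2 / config.rain_mean
        rain = rng.gamma(shape, scale, n)
    else:
        rain = np.full(n, config.rain_mean)
    temp = rng.normal(config.temp_mean, config.temp_sd, n)
    return pd.DataFrame({"year": years, "rainfall": rain, "temperature": temp})


def simulate_season(
    soil: SoilProfile,
    tillage: str,
    weather,
    carry_state: dict,
    coefficients: Coefficients,
    rng: np.random.Generator,
    extreme_threshold: float = np.inf,
) -> tuple[dict, dict]:
    """Advance one season; returns (record, updated carry state).

    ``carry_state`` holds the current csom stock under key ``"csom"``;
    ``weather`` needs ``rainfall`` and ``temperature`` entries.
    """
    c = coefficients
    is_ct = tillage == "CT"
    rain = float(weather["rainfall"])
    temp = float(weather["temperature"])
    extreme = rain > extreme_threshold

    # (1) carbon stock decay — faster under CT
    csom_prev = float(carry_state["csom"])
    decay = c.csom_decay_ct if is_ct else c.csom_decay_nt
    turnover = decay * csom_prev
    csom = csom_prev - turnover

    # (2) available water space, increasing in the carbon stock
    oc_eff = soil.oc_percent * (csom / soil.csom_init)
    aws = soil.water_capacity * (1.0 + c.aws_oc_coef * oc_eff)
    if is_ct:
        aws *= c.ct_aws_mult

    # (3) biomass: rain plateau x temperature suitability x fertility
    rain_factor = rain / (rain + c.rain_half)
    temp_factor = float(np.exp(-((temp - c.temp_opt) / c.temp_width) ** 2))
    fertility = (max(oc_eff, 1e-6) / 4.0) ** c.fert_exp
    soil_factor = SOILSCAPE_YIELD_FACTOR.get(soil.soilscape, 1.0)
    biomass = (c.biomass_max * rain_factor * temp_factor * fertility
               * soil_factor * float(_lognoise(rng, c.noise_cv)))

    # (4) interception of precipitation by the canopy (% of rainfall)
    interception = float(np.clip(
        c.interception_base + c.interception_slope * biomass / c.biomass_max,
        0.05, 0.65))

    # (5) runoff: rainfall fraction, CT > NT, sheltered by aws/interception,
    #     amplified in extreme-rainfall seasons
    coef = c.runoff_coef
    if is_ct:
        coef *= c.ct_runoff_mult
    coef *= float(np.exp(-c.runoff_aws_k * (aws - 120.0) / 400.0))
    coef *= (1.0 - c.runoff_icpt_k * interception)
    if extreme:
        coef *= c.extreme_runoff_mult
    runoff = max(0.0, rain * coef * float(_lognoise(rng, c.noise_cv)))

    # (6) yield: harvest index (noisy) x biomass x runoff stress
    stress = runoff / (runoff + c.stress_half)
    hi = c.harvest_index * float(_lognoise(rng, c.yield_noise_cv))
    crop_yield = max(0.0, hi * biomass * (1.0 - stress))
    if extreme:
        penalty = c.extreme_yield_penalty * max(0.0, (3.0 - soil.oc_percent) / 2.0)
        crop_yield *= (1.0 - penalty)

    # (7) emissions: background + carbon turnover, CT multiplier, T response
    ghg = (c.ghg_base + c.ghg_turnover_k * turnover)
    if is_ct:
        ghg *= c.ct_ghg_mult
    ghg *= (1.0 + c.ghg_temp_k * (temp - c.temp_opt))
    ghg = max(0.0, ghg * float(_lognoise(rng, c.noise_cv)))

    record = {
        "experiment": experiment_id(tillage, soil.soilscape, soil.oc_percent),
        "year": int(weather["year"]) if "year" in weather else -1,
        "tillage": tillage,
        "soilscape": soil_id(soil.soilscape, soil.oc_percent),
        "rainfall": rain,
        "temperature": temp,
        "csom": csom,
        "aws": aws,
        "interception": interception,
        "biomass": biomass,
        "yield": crop_yield,
        "runoff": runoff,
        "ghg": ghg,
    }
    return record, {"csom": csom}


def simulate_dataset(config: SimConfig | None = None) -> pd.DataFrame:
    """All experiments x all seasons; fully reproducible from ``config.seed``.

    Weather is drawn once and shared; each experiment gets its own
    deterministic noise substream and carries its csom stock forward
    season by season.
    """
    if config is None:
        config = SimConfig()
    weather = weather_series(config, np.random.default_rng([config.seed, 0]))
    threshold = config.extreme_rain_threshold()
    rows = []
    exp_idx = 0
    for tillage in config.tillage_systems:
        for soil in config.soils:
            exp_idx += 1
            rng = np.random.default_rng([config.seed, exp_idx])
            carry = {"csom": soil.csom_init}
            for w in weather.itertuples(index=False):
                rec, carry = simulate_season(
                    soil, tillage, w._asdict(), carry,
                    config.coefficients, rng, threshold)
                rows.append(rec)
    return pd.DataFrame(rows)


def calibration_report(records: pd.DataFrame) -> pd.DataFrame:
    """Per-experiment min/max/mean/sd of yield and runoff, one column per
    experiment — the layout used to eyeball the generator against the
    published per-soil summary statistics."""
    stats_rows = {}
    for var in ("yield", "runoff"):
        g = records.groupby("experiment")[var]
        stats_rows[f"{var}_min"] = g.min()
        stats_rows[f"{var}_max"] = g.max()
        stats_rows[f"{var}_mean"] = g.mean()
        stats_rows[f"{var}_sd"] = g.std(ddof=1)
    return pd.DataFrame(stats_rows).T
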