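"""Synthetic regurgitate tables and covariate series with realistic structure.

The generator emulates the statistical skeleton of a two-decade Arctic-fjord
diet monitoring series: ~879 samples over 19 sampling years (a presence-only
era in the 1980s plus a mass-based era), a step change after a configurable
regime year in the occurrence probabilities of Arctic versus Atlantic prey,
right-skewed (lognormal) per-occurrence meal masses, and trending
environmental covariates (declining sea-ice index, warming fjord, a
population series with a step).  Taxon occurrences are independent within a
sample — real co-occurrence structure is not modelled.  All randomness flows
from a single seed; a fixed seed reproduces every table bit for bit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .environment import AnnualSeries
from .records import COLONIES, DietSample, PreyItem, SampleTable

#: The study-like default year layout: 4 presence-only years, 15 mass years.
DEFAULT_BINARY_YEARS = (1982, 1983, 1984, 1987)
DEFAULT_MASS_YEARS = (1997, 1998) + tuple(range(2004, 2017))


@dataclass(frozen=True)
class TaxonSpec:
    """Occurrence probabilities per regime and a lognormal meal-mass model."""

    p_pre: float            # occurrence probability, years <= regime_year
    p_post: float           # occurrence probability after the regime year
    meal_mass_g: float      # mean of the per-occurrence mass distribution
    mass_sigma: float = 0.8  # lognormal shape (right skew)
    first_year: int | None = None  # taxon absent before this year
    otolith_mean_mm: float | None = None  # emit otoliths when set

    def __post_init__(self) -> None:
        for p in (self.p_pre, self.p_post):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occurrence probability {p} outside [0, 1]")
        if self.meal_mass_g <= 0:
            raise ValueError("meal mass must be positive")


def default_taxa() -> dict[str, TaxonSpec]:
    """Regime-conditional occurrence and meal-mass defaults.

    Probabilities encode the Arctic-to-Atlantic flip (polar cod 0.8 -> 0.3,
    capelin 0.02 -> 0.35, herring appearing at 0.1 only from 2013), and meal
    masses match typical per-occurrence wet weights (fish ~ 12-17 g,
    crustaceans ~ 3-8 g).
    """
    return {
        "polar cod": TaxonSpec(0.80, 0.30, 17.2, otolith_mean_mm=5.0),
        "capelin": TaxonSpec(0.02, 0.35, 15.7, otolith_mean_mm=2.8),
        "Atlantic herring": TaxonSpec(0.0, 0.10, 12.1, first_year=2013,
                                      otolith_mean_mm=2.2),
        "Thysanoessa inermis": TaxonSpec(0.20, 0.30, 8.0, mass_sigma=0.7),
        "Themisto libellula": TaxonSpec(0.15, 0.05, 2.8, mass_sigma=0.7),
        "Nereis spp.": TaxonSpec(0.10, 0.05, 4.9, mass_sigma=0.7),
        "unidentified fish": TaxonSpec(0.15, 0.15, 8.8),
    }


@dataclass(frozen=True)
class EnvSpec:
    """Linear-trend + noise covariates; slopes per year from ``start_year``."""

    start_year: int = 1997
    end_year: int = 2016
    ice_intercept: float = 19.9   # sea-ice index %, value at start_year
    ice_slope: float = -0.5       # % per year
    ice_sd: float = 4.0
    temp_intercept: float = 0.3   # deg C
    temp_slope: float = 0.1       # deg C per year
    temp_sd: float = 0.5
    pop_intercept: float = 167.8  # active nests
    pop_slope: float = -6.9
    pop_step_year: int = 2006     # last year before the step increase
    pop_post_intercept: float = 80.1
    pop_post_slope: float = 1.4
    pop_sd: float = 12.0
    clutch_mean: float = 1.74
    clutch_sd: float = 0.08
    success_mean: float = 0.8
    success_sd: float = 0.12


@dataclass(frozen=True)
class GeneratorConfig:
    mass_years: tuple[int, ...] = DEFAULT_MASS_YEARS
    binary_years: tuple[int, ...] = DEFAULT_BINARY_YEARS
    samples_per_year: int = 46
    regime_year: int = 2006  # last year of the Arctic-dominated regime
    taxa: dict[str, TaxonSpec] = field(default_factory=default_taxa)
    env: EnvSpec = field(default_factory=EnvSpec)

    def occurrence_probability(self, taxon: str, year: int) -> float:
        spec = self.taxa[taxon]
        if spec.first_year is not None and year < spec.first_year:
            return 0.0
        return spec.p_pre if year <= self.regime_year else spec.p_post

    def with_regime_year(self, year: int) -> "GeneratorConfig":
        return replace(self, regime_year=year)


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    mu = np.log(mean) - sigma ** 2 / 2.0  # so E[X] = mean
    return float(rng.lognormal(mu, sigma))


def generate_samples(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> SampleTable:
    """Draw a full regurgitate table from the configured regime structure.

    Each sample contains each taxon independently with its regime-conditional
    probability; present taxa receive a lognormal wet mass (mass era) or a
    bare presence record (binary era).  Fish taxa with an otolith model also
    receive two otolith measurements per fish.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    samples: list[DietSample] = []
    all_years = sorted(set(config.binary_years) | set(config.mass_years))
    for year in all_years:
        mass_based = year in config.mass_years
        for i in range(config.samples_per_year):
            items = []
            for taxon, spec in config.taxa.items():
                p = config.occurrence_probability(taxon, year)
                if rng.random() >= p:
                    continue
                if not mass_based:
                    items.append(PreyItem(taxon))
                    continue
                mass = _lognormal(rng, spec.meal_mass_g, spec.mass_sigma)
                otoliths: tuple[float, ...] = ()
                count = None
                if spec.otolith_mean_mm is not None:
                    count = 1 + int(rng.poisson(0.5))
                    per_fish = rng.normal(spec.otolith_mean_mm,
                                          0.15 * spec.otolith_mean_mm,
                                          size=count)
                    per_fish = np.clip(per_fish, 0.3, None)
                    # two otoliths per fish, read to 0.1 mm
                    otoliths = tuple(
                        round(float(v + rng.normal(0, 0.05)), 1)
                        for v in per_fish for _ in range(2))
                items.append(PreyItem(taxon, round(mass, 2), otoliths, count))
            samples.append(DietSample(
                sample_id=f"S{year}_{i:03d}",
                year=year,
                date=dt.date(year, 6, 15)
                + dt.timedelta(days=int(rng.integers(0, 60))),
                colony=str(rng.choice(COLONIES[:3])),
                stage="incubation" if rng.random() < 0.16 else "chick_rearing",
                bird="adult" if rng.random() < 0.81 else "chick",
                sex=str(rng.choice(["male", "female", "unknown"])),
                items=tuple(items),
                mass_based=mass_based,
            ))
    return SampleTable(samples)


def generate_env(config: GeneratorConfig | None = None,
                 seed: int | None = None) -> dict[str, AnnualSeries]:
    """Annual covariate series: trends plus i.i.d. Gaussian noise.

    Returns sea_ice_index (%), temperature (deg C), population_size (nests;
    declining, then a step increase after ``pop_step_year``), clutch_size and
    breeding_success (both trendless).
    """
    config = config or GeneratorConfig()
    e = config.env
    rng = np.random.default_rng(seed)
    years = np.arange(e.start_year, e.end_year + 1)
    t = years - e.start_year

    def series(name, values):
        return AnnualSeries(name, pd.Series(values, index=years))

    ice = e.ice_intercept + e.ice_slope * t + rng.normal(0, e.ice_sd, len(t))
    temp = e.temp_intercept + e.temp_slope * t \
        + rng.normal(0, e.temp_sd, len(t))
    pre = years <= e.pop_step_year
    pop = np.where(
        pre,
        e.pop_intercept + e.pop_slope * t,
        e.pop_post_intercept + e.pop_post_slope * (years - e.pop_step_year - 1),
    ) + rng.normal(0, e.pop_sd, len(t))
    clutch = rng.normal(e.clutch_mean, e.clutch_sd, len(t))
    success = rng.normal(e.success_mean, e.success_sd, len(t))
    return {
        "sea_ice_index": series("sea_ice_index", np.clip(ice, 0, 100)),
        "temperature": series("temperature", temp),
        "population_size": series("population_size", np.clip(pop, 0, None)),
        "clutch_size": series("clutch_size", np.clip(clutch, 0, 3)),
        "breeding_success": series("breeding_success",
                                   np.clip(success, 0, None)),
    }


def table_from_counts(n_samples: int,
                      occurrences: dict[str, tuple[int, float]],
                      year: int = 2000,
                      stage_counts: dict[str, int] | None = None
                      ) -> SampleTable:
    """Deterministic table realizing given occurrence counts and meal masses.

    ``occurrences`` maps taxon -> (N, meal_mass_g): the taxon appears in the
    first N of ``n_samples`` samples, each occurrence weighing exactly
    meal_mass_g.  By construction FO = 100 N / n and WW = meal_mass x N / n,
    which makes published summary rows (N, MM, n) reproducible as a concrete
    sample table.  ``stage_counts`` optionally assigns breeding-stage labels
    in order.
    """
    stages = []
    if stage_counts:
        for stage, count in stage_counts.items():
            stages.extend([stage] * count)
        if len(stages) != n_samples:
            raise ValueError("stage counts must sum to n_samples")
    samples = []
    for i in range(n_samples):
        items = tuple(
            PreyItem(taxon, mass)
            for taxon, (n_present, mass) in occurrences.items()
            if i < n_present
        )
        samples.append(DietSample(
            sample_id=f"T{i:04d}", year=year,
            stage=stages[i] if stages else "unknown", items=items))
    return SampleTable(samples)


def generate_step_series(name: str, years, mean_pre: float, mean_post: float,
                         changepoint_year: int, sd: float,
                         seed: int | None = None) -> AnnualSeries:
    """A noisy step series: N(mean_pre, sd) through the changepoint year,
    N(mean_post, sd) after — the canonical regime-shift test signal."""
    rng = np.random.default_rng(seed)
    years = np.asarray(sorted(years))
    means = np.where(years <= changepoint_year, mean_pre, mean_post)
    values = rng.normal(means, sd)
    return AnnualSeries(name, pd.Series(values, index=years))
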