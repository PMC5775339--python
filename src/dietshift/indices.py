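"""The four standard diet-composition indices for regurgitate samples.

For a category c (a taxon or an origin class) over a scope of samples:

* **FO** — frequency of occurrence, ``100 * N / n`` where N samples contain c;
  presence-based, so it bridges binary-era and mass-based data.
* **WW** — average wet weight, mean of c's mass across *all* mass-based
  samples (zeros included); a proxy of energetic importance.
* **MM** — average meal mass, mean of c's mass across only the samples where
  c occurs; ``WW = MM * N / n`` holds exactly before rounding.
* **AP** — average mass percentage, mean across samples of c's share of the
  sample's total mass; robust to outliers, gives each sample equal weight.

SEMs (sd/sqrt(n), sample sd) accompany WW, MM and AP; FO carries none, being
a single proportion rather than a mean of a per-sample quantity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .records import ORIGINS, DietSample, SampleTable, TaxonCatalog


def _is_origin(category: str) -> bool:
    return category in ORIGINS


def category_present(sample: DietSample, category: str,
                     catalog: TaxonCatalog) -> bool:
    if _is_origin(category):
        return any(catalog.origin_of(i.taxon) == category for i in sample.items)
    return any(i.taxon == category for i in sample.items)


def category_mass(sample: DietSample, category: str,
                  catalog: TaxonCatalog) -> float:
    """Wet mass (g) of a category in a mass-based sample, 0 when absent."""
    if not sample.mass_based:
        raise ValueError(
            f"sample {sample.sample_id!r} is presence-only; no mass available")
    if _is_origin(category):
        return sum(i.wet_mass or 0.0 for i in sample.items
                   if catalog.origin_of(i.taxon) == category)
    return sum(i.wet_mass or 0.0 for i in sample.items if i.taxon == category)


def _scope(table: SampleTable, year: int | None) -> SampleTable:
    return table if year is None else table.for_year(year)


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def frequency_of_occurrence(table: SampleTable, category: str,
                            catalog: TaxonCatalog,
                            year: int | None = None) -> float:
    """FO in percent: share of in-scope samples containing the category."""
    scope = _scope(table, year)
    if scope.n_samples == 0:
        raise ValueError(f"no samples in scope (year={year})")
    n_present = sum(category_present(s, category, catalog) for s in scope)
    return 100.0 * n_present / scope.n_samples


def average_wet_weight(table: SampleTable, category: str,
                       catalog: TaxonCatalog,
                       year: int | None = None) -> tuple[float, float]:
    """WW in grams with its SEM; mean over all mass-based samples in scope."""
    scope = _scope(table, year).mass_based()
    if scope.n_samples == 0:
        raise ValueError(f"no mass-based samples in scope (year={year})")
    masses = np.array([category_mass(s, category, catalog) for s in scope])
    return float(masses.mean()), _sem(masses)


def average_meal_mass(table: SampleTable, category: str,
                      catalog: TaxonCatalog,
                      year: int | None = None) -> tuple[float, float]:
    """MM in grams with its SEM; mean over samples where the category occurs."""
    scope = _scope(table, year).mass_based()
    masses = np.array([
        category_mass(s, category, catalog) for s in scope
        if category_present(s, category, catalog)
    ])
    if len(masses) == 0:
        raise ValueError(
            f"category {category!r} absent from all mass-based samples in scope")
    return float(masses.mean()), _sem(masses)


def average_mass_percentage(table: SampleTable, category: str,
                            catalog: TaxonCatalog,
                            year: int | None = None) -> tuple[float, float]:
    """AP in percent with its SEM; mean of per-sample mass fractions.

    Samples with zero total mass carry no compositional information and are
    excluded from the mean.
    """
    scope = _scope(table, year).mass_based()
    fractions = []
    for s in scope:
        total = s.total_mass
        if total <= 0:
            continue
        fractions.append(100.0 * category_mass(s, category, catalog) / total)
    if not fractions:
        raise ValueError(f"no samples with positive total mass (year={year})")
    arr = np.array(fractions)
    return float(arr.mean()), _sem(arr)


def index_table(table: SampleTable, categories: list[str],
                catalog: TaxonCatalog,
                by_year: bool = False) -> pd.DataFrame:
    """All four indices for each category, pooled or per year.

    FO uses every sample in scope; WW, MM and AP use the mass-based subset.
    Categories absent from a scope get MM = NaN (undefined, not zero).
    """
    scopes = [(y,) for y in table.years] if by_year else [(None,)]
    rows = []
    for (year,) in scopes:
        scope_all = _scope(table, year)
        scope_mass = scope_all.mass_based()
        for cat in categories:
            n_present = sum(
                category_present(s, cat, catalog) for s in scope_mass)
            row = {"category": cat}
            if by_year:
                row["year"] = year
            row["FO"] = frequency_of_occurrence(table, cat, catalog, year)
            row["N"] = n_present
            if scope_mass.n_samples:
                row["WW"], row["WW_sem"] = average_wet_weight(
                    table, cat, catalog, year)
                if n_present:
                    row["MM"], row["MM_sem"] = average_meal_mass(
                        table, cat, catalog, year)
                else:
                    row["MM"] = row["MM_sem"] = math.nan
                row["AP"], row["AP_sem"] = average_mass_percentage(
                    table, cat, catalog, year)
            else:
                for k in ("WW", "WW_sem", "MM", "MM_sem", "AP", "AP_sem"):
                    row[k] = math.nan
            row["n_samples"] = scope_all.n_samples
            row["n_mass_samples"] = scope_mass.n_samples
            rows.append(row)
    return pd.DataFrame(rows)


def format_index_table(df: pd.DataFrame) -> pd.DataFrame:
    """Render an index table at reporting precision: one decimal, SEM in
    parentheses."""
    out = df.copy()
    for metric in ("WW", "MM", "AP"):
        sem = out.pop(f"{metric}_sem")
        out[metric] = [
            "" if math.isnan(v) else
            (f"{v:.1f}" if math.isnan(s) else f"{v:.1f} ({s:.1f})")
            for v, s in zip(df[metric], sem)
        ]
    out["FO"] = [f"{v:.1f}" for v in df["FO"]]
    return out
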