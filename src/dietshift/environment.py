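"""Annual environmental indices, trends, detrending and correlation.

Covers construction of a regional sea-ice index from daily gridded
concentrations, volume-weighted fjord temperature from depth profiles, OLS
trend fits on annual series, linear detrending, and Pearson correlation with
Fisher-z confidence intervals — the toolkit for asking whether a diet index
tracks its physical environment beyond a shared long-term trend.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnnualSeries:
    """A named year-indexed numeric series (units documented by the name)."""

    name: str
    values: pd.Series  # index: int years, sorted, unique

    def __post_init__(self) -> None:
        s = pd.Series(self.values).dropna()
        s.index = s.index.astype(int)
        if s.index.has_duplicates:
            raise ValueError(f"series {self.name!r} has duplicate years")
        self.values = s.sort_index().astype(float)

    @classmethod
    def from_dict(cls, name: str, data: dict[int, float]) -> "AnnualSeries":
        return cls(name, pd.Series(data))

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def __len__(self) -> int:
        return len(self.values)


def as_annual_series(obj, name: str = "series") -> AnnualSeries:
    if isinstance(obj, AnnualSeries):
        return obj
    if isinstance(obj, pd.Series):
        return AnnualSeries(obj.name or name, obj)
    return AnnualSeries.from_dict(name, dict(obj))


def sea_ice_index(daily: pd.DataFrame) -> AnnualSeries:
    """Annual sea-ice index (%) from daily per-block ice concentrations.

    Averaging order matters and is fixed: block mean per day, then daily mean
    per month, then the annual value is the mean of the 12 monthly means —
    so short months weigh as much as long ones.  Years missing any month are
    dropped with a warning.

    ``daily`` columns: date (parseable), block_id, concentration_pct in
    [0, 100].
    """
    df = daily.copy()
    conc = df["concentration_pct"].astype(float)
    if (conc < 0).any() or (conc > 100).any():
        bad = conc[(conc < 0) | (conc > 100)].iloc[0]
        raise ValueError(f"ice concentration outside [0, 100]: {bad}")
    dates = pd.to_datetime(df["date"])
    df = pd.DataFrame({"year": dates.dt.year, "month": dates.dt.month,
                       "day": dates.dt.day, "conc": conc})
    day_mean = df.groupby(["year", "month", "day"])["conc"].mean()
    month_mean = day_mean.groupby(["year", "month"]).mean()
    annual = {}
    for year, grp in month_mean.groupby(level="year"):
        if len(grp) < 12:
            warnings.warn(
                f"year {year}: only {len(grp)} months of ice data; dropped",
                stacklevel=2)
            continue
        annual[int(year)] = float(grp.mean())
    return AnnualSeries.from_dict("sea_ice_index", annual)


def volume_weighted_temperature(depths, temperatures, areas) -> float:
    """Mean fjord temperature weighted by basin volume at each depth level.

    Each depth level's temperature is weighted by area x layer thickness and
    the sum is normalized by total volume: sum T(z) A(z) dz / sum A(z) dz.
    Areas must be non-negative and non-increasing with depth (a basin narrows
    downward).
    """
    z = np.asarray(depths, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    a = np.asarray(areas, dtype=float)
    if not (len(z) == len(t) == len(a)):
        raise ValueError("depth, temperature and area grids must match")
    if (a < 0).any():
        raise ValueError("areas must be non-negative")
    if len(z) > 1:
        order = np.argsort(z)
        z, t, a = z[order], t[order], a[order]
        if (np.diff(a) > 1e-9).any():
            raise ValueError("areas must be non-increasing with depth")
        dz = np.gradient(z)
    else:
        dz = np.ones(1)
    volume = float((a * dz).sum())
    if volume <= 0:
        raise ValueError("zero total volume")
    return float((t * a * dz).sum() / volume)


@dataclass
class TrendFit:
    """OLS fit of an annual series on years elapsed since its first year."""

    slope: float
    intercept: float
    slope_se: float
    f_statistic: float
    p_value: float
    r_squared: float
    n: int
    first_year: int

    def predict(self, years) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(years) - self.first_year)


def trend_regression(series) -> TrendFit:
    """Linear trend of an annual series; years centered at the first year."""
    s = as_annual_series(series)
    if len(s) < 3:
        raise ValueError(f"need >= 3 points, got {len(s)}")
    x = s.years - s.years[0]
    y = s.values.to_numpy()
    if np.ptp(y) == 0:
        return TrendFit(0.0, float(y[0]), 0.0, math.nan, math.nan, 0.0,
                        len(s), int(s.years[0]))
    res = stats.linregress(x, y)
    df = len(s) - 2
    f = res.rvalue ** 2 / (1 - res.rvalue ** 2) * df if res.rvalue ** 2 < 1 \
        else math.inf
    return TrendFit(float(res.slope), float(res.intercept),
                    float(res.stderr), float(f), float(res.pvalue),
                    float(res.rvalue ** 2), len(s), int(s.years[0]))


def detrend(series) -> AnnualSeries:
    """Residuals from the OLS regression of value on year (zero-mean output)."""
    s = as_annual_series(series)
    if len(s) < 3:
        raise ValueError(f"need >= 3 points to detrend, got {len(s)}")
    x = s.years - s.years[0]
    y = s.values.to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return AnnualSeries(f"{s.name}_detrended",
                        pd.Series(resid, index=s.values.index))


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    ci95: tuple[float, float]
    p: float
    n: int
    detrended: bool
    #: CI-based decision rule: significant iff the 95% CI excludes zero.
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.r <= hi + 1e-12):
            raise ValueError("confidence interval must contain r")
        self.significant = lo > 0 or hi < 0


def correlate(x, y, detrended: bool = False) -> CorrelationResult:
    """Pearson correlation between two annual series on overlapping years.

    Pairwise-complete: only years present in both series enter.  With
    ``detrended=True`` both series are first replaced by their residuals from
    a linear fit on year, removing a shared long-term trend.  The 95% CI uses
    the Fisher z transform; the associated significance flag is the CI
    excluding zero, and the two-sided t-test p value is also reported.
    """
    xs, ys = as_annual_series(x, "x"), as_annual_series(y, "y")
    common = xs.values.index.intersection(ys.values.index)
    if len(common) < 4:
        raise ValueError(f"need >= 4 overlapping years, got {len(common)}")
    xv = AnnualSeries(xs.name, xs.values.loc[common])
    yv = AnnualSeries(ys.name, ys.values.loc[common])
    if detrended:
        xv, yv = detrend(xv), detrend(yv)
    a, b = xv.values.to_numpy(), yv.values.to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(a, b)
    n = len(common)
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
    ci = (math.tanh(z - half), math.tanh(z + half))
    return CorrelationResult(xs.name, ys.name, float(r), ci, float(p), n,
                             detrended)


def correlation_table(pairs: list[tuple], detrended_modes=(False, True)
                      ) -> pd.DataFrame:
    """Correlate every (x, y) pair under each detrending mode."""
    rows = []
    for x, y in pairs:
        for mode in detrended_modes:
            try:
                res = correlate(x, y, detrended=mode)
            except ValueError as exc:
                warnings.warn(f"skipping pair: {exc}", stacklevel=2)
                continue
            rows.append({
                "x": res.x_name, "y": res.y_name, "detrended": res.detrended,
                "r": res.r, "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                "p": res.p, "n": res.n, "significant": res.significant,
            })
    return pd.DataFrame(rows)
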