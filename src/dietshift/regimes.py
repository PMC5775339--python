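"""Change-point (regime-shift) analysis of annual series with model selection.

A regime shift is an abrupt, persistent change in an annual index.  Five
candidate mean structures are fitted by ordinary least squares:

========================  ==========================================  ======
form                      structure                                   params
========================  ==========================================  ======
constant                  one mean                                    1
linear                    one intercept + one slope                   2
constant_changepoint      a mean per regime (step change)             2
linear_changepoint        shared slope, intercept shift at the break  3
linear_interaction_       separate intercept and slope per regime     4
changepoint
========================  ==========================================  ======

For change-point forms, every admissible break year is tried exhaustively
(each regime keeps at least ``min_segment`` points) and the best break kept.
Forms then compete on AICc, the small-sample-corrected Akaike criterion —
appropriate here because annual ecological series rarely exceed ~20 points.
Near-ties (ΔAICc < 0.01) go to the simpler form.

Reporting convention: a change between year y and y+1 is reported as break
year y, i.e. the last year of the previous regime; regime labels render as
"start–y" and "(y+1)–end".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .environment import AnnualSeries, as_annual_series

FORMS = (
    "constant",
    "linear",
    "constant_changepoint",
    "linear_changepoint",
    "linear_interaction_changepoint",
)
CHANGEPOINT_FORMS = tuple(f for f in FORMS if "changepoint" in f)

#: Minimum points per regime: one residual df per regime for linear pieces.
MIN_SEGMENT = 3

#: ΔAICc below which two forms are considered tied (simpler form preferred).
TIE_TOLERANCE = 0.01

_RSS_FLOOR = 1e-12  # below this a fit is treated as exact


@dataclass(frozen=True)
class CandidateForm:
    form: str
    changepoint_year: int | None = None

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if self.form in CHANGEPOINT_FORMS and self.changepoint_year is None:
            raise ValueError(f"form {self.form!r} needs a changepoint year")
        if self.form not in CHANGEPOINT_FORMS \
                and self.changepoint_year is not None:
            raise ValueError(f"form {self.form!r} takes no changepoint")


@dataclass
class RegimeFit:
    """A fitted candidate model with OLS inference and its selection score."""

    form: str
    changepoint_year: int | None
    terms: pd.DataFrame      # term, estimate, se, t, p
    n: int
    n_params: int
    rss: float
    f_statistic: float       # whole model vs grand mean; NaN for 'constant'
    f_p: float
    df_resid: int
    aicc: float
    years: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.terms["term"], self.terms["estimate"]))

    def regime_labels(self) -> list[str]:
        y0, y1 = int(self.years.min()), int(self.years.max())
        if self.changepoint_year is None:
            return [f"{y0}-{y1}"]
        cp = self.changepoint_year
        return [f"{y0}-{cp}", f"{cp + 1}-{y1}"]


def _design(years: np.ndarray, cand: CandidateForm) -> tuple[np.ndarray, list]:
    t = (years - years.min()).astype(float)
    if cand.form == "constant":
        X = np.ones((len(years), 1))
        names = ["intercept"]
    elif cand.form == "linear":
        X = np.column_stack([np.ones_like(t), t])
        names = ["intercept", "slope"]
    else:
        pre = (years <= cand.changepoint_year).astype(float)
        post = 1.0 - pre
        if cand.form == "constant_changepoint":
            X = np.column_stack([pre, post])
            names = ["intercept_pre", "intercept_post"]
        elif cand.form == "linear_changepoint":
            X = np.column_stack([pre, post, t])
            names = ["intercept_pre", "intercept_post", "slope"]
        else:  # linear_interaction_changepoint
            X = np.column_stack([pre, post, pre * t, post * t])
            names = ["intercept_pre", "intercept_post",
                     "slope_pre", "slope_post"]
    return X, names


def _aicc(n: int, rss: float, n_coef: int) -> float:
    if rss <= _RSS_FLOOR:
        return -math.inf
    k = n_coef + 1  # + residual variance
    penalty = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf
    return n * math.log(rss / n) + 2 * k + penalty


def fit_form(series, cand: CandidateForm | str,
             changepoint_year: int | None = None) -> RegimeFit:
    """OLS fit of one candidate mean structure to an annual series.

    Regime membership for change-point forms is year <= break (regime 1)
    versus year > break (regime 2); each regime must hold at least
    ``MIN_SEGMENT`` points.
    """
    if isinstance(cand, str):
        cand = CandidateForm(cand, changepoint_year)
    s = as_annual_series(series)
    years = s.years
    y = s.values.to_numpy()
    n = len(y)
    if cand.form in CHANGEPOINT_FORMS:
        n_pre = int((years <= cand.changepoint_year).sum())
        if min(n_pre, n - n_pre) < MIN_SEGMENT:
            raise ValueError(
                f"changepoint {cand.changepoint_year} leaves a regime with "
                f"fewer than {MIN_SEGMENT} points")
    X, names = _design(years, cand)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"{n} points cannot identify {p} parameters")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    terms = pd.DataFrame({
        "term": names, "estimate": beta, "se": se, "t": tvals, "p": pvals,
    })
    # whole-model F against the grand-mean model
    tss = float(((y - y.mean()) ** 2).sum())
    if p > 1 and rss > _RSS_FLOOR:
        f = ((tss - rss) / (p - 1)) / (rss / df_resid)
        f_p = float(stats.f.sf(f, p - 1, df_resid))
    elif p > 1:
        f, f_p = math.inf, 0.0
    else:
        f, f_p = math.nan, math.nan
    return RegimeFit(
        form=cand.form, changepoint_year=cand.changepoint_year,
        terms=terms, n=n, n_params=p, rss=rss,
        f_statistic=f, f_p=f_p, df_resid=df_resid,
        aicc=_aicc(n, rss, p), years=years, fitted=fitted,
    )


def admissible_changepoints(series, window: tuple[int, int] | None = None
                            ) -> list[int]:
    """Break years leaving >= MIN_SEGMENT points on both sides, optionally
    restricted to a [lo, hi] year window."""
    s = as_annual_series(series)
    years = s.years
    cps = [int(y) for y in years[MIN_SEGMENT - 1:-MIN_SEGMENT]]
    if window is not None:
        lo, hi = window
        cps = [y for y in cps if (lo is None or y >= lo)
               and (hi is None or y <= hi)]
    return cps


def scan_changepoints(series, form: str,
                      window: tuple[int, int] | None = None) -> RegimeFit:
    """Exhaustive scan of admissible break years for one change-point form.

    Returns the best fit (lowest AICc; within a form that equals lowest RSS);
    the full profile is attached as ``fit.scan_profile`` (year, rss, aicc).
    """
    if form not in CHANGEPOINT_FORMS:
        raise ValueError(f"{form!r} is not a changepoint form")
    s = as_annual_series(series)
    cps = admissible_changepoints(s, window)
    if not cps:
        raise ValueError("no admissible changepoint years in the window")
    fits = [fit_form(s, CandidateForm(form, cp)) for cp in cps]
    best = min(fits, key=lambda f: (f.rss, f.changepoint_year))
    best.scan_profile = pd.DataFrame({
        "changepoint_year": cps,
        "rss": [f.rss for f in fits],
        "aicc": [f.aicc for f in fits],
    })
    return best


def select_model(series, forms=FORMS,
                 window: tuple[int, int] | None = None) -> RegimeFit:
    """Fit every candidate form (scanning break years) and pick the AICc winner.

    Near-ties (ΔAICc < 0.01, including exact fits from noiseless data) resolve
    to the form with fewer parameters.  The full ranking is attached as
    ``fit.ranking`` with columns form, changepoint_year, n_params, rss, aicc,
    delta_aicc.
    """
    forms = list(forms)
    if len(forms) < 2:
        raise ValueError("need at least 2 candidate forms")
    fits: list[RegimeFit] = []
    for form in forms:
        if form in CHANGEPOINT_FORMS:
            try:
                fits.append(scan_changepoints(series, form, window))
            except ValueError:
                continue  # no admissible break years for this form
        else:
            fits.append(fit_form(series, CandidateForm(form)))
    if not fits:
        raise ValueError("no candidate form could be fitted")
    best_aicc = min(f.aicc for f in fits)
    if math.isinf(best_aicc):
        tied = [f for f in fits if math.isinf(f.aicc)]
    else:
        tied = [f for f in fits if f.aicc <= best_aicc + TIE_TOLERANCE]
    winner = min(tied, key=lambda f: f.n_params)
    ranking = pd.DataFrame({
        "form": [f.form for f in fits],
        "changepoint_year": [f.changepoint_year for f in fits],
        "n_params": [f.n_params for f in fits],
        "rss": [f.rss for f in fits],
        "aicc": [f.aicc for f in fits],
    }).sort_values("aicc", kind="stable").reset_index(drop=True)
    ranking["delta_aicc"] = ranking["aicc"] - ranking["aicc"].min()
    winner.ranking = ranking
    return winner


def regime_report(fits: dict[str, RegimeFit]) -> pd.DataFrame:
    """Flatten named fits into a long report (one row per model + per term)."""
    rows = []
    for name, fit in fits.items():
        rows.append({
            "variable": name, "type": fit.form,
            "changepoint_year": fit.changepoint_year,
            "term": "(model)", "estimate": math.nan,
            "df": fit.df_resid, "stat": fit.f_statistic, "p": fit.f_p,
        })
        labels = fit.regime_labels()
        for r in fit.terms.itertuples():
            term = r.term
            if term.endswith("_pre"):
                term = f"{term[:-4]} {labels[0]}"
            elif term.endswith("_post"):
                term = f"{term[:-5]} {labels[-1]}"
            else:
                term = f"{term} {labels[0] if len(labels) == 1 else ''}".strip()
            rows.append({
                "variable": name, "type": fit.form,
                "changepoint_year": fit.changepoint_year,
                "term": term, "estimate": r.estimate,
                "df": fit.df_resid, "stat": r.t, "p": r.p,
            })
    return pd.DataFrame(rows)
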