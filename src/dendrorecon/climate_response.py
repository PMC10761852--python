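"""Growth-climate response analysis.

Correlation functions are computed over a 17-month dendroclimatic window
(previous June through current October) with classical pairs-bootstrap
confidence intervals; seasonal partial correlations (seascorr) take a
primary variable (precipitation) and test a secondary variable
(temperature) after removing the primary, with significance from AR(1)
surrogate chronologies; moving correlations probe the temporal stability
of the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import MONTH_ABBR, MonthlyClimate

#: named seasons shown alongside single months in response figures
DEFAULT_SEASONS = {
    "DJF": [-12, 1, 2], "MAM": [3, 4, 5], "MAMJ": [3, 4, 5, 6],
    "FMAMJ": [2, 3, 4, 5, 6], "JJAS": [6, 7, 8, 9],
}


def month_label(m: int) -> str:
    """Signed-month label: -6 -> pJUN (previous year June), 6 -> JUN."""
    if m < 0:
        return "p" + MONTH_ABBR[-m - 1]
    if m > 12:
        return MONTH_ABBR[m - 13]
    return MONTH_ABBR[m - 1]


@dataclass
class SeasonalSeries:
    """A month-window aggregate of one climate variable, year-indexed."""

    variable: str
    months: list[int]            # signed: negative = previous year
    aggregation: str             # "sum" | "mean"
    values: pd.Series

    @property
    def label(self) -> str:
        return f"{self.variable}[{month_label(self.months[0])}-{month_label(self.months[-1])}]"


def _month_values(mc: MonthlyClimate, variable: str, month: int) -> pd.Series:
    """Year-indexed values of one signed month (negative = previous year)."""
    mat = mc.variable(variable)
    years = mc.years
    if month > 0:
        return pd.Series(mat[:, month - 1], index=years)
    m = -month
    s = pd.Series(mat[:, m - 1], index=years + 1)  # value attributed to next year
    return s


def seasonalize(mc: MonthlyClimate, variable: str, months: list[int],
                aggregation: str | None = None) -> SeasonalSeries:
    """Aggregate monthly climate to a signed-month window per year.

    Negative months refer to the previous calendar year (e.g. -6 = June of
    the year before ring formation).  Precipitation aggregates by sum,
    temperatures by mean, unless overridden.  Years where any member month
    is missing get NaN.
    """
    if not months:
        raise ValueError("empty month window")
    for m in months:
        if m == 0 or m < -12 or m > 12:
            raise ValueError(f"bad signed month {m} (use -12..-1 or 1..12)")
    if aggregation is None:
        aggregation = "sum" if variable in ("prcp", "scpdsi") else "mean"
    cols = pd.DataFrame({m: _month_values(mc, variable, m) for m in months})
    cols = cols.loc[mc.years[0]:mc.years[-1] + 1]
    agg = cols.sum(axis=1, skipna=False) if aggregation == "sum" else cols.mean(axis=1, skipna=False)
    agg = agg.dropna()
    return SeasonalSeries(variable=variable, months=list(months),
                          aggregation=aggregation, values=agg)


def window_months(start: int = -6, end: int = 10) -> list[int]:
    """The dendroclimatic window as signed months in chronological order;
    the default pJun..Oct spans 17 months: -6, -7, ..., -12, 1, 2, ..., 10
    (a negative month m is month |m| of the previous year)."""
    if start >= 0 and end >= start:
        return list(range(max(start, 1), end + 1))
    # previous-year part runs |start|..12, then current-year 1..end
    seq = [-m for m in range(-start, 13)]
    if end >= 1:
        seq += list(range(1, end + 1))
    return seq


@dataclass
class CorrelationFunction:
    """Bootstrapped correlations of a chronology with monthly/seasonal climate."""

    variable: str
    table: pd.DataFrame  # index: month/season label; columns r, lo, hi, significant
    n_years: int
    nboot: int


def _boot_ci(x: np.ndarray, y: np.ndarray, nboot: int, rng: np.random.Generator,
             level: float = 0.95) -> tuple[float, float, float]:
    """Pearson r with a classical pairs-bootstrap percentile interval."""
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    idx = rng.integers(0, n, size=(nboot, n))
    xs, ys = x[idx], y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    num = (xs * ys).sum(axis=1)
    den = np.sqrt((xs ** 2).sum(axis=1) * (ys ** 2).sum(axis=1))
    rb = num / np.where(den == 0, np.nan, den)
    a = (1.0 - level) / 2
    lo, hi = np.nanquantile(rb, [a, 1 - a])
    return r, float(lo), float(hi)


def bootstrap_corrfun(ch: pd.Series, mc: MonthlyClimate, variables: list[str],
                      start: int = -6, end: int = 10, nboot: int = 1000,
                      seed: int = 0, seasons: dict | None = None
                      ) -> dict[str, CorrelationFunction]:
    """Bootstrapped correlation function over the dendroclimatic window.

    ``ch`` is a year-indexed chronology (standard or residual).  For each
    variable, every month in the window and every named season is
    correlated with the chronology over the common years; significance is
    a 95% percentile bootstrap interval excluding zero.
    """
    if seasons is None:
        seasons = DEFAULT_SEASONS
    rng = np.random.default_rng(seed)
    out = {}
    for var in variables:
        if var not in mc.data:
            continue
        rows = {}
        targets: list[tuple[str, list[int]]] = [(month_label(m), [m]) for m in window_months(start, end)]
        targets += list(seasons.items())
        for label, months in targets:
            sx = seasonalize(mc, var, months)
            joint = pd.concat([ch.rename("c"), sx.values.rename("v")], axis=1).dropna()
            if len(joint) < 30:
                continue
            r, lo, hi = _boot_ci(joint["c"].to_numpy(), joint["v"].to_numpy(), nboot, rng)
            rows[label] = {"r": r, "lo": lo, "hi": hi,
                           "significant": bool(lo > 0 or hi < 0), "n": len(joint)}
        table = pd.DataFrame(rows).T
        out[var] = CorrelationFunction(variable=var, table=table,
                                       n_years=int(table["n"].max()) if len(table) else 0,
                                       nboot=nboot)
    return out


# ---------------------------------------------------------------------------
# seascorr

def _partial_corr(y: np.ndarray, x2: np.ndarray, x1: np.ndarray) -> float:
    """Correlation of y with the part of x2 orthogonal to x1.

    This semi-partial form measures the *additional* association the
    secondary variable carries once the primary's influence on it is
    removed; when the primary saturates y the result is ~0, and when the
    two climate variables are uncorrelated it equals the simple r.
    """
    u = np.column_stack([np.ones_like(x1), x1])
    beta, *_ = np.linalg.lstsq(u, x2, rcond=None)
    resid2 = x2 - u @ beta
    if resid2.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(y, resid2)[0, 1])


def _ar1_surrogates(x: np.ndarray, nsim: int, rng: np.random.Generator) -> np.ndarray:
    """AR(1) surrogate series matching lag-1 autocorrelation and variance."""
    phi = float(np.corrcoef(x[:-1], x[1:])[0, 1]) if len(x) > 2 else 0.0
    phi = min(max(phi, -0.99), 0.99)
    n = len(x)
    innov = rng.normal(0, 1.0, size=(nsim, n))
    out = np.empty((nsim, n))
    out[:, 0] = innov[:, 0]
    c = np.sqrt(1 - phi ** 2)
    for t in range(1, n):
        out[:, t] = phi * out[:, t - 1] + c * innov[:, t]
    sd = x.std() if x.std() > 0 else 1.0
    return x.mean() + (out - out.mean(axis=1, keepdims=True)) * sd


def seascorr(ch: pd.Series, mc: MonthlyClimate, primary: str = "prcp",
             secondary: str = "tmean", season_lengths: tuple = (1, 3, 5, 12),
             end_months: list[int] | None = None, nsim: int = 1000,
             seed: int = 0, level: float = 0.95) -> pd.DataFrame:
    """Seasonal partial-correlation analysis (seascorr).

    For each season length L and ending month, the chronology is
    correlated with the primary variable aggregated over the L months
    ending there (simple r), and with the secondary variable after
    partialling out the primary (partial r).  Significance uses empirical
    non-exceedance probabilities from ``nsim`` AR(1) surrogate
    chronologies that preserve the chronology's lag-1 persistence.
    """
    for L in season_lengths:
        if L < 1:
            raise ValueError("season lengths must be positive")
    if end_months is None:
        end_months = list(range(1, 13))
    rng = np.random.default_rng(seed)
    rows = []
    for L in season_lengths:
        for em in end_months:
            # months <= 0 wrap into the previous year: 0 -> pDec (-12), -1 -> pNov (-11)
            signed = [k if k >= 1 else -(k + 12) for k in range(em - L + 1, em + 1)]
            sp = seasonalize(mc, primary, signed)
            ss = seasonalize(mc, secondary, signed)
            joint = pd.concat([ch.rename("c"), sp.values.rename("p"),
                               ss.values.rename("s")], axis=1).dropna()
            if len(joint) < 30:
                continue
            c = joint["c"].to_numpy()
            p = joint["p"].to_numpy()
            s = joint["s"].to_numpy()
            r_p = float(np.corrcoef(c, p)[0, 1])
            r_s = _partial_corr(c, s, p)

            sur = _ar1_surrogates(c, nsim, rng)
            null_p = np.empty(nsim)
            null_s = np.empty(nsim)
            pz = (p - p.mean()) / p.std()
            for i in range(nsim):
                ci = sur[i]
                null_p[i] = np.corrcoef(ci, p)[0, 1]
                null_s[i] = _partial_corr(ci, s, p)
            a = (1 - level) / 2
            sig_p = r_p < np.quantile(null_p, a) or r_p > np.quantile(null_p, 1 - a)
            sig_s = r_s < np.quantile(null_s, a) or r_s > np.quantile(null_s, 1 - a)
            rows.append({"length": L, "end_month": month_label(em),
                         "r_primary": r_p, "sig_primary": bool(sig_p),
                         "r_secondary_partial": r_s, "sig_secondary": bool(sig_s),
                         "n": len(joint)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# moving correlations

@dataclass
class MovingCorrelation:
    variable: str
    window: int
    step: int
    table: pd.DataFrame  # columns: window_start, window_end, target, r, p, significant


def moving_corr(ch: pd.Series, mc: MonthlyClimate, variable: str,
                window: int = 30, step: int = 2, start: int = -6, end: int = 10,
                seasons: dict | None = None, alpha: float = 0.05) -> MovingCorrelation:
    """Moving-window correlations between a chronology and monthly/seasonal
    climate (default 30-yr windows advancing 2 yr)."""
    if seasons is None:
        seasons = DEFAULT_SEASONS
    targets: list[tuple[str, list[int]]] = [(month_label(m), [m]) for m in window_months(start, end)]
    targets += list(seasons.items())
    seasonal = {}
    for label, months in targets:
        seasonal[label] = seasonalize(mc, variable, months).values

    joint_all = pd.concat([ch.rename("c")] +
                          [v.rename(k) for k, v in seasonal.items()], axis=1)
    joint_all = joint_all.dropna(subset=["c"])
    years = joint_all.index.to_numpy()
    n_avail = len(joint_all.dropna())
    if n_avail < window:
        raise ValueError(f"overlap ({n_avail}) shorter than moving window ({window})")

    rows = []
    first = int(joint_all.dropna().index.min())
    last = int(joint_all.dropna().index.max())
    w0 = first
    while w0 + window - 1 <= last:
        sub = joint_all.loc[w0:w0 + window - 1].dropna()
        if len(sub) >= window * 0.9:
            c = sub["c"].to_numpy()
            for label in seasonal:
                v = sub[label].to_numpy()
                r, p = stats.pearsonr(c, v)
                rows.append({"window_start": w0, "window_end": w0 + window - 1,
                             "target": label, "r": float(r), "p": float(p),
                             "significant": bool(p < alpha)})
        w0 += step
    return MovingCorrelation(variable=variable, window=window, step=step,
                             table=pd.DataFrame(rows))


def index_corr(series: pd.Series, index_monthly: pd.DataFrame,
               months: list[int] | None = None) -> pd.DataFrame:
    """Pearson correlation of a year-indexed series (reconstruction or
    chronology) with each calendar month of a climate-mode index.

    ``index_monthly`` is a year x month (1..12 columns or JAN..DEC) table.
    """
    df = index_monthly.copy()
    if list(df.columns[:12]) != MONTH_ABBR:
        df.columns = MONTH_ABBR[:df.shape[1]]
    if months is None:
        months = list(range(1, 13))
    rows = []
    for m in months:
        col = df[MONTH_ABBR[m - 1]]
        joint = pd.concat([series.rename("s"), col.rename("i")], axis=1).dropna()
        if len(joint) < 30:
            raise ValueError(f"overlap too short for index correlation ({len(joint)} < 30)")
        r, p = stats.pearsonr(joint["s"], joint["i"])
        rows.append({"month": MONTH_ABBR[m - 1], "r": float(r), "p": float(p),
                     "significant": bool(p < 0.05), "n": len(joint)})
    return pd.DataFrame(rows).set_index("month")
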