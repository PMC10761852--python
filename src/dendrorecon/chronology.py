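"""Standard and residual chronology construction.

Each raw series is detrended by a modified negative exponential curve
``a*exp(-b*t) + k`` fitted over cambial age ``t`` (falling back to a
horizontal mean, or optionally a declining line, when the constrained fit
is unattainable), converted to a dimensionless ring-width index by
division, optionally prewhitened by an AIC-selected AR model, and the
per-year indices are averaged with Tukey's biweight robust mean.  Signal
strength is summarized by running Rbar and the expressed population
signal EPS = N*rbar / (N*rbar + 1 - rbar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tsa.ar_model import AutoReg

from .types import RingSeries, SiteCollection, pool

EPS_SENTINEL = np.nan


@dataclass
class DetrendedSeries:
    """Dimensionless ring-width index (expectation 1) for one core."""

    series_id: str
    first_year: int
    index: np.ndarray
    curve: str                      # "negexp" | "mean" | "line"
    params: dict = field(default_factory=dict)
    ar_order: int = 0               # 0 until prewhitened

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.index))

    def to_series(self) -> pd.Series:
        return pd.Series(self.index, index=self.years, name=self.series_id)


@dataclass
class Chronology:
    """Year-indexed standard/residual chronology with signal diagnostics."""

    years: np.ndarray
    standard: np.ndarray
    residual: np.ndarray | None
    sample_depth: np.ndarray
    rbar_windows: list = field(default_factory=list)  # (start, end, rbar, eps, n_eff)
    stats: dict = field(default_factory=dict)

    def series(self, kind: str = "standard") -> pd.Series:
        vals = {"standard": self.standard, "residual": self.residual}[kind]
        if vals is None:
            raise ValueError("no residual chronology was built")
        return pd.Series(vals, index=self.years, name=kind)

    def to_frame(self) -> pd.DataFrame:
        cols = {"std": self.standard, "depth": self.sample_depth}
        if self.residual is not None:
            cols["res"] = self.residual
        return pd.DataFrame(cols, index=pd.Index(self.years, name="year"))


# ---------------------------------------------------------------------------
# detrending

def _fit_negexp(widths: np.ndarray):
    """Constrained least squares of a*exp(-b*t)+k, a>0, b>0, k>=0."""
    n = len(widths)
    t = np.arange(1, n + 1, dtype=float)

    def model(t, a, b, k):
        return a * np.exp(-b * t) + k

    w0 = max(widths.mean(), 1e-6)
    p0 = [max(widths[: max(n // 10, 3)].mean() - widths[-max(n // 10, 3):].mean(), w0 * 0.1),
          5.0 / n, max(widths[-max(n // 10, 3):].mean(), 1e-6)]
    try:
        popt, _ = optimize.curve_fit(
            model, t, widths, p0=p0,
            bounds=([1e-12, 1e-12, 0.0], [np.inf, 10.0, np.inf]), maxfev=5000)
    except (RuntimeError, ValueError):
        return None
    a, b, k = popt
    fitted = model(t, a, b, k)
    # reject fits that are non-positive anywhere, have no real decline
    # (degenerate a ~ 0 or b ~ 0 on flat/rising growth), or rise
    if np.any(fitted <= 0) or b <= 1e-10:
        return None
    if fitted[0] - fitted[-1] <= 0.001 * widths.mean():
        return None
    return fitted, {"a": a, "b": b, "k": k}


def detrend_negexp(series: RingSeries, fallback: str = "mean") -> DetrendedSeries:
    """Detrend one series by ratio to a modified negative exponential.

    Falls back to the horizontal mean (default) or a declining linear fit
    when the constrained exponential is unattainable (e.g. rising growth),
    recording which curve was used.
    """
    w = series.widths
    if len(w) < 10:
        raise ValueError(f"series {series.series_id!r}: need >= 10 rings to detrend")
    if np.all(w == 0):
        raise ValueError(f"series {series.series_id!r}: all-zero series cannot be detrended")

    fit = _fit_negexp(w)
    if fit is not None:
        fitted, params = fit
        curve = "negexp"
    elif fallback == "line":
        t = np.arange(1, len(w) + 1, dtype=float)
        slope, icept = np.polyfit(t, w, 1)
        if slope >= 0:  # only a *declining* line is a valid age trend
            fitted, params, curve = np.full_like(w, w.mean()), {"mean": w.mean()}, "mean"
        else:
            fitted = slope * t + icept
            if np.any(fitted <= 0):
                fitted, params, curve = np.full_like(w, w.mean()), {"mean": w.mean()}, "mean"
            else:
                params, curve = {"slope": slope, "intercept": icept}, "line"
    else:
        fitted, params, curve = np.full_like(w, w.mean()), {"mean": w.mean()}, "mean"

    return DetrendedSeries(series_id=series.series_id, first_year=series.first_year,
                           index=w / fitted, curve=curve, params=params)


def prewhiten(d: DetrendedSeries, max_order: int = 3) -> DetrendedSeries:
    """Remove autoregressive persistence from a detrended index.

    Fits AR(p), p selected by AIC over 0..max_order, and returns the
    residuals re-centred to mean 1.  Degenerate (zero-variance) input is
    returned unchanged with p = 0.  The first p years are dropped.
    """
    x = d.index
    if len(x) < 3 * max_order:
        raise ValueError("series too short for prewhitening")
    if np.std(x) < 1e-12:
        return DetrendedSeries(d.series_id, d.first_year, x.copy(), d.curve, dict(d.params), 0)

    best_p, best_aic, best_resid = 0, np.inf, None
    for p in range(0, max_order + 1):
        try:
            res = AutoReg(x, lags=p).fit()
        except (ValueError, np.linalg.LinAlgError):
            continue
        aic = res.aic
        resid = res.resid if p else x - x.mean()
        if aic < best_aic:
            best_p, best_aic, best_resid = p, aic, resid
    out = best_resid + 1.0  # re-centre to mean ~1 (AR residuals have mean ~0)
    out = out - out.mean() + 1.0
    return DetrendedSeries(d.series_id, d.first_year + best_p, out, d.curve,
                           dict(d.params), best_p)


# ---------------------------------------------------------------------------
# robust averaging

def biweight_mean(values, c: float = 9.0, tol: float = 1e-8, max_iter: int = 200) -> float:
    """Tukey biweight robust location (c = 9, MAD scale, fixed point).

    With two or fewer values the arithmetic mean is returned (MAD is
    degenerate there).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values")
    if x.size <= 2:
        return float(x.mean())
    m = float(np.median(x))
    for _ in range(max_iter):
        s = float(np.median(np.abs(x - m)))
        if s < 1e-12:
            return m
        u = (x - m) / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - m) < tol:
            return new
        m = new
    return m


# ---------------------------------------------------------------------------
# signal strength

def eps_from_rbar(rbar: float, n: float) -> float:
    """Expressed population signal for mean inter-series correlation rbar
    and mean sample depth n; clipped to [0, 1]."""
    if n <= 0 or not np.isfinite(rbar):
        return EPS_SENTINEL
    denom = n * rbar + (1.0 - rbar)
    if denom <= 0:
        return 0.0
    return float(np.clip(n * rbar / denom, 0.0, 1.0))


def running_rbar_eps(frame: pd.DataFrame, window: int = 50, overlap: int = 25,
                     min_overlap: int = 30):
    """Running mean pairwise correlation and EPS over sliding windows.

    ``frame`` is a year-indexed wide table of detrended indices (NaN where
    a series is absent).  Windows advance by ``window - overlap`` years.
    Pairs contribute only where they share >= ``min_overlap`` common years
    in the window (capped at the window length).  Returns a list of
    ``(start_year, end_year, rbar, eps, mean_depth)`` tuples.
    """
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 series for running rbar")
    min_overlap = min(min_overlap, window)
    years = frame.index.to_numpy()
    step = max(window - overlap, 1)
    out = []
    start = int(years[0])
    while start + window - 1 <= int(years[-1]):
        end = start + window - 1
        sub = frame.loc[start:end]
        vals = sub.to_numpy()
        present = np.isfinite(vals)
        depth = present.sum(axis=1)
        rs = []
        ncol = vals.shape[1]
        for i in range(ncol):
            for j in range(i + 1, ncol):
                both = present[:, i] & present[:, j]
                if both.sum() >= min_overlap:
                    a, b = vals[both, i], vals[both, j]
                    if a.std() > 1e-12 and b.std() > 1e-12:
                        rs.append(np.corrcoef(a, b)[0, 1])
        mean_depth = float(depth[depth > 0].mean()) if np.any(depth > 0) else 0.0
        if rs:
            rbar = float(np.mean(rs))
            eps = eps_from_rbar(rbar, mean_depth)
        else:
            rbar, eps = EPS_SENTINEL, EPS_SENTINEL
        out.append((start, end, rbar, eps, mean_depth))
        start += step
    return out


def mean_sensitivity(x: np.ndarray) -> float:
    """Mean absolute relative first difference, a high-frequency variability
    measure: mean of |2 (x_{t+1} - x_t) / (x_{t+1} + x_t)|."""
    x = np.asarray(x, dtype=float)
    num = 2.0 * np.abs(np.diff(x))
    den = x[1:] + x[:-1]
    ok = den != 0
    return float(np.mean(num[ok] / den[ok]))


# ---------------------------------------------------------------------------
# chronology assembly

def build_chronology(collections: SiteCollection | list[SiteCollection],
                     prewhiten_series: bool = True, max_ar_order: int = 3,
                     fallback: str = "mean", rbar_window: int = 50,
                     rbar_overlap: int = 25, min_overlap: int = 30) -> Chronology:
    """Detrend, optionally prewhiten, and robust-average a set of series.

    Multiple collections are pooled (all series in one file) before
    averaging, so a regional composite is one chronology over the union of
    series rather than an average of site chronologies.
    """
    if isinstance(collections, SiteCollection):
        coll = collections
    else:
        if len(collections) == 0:
            raise ValueError("no collections given")
        coll = collections[0] if len(collections) == 1 else pool(list(collections))
    if len(coll) == 0:
        raise ValueError("empty collection")

    detrended = [detrend_negexp(s, fallback=fallback) for s in coll]
    std_frame = pd.DataFrame({d.series_id: d.to_series() for d in detrended}).sort_index()

    if prewhiten_series:
        resid = [prewhiten(d, max_order=max_ar_order) for d in detrended]
        res_frame = pd.DataFrame({d.series_id: d.to_series() for d in resid}).sort_index()
        res_frame = res_frame.reindex(std_frame.index)
    else:
        res_frame = None

    years = std_frame.index.to_numpy(dtype=int)
    std_vals = std_frame.to_numpy()
    depth = np.isfinite(std_vals).sum(axis=1)
    standard = np.array([biweight_mean(row[np.isfinite(row)]) for row in std_vals])
    if res_frame is not None:
        residual = np.full(len(years), np.nan)
        rv = res_frame.to_numpy()
        for i in range(len(years)):
            row = rv[i][np.isfinite(rv[i])]
            if row.size:
                residual[i] = biweight_mean(row)
    else:
        residual = None

    rbar_windows = (running_rbar_eps(std_frame, rbar_window, rbar_overlap, min_overlap)
                    if std_frame.shape[1] >= 2 else [])

    stats = {
        "n_series": std_frame.shape[1],
        "mean_sensitivity": mean_sensitivity(standard),
        "sd": float(np.std(standard, ddof=1)) if len(standard) > 1 else 0.0,
        "ac1": float(np.corrcoef(standard[:-1], standard[1:])[0, 1]) if len(standard) > 2 else np.nan,
    }
    return Chronology(years=years, standard=standard, residual=residual,
                      sample_depth=depth, rbar_windows=rbar_windows, stats=stats)


def truncate_by_eps(ch: Chronology, threshold: float = 0.85) -> int:
    """First reliable year: earliest year from which every subsequent
    running-EPS window stays at or above ``threshold``.

    Window EPS values are held constant across each window's years; the
    "all subsequent windows" rule avoids flickering around the threshold.
    """
    windows = [w for w in ch.rbar_windows if np.isfinite(w[3])]
    if not windows:
        raise ValueError("no running EPS available (need >= 2 series)")
    if not any(w[3] >= threshold for w in windows):
        raise ValueError(
            f"EPS never reaches {threshold} (max attained {max(w[3] for w in windows):.3f})")
    # walk windows from the end; find the earliest suffix all >= threshold
    first_ok = None
    for start, end, rbar, eps, n in reversed(windows):
        if eps >= threshold:
            first_ok = start
        else:
            break
    if first_ok is None:
        raise ValueError(
            f"EPS below {threshold} in the most recent window "
            f"(max attained {max(w[3] for w in windows):.3f})")
    return max(int(first_ok), int(ch.years[0]))


def pca_sites(chronologies: list[Chronology], kind: str = "standard"):
    """PCA on the correlation matrix of >= 2 site chronologies over their
    common span.  Returns (variance_fractions, loadings, common_years)."""
    if len(chronologies) < 2:
        raise ValueError("need >= 2 chronologies")
    frames = [c.series(kind) for c in chronologies]
    df = pd.concat(frames, axis=1, join="inner")
    df = df.dropna()
    if df.shape[0] < 30:
        raise ValueError(f"common span too short for PCA ({df.shape[0]} < 30 yr)")
    corr = np.corrcoef(df.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    fractions = evals / evals.sum()
    return fractions, evecs, df.index.to_numpy()
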