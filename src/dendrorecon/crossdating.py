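"""Cross-dating quality checks: Gleichlaeufigkeit and COFECHA-style
segment correlations against a leave-one-out master chronology.

Sign convention: a *positive* best lag means the tested series matches the
master better when shifted towards the past, i.e. the series was dated too
old; a series dated one year too young reports best lag -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chronology import biweight_mean, detrend_negexp, prewhiten
from .types import RingSeries, SiteCollection


@dataclass
class SegmentResult:
    start: int
    end: int
    r: float
    best_lag: int
    best_r: float
    flagged: bool


@dataclass
class CrossdateReport:
    series_id: str
    overall_r: float
    glk: float
    critical_r: float
    segments: list[SegmentResult] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return sum(s.flagged for s in self.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"series": self.series_id, "segment_start": s.start, "segment_end": s.end,
              "r": s.r, "best_lag": s.best_lag, "flag": s.flagged} for s in self.segments])


def glk(a: pd.Series, b: pd.Series) -> float:
    """Gleichlaeufigkeit: proportion of overlapping year-to-year changes
    with agreeing sign; a zero change on either side counts one half.

    Symmetric and invariant to adding a constant to either series.
    """
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError(f"overlap too short for GLK ({len(common)} < 2 yr)")
    # restrict to a contiguous run of common years for first differences
    av = a.loc[common].to_numpy(dtype=float)
    bv = b.loc[common].to_numpy(dtype=float)
    da, db = np.sign(np.diff(av)), np.sign(np.diff(bv))
    agree = np.where(da == db, 1.0, 0.0)
    agree[(da == 0) | (db == 0)] = 0.5  # no-change years count one half
    return float(agree.mean())


def tvalue_from_r(r: float, n: int) -> float:
    """Student t for a correlation r at sample size n (auxiliary diagnostic)."""
    r = min(max(r, -0.999999), 0.999999)
    return r * np.sqrt((n - 2) / (1.0 - r * r))


def critical_r(alpha: float, n: int) -> float:
    """One-tailed critical correlation at level alpha for n pairs."""
    t = stats.t.ppf(1.0 - alpha, df=n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def _standardized_residual_index(series: RingSeries, max_ar_order: int = 3) -> pd.Series:
    """Detrended, prewhitened, z-scored index used for dating checks."""
    d = prewhiten(detrend_negexp(series), max_order=max_ar_order)
    s = d.to_series()
    sd = s.std()
    if sd < 1e-12:
        return s * 0.0
    return (s - s.mean()) / sd


def segment_check(series: RingSeries, collection: SiteCollection,
                  seg_len: int = 50, seg_lag: int = 25, max_lag: int = 10,
                  alpha: float = 0.01, max_ar_order: int = 3,
                  index_cache: dict | None = None) -> CrossdateReport:
    """COFECHA-style dating check of one series against the rest.

    The master is the per-year biweight mean of the *other* series'
    standardized residual indices.  Each ``seg_len``-year segment
    (advancing by ``seg_lag``) is correlated with the master at lags
    ``-max_lag..max_lag``; a segment is flagged when its lag-0 r falls
    below the one-tailed critical r, or a nonzero lag correlates better.
    """
    if series.series_id not in collection.ids():
        raise ValueError(f"series {series.series_id!r} not in collection {collection.site_id!r}")
    others = [s for s in collection if s.series_id != series.series_id]
    if not others:
        raise ValueError("collection holds no other series to build a master from")

    if index_cache is None:
        index_cache = {}

    def idx(s: RingSeries) -> pd.Series:
        if s.series_id not in index_cache:
            index_cache[s.series_id] = _standardized_residual_index(s, max_ar_order)
        return index_cache[s.series_id]

    target = idx(series)
    frame = pd.DataFrame({s.series_id: idx(s) for s in others}).sort_index()
    master = pd.Series(
        [biweight_mean(row[np.isfinite(row)]) if np.any(np.isfinite(row)) else np.nan
         for row in frame.to_numpy()], index=frame.index, name="master")

    joint = pd.concat([target.rename("x"), master], axis=1).dropna()
    if len(joint) < seg_len:
        raise ValueError(f"overlap with master ({len(joint)}) shorter than segment length {seg_len}")
    years = joint.index.to_numpy()
    x = joint["x"].to_numpy()
    m = joint["master"].to_numpy()

    overall_r = float(np.corrcoef(x, m)[0, 1])
    g = glk(target, master)
    crit = critical_r(alpha, seg_len)

    segments = []
    start = 0
    while start + seg_len <= len(x):
        sl = slice(start, start + seg_len)
        seg_years = years[sl]
        xi = x[sl]
        r0 = np.nan
        best_lag, best_r = 0, -np.inf
        for lag in range(-max_lag, max_lag + 1):
            # positive lag: compare the segment against master shifted later,
            # i.e. the series is older than dated
            m_shift = pd.Series(m, index=years).reindex(seg_years + lag).to_numpy()
            ok = np.isfinite(m_shift)
            if ok.sum() < max(seg_len // 2, 10):
                continue
            r = float(np.corrcoef(xi[ok], m_shift[ok])[0, 1])
            if lag == 0:
                r0 = r
            if r > best_r:
                best_r, best_lag = r, lag
        flagged = (not np.isfinite(r0)) or (r0 < crit) or (best_lag != 0)
        segments.append(SegmentResult(int(seg_years[0]), int(seg_years[-1]),
                                      float(r0), int(best_lag), float(best_r), bool(flagged)))
        start += seg_lag

    return CrossdateReport(series_id=series.series_id, overall_r=overall_r,
                           glk=g, critical_r=crit, segments=segments)


def crossdate_collection(collection: SiteCollection, **kwargs) -> list[CrossdateReport]:
    """Run ``segment_check`` for every series in the collection, sharing the
    detrended/prewhitened index computations across checks."""
    cache: dict = {}
    return [segment_check(s, collection, index_cache=cache, **kwargs)
            for s in collection]
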