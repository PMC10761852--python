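"""Linear transfer-function reconstruction and its validation.

Calibration fits ordinary least squares of the seasonal climate target on
the chronology index; skill is assessed with leave-one-out
cross-validation and split-sample calibration/verification using the
standard dendroclimatic battery: r, R^2, adjusted R^2, RMSE, F, the
Durbin-Watson statistic, a first-difference sign test, the product-mean
test, the reduction of error RE (calibration-mean null) and the
coefficient of efficiency CE (verification-mean null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw


@dataclass
class TransferModel:
    slope: float          # mm per index unit
    intercept: float      # mm
    cal_years: np.ndarray
    stats: dict = field(default_factory=dict)  # r, R2, R2adj, RMSE, F, p, DW

    def predict(self, index: np.ndarray | pd.Series):
        return self.slope * index + self.intercept


@dataclass
class ValidationStats:
    r: float
    R2: float
    R2adj: float | None
    RMSE: float
    RE: float
    CE: float | None
    sign_agree: int
    sign_disagree: int
    sign_p: float
    pmt_t: float
    pmt_degenerate: bool
    PRESS: float | None = None
    F: float | None = None
    p: float | None = None
    DW: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class Reconstruction:
    years: np.ndarray
    values: np.ndarray        # mm
    rmse: float               # half-width of the uncertainty band
    model: TransferModel
    negative_years: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def lower(self) -> np.ndarray:
        return self.values - self.rmse

    @property
    def upper(self) -> np.ndarray:
        return self.values + self.rmse

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name="reconstruction")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value_mm": self.values, "lower": self.lower,
                             "upper": self.upper},
                            index=pd.Index(self.years, name="year"))


def _align(ch: pd.Series, target: pd.Series, span: tuple[int, int] | None):
    joint = pd.concat([ch.rename("x"), target.rename("y")], axis=1).dropna()
    if span is not None:
        joint = joint.loc[span[0]:span[1]]
    return joint


def durbin_watson(residuals: np.ndarray) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("need >= 3 residuals")
    if np.sum(e ** 2) == 0:
        raise ValueError("zero residual variance")
    return float(_sm_dw(e))


def fit_transfer(ch: pd.Series, target: pd.Series,
                 span: tuple[int, int] | None = None,
                 min_overlap: int = 25) -> TransferModel:
    """OLS calibration of the seasonal target on the chronology index."""
    joint = _align(ch, target, span)
    if len(joint) < min_overlap:
        raise ValueError(f"calibration overlap too short ({len(joint)} < {min_overlap} yr)")
    x = joint["x"].to_numpy()
    y = joint["y"].to_numpy()
    if x.std() < 1e-12:
        raise ValueError("zero-variance predictor")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    icept, slope = res.params
    r = float(np.corrcoef(x, y)[0, 1])
    st = {
        "r": r,
        "R2": float(res.rsquared),
        "R2adj": float(res.rsquared_adj),
        "RMSE": float(np.sqrt(np.mean(res.resid ** 2))),
        "F": float(res.fvalue),
        "p": float(res.f_pvalue),
        "DW": durbin_watson(res.resid) if res.resid.std() > 0 else np.nan,
        "n": len(joint),
    }
    return TransferModel(slope=float(slope), intercept=float(icept),
                         cal_years=joint.index.to_numpy(), stats=st)


def sign_test(obs, pred) -> tuple[int, int, float]:
    """First-difference sign test: counts of agreeing/disagreeing
    year-to-year changes and a two-tailed binomial p (P(agree) = 1/2).
    Pairs where either difference is exactly zero are dropped."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(obs) < 3 or len(obs) != len(pred):
        raise ValueError("need paired series of length >= 3")
    do, dp = np.sign(np.diff(obs)), np.sign(np.diff(pred))
    keep = (do != 0) & (dp != 0)
    agree = int(np.sum(do[keep] == dp[keep]))
    disagree = int(np.sum(keep) - agree)
    n = agree + disagree
    p = float(stats.binomtest(agree, n, 0.5).pvalue) if n else 1.0
    return agree, disagree, p


def product_mean_test(obs, pred, cal_mean: float) -> tuple[float, bool]:
    """Product-mean test (Fritts): t on the separation between positive
    products and absolute negative products of departures from the
    calibration mean.

    Returns (t, degenerate); ``degenerate`` is True with t = +inf when all
    products share one sign (perfect association leaves nothing to test).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(obs) < 5:
        raise ValueError("need >= 5 pairs for the product-mean test")
    z = (obs - cal_mean) * (pred - cal_mean)
    pos = z[z > 0]
    neg = np.abs(z[z < 0])
    if len(pos) == 0 or len(neg) == 0:
        return np.inf, True
    m1, m2 = pos.mean(), neg.mean()
    s1 = pos.std(ddof=1) if len(pos) > 1 else 0.0
    s2 = neg.std(ddof=1) if len(neg) > 1 else 0.0
    denom = np.sqrt(s1 ** 2 / len(pos) + s2 ** 2 / len(neg))
    if denom == 0:
        return np.inf, True
    return float((m1 - m2) / denom), False


def reduction_of_error(obs, pred, cal_mean: float) -> float:
    """RE = 1 - SSE(pred) / SSE(calibration-mean null)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    denom = np.sum((obs - cal_mean) ** 2)
    if denom == 0:
        raise ValueError("observations constant at the calibration mean")
    return float(1.0 - np.sum((obs - pred) ** 2) / denom)


def coefficient_of_efficiency(obs, pred) -> float:
    """CE = 1 - SSE(pred) / SSE(verification-mean null)."""
    obs = np.asarray(obs, dtype=float)
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise ValueError("constant verification observations")
    return float(1.0 - np.sum((obs - np.asarray(pred, dtype=float)) ** 2) / denom)


def loocv(ch: pd.Series, target: pd.Series,
          span: tuple[int, int] | None = None) -> ValidationStats:
    """Leave-one-out cross-validation of the transfer model.

    Each year is predicted by a model fitted without it; RE uses the
    all-years calibration mean as the null predictor and PRESS is the sum
    of squared LOOCV residuals (mm^2).
    """
    joint = _align(ch, target, span)
    if len(joint) < 25:
        raise ValueError(f"calibration overlap too short ({len(joint)} < 25 yr)")
    x = joint["x"].to_numpy()
    y = joint["y"].to_numpy()
    n = len(x)
    pred = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        slope, icept = np.polyfit(x[mask], y[mask], 1)
        pred[i] = slope * x[i] + icept
    cal_mean = float(y.mean())
    resid = y - pred
    r = float(np.corrcoef(y, pred)[0, 1]) if pred.std() > 0 else np.nan
    agree, disagree, sp = sign_test(y, pred)
    pmt, degen = product_mean_test(y, pred, cal_mean)
    return ValidationStats(
        r=r, R2=float(r ** 2) if np.isfinite(r) else np.nan, R2adj=None,
        RMSE=float(np.sqrt(np.mean(resid ** 2))),
        RE=reduction_of_error(y, pred, cal_mean), CE=None,
        sign_agree=agree, sign_disagree=disagree, sign_p=sp,
        pmt_t=pmt, pmt_degenerate=degen,
        PRESS=float(np.sum(resid ** 2)),
        DW=durbin_watson(resid) if resid.std() > 0 else np.nan)


def _verify(x_cal, y_cal, x_ver, y_ver) -> ValidationStats:
    slope, icept = np.polyfit(x_cal, y_cal, 1)
    pred = slope * x_ver + icept
    cal_mean = float(y_cal.mean())
    r = float(np.corrcoef(y_ver, pred)[0, 1]) if pred.std() > 0 else np.nan
    agree, disagree, sp = sign_test(y_ver, pred)
    pmt, degen = product_mean_test(y_ver, pred, cal_mean)
    return ValidationStats(
        r=r, R2=float(r ** 2) if np.isfinite(r) else np.nan, R2adj=None,
        RMSE=float(np.sqrt(np.mean((y_ver - pred) ** 2))),
        RE=reduction_of_error(y_ver, pred, cal_mean),
        CE=coefficient_of_efficiency(y_ver, pred),
        sign_agree=agree, sign_disagree=disagree, sign_p=sp,
        pmt_t=pmt, pmt_degenerate=degen)


def split_sample(ch: pd.Series, target: pd.Series, split_year: int | None = None,
                 span: tuple[int, int] | None = None, min_half: int = 12) -> dict:
    """Split-sample calibration/verification in both directions.

    Returns {"early_cal": {...}, "late_cal": {...}} where each block holds
    the calibration fit on one half and the ValidationStats on the other.
    """
    joint = _align(ch, target, span)
    years = joint.index.to_numpy()
    if split_year is None:
        split_year = int(years[len(years) // 2 - 1])  # median calibration year
    first = joint.loc[:split_year]
    second = joint.loc[split_year + 1:]
    if len(first) < min_half or len(second) < min_half:
        raise ValueError(
            f"split halves too short ({len(first)}/{len(second)}, need >= {min_half} each)")

    out = {}
    for name, (cal, ver) in (("early_cal", (first, second)),
                             ("late_cal", (second, first))):
        model = fit_transfer(cal["x"], cal["y"], min_overlap=min_half)
        v = _verify(cal["x"].to_numpy(), cal["y"].to_numpy(),
                    ver["x"].to_numpy(), ver["y"].to_numpy())
        out[name] = {
            "calibration": {"span": (int(cal.index[0]), int(cal.index[-1])), **model.stats},
            "verification": {"span": (int(ver.index[0]), int(ver.index[-1])),
                             **v.to_dict()},
        }
    return out


def reconstruct(model: TransferModel, ch: pd.Series, truncation_year: int) -> Reconstruction:
    """Apply the calibrated transfer function back in time from
    ``truncation_year``; the uncertainty band is +/- calibration RMSE.
    Negative predictions are kept but flagged (linear extrapolation can
    undershoot zero precipitation)."""
    ch = ch.dropna()
    if truncation_year < ch.index.min() or truncation_year > ch.index.max():
        raise ValueError(f"truncation year {truncation_year} outside chronology span "
                         f"({ch.index.min()}-{ch.index.max()})")
    sub = ch.loc[truncation_year:]
    values = model.predict(sub.to_numpy())
    years = sub.index.to_numpy(dtype=int)
    neg = years[values < 0]
    return Reconstruction(years=years, values=values,
                          rmse=float(model.stats.get("RMSE", np.nan)),
                          model=model, negative_years=neg)
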