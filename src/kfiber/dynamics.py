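"""Time-series statistics of k-fiber lengths.

Covers minute binning of raw length samples, time-averaged length and
coefficient of variation per fiber, sister-pair sum conservation, and the
length autocorrelation

    rho(h) = sum_{i=1}^{n-h} (x_i - xbar)(x_{i+h} - xbar)
             / sum_{i=1}^{n} (x_i - xbar)^2

with a per-lag two-sample comparison between conditions.  By this
estimator rho(0) = 1 and |rho(h)| <= 1 for every lag (Cauchy–Schwarz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fiberlength import welch_ttest

__all__ = [
    "LengthSeries",
    "SisterPairSeries",
    "bin_by_minute",
    "series_stats",
    "sister_sum_stats",
    "autocorrelation",
    "autocorr_group_test",
]


@dataclass
class LengthSeries:
    """One fiber's length vs time (minutes, µm)."""

    fiber_id: str
    cell_id: str
    condition: str
    times: np.ndarray
    lengths: np.ndarray
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.shape != self.lengths.shape:
            raise ValueError("times and lengths must have the same shape")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        finite = self.lengths[np.isfinite(self.lengths)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("lengths must be positive")


@dataclass
class SisterPairSeries:
    """Two sister fibers on a common time grid, plus their length sum."""

    a: LengthSeries
    b: LengthSeries

    def common(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, lengths_a, lengths_b) restricted to shared time points."""
        ta = np.round(self.a.times, 9)
        tb = np.round(self.b.times, 9)
        common, ia, ib = np.intersect1d(ta, tb, return_indices=True)
        return common, self.a.lengths[ia], self.b.lengths[ib]

    @property
    def sum_series(self) -> tuple[np.ndarray, np.ndarray]:
        t, xa, xb = self.common()
        return t, xa + xb


def bin_by_minute(series: LengthSeries) -> LengthSeries:
    """Average samples into integer-minute bins (bin b: floor(t) == b).

    Empty bins are left missing rather than interpolated.
    """
    if len(series.times) == 0:
        raise ValueError("empty series")
    bins = np.floor(series.times).astype(int)
    df = pd.DataFrame({"bin": bins, "x": series.lengths}).groupby("bin")["x"].mean()
    return LengthSeries(
        fiber_id=series.fiber_id,
        cell_id=series.cell_id,
        condition=series.condition,
        times=df.index.to_numpy(dtype=float),
        lengths=df.to_numpy(),
        events=dict(series.events),
    )


def series_stats(series: LengthSeries | np.ndarray) -> dict:
    """Time-mean, sample SD (ddof=1) and CV = 100·sd/mean of one series."""
    x = series.lengths if isinstance(series, LengthSeries) else np.asarray(series, float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    mean = float(np.mean(x))
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero-mean series")
    sd = float(np.std(x, ddof=1))
    return {"time_mean": mean, "sd": sd, "cv": 100.0 * sd / mean}


def sister_sum_stats(pair: SisterPairSeries, min_overlap: int = 5) -> dict:
    """Statistics of the summed sister lengths.

    Pairs overlapping on fewer than ``min_overlap`` frames are rejected
    (fibers were only measured when visible across at least 5 frames).
    """
    t, xa, xb = pair.common()
    if len(t) < min_overlap:
        warnings.warn(
            f"pair ({pair.a.fiber_id}, {pair.b.fiber_id}): only {len(t)} "
            f"overlapping frames (<{min_overlap}); excluded"
        )
        raise ValueError("insufficient sister overlap")
    s = xa + xb
    out = {f"sum_{k}": v for k, v in series_stats(s).items()}
    out["cv_a"] = series_stats(xa)["cv"]
    out["cv_b"] = series_stats(xb)["cv"]
    out["n_frames"] = int(len(t))
    return out


def autocorrelation(series: LengthSeries | np.ndarray, max_lag: int) -> np.ndarray:
    """Length autocorrelation rho(h) for h = 0..max_lag.

    The mean is the full-series mean and the denominator runs over all n
    deviations, so rho(0) = 1 exactly.  Missing values (NaN) are dropped
    pairwise from the numerator and from the mean/denominator.
    """
    x = series.lengths if isinstance(series, LengthSeries) else np.asarray(series, float)
    ok = np.isfinite(x)
    n = len(x)
    if ok.sum() < max_lag + 2:
        raise ValueError("series too short for requested max_lag")
    xbar = np.mean(x[ok])
    d = np.where(ok, x - xbar, 0.0)
    denom = float(np.sum(d[ok] ** 2))
    if denom == 0:
        raise ZeroDivisionError("autocorrelation undefined for constant series")
    rho = np.empty(max_lag + 1)
    for h in range(max_lag + 1):
        both = ok[: n - h] & ok[h:]
        rho[h] = np.sum(d[: n - h][both] * d[h:][both]) / denom
    return rho


def ensemble_autocorrelation(series_list: list[LengthSeries], max_lag: int) -> np.ndarray:
    """Ensemble autocorrelation over many fibers on a shared grid.

    Averages lagged products across fibers around the grand mean of all
    samples, normalizing each lag by its number of terms.  Unlike the
    per-fiber estimator (whose subtracted per-series mean and full-n
    denominator bias short series downward), this converges to the
    process autocorrelation as the ensemble grows, so it is the right
    quantity to compare against a closed form like the
    Ornstein–Uhlenbeck exp(−h·dt/tau).
    """
    xs = [np.asarray(s.lengths, float) for s in series_list]
    grand = np.mean(np.concatenate(xs))
    num = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1)
    for x in xs:
        d = x - grand
        for h in range(max_lag + 1):
            num[h] += float(np.sum(d[: len(d) - h] * d[h:]))
            cnt[h] += max(len(d) - h, 0)
    if cnt[0] == 0 or num[0] == 0:
        raise ZeroDivisionError("ensemble autocorrelation undefined")
    return (num / cnt) / (num[0] / cnt[0])


def autocorr_group_test(acf_by_condition: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-lag group means ± SD and Welch p between two conditions.

    ``acf_by_condition`` maps a condition label to an array of shape
    (n_fibers, n_lags); fibers too short for a lag may hold NaN there.
    No multiplicity correction is applied (per-lag asterisks).
    """
    conds = sorted(acf_by_condition)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    a = np.asarray(acf_by_condition[conds[0]], dtype=float)
    b = np.asarray(acf_by_condition[conds[1]], dtype=float)
    n_lags = min(a.shape[1], b.shape[1])
    rows = []
    for h in range(n_lags):
        xa, xb = a[:, h], b[:, h]
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        row = {
            "lag": h,
            f"mean_{conds[0]}": np.mean(xa) if len(xa) else np.nan,
            f"sd_{conds[0]}": np.std(xa, ddof=1) if len(xa) > 1 else np.nan,
            f"mean_{conds[1]}": np.mean(xb) if len(xb) else np.nan,
            f"sd_{conds[1]}": np.std(xb, ddof=1) if len(xb) > 1 else np.nan,
        }
        if len(xa) >= 2 and len(xb) >= 2 and (np.ptp(xa) > 0 or np.ptp(xb) > 0):
            row["p"] = welch_ttest(xa, xb)["p"]
        else:
            row["p"] = np.nan  # lag with a single fiber (or degenerate): skipped
        rows.append(row)
    return pd.DataFrame(rows)
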