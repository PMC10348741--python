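"""Regrowth analysis after acute k-fiber shortening.

Applies to laser ablation (cut at t = 0) and to drug-washout reassembly
(washout at t = 0).  Lengths are binned by minute per fiber, averaged
across fibers, regressed over the first five minutes for the initial
growth rate, and normalized against unablated neighbours for the
fraction of length recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import LengthSeries, bin_by_minute
from .fiberlength import welch_ttest

__all__ = [
    "RegrowthDataset",
    "group_bin_average",
    "initial_growth_rate",
    "fraction_recovered",
    "window_means",
]


@dataclass
class RegrowthDataset:
    """Ablated and unablated length series sharing t = 0 at the event."""

    ablated: list[LengthSeries]
    unablated: list[LengthSeries]
    condition: str = ""


def _binned_frame(series_list: list[LengthSeries]) -> pd.DataFrame:
    """Rows = fibers, columns = integer-minute bins."""
    cols = {}
    for s in series_list:
        b = bin_by_minute(s)
        cols[s.fiber_id] = pd.Series(b.lengths, index=b.times.astype(int))
    return pd.DataFrame(cols).T


def group_bin_average(dataset: RegrowthDataset) -> pd.DataFrame:
    """Per-minute across-fiber mean ± SD for each group.

    Bins with no data in any fiber of a group stay missing.
    """
    frames = {}
    for name, group in [("ablated", dataset.ablated), ("unablated", dataset.unablated)]:
        if not group:
            continue
        bf = _binned_frame(group)
        frames[f"{name}_mean"] = bf.mean(axis=0)
        frames[f"{name}_sd"] = bf.std(axis=0, ddof=1)
        frames[f"{name}_n"] = bf.notna().sum(axis=0)
    out = pd.DataFrame(frames)
    out.index.name = "minute"
    return out.sort_index()


def initial_growth_rate(
    dataset: RegrowthDataset,
    *,
    window_min: tuple[int, int] = (0, 5),
    require_bins: tuple[int, int] = (0, 6),
) -> dict:
    """OLS regrowth rate (µm/min) per ablated fiber, plus the group mean.

    A fiber is eligible only if it has data in every minute bin of
    ``require_bins`` (0–6 min); the slope is fit on bins 0–5 min
    inclusive.  Excluded fibers are reported with a reason.
    """
    rates, excluded = {}, {}
    need = np.arange(require_bins[0], require_bins[1] + 1)
    fit_bins = np.arange(window_min[0], window_min[1] + 1)
    for s in dataset.ablated:
        b = bin_by_minute(s)
        have = set(b.times.astype(int))
        if not set(need) <= have:
            excluded[s.fiber_id] = f"missing bins {sorted(set(need) - have)} in 0-6 min"
            continue
        sel = np.isin(b.times.astype(int), fit_bins)
        if sel.sum() < 3:
            excluded[s.fiber_id] = "fewer than 3 bins in the regression window"
            continue
        fit = sps.linregress(b.times[sel], b.lengths[sel])
        rates[s.fiber_id] = float(fit.slope)
    vals = np.array(list(rates.values()))
    return {
        "per_fiber": rates,
        "excluded": excluded,
        "mean": float(np.mean(vals)) if len(vals) else np.nan,
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
        "n": int(len(vals)),
    }


def fraction_recovered(dataset: RegrowthDataset) -> pd.DataFrame:
    """Per-minute fraction of length recovered vs unablated neighbours.

    The reference is the time-average of the unablated group-mean trace;
    fraction(t) = ablated bin mean / reference.  A per-bin Welch test
    compares ablated vs unablated fiber-level bin values (uncorrected,
    per-time asterisks).
    """
    if not dataset.unablated:
        raise ValueError("unablated reference group is empty")
    abl = _binned_frame(dataset.ablated)
    unabl = _binned_frame(dataset.unablated)
    reference = float(unabl.mean(axis=0).mean())
    rows = []
    for minute in sorted(abl.columns):
        a = abl[minute].dropna().to_numpy()
        u = unabl[minute].dropna().to_numpy() if minute in unabl.columns else np.array([])
        row = {"minute": int(minute), "fraction": float(np.mean(a)) / reference if len(a) else np.nan}
        if len(a) >= 2 and len(u) >= 2 and (np.ptp(a) > 0 or np.ptp(u) > 0):
            row["p"] = welch_ttest(a, u)["p"]
        else:
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def window_means(
    series_list: list[LengthSeries],
    *,
    before_max_min: float = -10.0,
    after_min_min: float = 10.0,
) -> dict:
    """Per-fiber time-averaged lengths before (t ≤ −10 min) and after
    (t ≥ 10 min) a washout at t = 0, with a Welch comparison.

    Used for drug-washout recovery: 'before' is the pre-treatment
    steady state, 'after' the reassembled steady state.
    """
    before, after = [], []
    for s in series_list:
        pre = s.lengths[s.times <= before_max_min]
        post = s.lengths[s.times >= after_min_min]
        if len(pre):
            before.append(float(np.mean(pre)))
        if len(post):
            after.append(float(np.mean(post)))
    out = {
        "before_mean": float(np.mean(before)) if before else np.nan,
        "before_sd": float(np.std(before, ddof=1)) if len(before) > 1 else np.nan,
        "before_n": len(before),
        "after_mean": float(np.mean(after)) if after else np.nan,
        "after_sd": float(np.std(after, ddof=1)) if len(after) > 1 else np.nan,
        "after_n": len(after),
    }
    if len(before) >= 2 and len(after) >= 2:
        out["test"] = welch_ttest(before, after)
    return out
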