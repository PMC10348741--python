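"""Anaphase metrics: chromatid separation velocity and chromosome-mass
partitioning among daughter 'cells'.

Separation is tracked as the distance between sister chromatids (between
the plus-ends of their attached k-fibers) from anaphase onset; the
velocity is the OLS slope fit to the across-pair averaged trace.  Mass
partitioning sums DNA intensity of a summed z-projection inside each
drawn cell outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.draw import polygon2mask

__all__ = [
    "SeparationSeries",
    "separation_velocity",
    "mass_fractions",
    "sum_projection",
]


@dataclass
class SeparationSeries:
    """Sister–sister distance vs time from anaphase onset for one pair."""

    pair_id: str
    times_min: np.ndarray
    distances_um: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        if self.times_min.shape != self.distances_um.shape:
            raise ValueError("times and distances must match")


def separation_velocity(series_list: list[SeparationSeries]) -> dict:
    """Across-pair average separation trace and its fitted velocity.

    Pairs are aligned on their common onset time axis; per-time mean and
    SD are taken across pairs, and the velocity is the OLS slope of the
    averaged trace (the line of best fit to the condition average).
    """
    if not series_list:
        raise ValueError("no separation series")
    cols = {s.pair_id: pd.Series(s.distances_um, index=np.round(s.times_min, 9))
            for s in series_list}
    table = pd.DataFrame(cols)
    mean_trace = table.mean(axis=1)
    if len(mean_trace) < 2:
        raise ValueError("need at least 2 time points")
    fit = sps.linregress(mean_trace.index.to_numpy(), mean_trace.to_numpy())
    return {
        "times_min": mean_trace.index.to_numpy(),
        "mean_um": mean_trace.to_numpy(),
        "sd_um": table.std(axis=1, ddof=1).to_numpy(),
        "velocity_um_min": float(fit.slope),
        "intercept_um": float(fit.intercept),
        "n_pairs": int(table.shape[1]),
    }


def sum_projection(stack: np.ndarray) -> np.ndarray:
    """Summed-intensity z-projection of a (z, y, x) stack."""
    arr = np.asarray(stack, dtype=float)
    return arr.sum(axis=0) if arr.ndim == 3 else arr


def mass_fractions(
    image: np.ndarray,
    outlines: list[np.ndarray],
    *,
    background: float = 0.0,
    overlap_tolerance_px: int = 0,
) -> dict:
    """Fraction of chromosome mass inside each daughter-'cell' outline.

    ``image`` is a summed-intensity projection (or a stack, projected
    here); each outline is an (n, 2) polygon in (x, y) pixel
    coordinates.  Fractions are summed DNA intensity per outline over
    the total across outlines, so they sum to 1.  Overlapping outlines
    are an error naming the offending pair.  No background subtraction
    by default; pass ``background`` to subtract a constant first.
    """
    img = sum_projection(image)
    if np.any(img < 0):
        raise ValueError("intensities must be non-negative")
    if background:
        img = np.clip(img - background, 0.0, None)
    masks = []
    for k, poly in enumerate(outlines):
        poly = np.asarray(poly, dtype=float)
        masks.append(polygon2mask(img.shape, poly[:, ::-1]))  # (row, col)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if int(np.sum(masks[i] & masks[j])) > overlap_tolerance_px:
                raise ValueError(f"outlines {i} and {j} overlap")
    sums = np.array([float(img[m].sum()) for m in masks])
    total = sums.sum()
    if total == 0:
        raise ValueError("total intensity inside outlines is zero")
    return {
        "fractions": sums / total,
        "sums": sums,
        "count": int(len(outlines)),
    }
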