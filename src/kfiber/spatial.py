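"""Spatial coordination of k-fiber lengths within the spindle.

The metaphase-plate axis is the best-fit line through kinetochore
positions (k-fiber plus-ends); the long spindle axis is its
perpendicular through the mean plus-end position.  Fibers are binned
"inner" (≤ 2 µm from the long axis) or "outer" (≥ 3 µm), and each gets
a signed alignment score: the plus-end's distance to the plate, positive
when both fiber ends sit on the same side of the plate (under-aligned),
negative when the fiber crosses it (over-aligned).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .fiberlength import welch_ttest

__all__ = [
    "SpindleAxes",
    "fit_spindle_axes",
    "classify_inner_outer",
    "alignment_score",
    "correlate_length_position",
    "interkinetochore_distances",
]


@dataclass
class SpindleAxes:
    """Plate axis and long axis, each a (point, unit direction) pair."""

    centroid: np.ndarray  # (2,) µm
    plate_dir: np.ndarray  # unit vector along the metaphase plate
    long_dir: np.ndarray  # unit vector along the long (pole-to-pole) axis

    def dist_to_long_axis(self, p) -> float:
        """Perpendicular distance (µm) from a point to the long axis."""
        v = np.asarray(p, float) - self.centroid
        return abs(float(v @ self.plate_dir))

    def signed_dist_to_plate(self, p) -> float:
        """Signed distance (µm) from a point to the plate axis."""
        v = np.asarray(p, float) - self.centroid
        return float(v @ self.long_dir)


def _canonical(v: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero component positive."""
    v = v / np.linalg.norm(v)
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    return -v if len(nz) and v[nz[0]] < 0 else v


def fit_spindle_axes(plus_end_positions: np.ndarray, *, method: str = "orthogonal") -> SpindleAxes:
    """Fit spindle axes from k-fiber plus-end (kinetochore) positions.

    ``orthogonal`` (default): the plate axis is the first principal
    direction of the plus-end cloud (orthogonal-distance fit, rotation
    invariant).  ``ols`` fits y on x instead.  The long axis is the
    perpendicular through the centroid.
    """
    pts = np.asarray(plus_end_positions, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("need at least 3 plus-end positions")
    centroid = pts.mean(axis=0)
    d = pts - centroid
    if np.allclose(d, 0):
        raise ValueError("all positions identical")
    if method == "orthogonal":
        cov = d.T @ d
        evals, evecs = np.linalg.eigh(cov)
        if np.isclose(evals[0], evals[1], rtol=1e-9):
            warnings.warn("isotropic plus-end cloud: plate direction ambiguous; "
                          "tie-break by smallest angle to the x-axis")
            plate = np.array([1.0, 0.0])
        else:
            plate = evecs[:, -1]
    elif method == "ols":
        if np.ptp(d[:, 0]) == 0:
            plate = np.array([0.0, 1.0])
        else:
            slope = np.polyfit(d[:, 0], d[:, 1], 1)[0]
            plate = np.array([1.0, slope])
    else:
        raise ValueError(f"unknown method {method!r}")
    plate = _canonical(plate)
    long_dir = _canonical(np.array([-plate[1], plate[0]]))
    return SpindleAxes(centroid=centroid, plate_dir=plate, long_dir=long_dir)


def classify_inner_outer(dist_to_long_axis_um: float) -> str:
    """'inner' if ≤ 2 µm from the long axis, 'outer' if ≥ 3 µm; the open
    gap (2, 3) µm is 'unclassified' and excluded from comparisons."""
    d = float(dist_to_long_axis_um)
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d <= 2.0:
        return "inner"
    if d >= 3.0:
        return "outer"
    return "unclassified"


def alignment_score(plus_pos, minus_pos, axes: SpindleAxes) -> float:
    """Signed chromosome-alignment score (µm) for one fiber.

    Magnitude: perpendicular distance from the plus-end to the plate
    axis.  Sign: positive if both ends lie on the same side of the plate
    (under-aligned), negative if they straddle it (over-aligned); an end
    exactly on the plate counts as same-side.
    """
    sp = axes.signed_dist_to_plate(plus_pos)
    sm = axes.signed_dist_to_plate(minus_pos)
    same_side = sp * sm >= 0
    return abs(sp) if same_side else -abs(sp)


def correlate_length_position(lengths, scores, zones=None) -> dict:
    """Pearson correlation of length vs alignment score, with the OLS
    slope, plus an inner-vs-outer Welch comparison when zones are given."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    out = {"r": float(r), "p": float(p), "slope": float(fit.slope),
           "intercept": float(fit.intercept), "n": int(len(x))}
    if zones is not None:
        zones = np.asarray(zones)
        inner = y[zones == "inner"]
        outer = y[zones == "outer"]
        out["inner_mean"] = float(np.mean(inner)) if len(inner) else np.nan
        out["outer_mean"] = float(np.mean(outer)) if len(outer) else np.nan
        if len(inner) >= 2 and len(outer) >= 2:
            out["inner_outer_test"] = welch_ttest(inner, outer)
    return out


def interkinetochore_distances(pairs: dict[str, tuple]) -> dict[str, float]:
    """Euclidean sister–sister distance per pair.

    ``pairs`` maps pair id -> (plus_pos_a, plus_pos_b); a pair with a
    missing member is skipped with a warning.
    """
    out = {}
    for pid, pair in pairs.items():
        if pair is None or len(pair) != 2 or pair[0] is None or pair[1] is None:
            warnings.warn(f"pair {pid}: unpaired fiber skipped")
            continue
        a, b = (np.asarray(p, dtype=float) for p in pair)
        out[pid] = float(np.linalg.norm(a - b))
    return out
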