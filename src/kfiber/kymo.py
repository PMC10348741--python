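"""Kymograph construction, photomark tracking, and poleward-flux estimation.

A kymograph row is the max-intensity projection across a 5-pixel-high
stationary box around one k-fiber at one time point.  The photobleach
mark appears as a dark trace; poleward flux is the rate at which the
mark approaches the fiber's minus-end, estimated as minus one times the
OLS slope of the mark-to-minus-end distance over time.  Regressions use
true timestamps, never frame indices, so a mid-movie cadence change
(e.g. 12 s frames switching to 1 min) is handled transparently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate, warp_polar

__all__ = [
    "Kymograph",
    "FeatureTracks",
    "register_rigid",
    "build_kymograph",
    "track_features",
    "flux_rate",
]


@dataclass
class Kymograph:
    """Time × position intensity matrix for one fiber."""

    matrix: np.ndarray  # (n_frames, n_positions)
    pixel_size_um: float
    times_min: np.ndarray  # true timestamps per row
    box_height_px: int = 5

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.matrix.shape[0] != len(self.times_min):
            raise ValueError("row count must equal frame count")


@dataclass
class FeatureTracks:
    """Feature positions (µm along the fiber axis) per frame."""

    times_min: np.ndarray
    mark_um: np.ndarray
    minus_end_um: np.ndarray
    kinetochore_um: np.ndarray | None = None
    provenance: str = "manual"
    flags: dict = field(default_factory=dict)


def _estimate_rotation(ref: np.ndarray, mov: np.ndarray) -> float:
    """Rotation angle (degrees) via polar-resampled FFT magnitudes."""
    # log magnitude tames the DC peak; moderate radius keeps informative bands
    f_ref = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(ref))))
    f_mov = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(mov))))
    radius = min(ref.shape) // 4
    p_ref = warp_polar(f_ref, radius=radius, output_shape=(720, radius))
    p_mov = warp_polar(f_mov, radius=radius, output_shape=(720, radius))
    shifts, _, _ = phase_cross_correlation(p_ref, p_mov, upsample_factor=20,
                                           normalization=None)
    angle = shifts[0] * 360.0 / 720.0
    # FFT magnitude has 180 deg symmetry: fold into (-90, 90]
    if angle > 90:
        angle -= 180
    elif angle <= -90:
        angle += 180
    return float(angle)


def register_rigid(
    timelapse: np.ndarray,
    reference_channel: np.ndarray | None = None,
    *,
    estimate_rotation: bool = True,
    upsample: int = 20,
) -> tuple[np.ndarray, list[dict]]:
    """Rigidly register a (t, y, x) timelapse to its first frame.

    Per-frame translation comes from phase correlation; rotation (if
    requested) from correlating polar-resampled FFT magnitudes, applied
    before the translation estimate.  ``reference_channel`` may supply a
    separate (t, y, x) stack in which to *estimate* the transforms (the
    tubulin channel), applied to ``timelapse``.  Featureless frames get
    the identity transform with a warning.
    """
    stack = np.asarray(timelapse, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (t, y, x) stack with >= 2 frames")
    est = stack if reference_channel is None else np.asarray(reference_channel, float)
    ref = est[0]
    out = np.empty_like(stack)
    out[0] = stack[0]
    transforms = [{"shift": (0.0, 0.0), "rotation_deg": 0.0}]
    for t in range(1, stack.shape[0]):
        frame = est[t]
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            warnings.warn(f"frame {t}: featureless; identity transform")
            out[t] = stack[t]
            transforms.append({"shift": (0.0, 0.0), "rotation_deg": 0.0})
            continue
        angle = _estimate_rotation(ref, frame) if estimate_rotation else 0.0
        derot_est = rotate(frame, -angle, preserve_range=True) if angle else frame
        shift, _, _ = phase_cross_correlation(ref, derot_est, upsample_factor=upsample,
                                              normalization=None)
        moved = rotate(stack[t], -angle, preserve_range=True) if angle else stack[t]
        out[t] = ndimage.shift(moved, shift, order=1, mode="nearest")
        transforms.append({"shift": (float(shift[0]), float(shift[1])),
                           "rotation_deg": float(angle)})
    return out, transforms


def build_kymograph(
    timelapse: np.ndarray,
    line: tuple,
    pixel_size_um: float,
    times_min: np.ndarray,
    box_height_px: int = 5,
) -> Kymograph:
    """Kymograph from a stationary oriented box around a fiber.

    ``line`` is ((x0, y0), (x1, y1)) in pixel coordinates; the box is
    ``box_height_px`` wide perpendicular to the line and is held fixed
    across frames.  Row t = per-column max across the box height.
    """
    stack = np.asarray(timelapse, dtype=float)
    (x0, y0), (x1, y1) = line
    p0 = np.array([x0, y0], float)
    p1 = np.array([x1, y1], float)
    length = np.linalg.norm(p1 - p0)
    n_cols = int(round(length)) + 1
    t_hat = (p1 - p0) / length
    n_hat = np.array([-t_hat[1], t_hat[0]])
    cols = p0 + np.linspace(0, length, n_cols)[:, None] * t_hat
    offs = np.arange(box_height_px, dtype=float) - (box_height_px - 1) / 2.0
    coords = cols[:, None, :] + offs[None, :, None] * n_hat  # (cols, h, xy)
    h, w = stack.shape[1:]
    if (coords[..., 0].min() < -0.5 or coords[..., 0].max() > w - 0.5
            or coords[..., 1].min() < -0.5 or coords[..., 1].max() > h - 0.5):
        raise ValueError("box exits the frame")
    rows = []
    flat = [coords[..., 1].ravel(), coords[..., 0].ravel()]
    for frame in stack:
        vals = ndimage.map_coordinates(frame, flat, order=1, mode="nearest")
        rows.append(vals.reshape(n_cols, box_height_px).max(axis=1))
    return Kymograph(np.array(rows), pixel_size_um, np.asarray(times_min, float),
                     box_height_px)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-pixel extremum position by a parabola through 3 samples."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def _track_minus_end(row: np.ndarray) -> float:
    """Half-max crossing of the distal (right-hand) intensity edge, px."""
    bg = float(row[-1])
    plateau = float(np.percentile(row, 90))
    half = bg + (plateau - bg) / 2.0
    for i in range(len(row) - 1, 0, -1):
        if row[i - 1] >= half > row[i]:
            frac = (row[i - 1] - half) / (row[i - 1] - row[i])
            return (i - 1) + frac
    return float(len(row) - 1)


def track_features(
    kymograph: Kymograph,
    mode: str = "auto",
    *,
    manual_tracks: "FeatureTracks | None" = None,
    mark_seed_px: float | None = None,
    search_halfwidth_px: int = 6,
) -> FeatureTracks:
    """Track the photomark and minus-end through a kymograph.

    ``manual`` mode passes through externally drawn tracks (the
    reference path for reproducing manually measured statistics).
    ``auto`` mode finds, per row, the intensity dip nearest the previous
    mark position (refined to sub-pixel by a parabola) and the minus-end
    as the half-max crossing of the distal intensity edge.  A lost mark
    (empty search window) truncates the track with a flag.
    """
    if mode == "manual":
        if manual_tracks is None:
            raise ValueError("manual mode requires manual_tracks")
        return manual_tracks
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    mat = kymograph.matrix
    n_frames, width = mat.shape
    marks = np.full(n_frames, np.nan)
    minus = np.full(n_frames, np.nan)
    flags: dict = {}
    if mark_seed_px is None:
        # seed inside the fiber: between the proximal half-max rise and the
        # distal minus-end edge, clear of both by a few pixels
        row0 = mat[0]
        bg = float(min(row0[0], row0[-1]))
        plateau = float(np.percentile(row0, 90))
        half = bg + (plateau - bg) / 2.0
        above = np.flatnonzero(row0 >= half)
        if len(above) < 8:
            raise ValueError("no fiber plateau found to seed the mark search")
        lo_edge, hi_edge = int(above[0]) + 3, int(above[-1]) - 3
        interior = mat[0][lo_edge:hi_edge]
        mark_seed_px = float(np.argmin(interior)) + lo_edge
    prev = mark_seed_px
    for t in range(n_frames):
        lo = max(int(round(prev)) - search_halfwidth_px, 0)
        hi = min(int(round(prev)) + search_halfwidth_px + 1, width)
        if hi - lo < 3:
            flags["lost_at_frame"] = t
            break
        window = mat[t, lo:hi]
        i = int(np.argmin(window))
        marks[t] = (lo + _parabolic_refine(window, i))
        minus[t] = _track_minus_end(mat[t])
        if minus[t] - marks[t] < 4:  # dip merging with the distal edge
            marks[t] = minus[t] = np.nan
            flags["lost_at_frame"] = t
            break
        prev = marks[t]
    px = kymograph.pixel_size_um
    ok = np.isfinite(marks)
    return FeatureTracks(
        times_min=kymograph.times_min[ok],
        mark_um=marks[ok] * px,
        minus_end_um=minus[ok] * px,
        provenance="auto",
        flags=flags,
    )


def flux_rate(tracks: FeatureTracks) -> dict:
    """Poleward flux (µm/min) from one fiber's tracks.

    d(t) = minus_end − mark; flux = −(OLS slope of d vs t), so a mark
    approaching the minus-end gives positive flux.
    """
    t = np.asarray(tracks.times_min, float)
    d = np.asarray(tracks.minus_end_um, float) - np.asarray(tracks.mark_um, float)
    ok = np.isfinite(d) & np.isfinite(t)
    if ok.sum() < 3:
        raise ValueError("need at least 3 tracked frames")
    fit = sps.linregress(t[ok], d[ok])
    return {"flux_um_min": -float(fit.slope), "stderr": float(fit.stderr),
            "n": int(ok.sum())}


def group_flux(per_fiber_tracks: list[FeatureTracks]) -> dict:
    """Group flux = mean of per-fiber regression slopes (each trace is
    one point), with the across-fiber SD."""
    vals, skipped = [], 0
    for tr in per_fiber_tracks:
        try:
            vals.append(flux_rate(tr)["flux_um_min"])
        except ValueError:
            skipped += 1
    arr = np.array(vals)
    return {
        "mean": float(np.mean(arr)) if len(arr) else np.nan,
        "sd": float(np.std(arr, ddof=1)) if len(arr) > 1 else np.nan,
        "n": int(len(arr)),
        "excluded": skipped,
        "per_fiber": vals,
    }
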