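"""Whole-spindle shape and centrosome-radius measurement.

Spindle major/minor axes come from Otsu-thresholding the (projected)
tubulin image, keeping the largest connected component, and reading the
axes of the ellipse with the same normalized second central moments.
The centrosome radius is the half-width-at-half-max of a line profile
through a focused pole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "AxesMeasurement",
    "LineProfile",
    "measure_spindle_axes",
    "estimate_centrosome_radius",
    "extract_path_profile",
]


@dataclass
class AxesMeasurement:
    major_axis_um: float
    minor_axis_um: float
    centroid_um: tuple[float, float]
    orientation_rad: float


@dataclass
class LineProfile:
    """Intensity along a scan; positions in µm, strictly increasing."""

    positions_um: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.shape != self.intensities.shape:
            raise ValueError("positions and intensities must match")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")


def measure_spindle_axes(image: np.ndarray, pixel_size_um: float) -> AxesMeasurement:
    """Ellipse-moment major/minor axes of the thresholded spindle.

    Binarizes with Otsu's threshold, keeps the largest 8-connected
    foreground component, and returns the axis lengths (µm) of the
    ellipse with the same normalized second central moments.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2D image")
    if np.ptp(img) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    lab = label(mask, connectivity=2)
    props = regionprops(lab)
    largest = max(props, key=lambda p: p.area)
    cy, cx = largest.centroid
    return AxesMeasurement(
        major_axis_um=largest.axis_major_length * pixel_size_um,
        minor_axis_um=largest.axis_minor_length * pixel_size_um,
        centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
        orientation_rad=float(largest.orientation),
    )


def otsu_mask(image: np.ndarray) -> np.ndarray:
    """Otsu foreground mask (exposed for inspection/tests)."""
    return np.asarray(image, dtype=float) > threshold_otsu(np.asarray(image, float))


def _half_cross(pos: np.ndarray, inten: np.ndarray, half: float) -> float | None:
    """Distance from pos[0] to the first linear-interpolated crossing of
    ``half`` walking outward along the given (already ordered) arm."""
    for i in range(1, len(inten)):
        if inten[i] <= half:
            lo, hi = inten[i], inten[i - 1]
            if hi == lo:
                return abs(pos[i] - pos[0])
            frac = (hi - half) / (hi - lo)
            x = pos[i - 1] + frac * (pos[i] - pos[i - 1])
            return abs(x - pos[0])
    return None


def estimate_centrosome_radius(profile: LineProfile) -> float:
    """Half-width-at-half-max radius (µm) of a pole intensity peak.

    Background is the profile minimum; the radius is the distance from
    the peak to the half-max crossing, linearly interpolated between
    samples and averaged over the two sides of the peak.
    """
    pos, inten = profile.positions_um, profile.intensities
    ipk = int(np.argmax(inten))
    if ipk in (0, len(inten) - 1):
        raise ValueError("monotone profile: no interior peak")
    bg = float(np.min(inten))
    peak = float(inten[ipk])
    if peak == bg:
        raise ValueError("flat profile: no peak")
    half = bg + (peak - bg) / 2.0
    left = _half_cross(pos[: ipk + 1][::-1], inten[: ipk + 1][::-1], half)
    right = _half_cross(pos[ipk:], inten[ipk:], half)
    arms = [a for a in (left, right) if a is not None]
    if not arms:
        raise ValueError("monotone profile: no half-max crossing on either side")
    return float(np.mean(arms))


def extract_path_profile(
    image: np.ndarray,
    points_um: np.ndarray,
    pixel_size_um: float,
    width_px: int = 15,
    *,
    sample_step_px: float = 0.1,
) -> LineProfile:
    """Wide-line intensity profile along a traced path.

    The path (planar control points, µm) is resampled at
    ``sample_step_px`` arc-length steps; at each sample the profile
    takes the *maximum* intensity across a ``width_px``-wide band
    perpendicular to the path (wide-line semantics).  Positions are µm
    of arc length.  Pixel centers sit at integer indices; physical
    coordinate = index × pixel size.
    """
    from .fiberlength import _catmull_rom_sample, _dedupe

    img = np.asarray(image, dtype=float)
    pts_px = _dedupe(np.asarray(points_um, dtype=float) / pixel_size_um)
    if len(pts_px) < 2:
        raise ValueError("need at least 2 distinct points")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if len(pts_px) == 2:
        n = max(int(np.ceil(np.linalg.norm(pts_px[1] - pts_px[0]) / sample_step_px)), 2)
        t = np.linspace(0, 1, n + 1)[:, None]
        dense = pts_px[0] + t * (pts_px[1] - pts_px[0])
    else:
        dense = _catmull_rom_sample(pts_px, sample_step_px)
    seg = np.diff(dense, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    # unit tangents (repeat last), then unit normals
    tang = np.vstack([seg, seg[-1]])
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offs = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    # sample coords: (n_samples, width) in (x, y) px
    coords = dense[:, None, :] + offs[None, :, None] * normal[:, None, :]
    h, w = img.shape
    if (coords[..., 0].min() < -0.5 or coords[..., 0].max() > w - 0.5
            or coords[..., 1].min() < -0.5 or coords[..., 1].max() > h - 0.5):
        raise ValueError("path (or its band) exits the image bounds")
    vals = ndimage.map_coordinates(
        img, [coords[..., 1].ravel(), coords[..., 0].ravel()], order=1, mode="nearest"
    ).reshape(coords.shape[:2])
    inten = vals.max(axis=1)
    pos_um = arc * pixel_size_um
    keep = np.concatenate([[True], np.diff(pos_um) > 0])
    return LineProfile(pos_um[keep], inten[keep])
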