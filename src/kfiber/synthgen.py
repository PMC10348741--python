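"""Synthetic spindle scenes with known ground truth.

Every analysis stage in this package is exercised against data from this
module: spindle geometries (focused k-fibers converging on two poles, or
unfocused fibers with scattered minus-end directions), rendered
fluorescence z-stacks (line-integrated fibers convolved with a Gaussian
PSF plus noise), sister length time series (anti-phase oscillations with
conserved sums in focused spindles; independent Ornstein–Uhlenbeck
processes when unfocused), ablation-regrowth trajectories, photomark
kymographs advected by poleward flux, and anaphase separation series.
Each generator records its planted parameters in a SceneTruth so that
measurement pipelines can be tested for parameter recovery.

Default parameters are the reference experimental conditions: control fiber lengths
8.01 ± 1.76 µm, unfocused 7.81 ± 2.52 µm, truncated at 0.5 µm; 0.3 µm
z-steps; 105 nm pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import truncnorm

from .dynamics import LengthSeries, SisterPairSeries
from .fiberlength import FiberTrace
from .kymo import FeatureTracks, Kymograph

__all__ = [
    "SceneParams",
    "SceneTruth",
    "ImageStack",
    "make_geometry",
    "render_zstack",
    "simulate_length_series",
    "simulate_ablation_series",
    "simulate_kymograph",
    "simulate_anaphase",
]

#: Study-condition length distributions (mean, SD) in µm per condition.
CONDITION_LENGTHS = {"focused": (8.01, 1.76), "unfocused": (7.81, 2.52)}
LENGTH_TRUNCATION_UM = 0.5


@dataclass
class SceneParams:
    """Parameters of one synthetic spindle scene."""

    condition: str = "focused"
    n_fibers: int = 16
    mean_length_um: float = 8.01
    sd_length_um: float = 1.76
    pole_positions: tuple = ((-8.0, 0.0, 3.0), (8.0, 0.0, 3.0))
    plate_center: tuple = (0.0, 0.0, 3.0)
    plate_normal: tuple = (1.0, 0.0, 0.0)
    plate_radius_um: float = 4.5  # half the ~9 µm spindle minor axis
    plate_axial_jitter_um: float = 0.4  # kinetochore scatter along the spindle axis
    psf_sigma_um: float = 0.25
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0
    pixel_size_um: float = 0.105
    z_step_um: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("focused", "unfocused"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_fibers % 2:
            raise ValueError("n_fibers must be even (sister pairing)")
        if self.mean_length_um <= 0 or self.sd_length_um < 0:
            raise ValueError("invalid length distribution parameters")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass
class SceneTruth:
    """Ground truth for a generated scene (everything a recovery test needs)."""

    condition: str = ""
    lengths_um: dict = field(default_factory=dict)  # fiber_id -> true 3D length
    plus_ends: dict = field(default_factory=dict)   # fiber_id -> (x, y, z) µm
    minus_ends: dict = field(default_factory=dict)
    sisters: dict = field(default_factory=dict)     # fiber_id -> sister_id
    poles: tuple | None = None
    plate_center: tuple | None = None
    plate_normal: tuple | None = None
    flux_um_min: float | None = None
    plus_growth_um_min: float | None = None
    growth_rate_um_min: float | None = None
    tau_min: float | None = None
    oscillation_amplitude_um: float | None = None
    oscillation_period_min: float | None = None
    mark_track_um: np.ndarray | None = None
    minus_end_track_um: np.ndarray | None = None
    times_min: np.ndarray | None = None
    v_sep_um_min: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


@dataclass
class ImageStack:
    """Intensity volume (z, y, x) or timelapse (t, y, x) with voxel sizes."""

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 0.3
    axis0: str = "z"  # "z" or "t"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel sizes must be positive")


def _truncated_lengths(rng, n, mean, sd) -> np.ndarray:
    if sd == 0:
        return np.full(n, float(mean))
    a = (LENGTH_TRUNCATION_UM - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_geometry(params: SceneParams) -> tuple[list[FiberTrace], SceneTruth]:
    """Generate a spindle geometry as straight 3D fibers.

    Plus-ends sit near the metaphase plate (bi-oriented sister pairs on
    opposite sides).  Focused fibers point their minus-ends at the pole
    of their spindle half, so minus-ends converge; unfocused fibers get
    scattered minus-end directions away from the plate.  True lengths
    are drawn from a truncated normal.  Traces store the planar (x, y)
    projection plus the z-slice span, as a manual tracer would record.
    """
    rng = np.random.default_rng(params.seed)
    n_pairs = params.n_fibers // 2
    lengths = _truncated_lengths(rng, params.n_fibers,
                                 params.mean_length_um, params.sd_length_um)
    normal = _unit(np.asarray(params.plate_normal, float))
    center = np.asarray(params.plate_center, float)
    # two in-plane directions spanning the plate
    helper = np.array([0.0, 0.0, 1.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, helper))
    w = np.cross(normal, u)
    poles = [np.asarray(p, float) for p in params.pole_positions]
    traces: list[FiberTrace] = []
    truth = SceneTruth(condition=params.condition,
                       poles=tuple(tuple(p) for p in poles),
                       plate_center=tuple(center),
                       plate_normal=tuple(normal))
    k = 0
    for pair in range(n_pairs):
        r = params.plate_radius_um * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        in_plane = r * (math.cos(phi) * u + math.sin(phi) * w)
        sep = 0.5  # half the ~1 µm interkinetochore distance
        axial = rng.normal(scale=params.plate_axial_jitter_um)
        for half, sign in (("a", -1.0), ("b", 1.0)):
            L = float(lengths[k])
            plus = center + in_plane + (sign * sep + axial) * normal
            if params.condition == "focused":
                pole = poles[0] if sign < 0 else poles[1]
                direction = _unit(pole - plus)
            else:
                # scattered minus-end direction, biased away from the plate
                d = sign * normal + rng.normal(scale=0.6, size=3)
                direction = _unit(d)
            minus = plus + L * direction
            fiber_id = f"{pair:02d}{half}"
            sister_id = f"{pair:02d}{'b' if half == 'a' else 'a'}"
            z0, z1 = sorted((plus[2], minus[2]))
            z_span = (int(round(z0 / params.z_step_um)),
                      int(round(z1 / params.z_step_um)))
            traces.append(FiberTrace(
                cell_id="synthetic",
                fiber_id=fiber_id,
                condition=params.condition,
                points=np.array([plus[:2], minus[:2]]),
                z_span=z_span,
                z_step_um=params.z_step_um,
                sister_id=sister_id,
                terminates_at_pole=False,
            ))
            truth.lengths_um[fiber_id] = L
            truth.plus_ends[fiber_id] = tuple(plus)
            truth.minus_ends[fiber_id] = tuple(minus)
            truth.sisters[fiber_id] = sister_id
            k += 1
    return traces, truth


def render_zstack(
    traces: list[FiberTrace],
    params: SceneParams,
    truth: SceneTruth | None = None,
    *,
    shape_zyx: tuple[int, int, int] | None = None,
    origin_um: tuple[float, float] = (0.0, 0.0),
    fiber_intensity: float = 100.0,
    centrosome_intensity: float = 0.0,
    background: float = 10.0,
) -> ImageStack:
    """Render traced fibers into a confocal-like z-stack.

    Each fiber is a line integral of intensity along its 3D path (z from
    the truth when given, else linear across the trace's slice span),
    convolved with an isotropic Gaussian PSF of ``psf_sigma_um``.
    Optional centrosome blobs are point sources at the poles.  Additive
    Gaussian noise (``gaussian_sd``) and Poisson scaling
    (``poisson_scale``) follow the scene's noise model.
    """
    px, dz = params.pixel_size_um, params.z_step_um
    if shape_zyx is None:
        zs = [t.z_span[1] for t in traces] + [1]
        xy = np.vstack([t.points for t in traces]) if traces else np.zeros((1, 2))
        ox, oy = origin_um
        shape_zyx = (max(zs) + 4,
                     int((xy[:, 1].max() - oy) / px) + 16,
                     int((xy[:, 0].max() - ox) / px) + 16)
    vol = np.zeros(shape_zyx, dtype=float)
    ox, oy = origin_um
    step = px / 3.0  # sub-voxel line sampling
    for tr in traces:
        if truth is not None and tr.fiber_id in truth.plus_ends:
            p0 = np.asarray(truth.plus_ends[tr.fiber_id], float)
            p1 = np.asarray(truth.minus_ends[tr.fiber_id], float)
        else:
            p0 = np.array([*tr.points[0], tr.z_span[0] * dz])
            p1 = np.array([*tr.points[-1], tr.z_span[1] * dz])
        L = np.linalg.norm(p1 - p0)
        n = max(int(L / step), 2)
        pts = p0 + np.linspace(0, 1, n)[:, None] * (p1 - p0)
        iz = np.round(pts[:, 2] / dz).astype(int)
        iy = np.round((pts[:, 1] - oy) / px).astype(int)
        ix = np.round((pts[:, 0] - ox) / px).astype(int)
        ok = ((0 <= iz) & (iz < shape_zyx[0]) & (0 <= iy) & (iy < shape_zyx[1])
              & (0 <= ix) & (ix < shape_zyx[2]))
        if not ok.all():
            raise ValueError(f"fiber {tr.fiber_id} does not fit in the volume")
        np.add.at(vol, (iz, iy, ix), fiber_intensity * L / n)
    if centrosome_intensity and truth is not None and truth.poles:
        for pole in truth.poles:
            iz = int(round(pole[2] / dz))
            iy = int(round((pole[1] - oy) / px))
            ix = int(round((pole[0] - ox) / px))
            if 0 <= iz < shape_zyx[0] and 0 <= iy < shape_zyx[1] and 0 <= ix < shape_zyx[2]:
                vol[iz, iy, ix] += centrosome_intensity
    from scipy.ndimage import gaussian_filter

    sigma_vox = (params.psf_sigma_um / dz, params.psf_sigma_um / px,
                 params.psf_sigma_um / px)
    vol = gaussian_filter(vol, sigma=sigma_vox)
    vol += background
    rng = np.random.default_rng(params.seed + 1)
    if params.poisson_scale > 0:
        vol = rng.poisson(vol * params.poisson_scale) / params.poisson_scale
    if params.gaussian_sd > 0:
        vol = vol + rng.normal(scale=params.gaussian_sd, size=vol.shape)
    return ImageStack(np.clip(vol, 0.0, None), px, dz, axis0="z")


#: Sister-dynamics defaults reproducing the observed statistics at the
#: ~10-20 min observation windows of live metaphase spindles: temporal CV ~12%
#: (focused) / ~17% (unfocused) and sister-sum CV ~6% (focused).  The
#: "noise" on each sister is uncoordinated fluctuation plus measurement
#: error; it is the only term breaking sum conservation.
OSC_AMPLITUDE_UM = 1.05
OSC_PERIOD_MIN = 4.0
MEASUREMENT_NOISE_UM = 0.6
OU_TAU_MIN = 5.0
OU_STATIONARY_SD_UM = 1.6


def simulate_length_series(
    condition: str,
    n_pairs: int,
    duration_min: float,
    dt_min: float,
    seed: int,
    *,
    mean_um: float = 7.6,
    amplitude_um: float = OSC_AMPLITUDE_UM,
    period_min: float = OSC_PERIOD_MIN,
    noise_sd_um: float = MEASUREMENT_NOISE_UM,
    tau_min: float = OU_TAU_MIN,
    ou_sd_um: float = OU_STATIONARY_SD_UM,
) -> tuple[list[SisterPairSeries], SceneTruth]:
    """Sister length time series with known dynamics.

    Focused: each pair shares a conserved sum; one sister oscillates as
    a sinusoid with a random phase, the other is the sum minus the first
    (anti-phase), plus independent measurement noise on each.  With
    ``noise_sd_um = 0`` the sister sum is exactly constant.  Unfocused:
    the two sisters are independent Ornstein–Uhlenbeck processes with
    relaxation time ``tau_min`` and stationary SD ``ou_sd_um``
    (exact discretization), so the ensemble autocorrelation at lag h is
    exp(−h·dt/tau).  All lengths are clipped strictly positive.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if duration_min < 2 * dt_min:
        raise ValueError("duration must cover at least 2 time steps")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 1e-9, dt_min)
    n_t = len(times)
    pairs: list[SisterPairSeries] = []
    truth = SceneTruth(condition=condition, tau_min=tau_min,
                       oscillation_amplitude_um=amplitude_um,
                       oscillation_period_min=period_min,
                       times_min=times)
    for p in range(n_pairs):
        ida, idb = f"{p:02d}a", f"{p:02d}b"
        if condition == "focused":
            total = 2 * mean_um
            phase = rng.uniform(0, 2 * math.pi)
            osc = amplitude_um * np.sin(2 * math.pi * times / period_min + phase)
            xa = mean_um + osc
            xb = total - xa
            xa = xa + rng.normal(scale=noise_sd_um, size=n_t)
            xb = xb + rng.normal(scale=noise_sd_um, size=n_t)
        else:
            def ou():
                x = np.empty(n_t)
                x[0] = mean_um + ou_sd_um * rng.standard_normal()
                a = math.exp(-dt_min / tau_min)
                s = ou_sd_um * math.sqrt(1 - a * a)
                for i in range(1, n_t):
                    x[i] = mean_um + a * (x[i - 1] - mean_um) + s * rng.standard_normal()
                return x
            xa, xb = ou(), ou()
        xa = np.clip(xa, 0.2, None)
        xb = np.clip(xb, 0.2, None)
        pairs.append(SisterPairSeries(
            LengthSeries(ida, "synthetic", condition, times, xa),
            LengthSeries(idb, "synthetic", condition, times, xb),
        ))
        truth.lengths_um[ida] = mean_um
        truth.lengths_um[idb] = mean_um
        truth.sisters[ida] = idb
        truth.sisters[idb] = ida
    return pairs, truth


def simulate_ablation_series(
    baseline_um: float,
    stub_um: float,
    growth_rate_um_min: float,
    t_ablate_min: float,
    duration_min: float,
    dt_min: float,
    noise_sd: float,
    seed: int,
    *,
    fiber_id: str = "ablated",
    condition: str = "focused",
) -> LengthSeries:
    """One ablated fiber's length trajectory.

    Baseline before the cut; drops to the stub length at ``t_ablate``;
    regrows linearly at ``growth_rate_um_min`` until reaching baseline,
    then plateaus.  Gaussian noise of SD ``noise_sd`` is added.
    """
    if stub_um >= baseline_um:
        raise ValueError("stub must be shorter than baseline")
    if growth_rate_um_min < 0:
        raise ValueError("growth rate must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 1e-9, dt_min)
    clean = np.where(
        times < t_ablate_min,
        baseline_um,
        np.minimum(baseline_um, stub_um + growth_rate_um_min * (times - t_ablate_min)),
    )
    noisy = clean + (rng.normal(scale=noise_sd, size=len(times)) if noise_sd > 0 else 0.0)
    return LengthSeries(fiber_id, "synthetic", condition,
                        times - t_ablate_min,  # experiment origin at the cut
                        np.clip(noisy, 0.05, None),
                        events={"ablation_time": 0.0})


def simulate_kymograph(
    flux_um_min: float,
    plus_growth_um_min: float,
    fiber_len_um: float,
    mark_offset_um: float,
    duration_min: float,
    dt_min: float,
    pixel_size_um: float,
    noise_sd: float,
    seed: int,
    *,
    mark_depth: float = 0.6,
    mark_sigma_um: float = 0.25,
    edge_sigma_um: float = 0.15,
    intensity_noise_sd: float = 0.0,
) -> tuple[Kymograph, SceneTruth]:
    """Photomark kymograph with planted flux.

    In the kinetochore frame the fiber lattice moves away from the
    kinetochore at the plus-end polymerization rate, carrying the mark;
    the minus-end recedes at (polymerization − flux).  The true
    mark-to-minus-end distance therefore shrinks at exactly
    ``flux_um_min``.  The mark is rendered as a Gaussian intensity dip,
    the minus-end as a smoothed intensity edge; ``noise_sd`` jitters the
    rendered feature positions (µm) per frame.  The returned SceneTruth
    carries the exact tracks.
    """
    if not 0 < mark_offset_um < fiber_len_um:
        raise ValueError("mark must lie inside the fiber")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 1e-9, dt_min)
    mark = mark_offset_um + plus_growth_um_min * times
    minus = fiber_len_um + (plus_growth_um_min - flux_um_min) * times
    if np.any(minus - mark < 3 * mark_sigma_um):
        raise ValueError(
            "mark reaches the minus-end within the simulated interval; "
            "shorten duration or move the mark"
        )
    margin_um = 1.5
    width_um = margin_um + float(minus.max()) + 3.0
    n_px = int(math.ceil(width_um / pixel_size_um))
    x = np.arange(n_px) * pixel_size_um
    rows = np.empty((len(times), n_px))
    from scipy.special import erf

    for i, t in enumerate(times):
        jm = mark[i] + (rng.normal(scale=noise_sd) if noise_sd > 0 else 0.0)
        je = minus[i] + (rng.normal(scale=noise_sd) if noise_sd > 0 else 0.0)
        # plateau from the kinetochore (at x = margin) to the minus-end
        rise = 0.5 * (1 + erf((x - margin_um) / (edge_sigma_um * math.sqrt(2))))
        fall = 0.5 * (1 - erf((x - (margin_um + je)) / (edge_sigma_um * math.sqrt(2))))
        profile = rise * fall
        profile *= 1 - mark_depth * np.exp(-0.5 * ((x - (margin_um + jm)) / mark_sigma_um) ** 2)
        row = 20.0 + 100.0 * profile
        if intensity_noise_sd > 0:
            row = row + rng.normal(scale=intensity_noise_sd, size=n_px)
        rows[i] = row
    kymo = Kymograph(rows, pixel_size_um, times, box_height_px=5)
    truth = SceneTruth(
        flux_um_min=flux_um_min,
        plus_growth_um_min=plus_growth_um_min,
        times_min=times,
        mark_track_um=margin_um + mark,
        minus_end_track_um=margin_um + minus,
    )
    return kymo, truth


def true_tracks(truth: SceneTruth) -> FeatureTracks:
    """SceneTruth kymograph tracks as a FeatureTracks (oracle path)."""
    return FeatureTracks(
        times_min=truth.times_min,
        mark_um=truth.mark_track_um,
        minus_end_um=truth.minus_end_track_um,
        provenance="manual",
    )


def noisy_tracks(truth: SceneTruth, noise_sd_um: float, seed: int) -> FeatureTracks:
    """Truth tracks with independent Gaussian position noise, emulating
    manual segmented-line placement error."""
    rng = np.random.default_rng(seed)
    n = len(truth.times_min)
    return FeatureTracks(
        times_min=truth.times_min,
        mark_um=truth.mark_track_um + rng.normal(scale=noise_sd_um, size=n),
        minus_end_um=truth.minus_end_track_um + rng.normal(scale=noise_sd_um, size=n),
        provenance="manual",
    )


def simulate_anaphase(
    v_sep_um_min: float,
    n_pairs: int,
    duration_min: float,
    dt_min: float,
    seed: int,
    *,
    noise_sd: float = 0.0,
):
    """Sister-chromatid separation distance series: v·t plus noise."""
    if v_sep_um_min < 0:
        raise ValueError("separation velocity must be non-negative")
    from .anaphase import SeparationSeries

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 1e-9, dt_min)
    out = []
    for p in range(n_pairs):
        d = v_sep_um_min * times
        if noise_sd > 0:
            d = d + rng.normal(scale=noise_sd, size=len(times))
        out.append(SeparationSeries(f"pair{p:02d}", times, np.clip(d, 0.0, None)))
    truth = SceneTruth(v_sep_um_min=v_sep_um_min, times_min=times)
    return out, truth
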