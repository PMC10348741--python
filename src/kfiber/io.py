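"""Tidy-table and image I/O for the pipeline.

Trace CSV schema (one row per control point):
    cell_id, fiber_id, sister_id, condition, point_index, x_um, y_um,
    z_first, z_last, z_step_um, terminates_at_pole
Length-series CSV (long format):
    cell_id, fiber_id, condition, time_min, length_um
Manual kymograph tracks CSV:
    frame, time_min, kinetochore_um, mark_um, minus_end_um
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dynamics import LengthSeries
from .fiberlength import FiberTrace
from .kymo import FeatureTracks
from .synthgen import ImageStack

TRACE_COLUMNS = ["cell_id", "fiber_id", "sister_id", "condition", "point_index",
                 "x_um", "y_um", "z_first", "z_last", "z_step_um",
                 "terminates_at_pole"]


def write_traces_csv(traces, path) -> None:
    rows = []
    for tr in traces:
        for i, (x, y) in enumerate(tr.points):
            rows.append({
                "cell_id": tr.cell_id, "fiber_id": tr.fiber_id,
                "sister_id": tr.sister_id if tr.sister_id is not None else "",
                "condition": tr.condition, "point_index": i,
                "x_um": x, "y_um": y,
                "z_first": tr.z_span[0], "z_last": tr.z_span[1],
                "z_step_um": tr.z_step_um,
                "terminates_at_pole": tr.terminates_at_pole,
            })
    # 1e-4 µm (0.1 nm) precision: far below tracing accuracy
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.4f")


def read_traces_csv(path) -> list[FiberTrace]:
    df = pd.read_csv(path, dtype={"cell_id": str, "fiber_id": str, "sister_id": str})
    traces = []
    for (cell, fiber), grp in df.groupby(["cell_id", "fiber_id"], sort=True):
        grp = grp.sort_values("point_index")
        first = grp.iloc[0]
        sister = first["sister_id"]
        traces.append(FiberTrace(
            cell_id=str(cell), fiber_id=str(fiber),
            condition=str(first["condition"]),
            points=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            z_span=(int(first["z_first"]), int(first["z_last"])),
            z_step_um=float(first["z_step_um"]),
            sister_id=None if pd.isna(sister) or sister == "" else str(sister),
            terminates_at_pole=bool(first["terminates_at_pole"]),
        ))
    return traces


def write_series_csv(series_list, path) -> None:
    rows = []
    for s in series_list:
        for t, x in zip(s.times, s.lengths):
            rows.append({"cell_id": s.cell_id, "fiber_id": s.fiber_id,
                         "condition": s.condition, "time_min": t, "length_um": x})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")


def read_series_csv(path) -> list[LengthSeries]:
    df = pd.read_csv(path, dtype={"cell_id": str, "fiber_id": str})
    out = []
    for (cell, fiber), grp in df.groupby(["cell_id", "fiber_id"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(LengthSeries(
            fiber_id=str(fiber), cell_id=str(cell),
            condition=str(grp.iloc[0]["condition"]),
            times=grp["time_min"].to_numpy(dtype=float),
            lengths=grp["length_um"].to_numpy(dtype=float),
        ))
    return out


def read_tracks_csv(path) -> FeatureTracks:
    df = pd.read_csv(path).sort_values("time_min")
    kin = df["kinetochore_um"].to_numpy(float) if "kinetochore_um" in df else None
    return FeatureTracks(
        times_min=df["time_min"].to_numpy(float),
        mark_um=df["mark_um"].to_numpy(float),
        minus_end_um=df["minus_end_um"].to_numpy(float),
        kinetochore_um=kin,
        provenance="manual",
    )


def write_tracks_csv(tracks: FeatureTracks, path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(tracks.times_min)),
        "time_min": tracks.times_min,
        "mark_um": tracks.mark_um,
        "minus_end_um": tracks.minus_end_um,
    })
    if tracks.kinetochore_um is not None:
        df["kinetochore_um"] = tracks.kinetochore_um
    df.to_csv(path, index=False)


def write_stack(stack: ImageStack, path) -> None:
    """Multi-page TIFF, one page per z-slice (or time point)."""
    tifffile.imwrite(str(path), stack.data.astype(np.float32))


def read_stack(path, pixel_size_um: float, z_step_um: float = 0.3,
               axis0: str = "z") -> ImageStack:
    data = tifffile.imread(str(path))
    return ImageStack(np.asarray(data, dtype=float), pixel_size_um, z_step_um, axis0)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
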