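"""Configuration, orchestration, and source-spreadsheet ingestion.

A RunConfig (usually loaded from YAML) selects pipeline stages and
carries the physical constants; :func:`run` executes the stages in
order, writing tidy CSV/JSON outputs stamped with the package version
and a hash of the config so a rerun is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from . import __version__
from .ablation import RegrowthDataset, fraction_recovered, group_bin_average, initial_growth_rate
from .dynamics import autocorrelation, bin_by_minute, series_stats
from .fiberlength import cohort_stats, measure_traces
from .kymo import flux_rate
from .spatial import alignment_score, classify_inner_outer, fit_spindle_axes
from .synthgen import SceneParams, make_geometry, render_zstack

log = logging.getLogger("kfiber")

STAGES = ("simulate", "morphometry", "lengths", "spatial", "dynamics",
          "ablation", "flux", "anaphase", "ingest", "report")


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=list)
    inputs: dict = field(default_factory=dict)   # stage -> path(s)
    output_dir: str = "results"
    condition_labels: tuple = ("focused", "unfocused")
    pixel_size_um: float = 0.105
    z_step_um: float = 0.3
    centrosome_radius_um: float = 0.97
    frame_interval_min: float = 0.2
    seed: int = 0
    scene: dict = field(default_factory=dict)  # SceneParams overrides for simulate

    def __post_init__(self) -> None:
        for name, v in [("pixel_size_um", self.pixel_size_um),
                        ("z_step_um", self.z_step_um),
                        ("frame_interval_min", self.frame_interval_min)]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "condition_labels" in raw:
            raw["condition_labels"] = tuple(raw["condition_labels"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["condition_labels"] = list(self.condition_labels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        d = asdict(self)
        d.pop("output_dir", None)  # hash the analysis, not its destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.digest(), "package_version": __version__}


def run(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order.

    Returns a machine-readable summary; every output file carries the
    config hash and package version.  Exclusions (e.g. the regrowth-rate
    eligibility rule) are logged with fiber ids.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages_run": [], **_stamp(config)}
    for stage in [s for s in STAGES if s in config.stages]:
        fn = _STAGE_FUNCS[stage]
        summary[stage] = fn(config, out)
        summary["stages_run"].append(stage)
    kio.write_json(summary, out / "run_summary.json")
    return summary


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    params = SceneParams(**{"seed": cfg.seed, "pixel_size_um": cfg.pixel_size_um,
                            "z_step_um": cfg.z_step_um, **cfg.scene})
    traces, truth = make_geometry(params)
    kio.write_traces_csv(traces, out / "traces.csv")
    kio.write_json({**truth.to_dict(), **_stamp(cfg)}, out / "scene_truth.json")
    if cfg.scene.get("render", False):
        stack = render_zstack(traces, params, truth)
        kio.write_stack(stack, out / "zstack.tif")
    return {"n_fibers": len(traces)}


def _stage_lengths(cfg: RunConfig, out: Path) -> dict:
    traces = kio.read_traces_csv(cfg.inputs.get("lengths", out / "traces.csv"))
    records = measure_traces(traces, cfg.centrosome_radius_um)
    records.to_csv(out / "length_records.csv", index=False)
    stats = cohort_stats(records)
    stats["per_cell"].to_csv(out / "per_cell_stats.csv", index=False)
    kio.write_json({"pooled": stats["pooled"].to_dict("records"),
                    "tests": stats["tests"], **_stamp(cfg)},
                   out / "length_summary.json")
    return {"n_fibers": len(records),
            "mean_um": float(records["corrected_length_um"].mean())}


def _stage_spatial(cfg: RunConfig, out: Path) -> dict:
    traces = kio.read_traces_csv(cfg.inputs.get("spatial", out / "traces.csv"))
    rows = []
    for cell_id in sorted({t.cell_id for t in traces}):
        cell = [t for t in traces if t.cell_id == cell_id]
        paired = [t for t in cell if t.sister_id]
        if len(paired) < 3:
            log.warning("cell %s: fewer than 3 paired plus-ends; skipped", cell_id)
            continue
        axes = fit_spindle_axes(np.array([t.points[0] for t in paired]))
        for t in cell:
            dist = axes.dist_to_long_axis(t.points[0])
            rows.append({
                "cell_id": cell_id, "fiber_id": t.fiber_id,
                "dist_to_long_axis_um": dist,
                "zone": classify_inner_outer(dist),
                "alignment_score_um": alignment_score(t.points[0], t.points[-1], axes),
            })
    df = pd.DataFrame(rows)
    df.to_csv(out / "alignment_records.csv", index=False)
    return {"n_fibers": len(df)}


def _stage_dynamics(cfg: RunConfig, out: Path) -> dict:
    series = kio.read_series_csv(cfg.inputs.get("dynamics", out / "length_series.csv"))
    stats_rows, acf_rows = [], []
    for s in series:
        b = bin_by_minute(s)
        st = series_stats(b)
        stats_rows.append({"fiber_id": s.fiber_id, "cell_id": s.cell_id,
                           "condition": s.condition, **st})
        max_lag = max(len(b.lengths) - 2, 0)
        if max_lag >= 1:
            rho = autocorrelation(b, max_lag)
            acf_rows += [{"fiber_id": s.fiber_id, "condition": s.condition,
                          "lag": h, "rho": rho[h]} for h in range(len(rho))]
    pd.DataFrame(stats_rows).to_csv(out / "series_stats.csv", index=False)
    pd.DataFrame(acf_rows).to_csv(out / "acf.csv", index=False)
    return {"n_series": len(series)}


def _stage_ablation(cfg: RunConfig, out: Path) -> dict:
    paths = cfg.inputs.get("ablation", {})
    ablated = kio.read_series_csv(paths["ablated"])
    unablated = kio.read_series_csv(paths["unablated"])
    ds = RegrowthDataset(ablated=ablated, unablated=unablated)
    group_bin_average(ds).to_csv(out / "regrowth_binned.csv")
    rates = initial_growth_rate(ds)
    for fid, why in rates["excluded"].items():
        log.warning("growth-rate exclusion: fiber %s (%s)", fid, why)
    frac = fraction_recovered(ds)
    frac.to_csv(out / "fraction_recovered.csv", index=False)
    kio.write_json({**{k: rates[k] for k in ("per_fiber", "excluded", "mean", "sd", "n")},
                    **_stamp(cfg)}, out / "growth_rates.json")
    return {"growth_rate_mean": rates["mean"], "n": rates["n"]}


def _stage_flux(cfg: RunConfig, out: Path) -> dict:
    paths = cfg.inputs.get("flux", [])
    rows = []
    for p in paths:
        tracks = kio.read_tracks_csv(p)
        res = flux_rate(tracks)
        rows.append({"source": str(p), **res})
    df = pd.DataFrame(rows)
    df.to_csv(out / "flux_rates.csv", index=False)
    return {"mean_flux_um_min": float(df["flux_um_min"].mean()) if len(df) else np.nan,
            "n": len(df)}


def _stage_anaphase(cfg: RunConfig, out: Path) -> dict:
    from .anaphase import SeparationSeries, separation_velocity
    df = pd.read_csv(cfg.inputs["anaphase"], dtype={"pair_id": str})
    series = [SeparationSeries(pid, g["time_min"].to_numpy(float),
                               g["distance_um"].to_numpy(float))
              for pid, g in df.groupby("pair_id", sort=True)]
    res = separation_velocity(series)
    kio.write_json({"velocity_um_min": res["velocity_um_min"],
                    "n_pairs": res["n_pairs"], **_stamp(cfg)},
                   out / "separation_velocity.json")
    return {"velocity_um_min": res["velocity_um_min"]}


def _stage_morphometry(cfg: RunConfig, out: Path) -> dict:
    from .morphometry import measure_spindle_axes
    rows = []
    for item in cfg.inputs.get("morphometry", []):
        stack = kio.read_stack(item["path"], cfg.pixel_size_um, cfg.z_step_um)
        img = stack.data.max(axis=0) if stack.data.ndim == 3 else stack.data
        m = measure_spindle_axes(img, cfg.pixel_size_um)
        rows.append({"cell_id": item.get("cell_id", Path(item["path"]).stem),
                     "condition": item.get("condition", ""),
                     "major_um": m.major_axis_um, "minor_um": m.minor_axis_um,
                     "orientation_rad": m.orientation_rad})
    pd.DataFrame(rows).to_csv(out / "spindle_axes.csv", index=False)
    return {"n_cells": len(rows)}


def _stage_ingest(cfg: RunConfig, out: Path) -> dict:
    tidy, errors = ingest_source_data(cfg.inputs["ingest"]["path"],
                                      cfg.inputs["ingest"].get("schema", "lengths_long"))
    tidy.to_csv(out / "ingested.csv", index=False)
    if errors:
        kio.write_json(errors, out / "ingest_errors.json")
    return {"n_rows": len(tidy), "n_errors": len(errors)}


def _stage_report(cfg: RunConfig, out: Path) -> dict:
    produced = sorted(p.name for p in out.iterdir()
                      if p.suffix in (".csv", ".json") and p.name != "run_summary.json")
    return {"outputs": produced}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "morphometry": _stage_morphometry,
    "lengths": _stage_lengths,
    "spatial": _stage_spatial,
    "dynamics": _stage_dynamics,
    "ablation": _stage_ablation,
    "flux": _stage_flux,
    "anaphase": _stage_anaphase,
    "ingest": _stage_ingest,
    "report": _stage_report,
}

# --------------------------------------------------------------------------
# Source-data identifier convention: '211217_001_01b_MAX13-19'
#   chars 1-10  -> cell id ('211217_001')
#   chars 12-14 -> fiber id + spindle half ('01' + 'b')
#   trailing    -> z-plane span ('13-19'), after an optional 'MAX' prefix
# --------------------------------------------------------------------------

_ID_RE = re.compile(
    r"^(?P<cell>\d{6}_\d{3})_(?P<fiber>\d{2})(?P<half>[ab])_"
    r"(?:MAX)?(?P<z0>\d+)[-–](?P<z1>\d+)$"
)


def parse_measurement_id(identifier: str) -> dict:
    """Parse a deposited-measurement identifier into its components.

    Raises ValueError naming the first offending position on malformed
    input rather than silently dropping the row.
    """
    m = _ID_RE.match(identifier)
    if not m:
        # locate the failure for the error report
        probe = re.match(r"^\d{6}_\d{3}", identifier)
        pos = probe.end() if probe else 0
        raise ValueError(
            f"malformed identifier {identifier!r}: parse failed at position {pos}"
        )
    return {
        "cell_id": m["cell"],
        "fiber_id": m["fiber"],
        "half": m["half"],
        "z_span": (int(m["z0"]), int(m["z1"])),
    }


def ingest_source_data(path, schema: str = "lengths_long") -> tuple[pd.DataFrame, list]:
    """Ingest a deposited per-fiber spreadsheet into a tidy table.

    ``lengths_long`` expects columns ``identifier`` and ``length_um``
    (optionally ``time_min``); the identifier is expanded into cell id,
    fiber id, spindle half, and z-span.  Malformed identifiers are
    collected into a row-level error report, never silently dropped.
    """
    if schema != "lengths_long":
        raise ValueError(f"unknown ingestion schema {schema!r}")
    path = Path(path)
    raw = pd.read_excel(path) if path.suffix in (".xlsx", ".xls") else pd.read_csv(path)
    rows, errors = [], []
    for i, rec in raw.iterrows():
        try:
            parsed = parse_measurement_id(str(rec["identifier"]))
        except ValueError as e:
            errors.append({"row": int(i), "error": str(e)})
            continue
        row = {**parsed, "z_first": parsed["z_span"][0], "z_last": parsed["z_span"][1]}
        del row["z_span"]
        for col in raw.columns:
            if col != "identifier":
                row[col] = rec[col]
        rows.append(row)
    return pd.DataFrame(rows), errors
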