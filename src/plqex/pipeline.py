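"""Config-driven end-to-end orchestration with provenance logging.

``run_pipeline`` executes trajectory loading, alignment, equilibration
trimming, state labeling, event detection, statistics and (optionally)
density accumulation in order, writes every report to the output directory,
and records a manifest (parameters, seed, package version, input checksums)
sufficient to reproduce the bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .density import accumulate_density_trajectory, write_opendx
from .events import (DEFAULT_HYSTERESIS_NM, DEFAULT_MIN_DWELL_NS,
                     annotate_orientations, detect_flipflops, detect_passages_all,
                     events_to_frame, label_trace, write_events_tsv)
from .geometry import load_geometry
from .stats import (cavity_occupancy, compute_flux_table, conservation_audit,
                    estimate_timescale, mean_interevent_time)
from .trajio import RoleMap, discard_equilibration, read_trajectory


class PipelineError(RuntimeError):
    """Stage failure; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and parameters of one analysis run."""

    trajectory: str
    geometry: str
    role_map: str
    out_dir: str
    structure: str | None = None
    seed: int = 0
    t_eq_ns: float = 0.0
    hysteresis_nm: float = DEFAULT_HYSTERESIS_NM
    min_dwell_ns: float = DEFAULT_MIN_DWELL_NS
    flipflop_delta_z_nm: float = 0.3
    end_window_frac: float = 0.05
    density_voxel_nm: float = 0.1
    with_density: bool = False
    monitored_time_ns: dict = field(default_factory=dict)  # optional overrides

    def validate(self) -> None:
        for key in ("trajectory", "geometry", "role_map"):
            path = getattr(self, key)
            if not Path(path).exists():
                raise FileNotFoundError(f"{key} file not found: {path}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a manifest dict; all reports land in ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    with _stage("geometry"):
        model = load_geometry(config.geometry)
    with _stage("trajio"):
        role_map = RoleMap.from_yaml(config.role_map)
        traj = read_trajectory(config.structure, config.trajectory, role_map)
        if config.t_eq_ns > 0:
            traj = discard_equilibration(traj, config.t_eq_ns)
    with _stage("events"):
        traces = label_trace(traj, role_map, model, config.hysteresis_nm)
        passages = detect_passages_all(traces, config.min_dwell_ns)
        passages = annotate_orientations(passages, traj, role_map, model)
        flips = [ev for tr in traces.values()
                 for ev in detect_flipflops(tr, model, config.flipflop_delta_z_nm)]
        write_events_tsv(passages, out / "passage_events.tsv")
        events_to_frame(flips).to_csv(out / "flipflop_events.tsv", sep="\t",
                                      index=False, float_format="%.6f")
        outputs["passage_events"] = str(out / "passage_events.tsv")
        outputs["flipflop_events"] = str(out / "flipflop_events.tsv")
    with _stage("stats"):
        span_ns = float(traj.times[-1] - traj.times[0])
        monitored = {m: float(config.monitored_time_ns.get(m, span_ns))
                     for m in range(len(model.monomers))}
        flux = compute_flux_table(passages, monitored)
        flux.to_tsv(out / "flux_table.tsv")
        flux.wide().to_csv(out / "flux_table_wide.tsv", sep="\t")
        occupancy = cavity_occupancy(traces, model,
                                     end_window_ns=config.end_window_frac * span_ns)
        occupancy.to_tsv(out / "occupancy.tsv")
        audit = conservation_audit(traces, passages)
        n_full = sum(1 for ev in passages if ev.completeness == "full")
        cavity_flips = [ev for ev in flips if ev.compartment == "cavity"]
        residence_us = float(occupancy.counts.to_numpy().sum(axis=1).mean()
                             * span_ns * 1e-3 * len(model.monomers))
        timescale = estimate_timescale(len(cavity_flips), residence_us)
        summary = {
            "n_full_passages": n_full,
            "n_partial_passages": sum(1 for ev in passages if ev.completeness == "partial"),
            "n_trapped": sum(1 for ev in passages if ev.completeness == "trapped"),
            "n_flipflops_cavity": len(cavity_flips),
            "n_flipflops_bulk": len(flips) - len(cavity_flips),
            "cavity_occupancy_end_mean": occupancy.end_mean,
            "cavity_occupancy_end_sem": occupancy.end_sem,
            "flipflop_timescale_us": {"kind": timescale.kind,
                                      "value_us": timescale.value_us},
            "mean_interevent_time_us": (
                mean_interevent_time(n_full, sum(monitored.values()) * 1e-3)
                if n_full else None),
            "conservation_ok": audit.ok,
            "conservation_violations": audit.violations,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        outputs.update({"flux_table": str(out / "flux_table.tsv"),
                        "occupancy": str(out / "occupancy.tsv"),
                        "summary": str(out / "summary.json")})
    if config.with_density:
        with _stage("density"):
            origin = np.zeros(3)
            extent = traj.box[0]
            grid = accumulate_density_trajectory(traj, role_map, origin, extent,
                                                 config.density_voxel_nm)
            write_opendx(grid, out / "density.dx")
            outputs["density"] = str(out / "density.dx")

    manifest = {
        "package": "plqex",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("out_dir",)},
        "inputs": {key: {"path": getattr(config, key), "sha256": _sha256(getattr(config, key))}
                   for key in ("trajectory", "geometry", "role_map")},
        "outputs": outputs,
        "n_frames": int(traj.n_frames),
        "n_ligands": len(role_map.ligands),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
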