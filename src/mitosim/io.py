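"""Configuration files, trajectory/summary writers, and the run manifest.

Configurations are hierarchical YAML with the blocks ``mitochondrion:``,
``cell:``, ``drugs:``, ``perturbations:`` and ``ablations:``; an empty file
yields the all-defaults control experiment (30 000 min horizon, 65 cells,
500 grid points).  Outputs are RFC-4180 CSV and JSON only, with numeric
formatting that is bit-stable across reruns of the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .engine import TrajectorySet
from .observables import CONSTANTS, baseline_ros, survival_and_state_curves, time_to_ros_threshold
from .params import ConfigError, SimulationConfig

__all__ = ["load_config", "save_config", "write_outputs", "RunManifest", "run_summary"]


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration; defaults fill missing keys.

    Unknown keys warn rather than fail; invariant violations raise
    :class:`~mitosim.params.ConfigError` naming the offending key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config.to_dict()
    d["mitochondrion"] = d.pop("mito")
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


@dataclasses.dataclass
class RunManifest:
    """Reproducibility metadata written next to every run's outputs."""

    config_hash: str
    seed: int
    preset: str = ""
    version: str = __version__
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_summary(traj: TrajectorySet, aged_threshold_nM: float = CONSTANTS.ros_aged_threshold_nM) -> dict:
    """Endpoint summary of one run (JSON-serializable)."""
    surv = survival_and_state_curves(traj)
    crossings = [
        time_to_ros_threshold(traj.time, traj.ros[:, c], aged_threshold_nM)
        for c in range(traj.n_cells)
    ]
    crossed = [c for c in crossings if c is not None]
    het = traj.heteroplasmy_percent_per_cell()
    alive_end = traj.alive[-1]
    return {
        "n_cells": int(traj.n_cells),
        "t_end_min": float(traj.time[-1]),
        "baseline_ros_nM": baseline_ros(traj),
        "final_tissue_ros_nM": float(traj.tissue_mean("ros")[-1]),
        "final_tissue_atp_mM": float(traj.tissue_mean("atp")[-1]),
        "final_tissue_nad_rel": float(traj.tissue_mean("nad")[-1]),
        "final_mito_count_mean": float(traj.tissue_mean("count")[-1]),
        "final_heteroplasmy_pct_mean": float(het[-1][alive_end].mean()) if alive_end.any() else None,
        "final_survival_fraction": float(surv["survival_fraction"].iloc[-1]),
        "n_cells_crossing_aged_threshold": len(crossed),
        "aged_threshold_nM": float(aged_threshold_nM),
        "time_to_aged_threshold_min": {
            "median": float(np.median(crossed)) if crossed else None,
            "per_cell": [None if c is None else float(c) for c in crossings],
        },
        "survival_curve": {
            "time_min": [float(t) for t in surv["time_min"]],
            "survival_fraction": [float(s) for s in surv["survival_fraction"]],
        },
    }


def write_outputs(
    traj: TrajectorySet,
    manifest: RunManifest,
    outdir: str | Path,
    float_format: str = "%.10g",
) -> dict[str, Path]:
    """Write cells.csv, tissue.csv, summary.json and manifest.json.

    Re-running the same seed and configuration produces byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "cells.csv",
        "tissue": outdir / "tissue.csv",
        "summary": outdir / "summary.json",
        "manifest": outdir / "manifest.json",
    }
    traj.to_cells_dataframe().to_csv(paths["cells"], index=False, float_format=float_format, lineterminator="\n")
    traj.to_tissue_dataframe().to_csv(paths["tissue"], index=False, float_format=float_format, lineterminator="\n")
    paths["summary"].write_text(json.dumps(run_summary(traj), indent=1, sort_keys=True))
    manifest.outputs = {k: str(v) for k, v in paths.items() if k != "manifest"}
    paths["manifest"].write_text(json.dumps(manifest.to_dict(), indent=1, sort_keys=True))
    return paths
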