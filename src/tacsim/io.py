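"""Configuration files, snapshot persistence, rendering and run manifests.

Config files are YAML with nested sections (``simulation``, ``mechanics``,
``ecm``, ``thresholds``, ``metrics``); every unspecified key takes the
model's calibrated default, so an empty file is a valid configuration.
Snapshots are written as plain-text tables (cells as CSV, the grid as a
node table) plus a JSON metrics/metadata record, all round-trippable.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecm import RemodelParams, read_grid, write_grid_hdf5, write_grid_text
from .engine import SimulationConfig, SnapshotRecord
from .lifecycle import Cell, CellState, Thresholds
from .mechanics import MechanicsParams
from .metrics import MetricsConfig, TACSReport

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "RunManifest",
    "write_snapshot",
    "read_snapshot",
    "render",
]


class ConfigError(ValueError):
    """Raised with every validation violation listed, one per line."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


_SIMULATION_KEYS = {
    "scenario", "seed", "dt_s", "duration_h", "snapshot_interval_h", "domain",
    "spacing_um", "cell_radius_um", "maturation_h", "sense_radius_um",
    "persistent_direction", "initial_cells", "initial_age", "initial_state",
    "stiffen_batch", "compute_metrics",
}
_MECHANICS_KEYS = {"f_rep", "f_adh", "r_adh", "nu", "g_mag", "alpha", "g_star"}
_ECM_KEYS = {"beta", "delta_xi", "xi_max", "xi0"}
_THRESHOLD_KEYS = {"xi_div", "xi_mot"}
_METRICS_KEYS = {
    "shell_width_um", "n_sectors", "index_threshold", "order_gate",
    "order_alpha", "min_nodes", "concave_ratio",
}


def load_config(path) -> SimulationConfig:
    """Load and fully validate a YAML configuration.

    Unknown keys and out-of-range values are all collected and reported in
    a single :class:`ConfigError`.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError([f"top level must be a mapping, got {type(data).__name__}"])
    violations = []
    known_sections = {"simulation", "mechanics", "ecm", "thresholds", "metrics"}
    for key in data:
        if key not in known_sections:
            violations.append(f"unknown section {key!r}")
    sections = {}
    for name, allowed in (
        ("simulation", _SIMULATION_KEYS),
        ("mechanics", _MECHANICS_KEYS),
        ("ecm", _ECM_KEYS),
        ("thresholds", _THRESHOLD_KEYS),
        ("metrics", _METRICS_KEYS),
    ):
        sec = data.get(name) or {}
        if not isinstance(sec, dict):
            violations.append(f"section {name!r} must be a mapping")
            sec = {}
        for key in sec:
            if key not in allowed:
                violations.append(f"unknown key {name}.{key}")
        sections[name] = sec
    sim = sections["simulation"]
    mech = sections["mechanics"]
    ecm_s = sections["ecm"]
    thr = sections["thresholds"]
    met = sections["metrics"]

    def build(factory, label, **kwargs):
        try:
            return factory(**kwargs)
        except ValueError as exc:
            violations.append(f"{label}: {exc}")
            return factory()

    mechanics = build(
        MechanicsParams, "mechanics",
        f_rep=float(mech.get("f_rep", 50.0)),
        f_adh=float(mech.get("f_adh", 5.0)),
        r_adh=float(mech.get("r_adh", 16.0)),
        nu=float(mech.get("nu", 250.0)),
        g_mag=float(mech.get("g_mag", 0.08)),
        alpha=float(mech.get("alpha", 1.0)),
        g_star=mech.get("g_star"),
    )
    remodel = build(
        RemodelParams, "ecm",
        beta=float(ecm_s.get("beta", 0.5)),
        delta_xi=float(ecm_s.get("delta_xi", 4e-5)),
        xi_max=float(ecm_s.get("xi_max", 500.0)),
        xi0=float(ecm_s.get("xi0", 1.0)),
    )
    thresholds = build(
        Thresholds, "thresholds",
        xi_div=float(thr.get("xi_div", 30.0)),
        xi_mot=float(thr.get("xi_mot", 50.0)),
    )
    metrics = MetricsConfig(
        shell_width=float(met.get("shell_width_um", 12.0)),
        n_sectors=int(met.get("n_sectors", 12)),
        index_threshold=float(met.get("index_threshold", 0.75)),
        order_gate=float(met.get("order_gate", 0.5)),
        order_alpha=float(met.get("order_alpha", 1e-3)),
        min_nodes=int(met.get("min_nodes", 8)),
        concave_ratio=float(met.get("concave_ratio", 0.5)),
    )
    domain = sim.get("domain", [400.0, 400.0])
    pd_rule = sim.get("persistent_direction", "radial")
    if isinstance(pd_rule, (list, tuple)):
        pd_rule = np.asarray(pd_rule, float)
    init_cells = sim.get("initial_cells", "single")
    if isinstance(init_cells, (list, tuple)):
        init_cells = np.asarray(init_cells, float)
    try:
        config = SimulationConfig(
            scenario=sim.get("scenario", "transition"),
            dt=float(sim.get("dt_s", 2.5)),
            duration_h=float(sim.get("duration_h", 144.0)),
            domain=tuple(float(v) for v in domain),
            spacing=float(sim.get("spacing_um", 4.0)),
            cell_radius=float(sim.get("cell_radius_um", 8.0)),
            maturation_h=float(sim.get("maturation_h", 20.0)),
            mechanics=mechanics,
            remodel=remodel,
            thresholds=thresholds,
            metrics=metrics,
            seed=int(sim.get("seed", 0)),
            snapshot_interval_h=float(sim.get("snapshot_interval_h", 24.0)),
            persistent_direction=pd_rule,
            sense_radius=(
                None
                if sim.get("sense_radius_um") is None
                else float(sim["sense_radius_um"])
            ),
            initial_cells=init_cells,
            initial_age=sim.get("initial_age", "zero"),
            initial_state=sim.get("initial_state", "proliferative"),
            stiffen_batch=int(sim.get("stiffen_batch", 1)),
            compute_metrics=bool(sim.get("compute_metrics", True)),
        )
    except ValueError as exc:
        violations.append(f"simulation: {exc}")
        config = None
    if violations:
        raise ConfigError(violations)
    return config


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as YAML; ``load_config`` restores it exactly."""
    mech = config.mechanics
    pd_rule = config.persistent_direction
    if isinstance(pd_rule, np.ndarray):
        pd_rule = [float(v) for v in pd_rule]
    init_cells = config.initial_cells
    if isinstance(init_cells, np.ndarray):
        init_cells = [[float(v) for v in row] for row in np.atleast_2d(init_cells)]
    data = {
        "simulation": {
            "scenario": config.scenario,
            "seed": config.seed,
            "dt_s": config.dt,
            "duration_h": config.duration_h,
            "snapshot_interval_h": config.snapshot_interval_h,
            "domain": [float(v) for v in config.domain],
            "spacing_um": config.spacing,
            "cell_radius_um": config.cell_radius,
            "maturation_h": config.maturation_h,
            "sense_radius_um": config.sense_radius,
            "persistent_direction": pd_rule,
            "initial_cells": init_cells,
            "initial_age": config.initial_age,
            "initial_state": config.initial_state,
            "stiffen_batch": config.stiffen_batch,
            "compute_metrics": config.compute_metrics,
        },
        "mechanics": {
            "f_rep": mech.f_rep,
            "f_adh": mech.f_adh,
            "r_adh": mech.r_adh,
            "nu": mech.nu,
            "g_mag": mech.g_mag,
            "alpha": mech.alpha,
            "g_star": (
                None
                if mech.g_star is None
                else [float(v) for v in mech.g_star]
            ),
        },
        "ecm": {
            "beta": config.remodel.beta,
            "delta_xi": config.remodel.delta_xi,
            "xi_max": config.remodel.xi_max,
            "xi0": config.remodel.xi0,
        },
        "thresholds": {
            "xi_div": float(config.thresholds.xi_div),
            "xi_mot": float(config.thresholds.xi_mot),
        },
        "metrics": {
            "shell_width_um": config.metrics.shell_width,
            "n_sectors": config.metrics.n_sectors,
            "index_threshold": config.metrics.index_threshold,
            "order_gate": config.metrics.order_gate,
            "order_alpha": config.metrics.order_alpha,
            "min_nodes": config.metrics.min_nodes,
            "concave_ratio": config.metrics.concave_ratio,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class RunManifest:
    """Record of a run's outputs; one entry per snapshot written."""

    seed: int
    version: str = __version__
    created: float = field(default_factory=time.time)
    config: dict = field(default_factory=dict)
    entries: list = field(default_factory=list)

    def add(self, entry: dict) -> None:
        for p in entry.values():
            if isinstance(p, str) and not Path(p).exists():
                raise FileNotFoundError(f"manifest entry references missing file {p}")
        self.entries.append(entry)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


_STATE_NAMES = {s: s.name.lower() for s in CellState}


def write_snapshot(
    record: SnapshotRecord,
    directory,
    basename: str | None = None,
    hdf5: bool = False,
) -> dict:
    """Persist one snapshot; returns the manifest entry (name -> path).

    Cells go to CSV (id, x, y, age, maturation_age, state), the grid to the
    text node table (optionally also the HDF5 container) and metrics plus
    metadata to JSON.  Field ordering is deterministic.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if basename is None:
        basename = f"snapshot_{record.step:08d}"
    cells_path = directory / f"{basename}_cells.csv"
    grid_path = directory / f"{basename}_grid.txt"
    meta_path = directory / f"{basename}_meta.json"
    df = pd.DataFrame(
        {
            "id": [c.identity for c in record.cells],
            "x": [float(c.position[0]) for c in record.cells],
            "y": [float(c.position[1]) for c in record.cells],
            "age": [c.age for c in record.cells],
            "maturation_age": [c.maturation_age for c in record.cells],
            "state": [_STATE_NAMES[c.state] for c in record.cells],
        }
    )
    df.to_csv(cells_path, index=False, float_format="%.17g")
    write_grid_text(record.grid, grid_path, step=record.step)
    entry = {
        "cells": str(cells_path),
        "grid": str(grid_path),
        "meta": str(meta_path),
    }
    if hdf5:
        h5_path = directory / f"{basename}_grid.h5"
        write_grid_hdf5(record.grid, h5_path, step=record.step)
        entry["grid_hdf5"] = str(h5_path)
    meta = {
        "time_h": record.time_h,
        "step": record.step,
        "n_cells": len(record.cells),
        "metrics": (
            None if record.metrics is None else dataclasses.asdict(record.metrics)
        ),
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return entry


def read_snapshot(directory, basename: str) -> SnapshotRecord:
    """Reload a snapshot written by :func:`write_snapshot`."""
    directory = Path(directory)
    df = pd.read_csv(directory / f"{basename}_cells.csv")
    meta = json.loads((directory / f"{basename}_meta.json").read_text())
    grid = read_grid(directory / f"{basename}_grid.txt")
    name_to_state = {v: k for k, v in _STATE_NAMES.items()}
    cells = [
        Cell(
            position=np.array([row.x, row.y]),
            age=float(row.age),
            maturation_age=float(row.maturation_age),
            state=name_to_state[row.state],
            identity=int(row.id),
        )
        for row in df.itertuples()
    ]
    metrics = None
    if meta.get("metrics") is not None:
        metrics = TACSReport(**meta["metrics"])
    return SnapshotRecord(
        time_h=float(meta["time_h"]),
        step=int(meta["step"]),
        cells=cells,
        grid=grid,
        metrics=metrics,
    )


def render(record: SnapshotRecord, path, segment_scale: float = 0.8) -> None:
    """Draw the snapshot: one short line segment per node along the fibril
    orientation, darker for stiffer fibrils, cells as filled circles colored
    by state."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    grid = record.grid
    coords = grid.node_coords().reshape(-1, 2)
    h = grid.orientation.reshape(-1, 2)
    xi = grid.stiffness.reshape(-1)
    half = 0.5 * segment_scale * grid.spacing * h
    segs = np.stack([coords - half, coords + half], axis=1)
    # darkness proportional to stiffness (log scale: xi spans 1..500 sigma)
    shade = np.log1p(np.maximum(xi, 0.0))
    shade = shade / max(shade.max(), 1e-12)
    colors = np.zeros((len(xi), 4))
    colors[:, 3] = 0.25 + 0.75 * shade  # alpha encodes darkness on white
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.add_collection(LineCollection(segs, colors=colors, linewidths=0.7))
    palette = {
        CellState.PROLIFERATIVE: "tab:green",
        CellState.GROWTH_ARRESTED: "tab:orange",
        CellState.MIGRATING: "tab:red",
    }
    for c in record.cells:
        ax.add_patch(
            plt.Circle(c.position, c.radius, color=palette[c.state], alpha=0.6)
        )
    nx, ny = grid.shape
    ax.set_xlim(grid.origin[0] - grid.spacing, grid.origin[0] + grid.spacing * nx)
    ax.set_ylim(grid.origin[1] - grid.spacing, grid.origin[1] + grid.spacing * ny)
    ax.set_aspect("equal")
    ax.set_title(f"t = {record.time_h:.1f} h, {len(record.cells)} cells")
    fig.savefig(path, dpi=120)
    plt.close(fig)
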