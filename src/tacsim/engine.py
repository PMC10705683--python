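"""Time stepping and scenario orchestration.

Each time step executes, in order: (1) lifecycle -- aging, stiffness
sensing, state decisions, divisions; (2) force assembly from current
positions; (3) the overdamped position update; (4) ECM remodeling driven by
this step's forces and movements.  Remodeling distinguishes

* **pushers**: non-migrating cells currently overlapping a neighbor (i.e.
  passively relocated by a repulsive force).  They align fibrils
  perpendicular to the force moving them, stiffen the surrounding annuli
  and displace (redistribute outward) the fibrils under their body.
* **pullers**: migrating cells.  They align fibrils parallel to their
  motility direction and stiffen the fibrils they pull on.

State decisions use the cumulative stiffness sensed within the configured
``sense_radius``.  The engine's default is ``R + dx`` (12 um): on the 4-um
grid that disk holds exactly 29 nodes, so unremodeled tissue (1 sigma per
node) sums to 29 sigma -- just below the 30-sigma growth-arrest threshold.
This is the geometry under which the calibrated thresholds (30/50 sigma)
produce the documented growth -> arrest -> migration sequence; a 16-um disk
holds 49 nodes and would arrest every cell at birth.  See docs/methods.md.

Runs are bitwise deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ecm as _ecm
from .ecm import ECMGrid, RemodelParams, init_random_field
from .lifecycle import (
    MATURATION_SPREAD,
    OVERCROWDING_LIMIT,
    Cell,
    CellState,
    Thresholds,
    try_divide,
)
from .mechanics import (
    MAX_ADHESIVE_NEIGHBORS,
    NEIGHBOR_RADIUS_FACTOR,
    MechanicsParams,
    _tiebreak_direction,
)
from .metrics import MetricsConfig, TACSReport, classify_regions, colony_boundary, nematic_order

__all__ = [
    "SimulationConfig",
    "SnapshotRecord",
    "scenario_config",
    "regime_config",
    "run",
    "run_sweep",
    "snapshot_digest",
]

logger = logging.getLogger("tacsim")

_EPS = 1e-12

#: A cell counts as "being pushed" (and hence remodels the ECM) only when it
#: overlaps a neighbor by more than this length (um).  The Hookean force
#: itself keeps its exact nominal support; the tolerance only keeps
#: floating-point noise at exact contact spacing from triggering fibril
#: capture with forces of order 1e-13.
OVERLAP_TOL = 1e-9

SCENARIOS = ("single_cell", "tacs1", "tacs2", "tacs3", "transition", "sweep")


@dataclass
class SimulationConfig:
    """Complete, validated description of one simulation run."""

    scenario: str = "transition"
    dt: float = 2.5  # s
    duration_h: float = 144.0
    domain: tuple[float, float] = (400.0, 400.0)  # um
    spacing: float = 4.0  # um
    cell_radius: float = 8.0  # um
    maturation_h: float = 20.0  # lineage base maturation age
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    remodel: RemodelParams = field(default_factory=RemodelParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0
    snapshot_interval_h: float = 24.0
    #: "radial" (outward from the domain center) or a fixed 2-vector.
    persistent_direction: object = "radial"
    #: Sensing radius for state decisions; None -> cell_radius + spacing.
    sense_radius: float | None = None
    #: "single", "hex19", "none", or an explicit (k, 2) array of positions.
    initial_cells: object = "single"
    initial_age: str = "zero"  # "zero" | "uniform"
    initial_state: str = "proliferative"  # "proliferative" | "migrating"
    #: Fast integration: apply stiffening every k steps with k*delta_xi
    #: (guarded by a displacement limit).  Must be 1 for reference runs.
    stiffen_batch: int = 1
    compute_metrics: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.dt <= 0.0:
            raise ValueError("dt must be > 0")
        if self.duration_h < 0.0:
            raise ValueError("duration must be >= 0")
        if self.snapshot_interval_h <= 0.0:
            raise ValueError("snapshot interval must be > 0")
        if self.spacing <= 0.0:
            raise ValueError("grid spacing must be > 0")
        if self.stiffen_batch < 1:
            raise ValueError("stiffen_batch must be >= 1")

    @property
    def sense_radius_value(self) -> float:
        return (
            self.cell_radius + self.spacing
            if self.sense_radius is None
            else self.sense_radius
        )


@dataclass
class SnapshotRecord:
    time_h: float
    step: int
    cells: list
    grid: ECMGrid
    metrics: TACSReport | None = None
    sensed: np.ndarray | None = None


def scenario_config(name: str, **overrides) -> SimulationConfig:
    """Build the canonical configuration for a named scenario.

    ``single_cell``: one permanently migrating cell headed for the top-left
    corner (alpha=1, beta=0.75).  ``tacs1``: cell-free random field.
    ``tacs2``: growing colony, thresholds disabled (beta=0.5).  ``tacs3``:
    invading cohort migrating left (alpha=1, beta=0.75).  ``transition``:
    the full growth-arrest-migration run (thresholds 30/50 sigma, beta=0.5,
    alpha=1, radial persistent direction, single centered cell).
    """
    presets: dict[str, dict] = {
        "single_cell": dict(
            scenario="single_cell",
            domain=(160.0, 160.0),
            duration_h=12.0,
            snapshot_interval_h=6.0,
            initial_cells=np.array([[120.0, 40.0]]),
            initial_state="migrating",
            mechanics=MechanicsParams(alpha=1.0, g_star=np.array([-1.0, 1.0])),
            remodel=RemodelParams(beta=0.75),
            thresholds=Thresholds(xi_div=np.inf, xi_mot=np.inf),
            persistent_direction=np.array([-1.0, 1.0]) / np.sqrt(2.0),
            compute_metrics=False,
        ),
        "tacs1": dict(
            scenario="tacs1",
            duration_h=0.0,
            initial_cells="none",
        ),
        "tacs2": dict(
            scenario="tacs2",
            duration_h=144.0,
            initial_cells="single",
            initial_age="uniform",
            remodel=RemodelParams(beta=0.5),
            thresholds=Thresholds(xi_div=np.inf, xi_mot=np.inf),
        ),
        "tacs3": dict(
            scenario="tacs3",
            duration_h=72.0,
            initial_cells="hex19",
            initial_state="migrating",
            mechanics=MechanicsParams(alpha=1.0, g_star=np.array([-1.0, 0.0])),
            remodel=RemodelParams(beta=0.75),
            thresholds=Thresholds(xi_div=np.inf, xi_mot=np.inf),
            persistent_direction=np.array([-1.0, 0.0]),
        ),
        "transition": dict(
            scenario="transition",
            duration_h=144.0,
            initial_cells="single",
            mechanics=MechanicsParams(alpha=1.0),
            remodel=RemodelParams(beta=0.5),
            thresholds=Thresholds(xi_div=30.0, xi_mot=50.0),
            persistent_direction="radial",
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    kwargs = presets[name]
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


#: Threshold pairs (xi_div, xi_mot) for the scaled 2-day regime runs on a
#: 200x200-um domain, chosen from the structure of the threshold-sweep
#: chart: an arrest threshold below the 29-sigma neighborhood baseline
#: suppresses everything; an unreachable motility threshold yields a pure
#: colony; a motility threshold below baseline turns every cell motile; the
#: calibrated pair (30, 50) lets all three signatures coexist.
REGIMES: dict[str, tuple[float, float]] = {
    "suppressed": (10.0, 1e9),
    "colony": (200.0, 1e9),
    "invasive": (200.0, 25.0),
    "coexist": (30.0, 50.0),
}


def regime_config(regime: str, seed: int = 0, duration_h: float = 48.0) -> SimulationConfig:
    """Scaled-down study condition for one threshold regime.

    All regimes share a 200x200-um domain and the same initial condition: a
    19-cell hexagonally packed colony at exact contact spacing (zero net
    force, so a fully arrested colony stays bitwise static), with ages
    staggered uniformly over a maturation period.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    xi_div, xi_mot = REGIMES[regime]
    return scenario_config(
        "transition",
        domain=(200.0, 200.0),
        duration_h=duration_h,
        snapshot_interval_h=12.0,
        initial_cells="hex19",
        initial_age="uniform",
        thresholds=Thresholds(xi_div=xi_div, xi_mot=xi_mot),
        seed=seed,
    )


def _hex_cluster(center: np.ndarray, spacing: float, rings: int = 2) -> np.ndarray:
    pts = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if max(abs(q), abs(r), abs(q + r)) <= rings:
                pts.append(
                    [
                        center[0] + spacing * (q + 0.5 * r),
                        center[1] + spacing * (np.sqrt(3.0) / 2.0) * r,
                    ]
                )
    return np.asarray(pts)


class _Simulation:
    """Struct-of-arrays state for one run; mirrors the scalar operations
    exactly (equivalence is asserted in the test suite)."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        w, h = config.domain
        dx = config.spacing
        nx, ny = int(round(w / dx)) + 1, int(round(h / dx)) + 1
        # RNG order: field first, then maturation ages, then initial ages
        self.grid = init_random_field(
            (nx, ny), dx, xi0=config.remodel.xi0, rng=self.rng
        )
        center = np.array([w / 2.0, h / 2.0])
        init = config.initial_cells
        if isinstance(init, str):
            if init == "single":
                pos = center[None, :]
            elif init == "hex19":
                pos = _hex_cluster(center, 2.0 * config.cell_radius)
            elif init == "none":
                pos = np.zeros((0, 2))
            else:
                raise ValueError(f"unknown initial_cells {init!r}")
        else:
            pos = np.atleast_2d(np.asarray(init, float))
        k = len(pos)
        self.pos = pos.astype(float).copy()
        self.mat = config.maturation_h * (
            1.0 + self.rng.uniform(-MATURATION_SPREAD, MATURATION_SPREAD, size=k)
        )
        if config.initial_age == "uniform":
            self.age = self.rng.uniform(0.0, self.mat)
        elif config.initial_age == "zero":
            self.age = np.zeros(k)
        else:
            raise ValueError(f"unknown initial_age {config.initial_age!r}")
        state0 = (
            CellState.MIGRATING
            if config.initial_state == "migrating"
            else CellState.PROLIFERATIVE
        )
        self.state = np.full(k, int(state0), dtype=np.int8)
        self.ids = np.arange(k, dtype=np.int64)
        self._next_id = k
        self.time_h = 0.0
        self.step_index = 0
        self.sensed = np.zeros(k)
        # footprint of the colony of origin: the radial reference for TACS
        # classification once every cell has migrated away
        if k:
            c0 = self.pos.mean(axis=0)
            r0 = float(np.linalg.norm(self.pos - c0, axis=1).max()) + config.cell_radius
            self._initial_footprint = (c0, r0)
        else:
            self._initial_footprint = None
        self._batch_pending = 0
        self._batch_anchor = self.pos.copy()
        self._stiffen_jobs: list = []

    # -- per-step pieces ---------------------------------------------------

    def _sense(self) -> np.ndarray:
        if len(self.pos) == 0:
            return np.zeros(0)
        radius = self.cfg.sense_radius_value
        flat, d2, valid = _ecm._windows(self.grid, self.pos, radius)
        mask = valid & (d2 <= radius * radius)
        xi = self.grid.stiffness.reshape(-1)
        vals = np.where(mask, xi[flat], 0.0).sum(axis=1)
        return vals

    def _neighbor_counts(self, d: np.ndarray) -> np.ndarray:
        # d comes from _pairwise with an inf diagonal, so self is excluded
        within = d <= NEIGHBOR_RADIUS_FACTOR * self.cfg.cell_radius
        return within.sum(axis=1)

    def _pairwise(self):
        diff = self.pos[:, None, :] - self.pos[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        return diff, d

    def _lifecycle(self) -> None:
        cfg = self.cfg
        dt_h = cfg.dt / 3600.0
        self.age += dt_h
        self.sensed = self._sense()
        thr = cfg.thresholds
        # state map; migration absorbing
        mig = self.state == int(CellState.MIGRATING)
        new = np.where(
            self.sensed > thr.xi_mot,
            int(CellState.MIGRATING),
            np.where(
                self.sensed > thr.xi_div,
                int(CellState.GROWTH_ARRESTED),
                int(CellState.PROLIFERATIVE),
            ),
        ).astype(np.int8)
        self.state = np.where(mig, np.int8(int(CellState.MIGRATING)), new)
        if len(self.pos) == 0:
            return
        _, d = self._pairwise()
        counts = self._neighbor_counts(d)
        eligible = np.flatnonzero(
            (self.state == int(CellState.PROLIFERATIVE))
            & (self.age >= self.mat)
            & (counts <= OVERCROWDING_LIMIT)
        )
        if eligible.size == 0:
            return
        add_pos, add_age, add_mat, add_ids = [], [], [], []
        for i in eligible:
            mother = Cell(
                position=self.pos[i],
                age=self.age[i],
                maturation_age=self.mat[i],
                radius=self.cfg.cell_radius,
                identity=int(self.ids[i]),
                maturation_base=self.cfg.maturation_h,
            )
            daughters = try_divide(
                mother, int(counts[i]), self.rng, next_identity=self._next_id
            )
            self._next_id += 2
            for dcell in daughters:
                add_pos.append(dcell.position)
                add_age.append(dcell.age)
                add_mat.append(dcell.maturation_age)
                add_ids.append(dcell.identity)
        keep = np.ones(len(self.pos), dtype=bool)
        keep[eligible] = False
        self.pos = np.vstack([self.pos[keep], np.asarray(add_pos)])
        self.age = np.concatenate([self.age[keep], add_age])
        self.mat = np.concatenate([self.mat[keep], add_mat])
        self.ids = np.concatenate([self.ids[keep], add_ids])
        self.state = np.concatenate(
            [self.state[keep], np.zeros(len(add_ids), dtype=np.int8)]
        )
        self.sensed = np.concatenate([self.sensed[keep], np.zeros(len(add_ids))])

    def _forces(self):
        """Vectorized pairwise repulsion/adhesion; returns (F, overlap)."""
        n = len(self.pos)
        cfg = self.cfg
        mech = cfg.mechanics
        if n == 0:
            return np.zeros((0, 2)), np.zeros(0, dtype=bool)
        diff, d = self._pairwise()
        R = cfg.cell_radius
        rep_pair = d < 2.0 * R
        coincident = d < _EPS
        safe_d = np.where(d < _EPS, 1.0, d)
        unit = diff / safe_d[..., None]
        F = np.einsum(
            "ij,ijk->ik", np.where(rep_pair, mech.f_rep * (2.0 * R - d), 0.0), unit
        )
        if coincident.any():  # rare: resolve with the documented tie-break
            for i, j in zip(*np.nonzero(coincident)):
                u = _tiebreak_direction(int(self.ids[i]), int(self.ids[j]))
                if self.ids[i] > self.ids[j]:
                    u = -u
                F[i] += mech.f_rep * 2.0 * R * u
        counts = self._neighbor_counts(d)
        adh_ok = counts <= MAX_ADHESIVE_NEIGHBORS
        adh_pair = (d > mech.r_adh) & (d < 2.0 * mech.r_adh)
        F_adh = np.einsum(
            "ij,ijk->ik", np.where(adh_pair, mech.f_adh * (mech.r_adh - d), 0.0), unit
        )
        F += np.where(adh_ok[:, None], F_adh, 0.0)
        pushed_pair = d < 2.0 * R - OVERLAP_TOL
        overlap = pushed_pair.any(axis=1) | coincident.any(axis=1)
        return F, overlap

    def _persistent_direction(self, idx: np.ndarray) -> np.ndarray:
        rule = self.cfg.persistent_direction
        if isinstance(rule, str) and rule == "radial":
            center = np.asarray(self.cfg.domain, float) / 2.0
            v = self.pos[idx] - center
            n = np.linalg.norm(v, axis=-1)
            out = np.where(
                n[:, None] > _EPS, v / np.where(n[:, None] > _EPS, n[:, None], 1.0),
                np.array([1.0, 0.0]),
            )
            return out
        v = np.asarray(rule, float)
        return np.tile(v / np.linalg.norm(v), (len(idx), 1))

    def _motility(self):
        """Motility forces and pull directions for migrating cells."""
        n = len(self.pos)
        G = np.zeros((n, 2))
        mig = np.flatnonzero(self.state == int(CellState.MIGRATING))
        if mig.size == 0:
            return G, mig, np.zeros((0, 2))
        cfg = self.cfg
        alpha = cfg.mechanics.alpha
        gstar = self._persistent_direction(mig)
        if alpha >= 1.0:
            gtilde = gstar
        else:
            radius = cfg.cell_radius + 2.0 * cfg.spacing
            flat, d2, valid = _ecm._windows(self.grid, self.pos[mig], radius)
            mask = valid & (d2 <= radius * radius)
            H = self.grid.orientation.reshape(-1, 2)
            h = H[flat]
            sign = np.where(np.einsum("kmi,ki->km", h, gstar) < 0.0, -1.0, 1.0)
            contrib = np.where(mask[..., None], sign[..., None] * h, 0.0)
            ni = mask.sum(axis=1)
            mean_h = contrib.sum(axis=1) / np.where(ni > 0, ni, 1)[:, None]
            gtilde = alpha * gstar + (1.0 - alpha) * np.where(
                ni[:, None] > 0, mean_h, 0.0
            )
        norm = np.linalg.norm(gtilde, axis=-1)
        ok = norm > _EPS
        unit = np.where(ok[:, None], gtilde / np.where(ok, norm, 1.0)[:, None], 0.0)
        G[mig] = cfg.mechanics.g_mag * unit
        return G, mig[ok], unit[ok]

    def _remodel(self, F: np.ndarray, overlap: np.ndarray, pull_idx, pull_dir) -> None:
        cfg = self.cfg
        mig = self.state == int(CellState.MIGRATING)
        pushing = overlap & ~mig
        push_idx = np.flatnonzero(pushing)
        # orientation: pushers align fibrils perpendicular to the force
        # moving them, pullers parallel to their motility direction
        fmag = np.linalg.norm(F[push_idx], axis=-1)
        has_dir = fmag > _EPS
        fdir = F[push_idx[has_dir]] / fmag[has_dir, None]
        perp = np.stack([-fdir[:, 1], fdir[:, 0]], axis=-1)
        _ecm._remodel_orientation_inplace(
            self.grid,
            self.pos[push_idx[has_dir]],
            perp,
            self.pos[pull_idx],
            pull_dir,
            cfg.cell_radius,
            cfg.remodel.beta,
        )
        # stiffening, optionally batched over k quiet steps
        self._stiffen_jobs.append((self.pos[pull_idx].copy(), self.pos[push_idx].copy()))
        self._batch_pending += 1
        k = cfg.stiffen_batch
        moved = (
            np.inf
            if len(self.pos) != len(self._batch_anchor)
            else float(np.abs(self.pos - self._batch_anchor).max(initial=0.0))
        )
        if self._batch_pending >= k or moved >= cfg.spacing / 4.0:
            scale = float(self._batch_pending)
            pull_pos, push_pos = self._stiffen_jobs[-1]
            if len(pull_pos):
                _ecm._stiffen_migration_inplace(
                    self.grid, pull_pos, cfg.cell_radius, cfg.remodel,
                    delta_xi=cfg.remodel.delta_xi * scale,
                )
            if len(push_pos):
                _ecm._stiffen_growth_inplace(
                    self.grid, push_pos, cfg.cell_radius, cfg.remodel,
                    delta_xi=cfg.remodel.delta_xi * scale,
                )
            self._stiffen_jobs.clear()
            self._batch_pending = 0
            self._batch_anchor = self.pos.copy()

    def step(self) -> None:
        cfg = self.cfg
        self._lifecycle()
        F, overlap = self._forces()
        G, pull_idx, pull_dir = self._motility()
        total = F + G
        if not np.all(np.isfinite(total)):
            raise RuntimeError(f"non-finite force at step {self.step_index}")
        self.pos = self.pos + (cfg.dt / cfg.mechanics.nu) * total
        np.clip(self.pos, [0.0, 0.0], list(cfg.domain), out=self.pos)
        if not np.all(np.isfinite(self.pos)):
            raise RuntimeError(f"non-finite cell position at step {self.step_index}")
        self._remodel(F, overlap, pull_idx, pull_dir)
        self.step_index += 1
        self.time_h += cfg.dt / 3600.0

    # -- snapshots ---------------------------------------------------------

    def cells(self) -> list[Cell]:
        return [
            Cell(
                position=self.pos[i].copy(),
                age=float(self.age[i]),
                maturation_age=float(self.mat[i]),
                radius=self.cfg.cell_radius,
                state=CellState(int(self.state[i])),
                identity=int(self.ids[i]),
                maturation_base=self.cfg.maturation_h,
            )
            for i in range(len(self.pos))
        ]

    def snapshot(self) -> SnapshotRecord:
        cells = self.cells()
        metrics = None
        if self.cfg.compute_metrics:
            if cells:
                # the colony proper is the coherent (non-migrating) cluster;
                # migrating cohorts are invasion fronts radiating from it and
                # must not inflate the boundary the shell is measured against.
                # When every cell has migrated there is no coherent colony
                # left; the radial corridors are then referenced to the
                # footprint of the colony of origin (a hull of scattered
                # runners would put boundary edges obliquely alongside
                # corridors and misread radial alignment as tangential).
                colony = [c for c in cells if c.state is not CellState.MIGRATING]
                if len(colony) >= 3:
                    boundary = colony_boundary(
                        colony, concave_ratio=self.cfg.metrics.concave_ratio
                    )
                else:
                    # fewer than three resident cells is not a polygonal
                    # colony; reference the footprint of the colony of origin
                    from shapely.geometry import Point

                    c0, r0 = self._initial_footprint
                    boundary = Point(c0).buffer(r0, quad_segs=64)
                metrics = classify_regions(self.grid, boundary, self.cfg.metrics)
            else:
                metrics = TACSReport(
                    tangential_index=float("nan"),
                    radial_index=float("nan"),
                    nematic_order=nematic_order(self.grid.orientation.reshape(-1, 2)),
                    shell_width=self.cfg.metrics.shell_width,
                )
        return SnapshotRecord(
            time_h=self.time_h,
            step=self.step_index,
            cells=cells,
            grid=self.grid.copy(),
            metrics=metrics,
            sensed=self.sensed.copy(),
        )


def run(config: SimulationConfig) -> list[SnapshotRecord]:
    """Execute one simulation; snapshots at t=0, every configured interval,
    and the final time."""
    sim = _Simulation(config)
    n_steps = int(round(config.duration_h * 3600.0 / config.dt))
    snap_every = max(1, int(round(config.snapshot_interval_h * 3600.0 / config.dt)))
    records = [sim.snapshot()]
    for s in range(n_steps):
        sim.step()
        if sim.step_index % snap_every == 0 and sim.step_index < n_steps:
            records.append(sim.snapshot())
        if sim.step_index % 1000 == 0:
            logger.info(
                "step %d/%d t=%.2f h cells=%d",
                sim.step_index, n_steps, sim.time_h, len(sim.pos),
            )
    if n_steps > 0:
        records.append(sim.snapshot())
    return records


def run_sweep(base: SimulationConfig, xi_div_values, xi_mot_values):
    """One run per (xi_div, xi_mot) pair with otherwise identical config and
    seed.  Returns ``(reports, table)``: final-snapshot TACS reports keyed by
    threshold pair, and a chart-ready tidy DataFrame."""
    xi_div_values = list(xi_div_values)
    xi_mot_values = list(xi_mot_values)
    if not xi_div_values or not xi_mot_values:
        raise ValueError("threshold value lists must be non-empty")
    reports: dict[tuple[float, float], TACSReport] = {}
    rows = []
    for xd in xi_div_values:
        for xm in xi_mot_values:
            cfg = replace(base, thresholds=Thresholds(xi_div=xd, xi_mot=xm))
            final = run(cfg)[-1]
            rep = final.metrics
            reports[(xd, xm)] = rep
            states = [c.state for c in final.cells]
            rows.append(
                {
                    "xi_div": xd,
                    "xi_mot": xm,
                    "n_cells": len(final.cells),
                    "n_migrating": sum(s is CellState.MIGRATING for s in states),
                    "n_arrested": sum(s is CellState.GROWTH_ARRESTED for s in states),
                    "tangential_index": rep.tangential_index if rep else np.nan,
                    "radial_index": rep.radial_index if rep else np.nan,
                    "labels_present": (
                        "".join(str(v) for v in sorted(rep.labels_present))
                        if rep
                        else ""
                    ),
                }
            )
    return reports, pd.DataFrame(rows)


def snapshot_digest(record: SnapshotRecord) -> str:
    """SHA-256 over the full snapshot state; equal seeds must give equal
    digests (the determinism contract)."""
    h = hashlib.sha256()
    h.update(np.float64(record.time_h).tobytes())
    for c in record.cells:
        h.update(np.asarray(c.position, float).tobytes())
        h.update(np.float64(c.age).tobytes())
        h.update(np.float64(c.maturation_age).tobytes())
        h.update(np.int64(c.identity).tobytes())
        h.update(np.int8(int(c.state)).tobytes())
    h.update(record.grid.orientation.tobytes())
    h.update(record.grid.stiffness.tobytes())
    return h.hexdigest()
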