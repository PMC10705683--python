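"""Cell aging, division, overcrowding, stiffness sensing and state switching.

A cell is proliferative until the cumulative fibril stiffness it senses in
its neighborhood crosses the growth-arrest threshold ``xi_div``; above the
migration threshold ``xi_mot`` it becomes motile.  Migration is absorbing
for a run (the model shows no reversion), while growth arrest is reversible
in principle (stiffness never decays locally, so in practice arrested cells
either stay arrested or start migrating).  Overcrowding -- more than 12
cells within two cell diameters -- blocks division without changing state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .ecm import ECMGrid, _windows

__all__ = [
    "CellState",
    "Cell",
    "Thresholds",
    "SensedStiffness",
    "sense_stiffness",
    "decide_state",
    "try_divide",
    "OVERCROWDING_LIMIT",
    "MATURATION_SPREAD",
]

#: Division is blocked when more than this many cells sit within two cell
#: diameters of the mother.
OVERCROWDING_LIMIT = 12

#: Daughter maturation ages fluctuate uniformly within +/- this fraction of
#: the lineage base maturation age.
MATURATION_SPREAD = 0.15


class CellState(IntEnum):
    PROLIFERATIVE = 0
    GROWTH_ARRESTED = 1
    MIGRATING = 2


@dataclass
class Cell:
    """Off-lattice cell agent.

    ``maturation_base`` is the lineage's base maturation age (20 h by
    default); ``maturation_age`` is this cell's own value, within +/-15% of
    the base.
    """

    position: np.ndarray
    age: float = 0.0  # h
    maturation_age: float = 20.0  # h
    radius: float = 8.0  # um
    state: CellState = CellState.PROLIFERATIVE
    identity: int = 0
    maturation_base: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.age < 0.0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.maturation_base is None:
            self.maturation_base = self.maturation_age


@dataclass
class Thresholds:
    """Sensed-stiffness levels (sigma) switching cell behavior."""

    xi_div: float = 30.0
    xi_mot: float = 50.0

    def __post_init__(self) -> None:
        if self.xi_div < 0.0 or self.xi_mot < 0.0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class SensedStiffness:
    """Local cumulative fibril stiffness (sigma) sensed by one cell."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0.0:
            raise ValueError("sensed stiffness must be >= 0")


def sense_stiffness(cell: Cell, grid: ECMGrid, radius: float | None = None) -> SensedStiffness:
    """Sum of node stiffness within ``radius`` of the cell center.

    The default radius is ``R + 2*dx`` (the full contact-guidance
    neighborhood, the same disk the motility and push remodeling use);
    the simulation engine passes its configured sensing radius explicitly.
    """
    if radius is None:
        radius = cell.radius + 2.0 * grid.spacing
    flat, d2, valid = _windows(grid, np.asarray(cell.position, float)[None, :], radius)
    mask = (valid & (d2 <= radius * radius))[0]
    value = float(grid.stiffness.reshape(-1)[flat[0][mask]].sum())
    return SensedStiffness(value)


def decide_state(
    cell: Cell,
    sensed: SensedStiffness,
    neighbor_count_4R: int,
    thresholds: Thresholds,
) -> Cell:
    """Map sensed stiffness onto the behavioral state.

    ``Xi <= xi_div`` -> proliferative; ``xi_div < Xi <= xi_mot`` -> growth
    arrested; ``Xi > xi_mot`` -> migrating.  Migration, once entered, is
    absorbing.  Overcrowding blocks division elsewhere but never changes the
    state here.
    """
    if cell.state is CellState.MIGRATING:
        return cell
    if sensed.value > thresholds.xi_mot:
        new = CellState.MIGRATING
    elif sensed.value > thresholds.xi_div:
        new = CellState.GROWTH_ARRESTED
    else:
        new = CellState.PROLIFERATIVE
    return cell if new is cell.state else replace(cell, state=new)


def try_divide(
    cell: Cell,
    neighbor_count_4R: int,
    rng: np.random.Generator,
    next_identity: int | None = None,
):
    """Divide a mature, non-overcrowded proliferative cell.

    Returns an empty tuple (no division) or two daughters placed at
    ``X +/- 0.5*R*(cos t, sin t)`` for one uniform angle t, so the
    daughter-pair separation is exactly R.  Daughter ages are zero and
    their maturation ages are ``base * (1 + tau)`` with independent
    ``tau ~ U(-0.15, 0.15)``.

    RNG consumption order per division: t, tau1, tau2.  Daughter ids are
    ``2*i + 1`` and ``2*i + 2`` (binary lineage encoding) unless
    ``next_identity`` is given.
    """
    if cell.state is not CellState.PROLIFERATIVE:
        raise ValueError("try_divide requires a proliferative cell")
    if cell.age < cell.maturation_age or neighbor_count_4R > OVERCROWDING_LIMIT:
        return ()
    theta = rng.uniform(0.0, 2.0 * np.pi)
    tau1 = rng.uniform(-MATURATION_SPREAD, MATURATION_SPREAD)
    tau2 = rng.uniform(-MATURATION_SPREAD, MATURATION_SPREAD)
    offset = 0.5 * cell.radius * np.array([np.cos(theta), np.sin(theta)])
    base = cell.maturation_base
    if next_identity is None:
        id1, id2 = 2 * cell.identity + 1, 2 * cell.identity + 2
    else:
        id1, id2 = next_identity, next_identity + 1
    make = lambda pos, tau, ident: Cell(
        position=np.asarray(cell.position, float) + pos,
        age=0.0,
        maturation_age=base * (1.0 + tau),
        radius=cell.radius,
        state=CellState.PROLIFERATIVE,
        identity=ident,
        maturation_base=base,
    )
    return (make(offset, tau1, id1), make(-offset, tau2, id2))
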