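"""Cell-cell and motility forces, and overdamped position updates.

Cells are off-lattice circular agents of constant radius R.  Overlapping
cells repel with a Hookean force of stiffness ``f_rep``; cells with at most
five neighbors within two cell diameters adhere with a Hookean force of
stiffness ``f_adh`` and resting length ``r_adh``.  A migrating cell exerts a
motility force whose direction competes between a persistent direction
``g_star`` (weight ``alpha``) and contact guidance by the mean fibril
orientation around the cell (weight ``1 - alpha``).  Motion is inertia-free:
``dX/dt = (F + G) / nu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ecm import ECMGrid, _windows, _EPS

__all__ = [
    "MechanicsParams",
    "ForceVector",
    "repulsive_force",
    "adhesive_force",
    "total_interaction_force",
    "motility_force",
    "step_positions",
]

#: Radius multiple defining the "two cell diameters" neighborhood used for
#: both the adhesion eligibility gate and the overcrowding gate.
NEIGHBOR_RADIUS_FACTOR = 4.0

#: Maximum number of neighbors (within two cell diameters) for which the
#: adhesive force still applies.
MAX_ADHESIVE_NEIGHBORS = 5


@dataclass
class MechanicsParams:
    """Mechanical constants.

    Units: forces in ug*um/s^2, stiffnesses in ug/(um*s^2), viscosity in
    ug/(um*s), lengths in um.  Defaults are the model's calibrated values:
    ``f_rep=50``, ``f_adh=5``, ``nu=250``, ``g_mag=0.08`` (giving a free
    persistent-cell speed of 0.00032 um/s).  ``r_adh`` defaults to one cell
    diameter (16 um) so adhesion engages on (16, 32) um, immediately outside
    contact.
    """

    f_rep: float = 50.0
    f_adh: float = 5.0
    r_adh: float = 16.0
    nu: float = 250.0
    g_mag: float = 0.08
    alpha: float = 1.0
    g_star: np.ndarray | None = None  # unit persistent direction, or None

    def __post_init__(self) -> None:
        for name in ("f_rep", "f_adh", "r_adh", "nu", "g_mag"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.g_star is not None:
            g = np.asarray(self.g_star, dtype=float)
            n = np.linalg.norm(g)
            if n < _EPS:
                raise ValueError("g_star must be a nonzero vector")
            self.g_star = g / n


@dataclass
class ForceVector:
    """A 2-D force with provenance."""

    vector: np.ndarray
    kind: str  # repulsive | adhesive | motility | total

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.kind not in {"repulsive", "adhesive", "motility", "total"}:
            raise ValueError(f"unknown force kind {self.kind!r}")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("force components must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


def _tiebreak_direction(identity_i: int, identity_j: int) -> np.ndarray:
    """Deterministic pseudo-random unit vector for coincident cell centers.

    Derived from the unordered id pair; the lower id is pushed along the
    vector, the higher id opposite, preserving pairwise antisymmetry.
    """
    a, b = sorted((int(identity_i), int(identity_j)))
    h = (a * 2654435761 + b * 40503 + 12345) % (2**32)
    ang = 2.0 * math.pi * h / 2.0**32
    return np.array([math.cos(ang), math.sin(ang)])


def repulsive_force(
    xi,
    xj,
    radius: float,
    params: MechanicsParams,
    identity_i: int = 0,
    identity_j: int = 1,
) -> ForceVector:
    """Hookean repulsion pushing cell i away from an overlapping cell j.

    Nonzero only for center distance d < 2R, with magnitude
    ``f_rep * (2R - d)``.  Coincident centers (d = 0) are resolved by a
    documented deterministic tie-break direction derived from the id pair.
    """
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    diff = xi - xj
    d = float(np.linalg.norm(diff))
    if d < _EPS:
        u = _tiebreak_direction(identity_i, identity_j)
        if identity_i > identity_j:
            u = -u
        return ForceVector(params.f_rep * 2.0 * radius * u, "repulsive")
    if d < 2.0 * radius:
        return ForceVector(params.f_rep * (2.0 * radius - d) * diff / d, "repulsive")
    return ForceVector(np.zeros(2), "repulsive")


def adhesive_force(xi, xj, params: MechanicsParams) -> ForceVector:
    """Hookean adhesion pulling cell i toward cell j.

    Nonzero only for ``r_adh < d < 2*r_adh`` with magnitude
    ``f_adh * (d - r_adh)`` directed toward j (the signed Hookean form
    ``f_adh * (r_adh - d)`` along ``xi - xj`` is negative there).
    Adhesion eligibility (at most five neighbors within two cell diameters)
    is the caller's responsibility.
    """
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    diff = xi - xj
    d = float(np.linalg.norm(diff))
    if params.r_adh < d < 2.0 * params.r_adh:
        return ForceVector(params.f_adh * (params.r_adh - d) * diff / d, "adhesive")
    return ForceVector(np.zeros(2), "adhesive")


def neighbor_count(cell_index: int, positions: np.ndarray, radius: float) -> int:
    """Number of other cells within two cell diameters (d <= 4R, inclusive)."""
    positions = np.asarray(positions, float)
    d = np.linalg.norm(positions - positions[cell_index], axis=-1)
    return int(np.sum(d <= NEIGHBOR_RADIUS_FACTOR * radius)) - 1


def total_interaction_force(cell_index: int, cells, params: MechanicsParams) -> ForceVector:
    """Sum of pairwise repulsion over overlapping neighbors plus adhesion
    (iff the focal cell has at most five neighbors within two cell
    diameters)."""
    positions = np.asarray([np.asarray(c.position, float) for c in cells])
    focal = cells[cell_index]
    radius = focal.radius
    total = np.zeros(2)
    adhesive_ok = (
        neighbor_count(cell_index, positions, radius) <= MAX_ADHESIVE_NEIGHBORS
    )
    for j, other in enumerate(cells):
        if j == cell_index:
            continue
        total += repulsive_force(
            focal.position, other.position, radius, params,
            identity_i=getattr(focal, "identity", cell_index),
            identity_j=getattr(other, "identity", j),
        ).vector
        if adhesive_ok:
            total += adhesive_force(focal.position, other.position, params).vector
    return ForceVector(total, "total")


def motility_force(
    cell_position,
    grid: ECMGrid,
    cell_radius: float,
    params: MechanicsParams,
) -> ForceVector:
    """Motility force of magnitude ``g_mag`` along the competition direction

    ``G~ = alpha * g_star + (1 - alpha) * mean(h)`` where the mean runs over
    fibrils within ``R + 2*dx`` of the cell center, each sign-aligned to
    ``g_star`` first (fibrils are axial).  If no fibril is in range the
    persistent term is used alone; perfect cancellation yields a zero force.
    """
    pos = np.asarray(cell_position, float)
    if params.g_star is None:
        raise ValueError("motility_force requires params.g_star")
    gstar = params.g_star
    alpha = params.alpha
    if alpha >= 1.0:
        gtilde = gstar.copy()
    else:
        radius = cell_radius + 2.0 * grid.spacing
        flat, d2, valid = _windows(grid, pos[None, :], radius)
        mask = (valid & (d2 <= radius * radius))[0]
        idx = flat[0][mask]
        if idx.size == 0:
            gtilde = gstar.copy()
        else:
            h = grid.orientation.reshape(-1, 2)[idx]
            sign = np.where(h @ gstar < 0.0, -1.0, 1.0)
            mean_h = (sign[:, None] * h).mean(axis=0)
            gtilde = alpha * gstar + (1.0 - alpha) * mean_h
    n = np.linalg.norm(gtilde)
    if n < _EPS:
        return ForceVector(np.zeros(2), "motility")
    return ForceVector(params.g_mag * gtilde / n, "motility")


def step_positions(cells, forces, dt: float, params: MechanicsParams, domain=None):
    """Forward-Euler overdamped update ``X <- X + (dt/nu) * F_total``.

    ``forces`` holds one total force (interaction + motility) per cell.
    Positions are clipped to the domain rectangle ``[0, W] x [0, H]`` when
    one is given (clipping a coordinate is equivalent to zeroing its outward
    velocity under forward Euler).  A non-finite force aborts with a
    diagnostic naming the cell.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if len(forces) != len(cells):
        raise ValueError("need exactly one total force per cell")
    out = []
    for cell, fv in zip(cells, forces):
        vec = fv.vector if isinstance(fv, ForceVector) else np.asarray(fv, float)
        if not np.all(np.isfinite(vec)):
            raise RuntimeError(
                f"non-finite force on cell id={getattr(cell, 'identity', '?')}"
            )
        new_pos = np.asarray(cell.position, float) + (dt / params.nu) * vec
        if domain is not None:
            new_pos = np.clip(new_pos, [0.0, 0.0], list(domain))
        out.append(replace(cell, position=new_pos))
    return out
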