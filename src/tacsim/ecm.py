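"""Extracellular-matrix orientation and stiffness fields and their remodeling.

The ECM is discretised on a regular rectangular grid of "fibril bundles".
Each node carries a unit orientation vector ``h(x, y)`` (the local fibril
direction, nematic: ``h`` and ``-h`` are physically identical) and a scalar
stiffness ``xi(x, y)`` expressed in units of sigma (1 sigma = 100 Pa).

Cells remodel this field in two ways:

* **orientation mixing** -- a cell exerting a force mixes its push/pull
  direction into the orientation of every node within a disk around it,
  weighted by the fibril compliance ``beta``; the result is re-normalised,
* **stiffening** -- a migrating cell pulls on nearby fibrils and a growing
  (pushed) cell pushes on them, raising stiffness by ``beta * delta_xi``
  times a 3/2/1 annulus weight; a growing cell additionally displaces the
  fibrils under its body, redistributing their stiffness onto the
  surrounding annuli.

All public operations are pure (they return a new :class:`ECMGrid`); the
``_*_inplace`` variants are used by the simulation engine for speed and are
exercised through the same tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ECMGrid",
    "RemodelParams",
    "init_random_field",
    "remodel_orientation",
    "stiffen_for_migration",
    "stiffen_for_growth",
    "write_grid_text",
    "read_grid_text",
    "write_grid_hdf5",
    "read_grid_hdf5",
    "read_grid",
]

#: Tolerance below which a vector is treated as degenerate (zero).
_EPS = 1e-12


@dataclass
class RemodelParams:
    """Fibril remodeling constants.

    Parameters
    ----------
    beta:
        Fibril compliance in [0, 1]: the fraction by which the local
        orientation yields to a cell-exerted direction per step, and the
        factor scaling force-induced stiffening.
    delta_xi:
        Per-step stiffening increment (sigma per time step).
    xi_max:
        Stiffness cap (sigma); 500 sigma = 5 kPa, a cancerous level.
    xi0:
        Initial uniform stiffness (sigma); 1 sigma = 100 Pa, normal
        mammary tissue.
    """

    beta: float = 0.5
    delta_xi: float = 4e-5
    xi_max: float = 500.0
    xi0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.delta_xi < 0.0:
            raise ValueError(f"delta_xi must be >= 0, got {self.delta_xi}")
        if not 0.0 < self.xi0 <= self.xi_max:
            raise ValueError(
                f"require 0 < xi0 <= xi_max, got xi0={self.xi0}, xi_max={self.xi_max}"
            )


@dataclass
class ECMGrid:
    """Regular grid of fibril orientation unit vectors and stiffness values.

    Node ``(i, j)`` sits at ``origin + spacing * (i, j)``; arrays are indexed
    ``[i, j]`` with ``i`` along x and ``j`` along y.
    """

    origin: np.ndarray
    spacing: float
    orientation: np.ndarray  # (nx, ny, 2), unit vectors
    stiffness: np.ndarray  # (nx, ny), sigma

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0.0:
            raise ValueError(f"grid spacing must be > 0, got {self.spacing}")
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        if self.orientation.ndim != 3 or self.orientation.shape[2] != 2:
            raise ValueError("orientation must have shape (nx, ny, 2)")
        if self.stiffness.shape != self.orientation.shape[:2]:
            raise ValueError("stiffness and orientation shapes disagree")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stiffness.shape

    def node_coords(self) -> np.ndarray:
        """Coordinates of every node, shape (nx, ny, 2)."""
        nx, ny = self.shape
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return self.origin + self.spacing * np.stack([ii, jj], axis=-1)

    def copy(self) -> "ECMGrid":
        return ECMGrid(
            origin=self.origin.copy(),
            spacing=self.spacing,
            orientation=self.orientation.copy(),
            stiffness=self.stiffness.copy(),
        )


def init_random_field(
    shape: tuple[int, int],
    spacing: float,
    xi0: float = 1.0,
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> ECMGrid:
    """Create an isotropic field: the TACS-1 (normal-tissue) initial state.

    Each node's orientation is ``(ex, ey) / ||(ex, ey)||`` with ``ex, ey``
    independent uniforms on [-1, 1] (a degenerate all-zero pair is redrawn);
    stiffness is uniformly ``xi0``.

    RNG consumption order (relevant for reproducibility): one (ex, ey) pair
    per node in C order, then redraws for degenerate pairs.
    """
    nx, ny = int(shape[0]), int(shape[1])
    if nx <= 0 or ny <= 0:
        raise ValueError(f"grid shape must be positive, got {shape}")
    if spacing <= 0.0:
        raise ValueError(f"grid spacing must be > 0, got {spacing}")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.uniform(-1.0, 1.0, size=(nx, ny, 2))
    norms = np.linalg.norm(eps, axis=-1)
    while np.any(norms < _EPS):  # pragma: no cover - probability ~0
        bad = norms < _EPS
        eps[bad] = rng.uniform(-1.0, 1.0, size=(int(bad.sum()), 2))
        norms = np.linalg.norm(eps, axis=-1)
    orientation = eps / norms[..., None]
    stiffness = np.full((nx, ny), float(xi0))
    return ECMGrid(origin=np.asarray(origin, float), spacing=float(spacing),
                   orientation=orientation, stiffness=stiffness)


# ---------------------------------------------------------------------------
# Node-window machinery: for a batch of cell centers, enumerate the grid
# nodes inside a fixed square window around each center together with their
# squared distances.  All remodeling and sensing operations are local, so
# this is the single geometric primitive everything else builds on.
# ---------------------------------------------------------------------------

def _windows(grid: ECMGrid, centers: np.ndarray, radius: float):
    """Return (flat_idx, d2, valid) arrays of shape (k, m) for k centers.

    ``m = (2*hw + 1)**2`` where ``hw`` is chosen so that every node within
    ``radius`` of any center lies inside its window.  ``valid`` marks window
    slots that correspond to actual in-domain nodes; ``flat_idx`` of invalid
    slots is clipped into range and must be masked by the caller.
    """
    nx, ny = grid.shape
    dx = grid.spacing
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    hw = int(np.ceil(radius / dx)) + 1
    ic = np.rint((centers - grid.origin) / dx).astype(np.int64)  # (k, 2)
    rng = np.arange(-hw, hw + 1)
    oi, oj = np.meshgrid(rng, rng, indexing="ij")
    off = np.stack([oi.ravel(), oj.ravel()], axis=-1)  # (m, 2)
    nodes = ic[:, None, :] + off[None, :, :]  # (k, m, 2)
    valid = (
        (nodes[..., 0] >= 0)
        & (nodes[..., 0] < nx)
        & (nodes[..., 1] >= 0)
        & (nodes[..., 1] < ny)
    )
    coords = grid.origin + dx * nodes
    d2 = np.sum((coords - centers[:, None, :]) ** 2, axis=-1)
    clipped = np.clip(nodes, 0, [nx - 1, ny - 1])
    flat = clipped[..., 0] * ny + clipped[..., 1]
    return flat, d2, valid


def _as_pos_dir_arrays(entries) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a list of (position, direction) pairs (or a pair of arrays)
    into (k, 2) position and unit-direction arrays, dropping degenerate
    directions."""
    if entries is None:
        return np.zeros((0, 2)), np.zeros((0, 2))
    if isinstance(entries, tuple) and len(entries) == 2 and np.ndim(entries[0]) == 2:
        pos, dirs = np.asarray(entries[0], float), np.asarray(entries[1], float)
    else:
        entries = list(entries)
        if not entries:
            return np.zeros((0, 2)), np.zeros((0, 2))
        pos = np.asarray([np.asarray(p, float) for p, _ in entries])
        dirs = np.asarray([np.asarray(d, float) for _, d in entries])
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(dirs))):
        raise ValueError("non-finite cell position or remodeling direction")
    norms = np.linalg.norm(dirs, axis=-1)
    keep = norms > _EPS
    return pos[keep], dirs[keep] / norms[keep, None]


def _remodel_orientation_inplace(
    grid: ECMGrid,
    push_pos: np.ndarray,
    push_dir: np.ndarray,
    pull_pos: np.ndarray,
    pull_dir: np.ndarray,
    cell_radius: float,
    beta: float,
) -> None:
    """Mix push (perpendicular, disk R+2*dx) and pull (parallel, disk R+dx)
    directions into the orientation field via the compliance mixing rule,
    with nematic sign alignment of every contribution to the node's
    current orientation."""
    if beta == 0.0:
        return
    dx = grid.spacing
    H = grid.orientation.reshape(-1, 2)
    acc = np.zeros_like(H)
    hit = np.zeros(H.shape[0], dtype=bool)
    groups = (
        (push_pos, push_dir, cell_radius + 2.0 * dx),
        (pull_pos, pull_dir, cell_radius + dx),
    )
    for pos, dirs, radius in groups:
        if len(pos) == 0:
            continue
        flat, d2, valid = _windows(grid, pos, radius)
        mask = valid & (d2 <= radius * radius)
        if not mask.any():
            continue
        h_here = H[flat]  # (k, m, 2)
        # fibrils are axial: flip each contribution into the half-plane of
        # the node's current orientation so antiparallel pushes reinforce
        # rather than cancel
        sign = np.where(np.einsum("kmi,ki->km", h_here, dirs) < 0.0, -1.0, 1.0)
        contrib = sign[..., None] * dirs[:, None, :]
        idx = flat[mask]
        np.add.at(acc, idx, contrib[mask])
        hit[idx] = True
    if not hit.any():
        return
    mixed = (1.0 - beta) * H[hit] + beta * acc[hit]
    norms = np.linalg.norm(mixed, axis=-1)
    ok = norms > _EPS
    new = H[hit]
    new[ok] = mixed[ok] / norms[ok, None]  # degenerate cancellation: keep old
    H[hit] = new


def remodel_orientation(
    grid: ECMGrid,
    pushers,
    pullers,
    cell_radius: float,
    beta: float,
) -> ECMGrid:
    """Return a grid with orientations remodeled by pushing/pulling cells.

    ``pushers``/``pullers`` are sequences of ``(position, direction)`` pairs:
    a pusher's direction is the unit vector perpendicular to the force moving
    it (a growing, passively relocated cell aligns fibrils tangentially), a
    puller's direction is its motility direction (a migrating cell aligns
    fibrils along its path).  Directions are used as unit vectors; magnitudes
    are discarded since the mixed vector is re-normalised anyway and ``beta``
    is the sole mixing weight.

    Nodes outside every interaction disk are returned bitwise unchanged;
    ``beta = 0`` is the identity.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    out = grid.copy()
    push_pos, push_dir = _as_pos_dir_arrays(pushers)
    pull_pos, pull_dir = _as_pos_dir_arrays(pullers)
    _remodel_orientation_inplace(
        out, push_pos, push_dir, pull_pos, pull_dir, cell_radius, beta
    )
    return out


def _migration_weights(d: np.ndarray, cell_radius: float, dx: float) -> np.ndarray:
    """3/2/1 annulus weights around a migrating (pulling) cell.

    Rings of width dx/2 starting at the cell boundary; the innermost zone
    (under the cell body, excluding the exact center) carries weight 3.
    """
    r, h2 = cell_radius, dx / 2.0
    w = np.zeros_like(d)
    w[(d > 0.0) & (d <= r)] = 3.0
    w[(d > r) & (d <= r + h2)] = 2.0
    w[(d > r + h2) & (d <= r + 2.0 * h2)] = 1.0
    return w


def _growth_weights(d: np.ndarray, cell_radius: float, dx: float) -> np.ndarray:
    """3/2/1 annulus weights around a growing (pushing) cell; nodes under
    the cell body carry weight 0 (they are displaced, not stiffened)."""
    r, h2 = cell_radius, dx / 2.0
    w = np.zeros_like(d)
    w[(d > r) & (d <= r + h2)] = 3.0
    w[(d > r + h2) & (d <= r + 2.0 * h2)] = 2.0
    w[(d > r + 2.0 * h2) & (d <= r + 3.0 * h2)] = 1.0
    return w


def _stiffen_migration_inplace(
    grid: ECMGrid,
    centers: np.ndarray,
    cell_radius: float,
    params: RemodelParams,
    delta_xi: float | None = None,
) -> None:
    centers = np.atleast_2d(np.asarray(centers, float))
    if len(centers) == 0:
        return
    dxi = params.delta_xi if delta_xi is None else delta_xi
    radius = cell_radius + grid.spacing
    flat, d2, valid = _windows(grid, centers, radius)
    w = _migration_weights(np.sqrt(d2), cell_radius, grid.spacing)
    mask = valid & (w > 0.0)
    xi = grid.stiffness.reshape(-1)
    np.add.at(xi, flat[mask], params.beta * dxi * w[mask])
    np.minimum(xi, params.xi_max, out=xi)


def stiffen_for_migration(
    grid: ECMGrid,
    cell_position,
    cell_radius: float,
    params: RemodelParams,
) -> ECMGrid:
    """Return a grid stiffened by one migrating cell pulling on fibrils.

    Every node within ``R + dx`` of the cell center gains
    ``beta * delta_xi * w`` with annulus weights 3 (under the cell),
    2 and 1 (rings of width dx/2 outside it); the result is capped at
    ``xi_max``.
    """
    out = grid.copy()
    _stiffen_migration_inplace(out, np.asarray(cell_position, float), cell_radius, params)
    return out


def _stiffen_growth_inplace(
    grid: ECMGrid,
    centers: np.ndarray,
    cell_radius: float,
    params: RemodelParams,
    delta_xi: float | None = None,
) -> None:
    """Growth stiffening with displacement of enclosed fibrils.

    Processed sequentially per cell so that overlapping cells never
    redistribute the same enclosed stiffness twice.
    """
    centers = np.atleast_2d(np.asarray(centers, float))
    if len(centers) == 0:
        return
    dxi = params.delta_xi if delta_xi is None else delta_xi
    radius = cell_radius + 1.5 * grid.spacing
    flat, d2, valid = _windows(grid, centers, radius)
    d = np.sqrt(d2)
    xi = grid.stiffness.reshape(-1)
    for k in range(len(centers)):
        w = _growth_weights(d[k], cell_radius, grid.spacing)
        ring = valid[k] & (w > 0.0)
        wsum = float(w[ring].sum())
        enclosed = valid[k] & (d[k] <= cell_radius)
        dzeta = 0.0
        if wsum > 0.0 and enclosed.any():
            enc_idx = flat[k][enclosed]
            total = float(xi[enc_idx].sum())
            if total > 0.0:
                # the cell body displaces the fibrils it covers: their
                # stiffness is moved onto the surrounding annuli, one
                # dzeta unit per ring weight (conserves total stiffness)
                dzeta = total / wsum
                xi[enc_idx] = 0.0
        xi[flat[k][ring]] += (params.beta * dxi + dzeta) * w[ring]
    np.minimum(xi, params.xi_max, out=xi)


def stiffen_for_growth(
    grid: ECMGrid,
    cell_position,
    cell_radius: float,
    params: RemodelParams,
) -> ECMGrid:
    """Return a grid stiffened by one growing (pushed) cell.

    Nodes strictly under the cell body receive no direct gain; the annuli
    outside it (rings of width dx/2, weights 3/2/1) gain
    ``(beta * delta_xi + dzeta) * w`` where ``dzeta`` redistributes the
    stiffness of the nodes the cell encloses over the ring weights.  A cell
    enclosing no nodes has ``dzeta = 0``.  Capped at ``xi_max``.
    """
    out = grid.copy()
    _stiffen_growth_inplace(out, np.asarray(cell_position, float), cell_radius, params)
    return out


# ---------------------------------------------------------------------------
# Grid dumps: plain-text table and HDF5 container, both round-trippable.
# ---------------------------------------------------------------------------

def write_grid_text(grid: ECMGrid, path, step: int | None = None) -> None:
    """One row per node: x, y, hx, hy, xi; metadata in '#' header lines."""
    nx, ny = grid.shape
    coords = grid.node_coords().reshape(-1, 2)
    h = grid.orientation.reshape(-1, 2)
    xi = grid.stiffness.reshape(-1, 1)
    data = np.hstack([coords, h, xi])
    header = (
        f"tacsim ecm grid\nspacing {float(grid.spacing)!r}\n"
        f"origin {float(grid.origin[0])!r} {float(grid.origin[1])!r}\n"
        f"shape {nx} {ny}\nstep {-1 if step is None else int(step)}\n"
        "x y hx hy xi"
    )
    np.savetxt(path, data, header=header, fmt="%.17g")


def read_grid_text(path) -> ECMGrid:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts and parts[0] in {"spacing", "origin", "shape"}:
                meta[parts[0]] = parts[1:]
    nx, ny = (int(v) for v in meta["shape"])
    data = np.loadtxt(path)
    return ECMGrid(
        origin=np.array([float(v) for v in meta["origin"]]),
        spacing=float(meta["spacing"][0]),
        orientation=data[:, 2:4].reshape(nx, ny, 2),
        stiffness=data[:, 4].reshape(nx, ny),
    )


def write_grid_hdf5(grid: ECMGrid, path, step: int | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("orientation", data=grid.orientation)
        f.create_dataset("stiffness", data=grid.stiffness)
        f.attrs["spacing"] = grid.spacing
        f.attrs["origin"] = grid.origin
        f.attrs["step"] = -1 if step is None else int(step)


def read_grid_hdf5(path) -> ECMGrid:
    import h5py

    with h5py.File(path, "r") as f:
        return ECMGrid(
            origin=np.asarray(f.attrs["origin"], float),
            spacing=float(f.attrs["spacing"]),
            orientation=f["orientation"][()],
            stiffness=f["stiffness"][()],
        )


def read_grid(path) -> ECMGrid:
    """Dispatch on suffix: .h5/.hdf5 binary container, otherwise text table."""
    s = str(path)
    if s.endswith((".h5", ".hdf5")):
        return read_grid_hdf5(path)
    return read_grid_text(path)
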