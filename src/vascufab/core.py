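"""Domain types and shared primitives.

Coordinate convention (shared by every module): continuous cell positions in
um with the origin at the lower-left corner, half-open domain
``[0, W) x [0, H)``.  Grids (solute fields, masks) are row-major with row 0
at the bottom; the centre of pixel ``(i, j)`` sits at
``((j + 0.5) h, (i + 0.5) h)`` where ``h`` is the resolution in um/pixel.
All four domain edges are zero-flux (closed culture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .config import CLOSE_PACKING_FRACTION, SimulationConfig


class CellKind(IntEnum):
    VASCULAR = 0
    CIRC_SOURCE = 1
    CIRC_SINK = 2
    PRODUCER = 3


#: kinds that never move and never feel forces
FIXED_KINDS = (CellKind.CIRC_SOURCE, CellKind.CIRC_SINK)


@dataclass
class Cell:
    """One off-lattice particle.

    ``active`` is meaningful for producers only (a producer is active when
    its local nutrient concentration exceeds the activation threshold);
    circulatory cells never move, and only vascular cells respond to
    chemotactic force.
    """

    id: int
    kind: CellKind
    position: tuple[float, float]   # (x, y) um
    radius: float                   # um
    biomass: float                  # pg
    active: bool = False


class CellArrays:
    """Struct-of-arrays view of a cell population (the fast path).

    Public per-cell operations take :class:`Cell`; the simulation loops work
    on these parallel arrays and convert at the boundary.
    """

    __slots__ = ("ids", "kinds", "pos", "radius", "biomass", "active")

    def __init__(self, ids, kinds, pos, radius, biomass, active):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.kinds = np.asarray(kinds, dtype=np.int8)
        self.pos = np.asarray(pos, dtype=np.float64)
        self.radius = np.asarray(radius, dtype=np.float64)
        self.biomass = np.asarray(biomass, dtype=np.float64)
        self.active = np.asarray(active, dtype=bool)

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_cells(cls, cells: list[Cell]) -> "CellArrays":
        return cls(
            [c.id for c in cells],
            [int(c.kind) for c in cells],
            [c.position for c in cells] if cells else np.empty((0, 2)),
            [c.radius for c in cells],
            [c.biomass for c in cells],
            [c.active for c in cells],
        )

    def to_cells(self) -> list[Cell]:
        return [
            Cell(
                id=int(self.ids[i]),
                kind=CellKind(int(self.kinds[i])),
                position=(float(self.pos[i, 0]), float(self.pos[i, 1])),
                radius=float(self.radius[i]),
                biomass=float(self.biomass[i]),
                active=bool(self.active[i]),
            )
            for i in range(len(self))
        ]

    @property
    def movable(self) -> np.ndarray:
        return ~np.isin(self.kinds, [int(k) for k in FIXED_KINDS])

    def kind_mask(self, *kinds: CellKind) -> np.ndarray:
        return np.isin(self.kinds, [int(k) for k in kinds])

    def copy(self) -> "CellArrays":
        return CellArrays(
            self.ids.copy(), self.kinds.copy(), self.pos.copy(),
            self.radius.copy(), self.biomass.copy(), self.active.copy(),
        )


# ---------------------------------------------------------------------------
# solute fields


@dataclass
class SoluteField:
    """A non-negative scalar concentration field on the regular 2D grid."""

    name: str
    values: np.ndarray   # (rows, cols), row 0 at the bottom
    resolution: float    # um per pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("field values must be 2D")
        if np.any(self.values < 0):
            raise ValueError(f"field {self.name!r} has negative values")

    @classmethod
    def zeros(cls, name: str, shape: tuple[int, int], resolution: float) -> "SoluteField":
        return cls(name, np.zeros(shape), resolution)

    def total_mass(self) -> float:
        """Integral of the field over the domain (conc * pixel area)."""
        return float(self.values.sum()) * self.resolution**2

    def sample(self, x, y):
        """Bilinear interpolation at continuous positions (um).

        Sample points outside the domain are clamped to the nearest interior
        point, consistent with the zero-flux boundary.
        """
        return bilinear_sample(self.values, self.resolution, x, y)


def bilinear_sample(values: np.ndarray, h: float, x, y):
    """Bilinearly interpolate grid ``values`` (pixel centres at (j+.5)h,
    (i+.5)h) at continuous coordinates; out-of-domain points are clamped."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    rows, cols = values.shape
    # fractional pixel-centre coordinates
    fx = np.clip(x / h - 0.5, 0.0, cols - 1.0)
    fy = np.clip(y / h - 0.5, 0.0, rows - 1.0)
    j0 = np.floor(fx).astype(np.int64)
    i0 = np.floor(fy).astype(np.int64)
    j1 = np.minimum(j0 + 1, cols - 1)
    i1 = np.minimum(i0 + 1, rows - 1)
    tx = fx - j0
    ty = fy - i0
    v00 = values[i0, j0]
    v01 = values[i0, j1]
    v10 = values[i1, j0]
    v11 = values[i1, j1]
    out = (v00 * (1 - tx) * (1 - ty) + v01 * tx * (1 - ty)
           + v10 * (1 - tx) * ty + v11 * tx * ty)
    return out if out.shape else float(out)


def laplacian_zero_flux(values: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirror) boundaries, units 1/um^2."""
    padded = np.pad(values, 1, mode="edge")
    return (
        padded[:-2, 1:-1] + padded[2:, 1:-1]
        + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * values
    ) / (h * h)


def stable_dt(h: float, D: float) -> float:
    """Largest forward-Euler-stable diffusion step, h^2/(4D)."""
    return h * h / (4.0 * D)


def steady_state_field(
    name: str,
    source_rate: np.ndarray,
    decay: float,
    D: float,
    h: float,
) -> SoluteField:
    """Direct solve of the diffusion-decay fixed point 0 = D lap(C) + S - bC.

    This is the stationary point of :func:`step_solute` (same 5-point
    stencil, same zero-flux borders), solved as one sparse linear system.
    Used for fields whose sources never move, where time-stepping to the
    slow-mode equilibrium would be wasteful.
    """
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    if decay <= 0:
        raise ValueError("steady state requires decay > 0")
    S = np.asarray(source_rate, dtype=np.float64)
    rows, cols = S.shape
    n = rows * cols
    main = np.full(n, decay)
    coef = D / (h * h)
    # zero-flux: the mirror neighbour cancels the off-diagonal at the border
    idx = np.arange(n).reshape(rows, cols)
    data, ri, ci = [], [], []
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        src = idx[max(di, 0):rows + min(di, 0), max(dj, 0):cols + min(dj, 0)]
        dst = idx[max(-di, 0):rows + min(-di, 0), max(-dj, 0):cols + min(-dj, 0)]
        ri.append(src.ravel())
        ci.append(dst.ravel())
        data.append(np.full(src.size, -coef))
        np.add.at(main, src.ravel(), coef)
    A = sparse.csr_matrix(
        (np.concatenate(data + [main]),
         (np.concatenate(ri + [np.arange(n)]), np.concatenate(ci + [np.arange(n)]))),
        shape=(n, n),
    )
    values = spsolve(A, S.ravel()).reshape(rows, cols)
    return SoluteField(name, np.maximum(values, 0.0), h)


def step_solute(
    field: SoluteField,
    source_rate: np.ndarray | float,
    decay: float,
    D: float,
    dt: float,
) -> SoluteField:
    """One operator-split step of d/dt C = D lap(C) + S - decay*C.

    Diffusion and source are advanced by forward Euler (5-point stencil,
    zero-flux borders); decay is applied as the exact exponential factor
    ``exp(-decay*dt)``, which is unconditionally stable and sign-preserving.
    Under the checked stability bound ``dt <= h^2/(4D)`` the update is a
    convex combination of non-negative values plus a non-negative source, so
    the field never goes negative and no clamping is performed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if D < 0 or decay < 0:
        raise ValueError("D and decay must be >= 0")
    h = field.resolution
    if D > 0 and dt > stable_dt(h, D) * (1 + 1e-12):
        raise ValueError(
            f"dt={dt:g}s violates the explicit stability bound "
            f"h^2/(4D)={stable_dt(h, D):g}s"
        )
    S = np.asarray(source_rate, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("source_rate must be >= 0")
    new = field.values + dt * (D * laplacian_zero_flux(field.values, h) + S)
    if decay > 0:
        new = new * math.exp(-decay * dt)
    return SoluteField(field.name, new, h)


# ---------------------------------------------------------------------------
# masks and rasterization


@dataclass
class BinaryMask:
    """Boolean pixel grid, same convention as :class:`SoluteField`."""

    values: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask values must be 2D")


def rasterize_particles(
    cells: list[Cell] | CellArrays,
    kinds: set[CellKind] | tuple[CellKind, ...],
    resolution: float,
    shape: tuple[int, int],
    dilation: float = 0.0,
) -> BinaryMask:
    """Render selected cells as a union of filled disks.

    A pixel is true iff its centre lies within ``radius + dilation`` of any
    selected cell centre.  ``dilation`` fattens the disks slightly so that
    cords of cells in point contact rasterize as connected strips (the
    replacement for rendering cells as illuminated spheres).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    arrays = cells if isinstance(cells, CellArrays) else CellArrays.from_cells(cells)
    mask = np.zeros(shape, dtype=bool)
    rows, cols = shape
    h = resolution
    sel = arrays.kind_mask(*kinds)
    for x, y, r in zip(arrays.pos[sel, 0], arrays.pos[sel, 1], arrays.radius[sel]):
        rr = r + dilation
        # bounding window of pixel indices
        i_lo = max(int(math.floor((y - rr) / h - 0.5)), 0)
        i_hi = min(int(math.ceil((y + rr) / h - 0.5)) + 1, rows)
        j_lo = max(int(math.floor((x - rr) / h - 0.5)), 0)
        j_hi = min(int(math.ceil((x + rr) / h - 0.5)) + 1, cols)
        if i_lo >= i_hi or j_lo >= j_hi:
            continue
        ii = (np.arange(i_lo, i_hi) + 0.5) * h - y
        jj = (np.arange(j_lo, j_hi) + 0.5) * h - x
        d2 = ii[:, None] ** 2 + jj[None, :] ** 2
        mask[i_lo:i_hi, j_lo:j_hi] |= d2 <= rr * rr
    return BinaryMask(mask, resolution)


# ---------------------------------------------------------------------------
# initial state


def make_initial_state(config: SimulationConfig, rng: np.random.Generator) -> list[Cell]:
    """Seed the domain: two fixed circulatory columns plus random interior cells.

    The left column (source) and right column (sink) each hold
    ``n_circulatory/2`` cells evenly spaced over the full height, centred at
    ``x = r`` and ``x = W - r`` (one cell-diameter-wide bands).  Interior
    cells are placed uniformly at random strictly between the columns; each
    is vascular with probability ``vascular_fraction``, else a producer.
    Initial overlaps are left to the shoving relaxation.  Deterministic given
    the generator state.
    """
    r = config.cell_radius
    W, H = config.domain_width, config.domain_height
    x_lo, x_hi = config.interior_x_range

    interior_area = (x_hi - x_lo) * H
    cell_area = math.pi * r * r * config.n_interior_cells
    if cell_area > CLOSE_PACKING_FRACTION * interior_area:
        raise ValueError(
            f"n_interior_cells={config.n_interior_cells} exceeds close packing "
            f"of the interior region ({cell_area:.0f} um^2 of cells in "
            f"{interior_area:.0f} um^2)"
        )

    cells: list[Cell] = []
    next_id = 0
    n_col = config.n_circulatory // 2
    for kind, x in ((CellKind.CIRC_SOURCE, r), (CellKind.CIRC_SINK, W - r)):
        for i in range(n_col):
            y = (i + 0.5) * H / n_col
            cells.append(Cell(next_id, kind, (x, y), r, config.cell_biomass_vascular))
            next_id += 1

    n = config.n_interior_cells
    xs = rng.uniform(x_lo, x_hi, size=n)
    ys = rng.uniform(0.0, H, size=n)
    is_vascular = rng.random(n) < config.vascular_fraction
    for i in range(n):
        kind = CellKind.VASCULAR if is_vascular[i] else CellKind.PRODUCER
        biomass = (config.cell_biomass_vascular if is_vascular[i]
                   else config.cell_biomass_producer)
        cells.append(Cell(next_id, kind, (float(xs[i]), float(ys[i])), r, biomass))
        next_id += 1
    return cells
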