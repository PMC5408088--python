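"""Phase I: self-organization of the vascular network.

Vascular and circulatory cells secrete chemoattractants (fast-decaying and
slow-decaying species respectively); vascular cells climb the summed
gradient by sampling the field across their body along a random direction,
adhere to each other, and are kept from overlapping by a shoving relaxation.
The interplay of short-range aggregation, long-range attraction toward the
circulatory columns, adhesion and crowding produces cords that join into a
network spanning the domain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import ChemoParams, SimulationConfig
from .core import (
    Cell,
    CellArrays,
    CellKind,
    SoluteField,
    bilinear_sample,
    make_initial_state,
    stable_dt,
    steady_state_field,
    step_solute,
)

logger = logging.getLogger(__name__)

#: residual pairwise overlap tolerated by the shoving relaxation, um
TOL_OVERLAP = 0.05


@dataclass
class MorphogenesisState:
    """Snapshot of Phase I at (or en route to) convergence."""

    cells: list[Cell]
    field_short: SoluteField   # vascular-cell chemoattractant (fast decay)
    field_long: SoluteField    # circulatory-cell chemoattractant (slow decay)
    substrate_Nc: float
    step: int
    max_displacement_last: float
    converged: bool = False


# ---------------------------------------------------------------------------
# single-cell operations (reference semantics; the loop uses the vectorized
# forms below)


def secretion_rate(cell: Cell, N_c: float, params: ChemoParams) -> float:
    """Chemoattractant secretion of one cell, per unit covered area.

    Monod kinetics in the secretion substrate: the total rate is
    ``mu_c * N_c/(N_c + k) * M`` (pg/s), deposited uniformly over the disk
    the cell covers, hence divided by ``pi r^2``.  Producers do not secrete.
    """
    if cell.kind == CellKind.PRODUCER:
        raise ValueError("producer cells do not secrete chemoattractant")
    if N_c < 0:
        raise ValueError("N_c must be >= 0")
    total = params.mu_c * N_c / (N_c + params.k) * cell.biomass
    return total / (math.pi * cell.radius**2)


def chemotaxis_force(
    cell: Cell,
    field: SoluteField,
    params: ChemoParams,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Saturating chemotactic force along one random direction, or ``None``.

    A uniform random unit vector c is drawn; the field is sampled one radius
    ahead (C+) and one radius behind (C-) of the cell centre (bilinear
    interpolation, out-of-domain samples clamped to the boundary), and
    ``F = lambda * [C+/(1+beta*C+) - C-/(1+beta*C-)]``.  The force ``F*c`` is
    applied only when F > 0 (the cell cannot push itself downhill).
    """
    if cell.kind != CellKind.VASCULAR:
        raise ValueError("only vascular cells respond to chemotactic force")
    theta = rng.uniform(0.0, 2.0 * math.pi)
    c = np.array([math.cos(theta), math.sin(theta)])
    x, y = cell.position
    r = cell.radius
    c_plus = field.sample(x + r * c[0], y + r * c[1])
    c_minus = field.sample(x - r * c[0], y - r * c[1])
    b = params.beta_sat
    F = params.lambda_ * (c_plus / (1.0 + b * c_plus) - c_minus / (1.0 + b * c_minus))
    if F > 0:
        return F * c
    return None


def adhesion_force(cell_a: Cell, cell_b: Cell, params: ChemoParams) -> np.ndarray:
    """Homotypic vascular-vascular adhesion: force on ``cell_a``.

    Attractive along the a->b axis with a linear ramp in the surface gap
    ``g = |a-b| - (r_a + r_b)``: magnitude ``adhesion_strength*(1 - g/range)``
    for ``0 < g <= range``, zero otherwise (overlap is the shoving
    algorithm's business).  Antisymmetric by construction.
    """
    if cell_a.kind != CellKind.VASCULAR or cell_b.kind != CellKind.VASCULAR:
        raise ValueError("adhesion is modeled between vascular cells only")
    a = np.asarray(cell_a.position)
    b = np.asarray(cell_b.position)
    d = float(np.linalg.norm(b - a))
    g = d - (cell_a.radius + cell_b.radius)
    if g <= 0 or g > params.adhesion_range:
        return np.zeros(2)
    mag = params.adhesion_strength * (1.0 - g / params.adhesion_range)
    return mag * (b - a) / d


# ---------------------------------------------------------------------------
# vectorized internals


def _chemotaxis_forces(
    arrays: CellArrays,
    field_values: np.ndarray,
    h: float,
    params: ChemoParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Chemotactic force for every cell (zero rows for non-vascular).

    One random direction per vascular cell per call, drawn in cell-index
    order from the single stream (reproducibility / tie-break rule).  With
    ``contact_inhibition`` a cell whose sampled direction points into a
    touching vascular neighbour produces no force: protrusions form only at
    free surface, which stops cords from compacting into round islands and
    lets them sprout instead.
    """
    forces = np.zeros_like(arrays.pos)
    sel = arrays.kind_mask(CellKind.VASCULAR)
    n = int(sel.sum())
    if n == 0 or params.lambda_ == 0:
        return forces
    pos = arrays.pos[sel]
    r = arrays.radius[sel][:, None]
    b = params.beta_sat
    k = max(int(params.n_directions), 1)

    pairs = np.empty((0, 2), dtype=np.int64)
    unit = np.empty((0, 2))
    if params.contact_inhibition and len(pos) > 1:
        contact = 2.0 * arrays.radius[sel].max() + params.contact_margin
        pairs = cKDTree(pos).query_pairs(contact, output_type="ndarray")
        if len(pairs):
            dvec = pos[pairs[:, 1]] - pos[pairs[:, 0]]
            d = np.linalg.norm(dvec, axis=1)
            d[d < 1e-12] = 1e-12
            unit = dvec / d[:, None]

    total = np.zeros_like(pos)
    for _ in range(k):
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        c = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        p_plus = pos + r * c
        p_minus = pos - r * c
        cp = bilinear_sample(field_values, h, p_plus[:, 0], p_plus[:, 1])
        cm = bilinear_sample(field_values, h, p_minus[:, 0], p_minus[:, 1])
        F = params.lambda_ * (cp / (1.0 + b * cp) - cm / (1.0 + b * cm))
        F = np.where(F > 0, F, 0.0)
        if len(pairs):
            # a touching neighbour blocks protrusion within a cone around
            # its direction; tangential sliding stays allowed
            i, j = pairs[:, 0], pairs[:, 1]
            cone = params.contact_cone_cos
            blocked_i = np.einsum("ij,ij->i", unit, c[i]) > cone
            blocked_j = np.einsum("ij,ij->i", -unit, c[j]) > cone
            blocked = np.zeros(n, dtype=bool)
            blocked[i[blocked_i]] = True
            blocked[j[blocked_j]] = True
            F = np.where(blocked, 0.0, F)
        total += F[:, None] * c
    forces[sel] = total / k
    return forces


def _adhesion_forces(arrays: CellArrays, params: ChemoParams) -> np.ndarray:
    """Pairwise vascular-vascular adhesion, accumulated per cell."""
    forces = np.zeros_like(arrays.pos)
    if params.adhesion_strength == 0:
        return forces
    sel = np.flatnonzero(arrays.kind_mask(CellKind.VASCULAR))
    if len(sel) < 2:
        return forces
    pos = arrays.pos[sel]
    rad = arrays.radius[sel]
    cutoff = 2.0 * rad.max() + params.adhesion_range
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = pos[j] - pos[i]
    d = np.linalg.norm(dvec, axis=1)
    g = d - (rad[i] + rad[j])
    act = (g > 0) & (g <= params.adhesion_range) & (d > 0)
    if not act.any():
        return forces
    i, j, dvec, d, g = i[act], j[act], dvec[act], d[act], g[act]
    mag = params.adhesion_strength * (1.0 - g / params.adhesion_range)
    f = (mag / d)[:, None] * dvec
    np.add.at(forces, sel[i], f)
    np.add.at(forces, sel[j], -f)
    return forces


def _relax_shoving_arrays(
    arrays: CellArrays,
    max_iters: int,
    W: float,
    H: float,
    tol_overlap: float = TOL_OVERLAP,
) -> float:
    """In-place shoving relaxation; returns the largest displacement of the
    final pass.

    Every overlapping pair is displaced half the overlap each along the
    separation axis; a pair with an immovable circulatory partner puts the
    whole correction on the mobile cell.  Positions are clamped into the
    domain after every pass.  Coincident centres separate along a direction
    derived deterministically from the cell ids.
    """
    movable = arrays.movable
    pos = arrays.pos
    rad = arrays.radius
    last_max = 0.0
    slack = 1.0    # um of motion the cached pair list stays valid for
    refresh = 4    # passes between neighbour-list rebuilds
    pairs = np.empty((0, 2), dtype=np.int64)
    for it in range(max_iters):
        if it % refresh == 0:
            cutoff = 2.0 * rad.max() - tol_overlap + slack
            pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        dvec = pos[j] - pos[i]
        d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        o = (rad[i] + rad[j]) - d
        act = o > tol_overlap
        if not act.any():
            return last_max
        i, j, dvec, d, o = i[act], j[act], dvec[act], d[act], o[act]
        zero = d < 1e-12
        if zero.any():
            ang = (arrays.ids[i[zero]] * 2654435761 + arrays.ids[j[zero]]) % 6283 / 1000.0
            dvec[zero] = np.stack([np.cos(ang), np.sin(ang)], axis=1)
            d[zero] = 1.0
        unit = dvec / d[:, None]
        mi = movable[i]
        mj = movable[j]
        # share of the overlap each partner absorbs
        share_i = np.where(mi & mj, 0.5, np.where(mi, 1.0, 0.0))
        share_j = np.where(mi & mj, 0.5, np.where(mj, 1.0, 0.0))
        disp = np.zeros_like(pos)
        np.add.at(disp, i, -(share_i * o)[:, None] * unit)
        np.add.at(disp, j, (share_j * o)[:, None] * unit)
        pos += disp
        np.clip(pos[:, 0], 0.0, W * (1 - 1e-12), out=pos[:, 0])
        np.clip(pos[:, 1], 0.0, H * (1 - 1e-12), out=pos[:, 1])
        last_max = float(np.linalg.norm(disp, axis=1).max())
    logger.debug("shoving left residual overlaps after %d passes", max_iters)
    return last_max


def relax_shoving(cells: list[Cell], max_iters: int = 100,
                  domain: tuple[float, float] | None = None) -> tuple[list[Cell], float]:
    """Resolve pairwise overlaps; returns (cells, largest displacement).

    ``domain`` is the (W, H) clamp box; when omitted it is taken large
    enough never to clamp.
    """
    arrays = CellArrays.from_cells(cells)
    if len(arrays) == 0:
        return [], 0.0
    if domain is None:
        span = float(np.abs(arrays.pos).max() + arrays.radius.max() + 1.0) * 2
        W = H = span
    else:
        W, H = domain
    disp = _relax_shoving_arrays(arrays, max_iters, W, H)
    return arrays.to_cells(), disp


# ---------------------------------------------------------------------------
# secretion source stamping


class _DiskStamp:
    """Precomputed pixel-offset template of a disk of one radius."""

    def __init__(self, radius: float, h: float):
        n = int(math.ceil(radius / h))
        ii, jj = np.mgrid[-n:n + 1, -n:n + 1]
        inside = (ii * h) ** 2 + (jj * h) ** 2 <= radius**2
        self.di = ii[inside]
        self.dj = jj[inside]
        self.n_px = int(inside.sum())


def _secretion_source(
    arrays: CellArrays,
    sel: np.ndarray,
    rate_per_cell: np.ndarray,
    shape: tuple[int, int],
    h: float,
    stamp: _DiskStamp,
) -> np.ndarray:
    """Per-pixel source-rate field from the selected secreting cells.

    Each cell's total rate is spread evenly over its covering pixel stamp
    centred at the pixel containing the cell centre; out-of-domain stamp
    pixels are clamped to the border (total secretion is conserved).
    """
    src = np.zeros(shape)
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        return src
    rows, cols = shape
    ci = np.clip((arrays.pos[idx, 1] / h).astype(np.int64), 0, rows - 1)
    cj = np.clip((arrays.pos[idx, 0] / h).astype(np.int64), 0, cols - 1)
    ii = np.clip(ci[:, None] + stamp.di[None, :], 0, rows - 1)
    jj = np.clip(cj[:, None] + stamp.dj[None, :], 0, cols - 1)
    per_px = (rate_per_cell[idx] / (stamp.n_px * h * h))[:, None]
    np.add.at(src, (ii.ravel(), jj.ravel()),
              np.broadcast_to(per_px, ii.shape).ravel())
    return src


def _relax_field(
    field: SoluteField,
    source: np.ndarray,
    decay: float,
    D: float,
    dt: float,
    max_substeps: int,
    eps_field: float,
) -> tuple[SoluteField, float]:
    """Advance a field toward quasi-steady state; returns (field, last
    relative per-substep change)."""
    rel = math.inf
    for _ in range(max_substeps):
        new = step_solute(field, source, decay, D, dt)
        denom = float(np.abs(new.values).sum()) + 1e-300
        rel = float(np.abs(new.values - field.values).sum()) / denom
        field = new
        if rel < eps_field:
            break
    return field, rel


# ---------------------------------------------------------------------------
# the Phase I loop


def run_morphogenesis(
    config: SimulationConfig,
    rng: np.random.Generator,
    cells: list[Cell] | None = None,
    n_solute_substeps: int = 15,
    initial_substeps: int = 600,
) -> MorphogenesisState:
    """Run Phase I to convergence (or to the step budget).

    Per mechanical step: (1) both chemoattractant fields are relaxed toward
    quasi-steady state with their secretion sources (vascular cells feed the
    fast-decay field, circulatory cells the slow-decay field); (2) each
    vascular cell receives one chemotactic force sample against the summed
    field plus pairwise adhesion, converted to displacement by overdamped
    motion ``dx = mobility * F * dt_mech`` capped at half a radius; (3)
    overlaps are resolved by shoving.  The loop stops when the largest
    displacement stays below ``eps_move`` and the relative field change
    below ``eps_field`` for ``patience`` consecutive steps, or at
    ``max_steps`` (logged).  Deterministic for a given generator state.
    """
    p = config.chemo_params
    conv = config.convergence
    h = config.grid_resolution
    shape = config.grid_shape
    W, H = config.domain_width, config.domain_height

    if cells is None:
        cells = make_initial_state(config, rng)
    arrays = CellArrays.from_cells(cells)

    field_short = SoluteField.zeros("chemo_short", shape, h)
    field_long = SoluteField.zeros("chemo_long", shape, h)
    dt_s = config.dt_solute if config.dt_solute > 0 else 0.999 * stable_dt(h, p.D_c)

    _relax_shoving_arrays(arrays, max_iters=120, W=W, H=H)

    stamp = _DiskStamp(config.cell_radius, h)
    monod = p.mu_c * p.N_c0 / (p.N_c0 + p.k)
    rate_per_cell = monod * arrays.biomass  # pg/s, per secreting cell

    sel_v = arrays.kind_mask(CellKind.VASCULAR)
    sel_c = arrays.kind_mask(CellKind.CIRC_SOURCE, CellKind.CIRC_SINK)

    # charge the fields before the first mechanical step; the circulatory
    # columns never move, so the slow-decay field is static for the whole
    # phase and is taken straight at its steady state (the fixed point of
    # the explicit stepper)
    src_v = _secretion_source(arrays, sel_v, rate_per_cell, shape, h, stamp)
    src_c = _secretion_source(arrays, sel_c, rate_per_cell, shape, h, stamp)
    field_short, _ = _relax_field(field_short, src_v, p.beta_v, p.D_c, dt_s,
                                  initial_substeps, conv.eps_field)
    field_long = steady_state_field("chemo_long", src_c, p.beta_c, p.D_c, h)

    cap = config.step_cap_factor * config.cell_radius
    quiet = 0
    step = 0
    max_disp = 0.0
    converged = False
    for step in range(1, conv.max_steps + 1):
        src_v = _secretion_source(arrays, sel_v, rate_per_cell, shape, h, stamp)
        field_short, rel_field = _relax_field(field_short, src_v, p.beta_v, p.D_c,
                                              dt_s, n_solute_substeps, conv.eps_field)

        if p.separate_fields:
            forces = _chemotaxis_forces(arrays, field_short.values, h, p, rng)
            forces += p.lambda_long_ratio * _chemotaxis_forces(
                arrays, field_long.values, h, p, rng)
        else:
            # one effective gradient; the circulatory species can be
            # down-weighted so local cord formation is not drowned out by
            # the columns' far louder source
            summed = field_short.values + p.lambda_long_ratio * field_long.values
            forces = _chemotaxis_forces(arrays, summed, h, p, rng)
        forces += _adhesion_forces(arrays, p)
        forces[~arrays.movable] = 0.0

        disp = config.mobility * config.dt_mech * forces
        norms = np.linalg.norm(disp, axis=1)
        over = norms > cap
        if over.any():
            disp[over] *= (cap / norms[over])[:, None]
        arrays.pos += disp
        np.clip(arrays.pos[:, 0], 0.0, W * (1 - 1e-12), out=arrays.pos[:, 0])
        np.clip(arrays.pos[:, 1], 0.0, H * (1 - 1e-12), out=arrays.pos[:, 1])
        move_disp = float(norms.max()) if len(norms) else 0.0

        shove_disp = _relax_shoving_arrays(arrays, max_iters=8, W=W, H=H)
        max_disp = max(move_disp, shove_disp)

        if max_disp < conv.eps_move and rel_field < conv.eps_field:
            quiet += 1
            if quiet >= conv.patience:
                converged = True
                break
        else:
            quiet = 0
        if step % 50 == 0:
            logger.info(
                "morphogenesis step %d: max displacement %.3f um, field change %.2e",
                step, max_disp, rel_field,
            )

    # final tidy-up so the returned morphology is overlap-free
    _relax_shoving_arrays(arrays, max_iters=60, W=W, H=H)
    if not converged:
        logger.info("morphogenesis stopped at step budget (%d steps)", step)

    return MorphogenesisState(
        cells=arrays.to_cells(),
        field_short=field_short,
        field_long=field_long,
        substrate_Nc=p.N_c0,
        step=step,
        max_displacement_last=max_disp,
        converged=converged,
    )
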