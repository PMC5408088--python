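"""Phase III: steady-state operation of the vascular cell factory.

Flowing vessels exchange material with the culture through their walls:
nutrient N enters along every perfused vessel (flow- and demand-limited),
producer cells convert N into product X with Michaelis-Menten kinetics and
product inhibition, and X is taken back up along the vessels and carried to
the sink.  Both solutes diffuse; the circulatory columns themselves always
act as one source-side and one sink-side exchange surface, which is also the
entire machinery of the no-network baseline.  Throughput is the product mass
removed per hour once the factory has settled into steady state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import FactoryParams, SimulationConfig
from .core import (
    Cell,
    CellArrays,
    CellKind,
    SoluteField,
    stable_dt,
    step_solute,
)
from .flow import FlowSolution, edge_conductance
from .vesselgraph import VesselGraph

logger = logging.getLogger(__name__)

PG_PER_UG = 1.0e6
S_PER_H = 3600.0


# ---------------------------------------------------------------------------
# the four kinetic laws


def nutrient_delivery_rate(Q: float, r: float, N_local: float, p: FactoryParams) -> float:
    """Nutrient supplied per unit vessel length, pg/(um*s).

    ``rho_n * 2*pi*r * |Q|/(k_out+|Q|) * k_l/(k_l+N)``: saturating in the
    flow and *decreasing* in the local nutrient level, so depleted
    microenvironments are replenished fastest.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if N_local < 0:
        raise ValueError("N_local must be >= 0")
    q = abs(Q)
    return p.rho_n * 2.0 * math.pi * r * q / (p.k_out + q) * p.k_l / (p.k_l + N_local)


def production_rate(N: float, X: float, p: FactoryParams) -> float:
    """Product synthesized by one producer cell, pg/s.

    ``mu_p * N/(N+k_p) * k_i/(X+k_i) * M_p``: Michaelis-Menten in nutrient
    with multiplicative product inhibition.
    """
    if N < 0 or X < 0:
        raise ValueError("N and X must be >= 0")
    return p.mu_p * N / (N + p.k_p) * p.k_i / (X + p.k_i) * p.M_p


def product_uptake_rate(Q: float, r: float, X_local: float, p: FactoryParams) -> float:
    """Product removed per unit vessel length, pg/(um*s).

    ``rho_p * 2*pi*r * |Q|/(k_in+|Q|) * X/(k_p+X)``: stagnant vessels remove
    nothing; removal accelerates as product accumulates.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if X_local < 0:
        raise ValueError("X_local must be >= 0")
    q = abs(Q)
    return p.rho_p * 2.0 * math.pi * r * q / (p.k_in + q) * X_local / (p.k_p + X_local)


def nutrient_consumption_rate(N: float, X: float, p: FactoryParams) -> float:
    """Nutrient consumed by one producer cell, pg/s.

    Same saturation and inhibition structure as production, at rate ``mu_n``;
    the consumption/production ratio is therefore mu_n/mu_p everywhere.
    """
    if N < 0 or X < 0:
        raise ValueError("N and X must be >= 0")
    return p.mu_n * N / (N + p.k_p) * p.k_i / (p.k_i + X) * p.M_p


# ---------------------------------------------------------------------------
# state


@dataclass
class FactoryState:
    """End state of a factory run plus cumulative accounting."""

    field_N: SoluteField
    field_X: SoluteField
    t: float
    delivered_per_edge: np.ndarray     # cumulative pg per exchange segment
    removed_per_edge: np.ndarray       # cumulative pg per exchange segment
    producer_active: np.ndarray        # bool per producer cell
    throughput_rate: float             # pg/s, trailing estimate
    steady: bool = False
    t_steady: float = math.nan
    window_removed_per_edge: np.ndarray | None = None   # pg in the window
    window_produced: float = 0.0       # pg synthesized inside the window
    window_duration: float = 0.0       # s
    produced_total: float = 0.0        # pg
    consumed_total: float = 0.0        # pg
    segment_labels: list[str] = field(default_factory=list)
    series: pd.DataFrame | None = None   # t, throughput_rate, active_fraction, ...


@dataclass
class _Segment:
    """One exchange surface: a graph edge path or a circulatory column."""

    label: str
    pixels: np.ndarray    # flat pixel indices
    Q: float              # um^3/s
    radius: float         # um
    length: float         # um


def _column_pipe_flow(config: SimulationConfig) -> float:
    """Flow through a virtual single pipe joining the two columns.

    Radius = cell radius, length = column separation; this is the perfusion
    the external circuit provides regardless of any interior network.
    """
    r = config.cell_radius
    sep = config.domain_width - 2.0 * config.cell_radius
    g = edge_conductance(r, sep, config.flow_params.eta)
    return g * config.flow_params.delta_P


def _build_segments(
    graph: VesselGraph | None,
    flow_solution: FlowSolution | None,
    config: SimulationConfig,
) -> list[_Segment]:
    h = config.grid_resolution
    rows, cols = config.grid_shape
    r = config.cell_radius
    segments: list[_Segment] = []

    # the two circulatory columns are always exchange surfaces
    q_col = _column_pipe_flow(config)
    n_band = max(int(round(2.0 * r / h)), 1)
    all_rows = np.arange(rows)
    left = (all_rows[:, None] * cols + np.arange(n_band)[None, :]).ravel()
    right = (all_rows[:, None] * cols + np.arange(cols - n_band, cols)[None, :]).ravel()
    segments.append(_Segment("column:source", left, q_col, r, config.domain_height))
    segments.append(_Segment("column:sink", right, q_col, r, config.domain_height))

    if graph is not None:
        flows = flow_solution.flows if flow_solution is not None else np.zeros(len(graph.edges))
        for k, e in enumerate(graph.edges):
            if not e.path:
                continue   # terminal attachment edges have no physical wall
            px = np.array([i * cols + j for i, j in e.path], dtype=np.int64)
            segments.append(_Segment(f"edge:{k}", px, float(flows[k]), e.radius, e.length))
    return segments


# ---------------------------------------------------------------------------
# the Phase III loop


def run_factory(
    cells: list[Cell] | CellArrays,
    graph: VesselGraph | None,
    flow_solution: FlowSolution | None,
    config: SimulationConfig,
) -> FactoryState:
    """Run the factory from empty fields to steady state, then account
    throughput over the production window.

    Per time step: vessel-wall delivery sources (local N = mean over a
    1-pixel-radius neighbourhood of each path pixel) and uptake sinks are
    applied along every exchange segment, producer reaction terms at each
    producer's pixel, and both fields diffuse with ``D_p`` via the shared
    explicit stepper (no decay).  Sinks are clipped per pixel so neither
    field ever goes negative.  Steady state is declared when the trailing
    removal rate drifts less than ``steady_tol`` (relative) between
    consecutive detection windows; the run then continues for
    ``production_window`` seconds of throughput accounting.
    """
    p = config.factory_params
    h = config.grid_resolution
    shape = config.grid_shape
    area = h * h

    arrays = cells if isinstance(cells, CellArrays) else CellArrays.from_cells(cells)
    segments = _build_segments(graph, flow_solution, config)

    dt = p.dt if p.dt > 0 else 0.999 * stable_dt(h, p.D_p)
    if p.D_p > 0 and dt > stable_dt(h, p.D_p):
        raise ValueError(
            f"factory dt={dt:g}s violates the stability bound {stable_dt(h, p.D_p):g}s"
        )

    # producers: pixel of each cell centre
    rows, cols = shape
    prod_sel = np.flatnonzero(arrays.kind_mask(CellKind.PRODUCER))
    pi = np.clip((arrays.pos[prod_sel, 1] / h).astype(np.int64), 0, rows - 1)
    pj = np.clip((arrays.pos[prod_sel, 0] / h).astype(np.int64), 0, cols - 1)
    prod_px = pi * cols + pj

    # concatenated segment pixels for fast per-segment means / scatters
    seg_px = np.concatenate([s.pixels for s in segments]) if segments else np.empty(0, int)
    seg_id = np.concatenate([np.full(len(s.pixels), k) for k, s in enumerate(segments)]) \
        if segments else np.empty(0, int)
    seg_npx = np.array([len(s.pixels) for s in segments], dtype=np.float64)
    seg_Q = np.array([abs(s.Q) for s in segments])
    seg_r = np.array([s.radius for s in segments])
    seg_len = np.array([s.length for s in segments])
    n_seg = len(segments)

    deliv_coef = p.rho_n * 2.0 * math.pi * seg_r * seg_Q / (p.k_out + seg_Q)   # pg/(um*s)
    uptake_coef = p.rho_p * 2.0 * math.pi * seg_r * seg_Q / (p.k_in + seg_Q)

    N = np.zeros(shape)
    X = np.zeros(shape)
    delivered = np.zeros(n_seg)
    removed = np.zeros(n_seg)
    produced_total = 0.0
    consumed_total = 0.0

    check_every = max(int(round(1.0 / dt)), 50)    # ~1 s of simulated time
    window_removed: np.ndarray | None = None
    window_produced = 0.0
    steady = False
    t_steady = math.nan
    prev_rate = math.nan
    rate = 0.0
    block_removed_start = 0.0
    t = 0.0
    step = 0
    series: list[tuple[float, float, float, float, float]] = []
    window_start_removed = None
    window_t0 = 0.0
    n_flat = N.reshape(-1)
    x_flat = X.reshape(-1)

    max_steps = int(math.ceil((p.max_sim_time + p.production_window) / dt))
    smooth_every = 5   # microenvironment means refresh; fields drift slowly
    Nsm = Xsm = None
    for step in range(1, max_steps + 1):
        if Nsm is None or step % smooth_every == 0:
            Nsm = ndimage.uniform_filter(N, size=3, mode="nearest")
            Xsm = ndimage.uniform_filter(X, size=3, mode="nearest")

        if n_seg:
            n_loc = np.bincount(seg_id, weights=Nsm.reshape(-1)[seg_px],
                                minlength=n_seg) / seg_npx
            x_loc = np.bincount(seg_id, weights=Xsm.reshape(-1)[seg_px],
                                minlength=n_seg) / seg_npx
            deliv_total = deliv_coef * p.k_l / (p.k_l + n_loc) * seg_len      # pg/s
            uptake_total = uptake_coef * x_loc / (p.k_p + x_loc) * seg_len    # pg/s
        else:
            deliv_total = uptake_total = np.zeros(0)

        # sources (conc/s per pixel)
        src_N = np.zeros(shape)
        src_X = np.zeros(shape)
        if n_seg:
            per_px = (deliv_total / seg_npx / area)[seg_id]
            np.add.at(src_N.reshape(-1), seg_px, per_px)
        if len(prod_px):
            n_at = n_flat[prod_px]
            x_at = x_flat[prod_px]
            prod_rate = p.mu_p * n_at / (n_at + p.k_p) * p.k_i / (x_at + p.k_i) * p.M_p
            np.add.at(src_X.reshape(-1), prod_px, prod_rate / area)
            produced_step = float(prod_rate.sum()) * dt
        else:
            prod_rate = np.zeros(0)
            produced_step = 0.0

        # diffusion + sources via the shared explicit stepper
        N_tent = step_solute(SoluteField("N", N, h), src_N, 0.0, p.D_p, dt).values
        X_tent = step_solute(SoluteField("X", X, h), src_X, 0.0, p.D_p, dt).values

        # sinks, clipped per pixel so fields stay non-negative
        sink_N = np.zeros(shape)
        sink_X = np.zeros(shape)
        if len(prod_px):
            cons_rate = p.mu_n * n_at / (n_at + p.k_p) * p.k_i / (p.k_i + x_at) * p.M_p
            np.add.at(sink_N.reshape(-1), prod_px, cons_rate / area)
        if n_seg:
            per_px_u = (uptake_total / seg_npx / area)[seg_id]
            np.add.at(sink_X.reshape(-1), seg_px, per_px_u)

        want_N = sink_N * dt
        take_N = np.minimum(want_N, N_tent)
        N = N_tent - take_N
        want_X = sink_X * dt
        take_X = np.minimum(want_X, X_tent)
        X = X_tent - take_X
        n_flat = N.reshape(-1)
        x_flat = X.reshape(-1)

        delivered += deliv_total * dt
        consumed_total += float(take_N.sum()) * area
        produced_total += produced_step
        if window_start_removed is not None:
            window_produced += produced_step
        if n_seg:
            # attribute the (possibly clipped) per-pixel uptake back to the
            # segments in proportion to what each requested there, so the
            # per-segment ledger sums exactly to the field mass removed
            tot_want = sink_X.reshape(-1)[seg_px]
            share = np.where(tot_want > 0, per_px_u / np.where(tot_want > 0, tot_want, 1.0), 0.0)
            seg_take = np.bincount(
                seg_id,
                weights=(take_X * area).reshape(-1)[seg_px] * share,
                minlength=n_seg,
            )
            removed += seg_take
        t += dt

        if window_start_removed is not None and t - window_t0 >= p.production_window:
            window_removed = removed - window_start_removed
            break

        if step % check_every == 0:
            block = float(removed.sum()) - block_removed_start
            rate = block / (check_every * dt)
            block_removed_start = float(removed.sum())
            active = n_flat[prod_px] > p.activation_threshold if len(prod_px) else np.zeros(0, bool)
            series.append((t, rate, float(active.mean()) if len(active) else 0.0,
                           float(N.sum()) * area, float(X.sum()) * area))
            if not steady and not math.isnan(prev_rate):
                drift = abs(rate - prev_rate) / max(abs(rate), 1e-30)
                near_zero = max(rate, prev_rate) < 1e-12
                if drift < p.steady_tol or (near_zero and t > 5 * check_every * dt):
                    steady = True
                    t_steady = t
                    window_start_removed = removed.copy()
                    window_t0 = t
            prev_rate = rate
            if not steady and t >= p.max_sim_time:
                logger.warning("factory reached max_sim_time without steady state")
                break

    active = n_flat[prod_px] > p.activation_threshold if len(prod_px) else np.zeros(0, bool)
    state = FactoryState(
        field_N=SoluteField("N", N, h),
        field_X=SoluteField("X", X, h),
        t=t,
        delivered_per_edge=delivered,
        removed_per_edge=removed,
        producer_active=active,
        throughput_rate=rate,
        steady=steady,
        t_steady=t_steady,
        window_removed_per_edge=window_removed,
        window_produced=window_produced,
        window_duration=(t - window_t0) if window_removed is not None else 0.0,
        produced_total=produced_total,
        consumed_total=consumed_total,
        segment_labels=[s.label for s in segments],
    )
    state.series = pd.DataFrame(
        series, columns=["t", "throughput_rate", "active_fraction", "total_N", "total_X"]
    )
    return state


def compute_throughput(state: FactoryState, window: float | None = None) -> float:
    """Steady-state throughput in ug/h.

    Sums the product mass removed by every exchange segment over the
    accounting window and divides by the window.  Raises if the factory
    never reached steady state.
    """
    if not state.steady or state.window_removed_per_edge is None:
        raise RuntimeError("throughput is only defined at steady state")
    duration = window if window is not None else state.window_duration
    if duration <= 0:
        raise ValueError("window must be > 0")
    mass_pg = float(state.window_removed_per_edge.sum())
    return mass_pg / PG_PER_UG / (state.window_duration / S_PER_H)


def per_volume_throughput(state: FactoryState, config: SimulationConfig) -> float:
    """Throughput per cubic um of culture (slab depth = one cell diameter)."""
    volume = config.domain_width * config.domain_height * 2.0 * config.cell_radius
    return compute_throughput(state) / volume


def baseline_throughput(config: SimulationConfig, seed: int | None = None) -> float:
    """Throughput of the identical factory with no vascular network.

    Runs the pipeline at vascular_fraction = 0: the producer layout is drawn
    and shoved exactly as usual, no interior network exists, and the two
    circulatory columns alone exchange material (single-pipe flow).
    """
    import dataclasses

    from .core import make_initial_state
    from .morphogenesis import relax_shoving

    cfg = dataclasses.replace(config, vascular_fraction=0.0)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cells = make_initial_state(cfg, rng)
    cells, _ = relax_shoving(cells, max_iters=120,
                             domain=(cfg.domain_width, cfg.domain_height))
    state = run_factory(cells, None, None, cfg)
    return compute_throughput(state)
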