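"""Evaluation harness: the three study designs plus synthetic fixtures.

The studies mirror the evaluation questions the factory design poses:
how productivity depends on the vascular/producer cell ratio, how robust
self-organization is to the random seed, and how productivity scales with
the separation of the circulatory columns.  All runs are fully determined
by (config, master seed): run ``k`` uses seed ``master_seed + k`` (mod
2^31), so reruns and parallel splits reproduce bit-identical records.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .core import BinaryMask
from .factory import (
    baseline_throughput,
    compute_throughput,
    per_volume_throughput,
    run_factory,
)
from .flow import solve_network_flow, source_sink_connected
from .morphogenesis import run_morphogenesis
from .vesselgraph import INTERIOR, SINK, SOURCE, GraphEdge, GraphNode, VesselGraph, extract_vessel_graph

logger = logging.getLogger(__name__)

SEED_MOD = 2**31


def derive_seed(master_seed: int, index: int) -> int:
    """Counter scheme for per-run seeds: master + run index, mod 2^31."""
    return int((master_seed + index) % SEED_MOD)


# ---------------------------------------------------------------------------
# one full three-phase run


@dataclass
class PipelineResult:
    seed: int
    vascular_fraction: float
    connected: bool
    throughput: float               # ug/h
    baseline: float                 # ug/h, same seed, fraction 0
    relative_productivity: float
    active_fraction: float
    per_volume_productivity: float  # ug/h per um^3
    n_nodes: int
    n_edges: int


def run_pipeline(
    config: SimulationConfig,
    seed: int,
    baseline: float | None = None,
) -> PipelineResult:
    """Morphogenesis -> graph extraction -> flow -> factory, one seed.

    A disconnected network is not an error: the factory then runs on the
    circulatory columns alone and scores baseline-like throughput.
    ``baseline`` can be passed in to avoid recomputing it per fraction (it
    depends only on the seed).
    """
    cfg = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(seed)
    morph = run_morphogenesis(cfg, rng)
    graph = extract_vessel_graph(morph.cells, cfg)
    connected = source_sink_connected(graph)
    flow_solution = solve_network_flow(graph, cfg.flow_params) if connected else None
    state = run_factory(morph.cells, graph if connected else None,
                        flow_solution, cfg)
    throughput = compute_throughput(state)
    if baseline is None:
        baseline = baseline_throughput(cfg, seed=seed)
    interior = [n for n in graph.nodes if n.kind == INTERIOR]
    return PipelineResult(
        seed=seed,
        vascular_fraction=cfg.vascular_fraction,
        connected=connected,
        throughput=throughput,
        baseline=baseline,
        relative_productivity=throughput / baseline if baseline > 0 else math.inf,
        active_fraction=float(state.producer_active.mean())
        if len(state.producer_active) else 0.0,
        per_volume_productivity=per_volume_throughput(state, cfg),
        n_nodes=len(interior),
        n_edges=len(graph.edges),
    )


# ---------------------------------------------------------------------------
# studies


@dataclass
class SweepRecord:
    vascular_fraction: float
    width: float                     # um, circulatory column separation proxy
    seed: int
    connected: bool
    throughput: float                # ug/h
    relative_productivity: float
    active_fraction: float
    per_volume_productivity: float


def _to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def sweep_vascular_fraction(
    config: SimulationConfig,
    fractions: list[float],
    reps: int,
    master_seed: int | None = None,
) -> list[SweepRecord]:
    """Full three-phase run for every (fraction, rep) pair.

    Seeds are shared across fractions (rep k uses seed master+k for every
    fraction) so the comparison is paired; each seed's no-network baseline
    is computed once and reused.  Fraction 0 scores relative productivity 1
    by definition (self-ratio).
    """
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    master = config.seed if master_seed is None else master_seed
    seeds = [derive_seed(master, k) for k in range(reps)]
    baselines = {s: baseline_throughput(config, seed=s) for s in seeds}
    records: list[SweepRecord] = []
    for frac in fractions:
        cfg = dataclasses.replace(config, vascular_fraction=frac)
        for s in seeds:
            if frac == 0.0:
                records.append(SweepRecord(frac, config.domain_width, s, False,
                                           baselines[s], 1.0, 0.0, math.nan))
                continue
            res = run_pipeline(cfg, s, baseline=baselines[s])
            records.append(SweepRecord(
                frac, config.domain_width, s, res.connected, res.throughput,
                res.relative_productivity, res.active_fraction,
                res.per_volume_productivity,
            ))
            logger.info("fraction %.2f seed %d: connected=%s rel=%.2f",
                        frac, s, res.connected, res.relative_productivity)
    return records


def summarize_sweep(records: list[SweepRecord]) -> pd.DataFrame:
    """Mean +/- sd of throughput and relative productivity per fraction."""
    df = _to_frame(records)
    return (df.groupby("vascular_fraction")
              .agg(n=("seed", "size"),
                   n_connected=("connected", "sum"),
                   throughput_mean=("throughput", "mean"),
                   throughput_sd=("throughput", "std"),
                   relative_mean=("relative_productivity", "mean"),
                   relative_sd=("relative_productivity", "std"),
                   active_mean=("active_fraction", "mean"))
              .reset_index())


def robustness_study(
    config: SimulationConfig,
    n_seeds: int,
    master_seed: int | None = None,
) -> dict:
    """Throughput spread of the fixed-fraction pipeline over random seeds.

    Returns the throughput list, mean, sd and coefficient of variation over
    the connected runs; disconnected runs are reported separately rather
    than polluting the spread statistics.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    master = config.seed if master_seed is None else master_seed
    results = [run_pipeline(config, derive_seed(master, k)) for k in range(n_seeds)]
    connected = [r.throughput for r in results if r.connected]
    arr = np.array(connected)
    mean = float(arr.mean()) if len(arr) else math.nan
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
    return {
        "throughputs": connected,
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if len(arr) > 1 and mean > 0 else math.nan,
        "n_connected": len(connected),
        "n_disconnected": n_seeds - len(connected),
        "disconnected_throughputs": [r.throughput for r in results if not r.connected],
    }


def width_scaling_study(
    config: SimulationConfig,
    widths: list[float],
    reps: int = 1,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Per-volume productivity as the circulatory column separation grows.

    Interior cell count scales with the domain area (constant seeding
    density), mirroring a wider culture rather than a sparser one.  The
    returned table carries one row per width plus the max relative spread of
    the per-volume productivity across widths.
    """
    if any(w <= 0 for w in widths):
        raise ValueError("widths must be > 0")
    master = config.seed if master_seed is None else master_seed
    base_density = config.n_interior_cells / (
        (config.interior_x_range[1] - config.interior_x_range[0]) * config.domain_height
    )
    rows = []
    for w in widths:
        cfg = dataclasses.replace(config, domain_width=float(w))
        n = int(round(base_density
                      * (cfg.interior_x_range[1] - cfg.interior_x_range[0])
                      * cfg.domain_height))
        cfg = dataclasses.replace(cfg, n_interior_cells=n)
        for k in range(reps):
            res = run_pipeline(cfg, derive_seed(master, k))
            rows.append({
                "width": w,
                "seed": res.seed,
                "connected": res.connected,
                "throughput": res.throughput,
                "per_volume_productivity": res.per_volume_productivity,
            })
    df = pd.DataFrame(rows)
    means = df.groupby("width")["per_volume_productivity"].mean()
    spread = float((means.max() - means.min()) / means.mean()) if means.mean() > 0 else math.nan
    df.attrs["per_volume_spread"] = spread
    return df


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_lattice_graph(
    rows: int,
    cols: int,
    radius: float,
    pitch: float,
    terminal_length_factor: float = 1e-6,
) -> VesselGraph:
    """Regular grid of identical pipes with terminals on the outer columns.

    Node (r, c) sits at (c*pitch, r*pitch); horizontal and vertical
    neighbours are joined by pipes of the given radius and length ``pitch``.
    The SOURCE (SINK) supernode connects to every left (right) column node
    through a near-zero-resistance edge (same radius, length
    ``terminal_length_factor * pitch``), so small lattices have
    hand-computable equivalent resistance.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    nodes = [GraphNode(r * cols + c, (c * pitch, r * pitch))
             for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            nid = r * cols + c
            if c + 1 < cols:
                edges.append(GraphEdge(nid, nid + 1, radius, pitch))
            if r + 1 < rows:
                edges.append(GraphEdge(nid, nid + cols, radius, pitch))
    src = GraphNode(rows * cols, (-pitch, (rows - 1) * pitch / 2.0), SOURCE)
    snk = GraphNode(rows * cols + 1, (cols * pitch, (rows - 1) * pitch / 2.0), SINK)
    tlen = terminal_length_factor * pitch
    for r in range(rows):
        edges.append(GraphEdge(src.id, r * cols, radius, tlen))
        edges.append(GraphEdge(snk.id, r * cols + cols - 1, radius, tlen))
    return VesselGraph(nodes + [src, snk], edges)


def make_phantom_mask(
    shape: str,
    resolution: float = 1.0,
    size: int = 64,
    strip_width: int = 5,
    k: int = 3,
) -> BinaryMask:
    """Deterministic masks with known topology for extraction tests.

    ``strip``: one horizontal bar (1 component, 0 holes).  ``cross``: a plus
    sign (1 component, 0 holes).  ``ring``: an annulus (1 component,
    1 hole).  ``lattice``: a k x k grid of bars ((k-1)^2 holes).
    """
    m = np.zeros((size, size), dtype=bool)
    w = strip_width
    mid = size // 2
    lo, hi = mid - w // 2, mid + (w + 1) // 2
    margin = max(4, w)
    if shape == "strip":
        m[lo:hi, margin:size - margin] = True
    elif shape == "cross":
        m[lo:hi, margin:size - margin] = True
        m[margin:size - margin, lo:hi] = True
    elif shape == "ring":
        yy, xx = np.mgrid[0:size, 0:size]
        rr = np.hypot(yy - mid + 0.5, xx - mid + 0.5)
        outer = size / 2 - margin
        m[(rr <= outer) & (rr >= outer - w)] = True
    elif shape == "lattice":
        span = size - 2 * margin
        positions = [margin + round(i * (span - w) / (k - 1)) for i in range(k)] \
            if k > 1 else [mid - w // 2]
        for p in positions:
            m[p:p + w, margin:size - margin] = True
            m[margin:size - margin, p:p + w] = True
    else:
        raise ValueError(f"unknown phantom shape {shape!r}")
    return BinaryMask(m, resolution)
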