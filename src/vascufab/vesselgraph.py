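"""Phase II, extraction half: vascular morphology -> network of pipes.

The binary vascular mask is skeletonized to a one-pixel-wide medial axis,
local vessel widths are measured with a Euclidean distance transform, and
the skeleton is traced into an undirected graph whose edges carry a radius
(half the mean local width along the branch) and a path length.  Source and
sink supernodes are attached to every node lying in a band next to the
circulatory columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize, thin

from .config import SimulationConfig
from .core import BinaryMask

SQRT2 = math.sqrt(2.0)

INTERIOR = "INTERIOR"
SOURCE = "SOURCE"
SINK = "SINK"


@dataclass
class GraphNode:
    id: int
    position: tuple[float, float]   # um
    kind: str = INTERIOR


@dataclass
class GraphEdge:
    node_i: int
    node_j: int
    radius: float   # um
    length: float   # um
    path: list[tuple[int, int]] = field(default_factory=list)   # pixel (row, col)


@dataclass
class VesselGraph:
    """Undirected pipe network; parallel edges and self-loops are allowed
    (a lacuna can close onto a single junction)."""

    nodes: list[GraphNode]
    edges: list[GraphEdge]

    def node(self, node_id: int) -> GraphNode:
        return self._node_map()[node_id]

    def _node_map(self) -> dict[int, GraphNode]:
        return {n.id: n for n in self.nodes}

    def terminal(self, kind: str) -> GraphNode | None:
        for n in self.nodes:
            if n.kind == kind:
                return n
        return None

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, position=n.position, kind=n.kind)
        for k, e in enumerate(self.edges):
            g.add_edge(e.node_i, e.node_j, key=k, radius=e.radius,
                       length=e.length, path=e.path, index=k)
        return g


@dataclass
class WidthMap:
    """Local vessel width in um, zero outside the mask."""

    values: np.ndarray
    resolution: float


# ---------------------------------------------------------------------------
# width


def local_width_map(mask: BinaryMask, method: str = "edt") -> WidthMap:
    """Local vessel width: twice the distance to the nearest background pixel.

    ``method='edt'`` (default) is the local-thickness approximation
    2*EDT; ``method='thickness'`` is the true local thickness (diameter of
    the largest inscribed disk covering each pixel), which is slower but
    does not under-report widths away from the centreline.
    """
    m = mask.values
    h = mask.resolution
    if m.all() and m.size:
        raise ValueError("mask has no background; local width is undefined")
    edt = ndimage.distance_transform_edt(m) * h
    if method == "edt":
        return WidthMap(2.0 * edt, h)
    if method != "thickness":
        raise ValueError(f"unknown width method {method!r}")
    width = np.zeros_like(edt)
    order = np.argsort(edt, axis=None)[::-1]
    rows, cols = m.shape
    for flat in order:
        i, j = divmod(int(flat), cols)
        r = edt[i, j]
        if r <= 0:
            break
        n = int(math.ceil(r / h))
        i0, i1 = max(i - n, 0), min(i + n + 1, rows)
        j0, j1 = max(j - n, 0), min(j + n + 1, cols)
        ii = (np.arange(i0, i1) - i) * h
        jj = (np.arange(j0, j1) - j) * h
        inside = ii[:, None] ** 2 + jj[None, :] ** 2 <= r * r
        block = width[i0:i1, j0:j1]
        np.maximum(block, np.where(inside, 2.0 * r, 0.0), out=block)
    width[~m] = 0.0
    return WidthMap(width, h)


# ---------------------------------------------------------------------------
# skeleton


_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(sk: np.ndarray) -> np.ndarray:
    return ndimage.convolve(sk.astype(np.uint8), _NEIGH_KERNEL,
                            mode="constant", cval=0)


def _two_by_two_blocks(sk: np.ndarray) -> np.ndarray:
    """Mask of pixels participating in a fully-true 2x2 block."""
    blocks = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
    out = np.zeros_like(sk)
    out[:-1, :-1] |= blocks
    out[1:, :-1] |= blocks
    out[:-1, 1:] |= blocks
    out[1:, 1:] |= blocks
    return out


def _is_simple_point(sk: np.ndarray, i: int, j: int) -> bool:
    """True if removing pixel (i, j) preserves local 8-connectivity."""
    patch = np.zeros((3, 3), dtype=bool)
    rows, cols = sk.shape
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii, jj = i + di, j + dj
            if 0 <= ii < rows and 0 <= jj < cols:
                patch[di + 1, dj + 1] = sk[ii, jj]
    patch[1, 1] = False
    lab, n = ndimage.label(patch, structure=np.ones((3, 3)))
    return n == 1


def _thin_blocks(sk: np.ndarray) -> np.ndarray:
    """Remove redundant pixels until no 2x2 block remains (topology kept)."""
    sk = sk.copy()
    for _ in range(8):
        blocks = _two_by_two_blocks(sk)
        if not blocks.any():
            break
        removed = False
        for i, j in zip(*np.nonzero(blocks)):
            if _two_by_two_blocks(sk)[i, j] and _is_simple_point(sk, i, j):
                sk[i, j] = False
                removed = True
        if not removed:
            break
    return sk


def skeletonize_mask(mask: BinaryMask) -> BinaryMask:
    """One-pixel-wide, 8-connected, topology-preserving medial axis.

    Uses the Lee thinning algorithm followed by a redundant-pixel cleanup
    that removes simple points until no 2x2 foreground block remains, so the
    result satisfies the width precondition of :func:`skeleton_to_graph`.
    """
    if not mask.values.any():
        return BinaryMask(np.zeros_like(mask.values), mask.resolution)
    sk = skeletonize(mask.values, method="lee").astype(bool)
    if _two_by_two_blocks(sk).any():
        sk = thin(sk)   # guaranteed-thin pass on the rare thick remnants
    sk = _thin_blocks(sk)
    return BinaryMask(sk, mask.resolution)


# ---------------------------------------------------------------------------
# skeleton -> graph

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_neighbors(sk: np.ndarray, i: int, j: int):
    rows, cols = sk.shape
    for di, dj in _OFFSETS:
        ii, jj = i + di, j + dj
        if 0 <= ii < rows and 0 <= jj < cols and sk[ii, jj]:
            yield (ii, jj)


def _step_length(p, q, h: float) -> float:
    return h * SQRT2 if (p[0] != q[0] and p[1] != q[1]) else h


def _path_length(path, h: float) -> float:
    return sum(_step_length(p, q, h) for p, q in zip(path[:-1], path[1:]))


def _mean_radius(path, widths: WidthMap) -> float:
    vals = [widths.values[p] for p in path]
    return 0.5 * float(np.mean(vals))


def skeleton_to_graph(skeleton: BinaryMask, widths: WidthMap) -> VesselGraph:
    """Trace a 1-pixel skeleton into nodes and edges.

    Pixels are classified by 8-neighbour count: 1 = endpoint, 2 = slab,
    >= 3 = junction.  Adjacent junction pixels merge into one node at their
    centroid; branches are traced slab to slab between nodes.  Edge length
    sums the pixel steps (h axial, h*sqrt(2) diagonal); edge radius is half
    the mean local width over the branch path.  A closed loop with no
    junction gets an anchor node at its lexicographically smallest pixel and
    a self-loop edge.  Deterministic: pixels are scanned in row-major order.
    """
    sk = skeleton.values
    h = skeleton.resolution
    counts = _neighbor_counts(sk)
    # 2x2 blocks inside junction clusters are legitimate thinning residue
    # and merge into one node below; a solid 3x3 square can never occur in
    # a thin skeleton and marks a genuinely thick input
    thick = ndimage.binary_erosion(sk, structure=np.ones((3, 3)))
    if thick.any():
        i, j = next(zip(*np.nonzero(thick)))
        raise ValueError(f"skeleton is wider than 1 pixel at ({int(i)}, {int(j)})")
    node_px = sk & (counts != 2)          # endpoints, junctions, isolated px
    junction_px = sk & (counts >= 3)

    # junction clusters -> one node each; endpoints/isolated -> own node
    lab, n_lab = ndimage.label(junction_px, structure=np.ones((3, 3)))
    px_to_node: dict[tuple[int, int], int] = {}
    nodes: list[GraphNode] = []
    for lbl in range(1, n_lab + 1):
        pix = np.argwhere(lab == lbl)
        cy, cx = pix.mean(axis=0)
        nid = len(nodes)
        nodes.append(GraphNode(nid, ((cx + 0.5) * h, (cy + 0.5) * h)))
        for i, j in pix:
            px_to_node[(int(i), int(j))] = nid
    for i, j in np.argwhere(node_px & ~junction_px):
        nid = len(nodes)
        nodes.append(GraphNode(nid, ((j + 0.5) * h, (i + 0.5) * h)))
        px_to_node[(int(i), int(j))] = nid

    edges: list[GraphEdge] = []
    visited_slab: set[tuple[int, int]] = set()
    seen_direct: set[tuple[int, int, int, int]] = set()

    def add_edge(path):
        a = px_to_node[path[0]]
        b = px_to_node[path[-1]]
        edges.append(GraphEdge(a, b, _mean_radius(path, widths),
                               _path_length(path, h), list(path)))

    # branches leaving node pixels
    for start in sorted(px_to_node):
        for nb in _pixel_neighbors(sk, *start):
            if nb in px_to_node:
                a, b = px_to_node[start], px_to_node[nb]
                if a != b:
                    key = (*min(start, nb), *max(start, nb))
                    if key not in seen_direct:
                        seen_direct.add(key)
                        add_edge([start, nb])
                continue
            if nb in visited_slab:
                continue
            path = [start, nb]
            visited_slab.add(nb)
            prev, cur = start, nb
            while cur not in px_to_node:
                nxts = [q for q in _pixel_neighbors(sk, *cur) if q != prev]
                # a slab pixel has exactly 2 neighbours; diagonal shortcuts
                # back to the previous pixel's neighbours are excluded
                nxts = [q for q in nxts if q not in path[-3:-1]]
                if not nxts:
                    break   # dangling slab (shouldn't happen); treat as end
                nxt = nxts[0]
                if nxt in px_to_node:
                    path.append(nxt)
                    break
                visited_slab.add(nxt)
                path.append(nxt)
                prev, cur = cur, nxt
            if path[-1] in px_to_node:
                add_edge(path)
            else:
                # dangling end without an endpoint pixel: make a node there
                tail = path[-1]
                nid = len(nodes)
                nodes.append(GraphNode(nid, ((tail[1] + 0.5) * h, (tail[0] + 0.5) * h)))
                px_to_node[tail] = nid
                add_edge(path)

    # pure loops: slab components never reached from a node pixel
    remaining = sk & (counts == 2)
    for p in visited_slab:
        remaining[p] = False
    for p in px_to_node:
        remaining[p] = False
    lab, n_lab = ndimage.label(remaining, structure=np.ones((3, 3)))
    for lbl in range(1, n_lab + 1):
        pix = [tuple(map(int, p)) for p in np.argwhere(lab == lbl)]
        anchor = min(pix)
        nid = len(nodes)
        nodes.append(GraphNode(nid, ((anchor[1] + 0.5) * h, (anchor[0] + 0.5) * h)))
        px_to_node[anchor] = nid
        nbs = [q for q in _pixel_neighbors(sk, *anchor) if q != anchor]
        if len(nbs) < 2:
            continue
        path = [anchor, nbs[0]]
        prev, cur = anchor, nbs[0]
        while cur != anchor:
            nxts = [q for q in _pixel_neighbors(sk, *cur)
                    if q != prev and q not in path[-3:-1]]
            if not nxts:
                break
            nxt = nxts[0]
            path.append(nxt)
            prev, cur = cur, nxt
        add_edge(path)

    return VesselGraph(nodes, edges)


# ---------------------------------------------------------------------------
# pruning and terminals


def prune_graph(graph: VesselGraph, min_spur_length: float) -> VesselGraph:
    """Remove short dead-end spurs and merge pass-through nodes.

    Iteratively deletes edges that end in a degree-1 INTERIOR node and are
    shorter than ``min_spur_length`` (edges touching SOURCE/SINK are never
    removed), then merges every remaining degree-2 INTERIOR node by
    concatenating its two edges (lengths add; radius is the length-weighted
    mean).
    """
    if min_spur_length < 0:
        raise ValueError("min_spur_length must be >= 0")
    g = graph.to_networkx()

    touched: set[int] = set()   # nodes that lost a spur
    changed = True
    while changed and min_spur_length > 0:
        changed = False
        for nid in list(g.nodes):
            if g.nodes[nid]["kind"] != INTERIOR or g.degree(nid) != 1:
                continue
            (u, v, key), = g.edges(nid, keys=True)
            other = v if u == nid else u
            if g.nodes[other]["kind"] != INTERIOR:
                continue
            if g.edges[u, v, key]["length"] < min_spur_length:
                g.remove_edge(u, v, key)
                g.remove_node(nid)
                touched.add(other)
                changed = True

    # merge only the pass-through nodes pruning created; a graph that was
    # all cycles to begin with passes through unchanged
    merged = True
    while merged:
        merged = False
        for nid in list(touched):
            if nid not in g or g.nodes[nid]["kind"] != INTERIOR or g.degree(nid) != 2:
                continue
            inc = list(g.edges(nid, keys=True, data=True))
            if len(inc) != 2:
                continue   # a self-loop contributes degree 2 via one edge
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            a = v1 if u1 == nid else u1
            b = v2 if u2 == nid else u2
            if a == nid or b == nid:
                continue   # self-loop involved; leave alone
            path1 = list(d1["path"])
            path2 = list(d2["path"])
            length = d1["length"] + d2["length"]
            radius = ((d1["radius"] * d1["length"] + d2["radius"] * d2["length"])
                      / length) if length > 0 else d1["radius"]
            newpath = _concat_paths(path1, path2)
            g.remove_edge(u1, v1, k1)
            g.remove_edge(u2, v2, k2)
            g.remove_node(nid)
            g.add_edge(a, b, radius=radius, length=length, path=newpath)
            merged = True

    return _from_networkx(g)


def _concat_paths(p1: list, p2: list) -> list:
    """Join two pixel paths that share one endpoint pixel."""
    if not p1 or not p2:
        return list(p1) + list(p2)
    if p1[-1] == p2[0]:
        return list(p1) + list(p2[1:])
    if p1[-1] == p2[-1]:
        return list(p1) + list(reversed(p2))[1:]
    if p1[0] == p2[0]:
        return list(reversed(p1)) + list(p2[1:])
    if p1[0] == p2[-1]:
        return list(p2) + list(p1[1:])
    return list(p1) + list(p2)


def _from_networkx(g: nx.MultiGraph) -> VesselGraph:
    nodes = [GraphNode(nid, tuple(data["position"]), data["kind"])
             for nid, data in sorted(g.nodes(data=True))]
    edges = [GraphEdge(u, v, d["radius"], d["length"], list(d.get("path", [])))
             for u, v, d in g.edges(data=True)]
    return VesselGraph(nodes, edges)


def attach_terminals(graph: VesselGraph, config: SimulationConfig) -> VesselGraph:
    """Couple the extracted network to the circulatory columns.

    Adds one SOURCE and one SINK supernode; every node within one cell
    diameter of the left (resp. right) column is joined to it by a
    near-zero-resistance edge (radius = the largest edge radius present,
    length = one pixel).  If no node lies in a band the graph is returned
    without that terminal's connections (the flow solve then reports
    disconnection).
    """
    r = config.cell_radius
    W, H = config.domain_width, config.domain_height
    h = config.grid_resolution
    band = 4.0 * r   # column band (2r) plus one cell diameter

    next_id = max((n.id for n in graph.nodes), default=-1) + 1
    src = GraphNode(next_id, (r, H / 2.0), SOURCE)
    snk = GraphNode(next_id + 1, (W - r, H / 2.0), SINK)
    max_radius = max((e.radius for e in graph.edges), default=r)

    # a skeleton node stands for a vessel extending one local radius to
    # each side; wide vessels abutting a column have retracted centrelines,
    # so the reach of each node grows by its incident vessel radius
    reach: dict[int, float] = {n.id: 0.0 for n in graph.nodes}
    for e in graph.edges:
        for nid in (e.node_i, e.node_j):
            reach[nid] = max(reach[nid], e.radius)

    new_edges = list(graph.edges)
    for n in graph.nodes:
        if n.kind != INTERIOR:
            continue
        if n.position[0] <= band + reach[n.id]:
            new_edges.append(GraphEdge(src.id, n.id, max_radius, h, []))
        if n.position[0] >= W - band - reach[n.id]:
            new_edges.append(GraphEdge(snk.id, n.id, max_radius, h, []))
    return VesselGraph(list(graph.nodes) + [src, snk], new_edges)


def extract_vessel_graph(cells, config: SimulationConfig) -> VesselGraph:
    """Full Phase II extraction: cells -> mask -> skeleton -> pruned graph
    with terminals attached."""
    from .core import CellKind, rasterize_particles

    mask = rasterize_particles(cells, (CellKind.VASCULAR,),
                               config.grid_resolution, config.grid_shape,
                               dilation=config.mask_dilation)
    if config.mask_closing > 0 and mask.values.any():
        # the render step blurs cells in point contact into one stroke;
        # closing bridges the same sub-resolution gaps in-memory
        closed = ndimage.binary_closing(
            mask.values, structure=np.ones((3, 3)),
            iterations=config.mask_closing)
        mask = BinaryMask(closed, mask.resolution)
    if not mask.values.any():
        g = VesselGraph([], [])
        return attach_terminals(g, config)
    widths = local_width_map(mask)
    sk = skeletonize_mask(mask)
    graph = skeleton_to_graph(sk, widths)
    graph = prune_graph(graph, config.spur_threshold)
    return attach_terminals(graph, config)
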