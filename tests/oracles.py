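"""Independent reference implementations used only by the test suite.

These deliberately re-derive results through different formulations than the
package (dense loop-law assembly instead of the nodal solve, per-pixel brute
force instead of windowed rasterization) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from vascufab.flow import edge_conductance
from vascufab.vesselgraph import SINK, SOURCE, VesselGraph


def loop_law_flows(graph: VesselGraph, delta_P: float, eta: float) -> np.ndarray:
    """Solve the pipe network from the literal edge/node/loop equations.

    Unknowns are the per-edge flows Q_e and pressure drops dP_e (no nodal
    potentials).  Equations: the laminar edge law Q_e = g_e * dP_e for every
    edge; zero net flow at every interior node; zero pressure-drop sum
    around every fundamental cycle of a spanning forest; and dP summed along
    one source->sink path equal to the imposed pressure difference.  Solved
    densely by least squares; exact for consistent systems.
    """
    import networkx as nx

    src = graph.terminal(SOURCE).id
    snk = graph.terminal(SINK).id
    g = nx.MultiGraph()
    g.add_nodes_from(n.id for n in graph.nodes)
    for k, e in enumerate(graph.edges):
        if e.node_i != e.node_j:
            g.add_edge(e.node_i, e.node_j, key=k)

    component = nx.node_connected_component(g, src)
    m = len(graph.edges)
    # unknown vector: [Q_0..Q_m-1, dP_0..dP_m-1]
    rows, rhs = [], []

    def row():
        return np.zeros(2 * m)

    for k, e in enumerate(graph.edges):
        r = row()
        if e.node_i == e.node_j or e.node_i not in component:
            r[k] = 1.0          # Q = 0 outside the perfused component
            rows.append(r); rhs.append(0.0)
            r2 = row(); r2[m + k] = 1.0
            rows.append(r2); rhs.append(0.0)
            continue
        ge = edge_conductance(e.radius, e.length, eta)
        # normalized form dP_e - Q_e/g_e = 0 keeps the system well scaled
        r[k] = -1.0 / ge
        r[m + k] = 1.0
        rows.append(r); rhs.append(0.0)

    for node in graph.nodes:
        if node.id in (src, snk) or node.id not in component:
            continue
        r = row()
        for k, e in enumerate(graph.edges):
            if e.node_i == e.node_j:
                continue
            if e.node_i == node.id:
                r[k] -= 1.0
            if e.node_j == node.id:
                r[k] += 1.0
        if np.any(r):
            rows.append(r); rhs.append(0.0)

    # fundamental cycles of a spanning forest + the source->sink path
    tree_keys = set()
    for comp in nx.connected_components(g):
        tree_keys |= {key for _, _, key in
                      nx.minimum_spanning_edges(g.subgraph(comp), keys=True, data=False)}
    tg = nx.Graph()
    tg.add_nodes_from(g.nodes)
    for u, v, key in g.edges(keys=True):
        if key in tree_keys:
            tg.add_edge(u, v, key=key)

    def signed_path_row(path_nodes):
        r = row()
        for a, b in zip(path_nodes[:-1], path_nodes[1:]):
            key = tg.edges[a, b]["key"]
            e = graph.edges[key]
            r[m + key] += 1.0 if e.node_i == a else -1.0
        return r

    for u, v, key in g.edges(keys=True):
        if key in tree_keys or u not in component:
            continue
        e = graph.edges[key]
        r = signed_path_row(nx.shortest_path(tg, v, u))
        r[m + key] += 1.0 if e.node_i == u else -1.0
        rows.append(r); rhs.append(0.0)

    rows.append(signed_path_row(nx.shortest_path(tg, src, snk)))
    rhs.append(delta_P)

    A = np.array(rows)
    b = np.array(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:m]


def brute_force_mask(cells, kinds, resolution, shape, dilation=0.0):
    """Per-pixel membership test: true iff the pixel centre is inside any
    selected disk."""
    rows, cols = shape
    out = np.zeros(shape, dtype=bool)
    for i in range(rows):
        for j in range(cols):
            cx = (j + 0.5) * resolution
            cy = (i + 0.5) * resolution
            for c in cells:
                if c.kind not in kinds:
                    continue
                r = c.radius + dilation
                if (c.position[0] - cx) ** 2 + (c.position[1] - cy) ** 2 <= r * r:
                    out[i, j] = True
                    break
    return out


def count_components_and_holes(mask: np.ndarray) -> tuple[int, int]:
    """8-connected foreground components and enclosed background holes
    (4-connected background components not touching the border)."""
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    lab_bg, n_bg = ndimage.label(~mask)  # 4-connectivity
    border = set(np.unique(lab_bg[0, :])) | set(np.unique(lab_bg[-1, :])) \
        | set(np.unique(lab_bg[:, 0])) | set(np.unique(lab_bg[:, -1]))
    border.discard(0)
    holes = n_bg - len(border)
    return n_comp, holes
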