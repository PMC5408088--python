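"""Serialization: cells to CSV, fields/masks to .npy or PNG, graphs to
JSON/GraphML, and the machine-readable run manifest."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimulationConfig
from .core import BinaryMask, Cell, CellKind, SoluteField
from .vesselgraph import GraphEdge, GraphNode, VesselGraph


def cells_to_csv(cells: list[Cell], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "kind": [c.kind.name for c in cells],
            "x": [c.position[0] for c in cells],
            "y": [c.position[1] for c in cells],
            "radius": [c.radius for c in cells],
            "biomass": [c.biomass for c in cells],
            "active": [c.active for c in cells],
        }
    )
    df.to_csv(path, index=False)


def cells_from_csv(path: str | Path) -> list[Cell]:
    df = pd.read_csv(path)
    return [
        Cell(int(r.id), CellKind[r.kind], (float(r.x), float(r.y)),
             float(r.radius), float(r.biomass), bool(r.active))
        for r in df.itertuples()
    ]


def save_field(field: SoluteField, path: str | Path) -> None:
    np.save(path, field.values)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".png":
        from PIL import Image

        # row 0 is the domain bottom; PNG rows run top-down
        Image.fromarray(mask.values[::-1].astype(np.uint8) * 255, mode="L").save(path)
    else:
        np.save(path, mask.values)


def graph_to_json(graph: VesselGraph, path: str | Path) -> None:
    doc = {
        "nodes": [
            {"id": n.id, "x": n.position[0], "y": n.position[1], "kind": n.kind}
            for n in graph.nodes
        ],
        "edges": [
            {"node_i": e.node_i, "node_j": e.node_j, "radius": e.radius,
             "length": e.length, "path": [list(p) for p in e.path]}
            for e in graph.edges
        ],
    }
    Path(path).write_text(json.dumps(doc))


def graph_from_json(path: str | Path) -> VesselGraph:
    doc = json.loads(Path(path).read_text())
    nodes = [GraphNode(n["id"], (n["x"], n["y"]), n["kind"]) for n in doc["nodes"]]
    edges = [
        GraphEdge(e["node_i"], e["node_j"], e["radius"], e["length"],
                  [tuple(p) for p in e["path"]])
        for e in doc["edges"]
    ]
    return VesselGraph(nodes, edges)


def graph_to_graphml(graph: VesselGraph, path: str | Path) -> None:
    g = nx.MultiGraph()
    for n in graph.nodes:
        g.add_node(n.id, x=n.position[0], y=n.position[1], kind=n.kind)
    for k, e in enumerate(graph.edges):
        g.add_edge(e.node_i, e.node_j, key=k, radius=e.radius, length=e.length)
    nx.write_graphml(g, path)


def write_manifest(config: SimulationConfig, seed: int, path: str | Path,
                   extra: dict | None = None) -> None:
    doc = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "config": dataclasses.asdict(config),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, default=float, indent=2))
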