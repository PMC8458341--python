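"""Spatial vascular graph container.

A :class:`VascularGraph` is an undirected spatial multigraph: vertices are
tube junctions or free tube endpoints with pixel (or micron) coordinates,
edges are individual vessel segments carrying a traced polyline path, a
length and a mean thickness.  Self-loops and parallel edges are legal (they
arise from skeleton cycles) and are kept in the morphometric edge table;
topological statistics collapse them separately (see :mod:`vascnet.metrics`).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["VascularGraph", "polyline_length"]

#: vertex roles; "cycle" marks the anchor vertex of an isolated skeleton loop
VERTEX_KINDS = ("junction", "endpoint", "cycle")


def polyline_length(path: Sequence[tuple[float, float]]) -> float:
    """Euclidean length of a polyline given as (x, y) points."""
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        return 0.0
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


class VascularGraph:
    """Undirected spatial multigraph of vessels.

    Parameters
    ----------
    units:
        ``"px"`` (uncalibrated) or ``"um"`` (after applying a pixel size).
    shape:
        Optional ``(height, width)`` of the image the graph lives in.
    """

    def __init__(self, units: str = "px", shape: tuple[int, int] | None = None):
        self.g = nx.MultiGraph()
        self.units = units
        if shape is not None:
            self.g.graph["shape"] = tuple(int(s) for s in shape)

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, int] | None:
        return self.g.graph.get("shape")

    @property
    def n_vertices(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def add_vertex(self, vid: int, x: float, y: float, kind: str = "junction") -> int:
        if kind not in VERTEX_KINDS:
            raise ValueError(f"unknown vertex kind {kind!r}")
        self.g.add_node(int(vid), x=float(x), y=float(y), kind=kind)
        return int(vid)

    def add_edge(
        self,
        u: int,
        v: int,
        path: Sequence[tuple[float, float]] | None = None,
        length: float | None = None,
        thickness: float = float("nan"),
    ) -> tuple[int, int, int]:
        """Add a vessel edge; ``length`` defaults to the Euclidean path length."""
        if path is None:
            path = [
                (self.g.nodes[u]["x"], self.g.nodes[u]["y"]),
                (self.g.nodes[v]["x"], self.g.nodes[v]["y"]),
            ]
        path = [(float(x), float(y)) for x, y in path]
        if length is None:
            length = polyline_length(path)
        if not length > 0:
            raise ValueError("edge length must be positive")
        key = self.g.add_edge(int(u), int(v), path=path, length=float(length),
                              thickness=float(thickness))
        return (int(u), int(v), key)

    def vertex_coords(self, vid: int) -> tuple[float, float]:
        d = self.g.nodes[vid]
        return (d["x"], d["y"])

    def edge_lengths(self) -> np.ndarray:
        return np.array([d["length"] for *_, d in self.g.edges(data=True)], dtype=float)

    def edge_thicknesses(self) -> np.ndarray:
        return np.array([d["thickness"] for *_, d in self.g.edges(data=True)], dtype=float)

    def copy(self) -> "VascularGraph":
        out = VascularGraph(units=self.units)
        out.g = self.g.copy()
        return out

    # ------------------------------------------------------------- structure
    def classify_vertices(self) -> None:
        """Set vertex ``kind`` from current degree (1 -> endpoint, >=3 -> junction).

        Degree-2 vertices are not legal in a finished graph (chains are traced
        through); the only exception is the anchor of an isolated cycle, whose
        self-loop contributes degree 2 and which keeps kind ``"cycle"``.
        """
        for v in self.g.nodes:
            deg = self.g.degree(v)
            has_loop = self.g.number_of_edges(v, v) > 0
            if has_loop and deg == 2:
                self.g.nodes[v]["kind"] = "cycle"
            elif deg == 1:
                self.g.nodes[v]["kind"] = "endpoint"
            else:
                self.g.nodes[v]["kind"] = "junction"

    def splice_degree2(self, vertices: Iterable[int] | None = None) -> int:
        """Trace through degree-2 vertices, merging their two edges into one.

        The merged edge concatenates the two polylines at the shared vertex;
        its length is the exact sum of the two (splice additivity) and its
        thickness the length-weighted mean.  Operates on ``vertices`` if
        given, else on every eligible vertex; returns the splice count.
        """
        n_spliced = 0
        pool = self.g.nodes if vertices is None else vertices
        todo = [v for v in pool
                if v in self.g and self.g.degree(v) == 2
                and self.g.number_of_edges(v, v) == 0]
        for v in todo:
            if v not in self.g or self.g.degree(v) != 2 or self.g.number_of_edges(v, v):
                continue
            inc = list(self.g.edges(v, keys=True, data=True))
            if len(inc) != 2:
                continue
            (u1, _, k1, d1), (u2, _, k2, d2) = (
                (a if b == v else b, v, k, d) for a, b, k, d in inc
            )
            p1 = _orient(d1["path"], self.vertex_coords(v), end=True)
            p2 = _orient(d2["path"], self.vertex_coords(v), end=False)
            path = p1 + p2[1:]
            length = d1["length"] + d2["length"]
            t1, t2 = d1["thickness"], d2["thickness"]
            if math.isnan(t1) and math.isnan(t2):
                thickness = float("nan")
            else:
                thickness = (t1 * d1["length"] + t2 * d2["length"]) / length
            self.g.remove_node(v)
            self.g.add_edge(u1, u2, path=path, length=length, thickness=thickness)
            n_spliced += 1
        return n_spliced

    def apply_pixel_size(self, pixel_size: float) -> "VascularGraph":
        """Return a copy with every length and thickness multiplied by
        ``pixel_size`` (µm/px); coordinates and topology are unchanged."""
        out = self.copy()
        for *_, d in out.g.edges(data=True):
            d["length"] *= pixel_size
            d["thickness"] *= pixel_size
        out.units = "um"
        return out

    # ------------------------------------------------------------------- I/O
    def vertex_table(self) -> pd.DataFrame:
        rows = [
            {"vertex_id": v, "x": d["x"], "y": d["y"], "kind": d["kind"]}
            for v, d in sorted(self.g.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["vertex_id", "x", "y", "kind"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"edge_id": i, "v1": min(u, v), "v2": max(u, v),
             "length": d["length"], "thickness": d["thickness"]}
            for i, (u, v, d) in enumerate(
                sorted(self.g.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]), e[2]["length"]))
            )
        ]
        return pd.DataFrame(rows, columns=["edge_id", "v1", "v2", "length", "thickness"])

    def to_graphml(self, path) -> None:
        g = nx.MultiGraph()
        g.graph.update({k: v for k, v in self.g.graph.items() if not isinstance(v, (tuple, list, dict))})
        g.graph["units"] = self.units
        if self.shape is not None:
            g.graph["height"], g.graph["width"] = self.shape
        for v, d in self.g.nodes(data=True):
            g.add_node(v, x=d["x"], y=d["y"], kind=d["kind"])
        for u, v, k, d in self.g.edges(keys=True, data=True):
            pth = ";".join(f"{x:.3f},{y:.3f}" for x, y in d["path"])
            g.add_edge(u, v, key=k, length_px=d["length"], thickness_px=d["thickness"], path=pth)
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path) -> "VascularGraph":
        raw = nx.read_graphml(path, force_multigraph=True)
        units = raw.graph.get("units", "px")
        shape = None
        if "height" in raw.graph and "width" in raw.graph:
            shape = (int(raw.graph["height"]), int(raw.graph["width"]))
        vg = cls(units=units, shape=shape)
        vg.g.graph.update({k: v for k, v in raw.graph.items()
                           if k not in ("units", "height", "width")})
        for v, d in raw.nodes(data=True):
            vg.add_vertex(int(v), float(d["x"]), float(d["y"]), d.get("kind", "junction"))
        for u, v, d in raw.edges(data=True):
            pth = [tuple(map(float, p.split(","))) for p in d["path"].split(";")] if d.get("path") else None
            vg.add_edge(int(u), int(v), path=pth,
                        length=float(d["length_px"]), thickness=float(d["thickness_px"]))
        return vg


def _orient(path, anchor_xy, end: bool):
    """Return ``path`` oriented so that the point nearest ``anchor_xy`` is at
    the end (``end=True``) or start (``end=False``)."""
    first = path[0]
    last = path[-1]
    d_first = (first[0] - anchor_xy[0]) ** 2 + (first[1] - anchor_xy[1]) ** 2
    d_last = (last[0] - anchor_xy[0]) ** 2 + (last[1] - anchor_xy[1]) ** 2
    at_end = d_last <= d_first
    if at_end != end:
        return list(reversed(path))
    return list(path)
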