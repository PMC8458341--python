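"""Synthetic data: tube-network scenes with known ground truth, and
abstract reference graphs.

The image generator emulates in-vitro tube-formation (Matrigel) assays as
seen by phase/brightfield time-lapse microscopy: a planar network of bright
tubes of roughly constant width on a dark background, degraded by additive
Gaussian noise, small intra-tube holes, and disconnected cell speckles.
The temporal generator emulates network remodeling, in which short vessel
segments are resorbed and neighbouring segments fuse, so the edge count
falls while the mean edge length rises.

Reference-graph generators (Watts–Strogatz ring-rewiring model and the
uniform G(n, m) random graph used as the "equivalent random network" null)
are thin seeded wrappers around networkx.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay
from skimage.draw import line as draw_line

from .extraction import ImageFrame
from .graph import VascularGraph, polyline_length

__all__ = [
    "SyntheticScene",
    "RemodelingSchedule",
    "generate_tube_network",
    "render_scene",
    "generate_remodeling_series",
    "generate_watts_strogatz",
    "generate_equivalent_random",
]

#: tubes thinner than this cannot be reliably skeletonized back to one line
MIN_TUBE_WIDTH = 3.0

_FG = 0.85  # tube intensity before noise
_BG = 0.08  # background intensity before noise


@dataclasses.dataclass
class SyntheticScene:
    """A rendered frame together with its ground-truth graph."""

    truth_graph: VascularGraph
    image: ImageFrame
    tube_width: float
    noise_sd: float
    hole_rate: float
    speckle_count: int
    rng_seed: int

    def __post_init__(self):
        if self.tube_width < MIN_TUBE_WIDTH:
            raise ValueError(f"tube_width must be >= {MIN_TUBE_WIDTH} px")
        h, w = self.image.pixels.shape
        for *_, d in self.truth_graph.g.edges(data=True):
            pts = np.asarray(d["path"])
            if (pts[:, 0] < 0).any() or (pts[:, 0] > w - 1).any() \
                    or (pts[:, 1] < 0).any() or (pts[:, 1] > h - 1).any():
                raise ValueError("truth polyline outside image bounds")


@dataclasses.dataclass
class RemodelingSchedule:
    """Frame times and per-step remodeling intensity.

    Defaults follow a 48 h assay imaged every 2 h.
    """

    n_frames: int = 25
    frame_times: Sequence[float] = None  # hours
    merge_fraction_per_frame: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.frame_times is None:
            self.frame_times = tuple(2.0 * i for i in range(self.n_frames))
        self.frame_times = tuple(float(t) for t in self.frame_times)
        if len(self.frame_times) != self.n_frames:
            raise ValueError("frame_times length must equal n_frames")
        if any(b <= a for a, b in zip(self.frame_times, self.frame_times[1:])):
            raise ValueError("frame_times must be strictly increasing")
        if not 0.0 <= self.merge_fraction_per_frame < 1.0:
            raise ValueError("merge_fraction_per_frame must be in [0, 1)")


# --------------------------------------------------------------------------
# geometry generator
# --------------------------------------------------------------------------

def generate_tube_network(
    n_seed_points: int,
    width: int,
    height: int,
    seed: int,
    *,
    min_separation: float = 30.0,
    prune_percentile: float = 85.0,
    min_angle_deg: float = 35.0,
) -> VascularGraph:
    """Generate a connected planar tube network inside a ``height``x``width``
    canvas.

    Vertices are random points with pairwise distance >= ``min_separation``
    (choose this at least twice the tube width you intend to render);
    edges come from the Delaunay triangulation with the longest
    ``100 - prune_percentile`` percent removed, re-adding the shortest
    dropped edges as needed to stay connected.  Edge pairs meeting a vertex
    at less than ``min_angle_deg`` are thinned (the longer edge goes) so
    rendered tubes neither fuse along their flanks nor enclose
    sub-resolution faces.  Degree-2 vertices left by pruning are traced
    through, which is what produces the gently bent polylines typical of
    the assay.
    """
    if n_seed_points < 3:
        raise ValueError("n_seed_points must be >= 3")
    if width < 64 or height < 64:
        raise ValueError("canvas must be at least 64x64")
    rng = np.random.default_rng(seed)
    margin = min_separation / 2.0 + 8.0
    if width - 2 * margin < min_separation or height - 2 * margin < min_separation:
        raise ValueError("canvas too small for requested separation")

    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_seed_points:
        attempts += 1
        if attempts > 400 * n_seed_points:
            raise ValueError(
                "cannot place seed points at the requested density/separation")
        cand = np.array([
            rng.uniform(margin, width - margin),   # x
            rng.uniform(margin, height - margin),  # y
        ])
        if all(np.hypot(*(cand - p)) >= min_separation for p in pts):
            pts.append(cand)
    coords = np.vstack(pts)

    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    lengths = {e: float(np.hypot(*(coords[e[0]] - coords[e[1]]))) for e in edges}
    # inclusive cutoff: an actual edge length, so tiny graphs keep all edges
    cutoff = np.percentile(list(lengths.values()), prune_percentile,
                           method="higher")

    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    for e, l in lengths.items():
        if l <= cutoff:
            g.add_edge(*e, length=l)
    # restore connectivity with the shortest dropped edges
    for e, l in sorted(lengths.items(), key=lambda kv: kv[1]):
        if nx.is_connected(g):
            break
        if not nx.has_path(g, e[0], e[1]):
            g.add_edge(*e, length=l)

    if g.number_of_nodes() > 3:
        _prune_shallow_angles(g, coords, math.radians(min_angle_deg))
    g.remove_nodes_from([v for v in list(g) if g.degree(v) == 0])
    if g.number_of_edges() == 0:
        raise ValueError("pruning removed every edge; lower min_angle_deg")

    vg = VascularGraph(units="px", shape=(height, width))
    relabel = {v: i for i, v in enumerate(sorted(g.nodes))}
    for v, i in relabel.items():
        vg.add_vertex(i, coords[v][0], coords[v][1])
    for u, v in g.edges:
        vg.add_edge(relabel[u], relabel[v],
                    path=[tuple(coords[u]), tuple(coords[v])])
    _simplify_chain_vertices(vg)
    vg.classify_vertices()
    return vg


def _simplify_chain_vertices(vg: VascularGraph) -> None:
    """Trace through pruning-created degree-2 vertices (producing the bent
    polyline edges typical of the assay), but leave pure-cycle components —
    e.g. a minimal triangle — intact as polygons."""
    changed = True
    while changed:
        changed = False
        for comp in list(nx.connected_components(vg.g)):
            if all(vg.g.degree(w) == 2 for w in comp):
                continue  # polygon: splicing would collapse it
            cand = [v for v in comp
                    if vg.g.degree(v) == 2 and not vg.g.number_of_edges(v, v)]
            if cand and vg.splice_degree2(cand):
                changed = True


def _prune_shallow_angles(g: nx.Graph, coords: np.ndarray, min_angle: float) -> None:
    """Remove, at each vertex, the longer edge of any pair subtending less
    than ``min_angle`` — unless that edge is a bridge (connectivity wins)."""
    changed = True
    while changed:
        changed = False
        bridges = set(frozenset(e) for e in nx.bridges(g))
        for v in list(g.nodes):
            nbrs = list(g.neighbors(v))
            if len(nbrs) < 2:
                continue
            vecs = {u: coords[u] - coords[v] for u in nbrs}
            removed = False
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, b = nbrs[i], nbrs[j]
                    va, vb = vecs[a], vecs[b]
                    cosang = np.dot(va, vb) / (np.hypot(*va) * np.hypot(*vb))
                    if math.acos(np.clip(cosang, -1.0, 1.0)) < min_angle:
                        longer = a if np.hypot(*va) >= np.hypot(*vb) else b
                        if frozenset((v, longer)) not in bridges:
                            g.remove_edge(v, longer)
                            changed = removed = True
                            break
                if removed:
                    break
    return None


# --------------------------------------------------------------------------
# renderer
# --------------------------------------------------------------------------

def render_scene(
    truth: VascularGraph,
    tube_width: float,
    noise_sd: float = 0.0,
    hole_rate: float = 0.0,
    speckle_count: int = 0,
    seed: int = 0,
    *,
    shape: tuple[int, int] | None = None,
    time: float = 0.0,
    frame_id: str | None = None,
) -> SyntheticScene:
    """Render a truth graph into a grayscale frame.

    Foreground = truth polylines dilated to ``tube_width`` (distance
    threshold at ``tube_width / 2``; odd widths render exactly), minus
    punched holes of area < ``tube_width``², plus off-tube speckles of
    area < (``tube_width``/2)², plus Gaussian intensity noise clipped to
    [0, 1].  Fully deterministic given ``seed``.
    """
    if tube_width < MIN_TUBE_WIDTH:
        raise ValueError(f"tube_width must be >= {MIN_TUBE_WIDTH} px")
    if shape is None:
        shape = truth.shape
    if shape is None:
        raise ValueError("no canvas shape: pass shape= or generate the truth "
                         "graph with one")
    h, w = shape
    rng = np.random.default_rng(seed)

    center = np.zeros((h, w), dtype=bool)
    for *_, d in truth.g.edges(data=True):
        pts = np.asarray(d["path"])
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(int(round(y0)), int(round(x0)),
                               int(round(y1)), int(round(x1)))
            center[rr.clip(0, h - 1), cc.clip(0, w - 1)] = True

    dist_to_center = ndi.distance_transform_edt(~center)
    mask = dist_to_center <= tube_width / 2.0

    # punch holes strictly inside the tubes so hole-filling is decidable
    n_tube_px = int(mask.sum())
    n_holes = int(round(hole_rate * n_tube_px / 1000.0))
    hole_r = max(1.0, tube_width / 3.0)
    if n_holes:
        edt_fg = ndi.distance_transform_edt(mask)
        cand = np.argwhere(edt_fg >= hole_r + 1.5)
        if len(cand):
            pick = cand[rng.choice(len(cand), size=min(n_holes, len(cand)),
                                   replace=False)]
            yy, xx = np.mgrid[0:h, 0:w]
            for r, c in pick:
                mask[(yy - r) ** 2 + (xx - c) ** 2 <= hole_r ** 2] = False

    image = np.where(mask, _FG, _BG)

    if speckle_count:
        spk_r = max(0.8, tube_width / 4.0)
        gap = spk_r + tube_width / 2.0 + 3.0
        allowed = np.argwhere(dist_to_center > gap)
        pick = allowed[rng.choice(len(allowed),
                                  size=min(speckle_count, len(allowed)),
                                  replace=False)]
        yy, xx = np.mgrid[0:h, 0:w]
        for r, c in pick:
            image[(yy - r) ** 2 + (xx - c) ** 2 <= spk_r ** 2] = _FG

    if noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, noise_sd, image.shape), 0.0, 1.0)

    frame = ImageFrame(pixels=image, time=time, pixel_size=None,
                       frame_id=frame_id)
    return SyntheticScene(truth_graph=truth, image=frame,
                          tube_width=float(tube_width),
                          noise_sd=float(noise_sd), hole_rate=float(hole_rate),
                          speckle_count=int(speckle_count), rng_seed=int(seed))


# --------------------------------------------------------------------------
# remodeling
# --------------------------------------------------------------------------

def remodel_step(vg: VascularGraph, n_remove: int, rng: np.random.Generator) -> VascularGraph:
    """One remodeling step: remove up to ``n_remove`` edges, splicing any
    resulting degree-2 vertices; a removal only commits if the graph stays
    connected and non-empty and the mean edge length does not decrease."""
    cur = vg.copy()
    removed = 0
    edges = list(cur.g.edges(keys=True))
    rng.shuffle(edges)
    for u, v, k in edges:
        if removed >= n_remove:
            break
        if not cur.g.has_edge(u, v, k) or cur.n_edges <= 1:
            continue
        trial = cur.copy()
        trial.g.remove_edge(u, v, k)
        trial.g.remove_nodes_from([w for w in (u, v)
                                   if w in trial.g and trial.g.degree(w) == 0])
        if trial.n_edges == 0 or not nx.is_connected(trial.g):
            continue
        trial.splice_degree2()
        if trial.edge_lengths().mean() >= cur.edge_lengths().mean() - 1e-9:
            trial.classify_vertices()
            cur = trial
            removed += 1
    return cur


def generate_remodeling_series(
    initial: VascularGraph,
    schedule: RemodelingSchedule,
    *,
    tube_width: float = 5.0,
    noise_sd: float = 0.0,
    hole_rate: float = 0.0,
    speckle_count: int = 0,
) -> list[SyntheticScene]:
    """Evolve ``initial`` under the schedule and render one scene per frame.

    Edge count is non-increasing and mean truth edge length non-decreasing
    across frames by construction.  Raises if the schedule would empty the
    graph before the final frame.
    """
    ss = np.random.SeedSequence(schedule.rng_seed)
    children = ss.spawn(schedule.n_frames + 1)
    remodel_rng = np.random.default_rng(children[0])

    scenes: list[SyntheticScene] = []
    cur = initial.copy()
    cur.classify_vertices()
    for i, t in enumerate(schedule.frame_times):
        if i > 0:
            n_remove = int(round(schedule.merge_fraction_per_frame * cur.n_edges))
            if n_remove > 0 and n_remove >= cur.n_edges:
                raise ValueError(
                    "schedule would empty the graph before the last frame")
            cur = remodel_step(cur, n_remove, remodel_rng)
        frame_seed = int(children[i + 1].generate_state(1)[0] % (2 ** 31))
        scenes.append(render_scene(
            cur, tube_width, noise_sd=noise_sd, hole_rate=hole_rate,
            speckle_count=speckle_count, seed=frame_seed, time=t,
            frame_id=f"frame_{i:03d}"))
    return scenes


# --------------------------------------------------------------------------
# abstract reference graphs
# --------------------------------------------------------------------------

def generate_watts_strogatz(n: int, k: int, p: float, seed: int) -> nx.Graph:
    """Ring lattice of ``n`` vertices, each joined to its ``k`` nearest
    neighbours, with every lattice edge rewired with probability ``p`` to a
    uniformly random non-duplicate, non-self target.  p=0 is the regular
    lattice, p=1 is essentially random; the edge count n·k/2 is conserved."""
    if not (isinstance(k, (int, np.integer)) and k % 2 == 0 and 2 <= k < n):
        raise ValueError("need n > k >= 2 with k even")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    return nx.watts_strogatz_graph(int(n), int(k), float(p), seed=int(seed))


def generate_equivalent_random(n: int, m: int, seed: int) -> nx.Graph:
    """Uniform simple random graph with exactly ``n`` vertices and ``m``
    edges — the 'equivalent random network' null used for σ."""
    if m > n * (n - 1) // 2:
        raise ValueError("m exceeds the number of possible edges")
    return nx.gnm_random_graph(int(n), int(m), seed=int(seed))
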