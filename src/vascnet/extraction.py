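"""Image-to-graph extraction for tube-formation assays.

The pipeline mirrors the standard workflow for quantifying tubulogenesis
images: (1) read the frame and convert to grayscale, (2) adjust contrast
and restrict to a region of interest, (3) binarize and clean (fill small
intra-tube holes, drop small disconnected objects), (4) skeletonize, and
(5) trace the skeleton into a spatial graph of junctions, endpoints and
individual vessel segments, measuring each segment's length (chamfer step
metric along the skeleton) and thickness (from the Euclidean distance
transform of the pre-skeleton mask).

Every stage is deterministic: byte-identical inputs give identical graphs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import morphology as skmorph
from skimage.util import img_as_float

from .graph import VascularGraph

__all__ = [
    "ImageFrame",
    "BinaryMask",
    "ExtractionConfig",
    "load_frame",
    "adjust_frame",
    "binarize_and_clean",
    "skeletonize_mask",
    "extract_graph",
    "process_frame",
]

_SQRT2 = float(np.sqrt(2.0))

# 8-neighbourhood offsets, clockwise
_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


@dataclasses.dataclass
class ImageFrame:
    """One time-point grayscale image, intensities in [0, 1]."""

    pixels: np.ndarray
    time: float = 0.0
    pixel_size: float | None = None  # µm per pixel
    frame_id: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel intensities must be finite")
        if self.time < 0:
            raise ValueError("time must be >= 0")


@dataclasses.dataclass
class BinaryMask:
    """Boolean foreground mask plus the provenance of how it was made."""

    pixels: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)


@dataclasses.dataclass
class ExtractionConfig:
    """Parameters of the full pipeline.

    ``max_hole_area`` and ``min_object_area`` are in px²;
    ``spur_factor`` controls adaptive skeleton-spur pruning (tip branches
    shorter than spur_factor x their own thickness are boundary artefacts
    of skeletonization, not vessels); set 0 to disable.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    clip_percentiles: tuple[float, float] = (0.0, 100.0)
    roi: object | None = None
    max_hole_area: float = 64.0
    min_object_area: float = 64.0
    spur_factor: float = 1.5
    pixel_size_um: float | None = None


# --------------------------------------------------------------------- steps

def load_frame(path, time: float = 0.0, pixel_size: float | None = None,
               frame_id: str | None = None) -> ImageFrame:
    """Step 1 — read a TIFF/PNG frame; RGB is reduced by luminance
    weighting; integer intensities are rescaled to [0, 1]."""
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"empty image: {path}")
    arr = img_as_float(arr)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale or RGB image: {path}")
    return ImageFrame(pixels=np.clip(arr, 0.0, 1.0), time=time,
                      pixel_size=pixel_size,
                      frame_id=frame_id or str(path))


def _roi_mask(roi, shape) -> np.ndarray | None:
    if roi is None:
        return None
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError("roi mask shape mismatch")
        mask = roi
    else:  # rectangle (row0, col0, row1, col1), half-open
        r0, c0, r1, c1 = (int(v) for v in roi)
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
    if not mask.any():
        raise ValueError("empty roi")
    return mask


def adjust_frame(frame: ImageFrame, roi=None,
                 clip_percentiles: tuple[float, float] = (0.0, 100.0)) -> ImageFrame:
    """Step 2 — contrast-stretch between the given intensity percentiles
    (computed within the roi when one is given) and zero everything
    outside the roi.  Constant images pass through unchanged."""
    lo_p, hi_p = clip_percentiles
    if not (0 <= lo_p < hi_p <= 100):
        raise ValueError("clip_percentiles must satisfy 0 <= low < high <= 100")
    mask = _roi_mask(roi, frame.pixels.shape)
    sample = frame.pixels[mask] if mask is not None else frame.pixels
    lo, hi = np.percentile(sample, [lo_p, hi_p])
    px = frame.pixels
    if hi - lo > 1e-12:
        px = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    else:
        px = px.copy()
    if mask is not None:
        px = np.where(mask, px, 0.0)
    return ImageFrame(pixels=px, time=frame.time, pixel_size=frame.pixel_size,
                      frame_id=frame.frame_id)


def binarize_and_clean(frame: ImageFrame, method: str = "otsu",
                       fixed_threshold: float | None = None,
                       max_hole_area: float = 64.0,
                       min_object_area: float = 64.0) -> BinaryMask:
    """Step 3 — threshold, fill enclosed background holes of area <=
    ``max_hole_area``, then delete foreground objects of area <
    ``min_object_area``.  An all-background result is legal."""
    px = frame.pixels
    if method == "otsu":
        if px.max() - px.min() < 1e-12:
            mask = np.zeros_like(px, dtype=bool)
            thr = float("nan")
        else:
            thr = float(skfilters.threshold_otsu(px))
            mask = px > thr
    elif method == "fixed":
        if fixed_threshold is None or not 0.0 <= fixed_threshold <= 1.0:
            raise ValueError("fixed threshold must be in [0, 1]")
        thr = float(fixed_threshold)
        mask = px > thr
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    # holes: background components (4-connected) not touching the border
    bg_labels, n_bg = ndi.label(~mask)
    if n_bg:
        border = np.unique(np.concatenate([
            bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]))
        areas = np.bincount(bg_labels.ravel(), minlength=n_bg + 1)
        fill = np.zeros(n_bg + 1, dtype=bool)
        for lab in range(1, n_bg + 1):
            fill[lab] = lab not in border and areas[lab] <= max_hole_area
        mask = mask | fill[bg_labels]

    if min_object_area > 0:
        # removes objects of area < min_object_area (max_size is inclusive)
        mask = skmorph.remove_small_objects(
            mask, max_size=int(np.ceil(min_object_area)) - 1, connectivity=2)
    return BinaryMask(pixels=mask, provenance={
        "method": method, "threshold": thr,
        "max_hole_area": max_hole_area, "min_object_area": min_object_area})


def skeletonize_mask(mask: BinaryMask) -> BinaryMask:
    """Step 4 — reduce the mask to a one-pixel-wide, topology-preserving,
    8-connected medial skeleton."""
    skel = skmorph.skeletonize(mask.pixels)
    prov = dict(mask.provenance)
    prov["skeletonized"] = True
    return BinaryMask(pixels=skel, provenance=prov)


# ----------------------------------------------------------- graph tracing

def extract_graph(skeleton: BinaryMask, source_mask: BinaryMask,
                  pixel_size: float | None = None,
                  spur_factor: float = 1.5,
                  merge_factor: float = 2.0) -> VascularGraph:
    """Step 5 — trace the skeleton into a vascular graph.

    Skeleton pixels with >= 3 neighbours are branch pixels; 8-connected
    branch clumps (merged within a 2-px radius) become junction vertices at
    their centroid, tip pixels become endpoint vertices, and each skeleton
    path between vertices becomes one edge.  Edge length is the chamfer
    step sum (1 per orthogonal, √2 per diagonal step); thickness is
    2 x mean distance-transform of the source mask along the edge minus the
    1-px pixel-boundary offset.  Isolated cycles become a single vertex
    carrying a self-loop.  Two skeletonization artefacts are repaired: tip
    branches shorter than ``spur_factor x thickness`` are pruned (boundary
    spurs), and junction-junction edges shorter than
    ``merge_factor x thickness`` are contracted (thinning splits one wide
    anatomical junction into a clump of nearby branch points).
    """
    skel = skeleton.pixels
    if skel.shape != source_mask.pixels.shape:
        raise ValueError("skeleton and source mask shapes differ")
    vg = VascularGraph(units="px", shape=skel.shape)
    if not skel.any():
        return vg

    edt = ndi.distance_transform_edt(source_mask.pixels)
    nbr_count = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                             mode="constant") - skel.astype(np.uint8)
    nbr_count[~skel] = 0

    branch = skel & (nbr_count >= 3)
    tip = skel & (nbr_count == 1)
    # drop isolated single pixels — they carry no edge
    skel = skel & ~(nbr_count == 0)

    # cluster branch pixels: label the 1-px-dilated branch mask so clumps
    # within a 2-px radius merge into one junction vertex
    dil = ndi.binary_dilation(branch, structure=np.ones((3, 3), bool))
    clump_labels, n_clumps = ndi.label(dil, structure=np.ones((3, 3), int))

    vertex_of: dict[tuple[int, int], int] = {}
    vid = 0
    clump_vid = {}
    for rc in map(tuple, np.argwhere(branch)):
        lab = clump_labels[rc]
        if lab not in clump_vid:
            clump_vid[lab] = vid
            vid += 1
        vertex_of[rc] = clump_vid[lab]
    n_junctions = vid
    # junction coordinates = centroid of the clump's branch pixels
    sums = np.zeros((n_junctions, 3))
    for rc, v in vertex_of.items():
        sums[v] += (rc[1], rc[0], 1.0)
    for rc in map(tuple, np.argwhere(tip)):
        if rc not in vertex_of:
            vertex_of[rc] = vid
            vid += 1

    for v in range(n_junctions):
        vg.add_vertex(v, sums[v, 0] / sums[v, 2], sums[v, 1] / sums[v, 2],
                      kind="junction")
    for rc, v in vertex_of.items():
        if v >= n_junctions:
            vg.add_vertex(v, rc[1], rc[0], kind="endpoint")

    skel_set = set(map(tuple, np.argwhere(skel)))

    def neighbours(rc):
        r, c = rc
        return [(r + dr, c + dc) for dr, dc in _NBRS if (r + dr, c + dc) in skel_set]

    visited: set[tuple[int, int]] = set()
    done_pairs: set[tuple] = set()

    def add_traced_edge(v1, v2, pix_path):
        length = _chamfer(pix_path)
        length += _euclid(vg.vertex_coords(v1), pix_path[0])
        length += _euclid(vg.vertex_coords(v2), pix_path[-1])
        if length <= 0:
            length = 0.5  # two vertices in adjacent clumps
        thickness = max(2.0 * float(np.mean([edt[p] for p in pix_path])) - 1.0, 0.5)
        path = [vg.vertex_coords(v1)] + [(c, r) for r, c in pix_path] \
            + [vg.vertex_coords(v2)]
        vg.add_edge(v1, v2, path=path, length=length, thickness=thickness)

    for start_rc in sorted(vertex_of):
        v1 = vertex_of[start_rc]
        for nb in neighbours(start_rc):
            if nb in vertex_of:
                v2 = vertex_of[nb]
                key = (min(start_rc, nb), max(start_rc, nb))
                if v2 == v1 or key in done_pairs:
                    continue
                done_pairs.add(key)
                add_traced_edge(v1, v2, [start_rc, nb])
                continue
            if nb in visited:
                continue
            # walk the chain
            pix_path = [start_rc, nb]
            visited.add(nb)
            prev, cur = start_rc, nb
            while True:
                nxts = [q for q in neighbours(cur) if q != prev]
                term = [q for q in nxts if q in vertex_of]
                # ignore stepping straight back into the starting clump
                term = [q for q in term
                        if not (len(pix_path) == 2 and vertex_of[q] == v1)]
                if term:
                    end = term[0]
                    add_traced_edge(v1, vertex_of[end], pix_path)
                    break
                frees = [q for q in nxts if q not in visited and q not in vertex_of]
                if not frees:
                    # dead end inside the chain (shouldn't happen on clean
                    # skeletons) — make it an endpoint
                    end_v = len(vg.g)
                    vg.add_vertex(end_v, cur[1], cur[0], kind="endpoint")
                    vertex_of[cur] = end_v
                    add_traced_edge(v1, end_v, pix_path[:-1] or [start_rc])
                    break
                nxt = min(frees)
                visited.add(nxt)
                pix_path.append(nxt)
                prev, cur = cur, nxt

    # isolated cycles: remaining unvisited chain pixels with no vertex
    remaining = sorted(skel_set - visited - set(vertex_of))
    seen = set()
    for rc in remaining:
        if rc in seen or rc in visited:
            continue
        loop = [rc]
        seen.add(rc)
        prev, cur = None, rc
        while True:
            nxts = [q for q in neighbours(cur) if q != prev and q not in seen]
            if not nxts:
                break
            nxt = min(nxts)
            seen.add(nxt)
            loop.append(nxt)
            prev, cur = cur, nxt
        if len(loop) < 3:
            continue
        anchor = len(vg.g)
        vg.add_vertex(anchor, rc[1], rc[0], kind="cycle")
        length = _chamfer(loop + [loop[0]])
        thickness = max(2.0 * float(np.mean([edt[p] for p in loop])) - 1.0, 0.5)
        path = [(c, r) for r, c in loop] + [(loop[0][1], loop[0][0])]
        vg.add_edge(anchor, anchor, path=path, length=length, thickness=thickness)
        visited.update(loop)

    _prune_spurs(vg, spur_factor)
    _contract_split_junctions(vg, merge_factor)
    _prune_spurs(vg, spur_factor)
    vg.splice_degree2()
    if merge_factor > 0:
        # self-loops no longer than a few tube widths are micro-holes at
        # junctions, not anatomical cycles; removing one can leave a
        # degree-2 vertex, so re-splice and re-prune until stable
        changed = True
        while changed:
            changed = False
            for u, v, k, d in list(vg.g.edges(keys=True, data=True)):
                thick = d["thickness"] if np.isfinite(d["thickness"]) else 1.0
                if u == v and d["length"] < 2 * merge_factor * max(thick, 1.0):
                    vg.g.remove_edge(u, v, k)
                    changed = True
            if changed:
                _prune_spurs(vg, spur_factor)
                vg.splice_degree2()
    vg.g.remove_nodes_from([v for v in list(vg.g) if vg.g.degree(v) == 0])
    vg.classify_vertices()

    if pixel_size is not None:
        vg = vg.apply_pixel_size(pixel_size)
    return vg


def _prune_spurs(vg: VascularGraph, spur_factor: float) -> None:
    """Iteratively drop junction→tip edges shorter than
    spur_factor x their own thickness (skeletonization boundary artefacts)."""
    if spur_factor <= 0:
        return
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(vg.g.edges(keys=True, data=True)):
            if u == v:
                continue
            deg_u, deg_v = vg.g.degree(u), vg.g.degree(v)
            # spur: exactly one side is a tip and the other a junction
            if (deg_u == 1) == (deg_v == 1):
                continue
            tip_end, other = (u, v) if deg_u == 1 else (v, u)
            if vg.g.degree(other) < 3:
                continue
            thick = d["thickness"] if np.isfinite(d["thickness"]) else 0.0
            # artefact scale never drops below the 8-connectivity clump
            # radius, even for the thinnest resolvable tubes
            limit = spur_factor * max(thick, 4.0)
            if d["length"] < limit:
                vg.g.remove_edge(u, v, k)
                vg.g.remove_node(tip_end)
                changed = True


def _contract_split_junctions(vg: VascularGraph, merge_factor: float) -> None:
    """Merge junction pairs joined by an edge much shorter than the local
    tube width — thinning splits a single wide junction into several
    nearby branch points and this undoes it."""
    if merge_factor <= 0:
        return
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(vg.g.edges(keys=True, data=True)):
            if u == v or u not in vg.g or v not in vg.g:
                continue
            if vg.g.degree(u) < 3 or vg.g.degree(v) < 3:
                continue
            thick = d["thickness"] if np.isfinite(d["thickness"]) else 0.0
            if d["length"] >= merge_factor * max(thick, 4.0):
                continue
            xu, yu = vg.vertex_coords(u)
            xv, yv = vg.vertex_coords(v)
            x, y = (xu + xv) / 2.0, (yu + yv) / 2.0
            # move v's other edges onto u, then drop v
            for a, b, kk, dd in list(vg.g.edges(v, keys=True, data=True)):
                other = b if a == v else a
                if other == u and kk == k:
                    continue
                if other == v:  # self-loop at v
                    vg.g.add_edge(u, u, **dd)
                else:
                    vg.g.add_edge(u, other, **dd)
            vg.g.remove_node(v)
            vg.g.nodes[u]["x"], vg.g.nodes[u]["y"] = x, y
            # drop artefactual short self-loops created by the contraction
            for a, b, kk, dd in list(vg.g.edges(u, keys=True, data=True)):
                if a == b and dd["length"] < merge_factor * max(thick, 1.0):
                    vg.g.remove_edge(a, b, kk)
            changed = True
            break


def _chamfer(pix_path) -> float:
    total = 0.0
    for (r0, c0), (r1, c1) in zip(pix_path[:-1], pix_path[1:]):
        total += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return total


def _euclid(xy, rc) -> float:
    return float(np.hypot(xy[0] - rc[1], xy[1] - rc[0]))


# ------------------------------------------------------------- composition

def process_frame(frame: ImageFrame, config: ExtractionConfig | None = None) -> VascularGraph:
    """Run the full pipeline (adjust → binarize/clean → skeletonize →
    extract) and record the parameters in the graph's provenance."""
    cfg = config or ExtractionConfig()
    adj = adjust_frame(frame, roi=cfg.roi, clip_percentiles=cfg.clip_percentiles)
    mask = binarize_and_clean(adj, method=cfg.threshold_method,
                              fixed_threshold=cfg.fixed_threshold,
                              max_hole_area=cfg.max_hole_area,
                              min_object_area=cfg.min_object_area)
    skel = skeletonize_mask(mask)
    vg = extract_graph(skel, mask, pixel_size=cfg.pixel_size_um,
                       spur_factor=cfg.spur_factor)
    vg.g.graph["frame_id"] = frame.frame_id or ""
    vg.g.graph["time_h"] = float(frame.time)
    vg.g.graph["threshold"] = mask.provenance.get("threshold", float("nan"))
    return vg
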