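# Methods

`vascnet` quantifies the development of vessel-like networks formed in
in-vitro tube-formation (Matrigel) assays — by endothelial cells
(angiogenesis) or by VM-competent cancer cells (vasculogenic mimicry) —
from time-lapse microscopy frames, and demonstrates the road-traffic
(Braess paradox) analogy for network remodeling. This note records the
models, the defaults, and the choices made where the design was open.

## Image-to-graph extraction

A frame is processed in five deterministic steps:

1. **Read.** TIFF/PNG; RGB is reduced by Rec. 709 luminance weights;
   integer intensities are rescaled to [0, 1].
2. **Adjust.** Contrast stretch between two intensity percentiles
   (default (0, 100), i.e. a pure affine rescale), optional region of
   interest outside which pixels are zeroed. Constant frames pass through
   unchanged rather than dividing by zero.
3. **Binarize and clean.** Otsu threshold by default (a fixed threshold
   in [0, 1] is available). Background components enclosed by foreground
   with area ≤ `max_hole_area` (default 64 px²) are filled — these are the
   bright-rimmed lumens and debris shadows inside tubes. Foreground
   components with area < `min_object_area` (default 64 px²) are deleted —
   isolated cells not connected to tubular structures.
4. **Skeletonize.** Topology-preserving thinning to a one-pixel-wide,
   8-connected medial skeleton (scikit-image).
5. **Trace.** Skeleton pixels with ≥ 3 neighbours are branch pixels;
   8-connected branch clumps become junction vertices at their centroid,
   tip pixels become endpoint vertices, and each skeleton path between
   vertices becomes one vessel edge. Degree-2 skeleton pixels are never
   vertices (chains are traced through). Isolated skeleton cycles are
   recorded as one vertex carrying a self-loop.

**Edge length** is the chamfer step sum along the skeleton path (1 per
orthogonal step, √2 per diagonal), plus the short closing segments to the
vertex centroids. The chamfer metric overestimates the Euclidean length
of oblique lines by up to ~8% (worst at 22.5°); this bias partially
cancels the tip retraction that thinning causes at endpoint edges, and
mean edge lengths recover synthetic ground truth within 10%.

**Edge thickness** is `2 × mean(EDT) − 1`, where EDT is the Euclidean
distance transform of the pre-skeleton mask sampled along the edge's
skeleton pixels. At the medial axis of a ribbon of width w the distance
to the nearest *background pixel centre* is (w + 1)/2, so the naive
2×EDT estimate carries a one-pixel positive bias (33% at w = 3); the −1
term removes the half-pixel boundary offset on each side. Thicknesses
recover rendered tube widths within 15% down to 3-px tubes.

**Artefact repair.** Thinning produces two well-known artefacts that are
repaired on the graph, both gated by a locally measured scale (the
artefact's own thickness, floored at 4 px — the clump radius of
8-connectivity thinning, below which the estimate is unreliable for the
thinnest resolvable tubes):

* *Spurs*: junction→tip edges shorter than `spur_factor × thickness`
  (default 1.5) are boundary-perturbation spurs, not vessels.
* *Split junctions*: one wide anatomical junction thins into a clump of
  nearby branch points joined by sub-resolution edges; junction–junction
  edges shorter than `merge_factor × thickness` (default 2.0) are
  contracted. Self-loops shorter than twice that limit are micro-holes at
  junctions, not anatomical cycles, and are dropped.

After repair, any vertex left with degree 2 is spliced through; splices
conserve length exactly and average thickness by length.

A pixel size in µm/px, if supplied, multiplies every length and thickness
and changes nothing else. The pipeline contains no randomness: identical
inputs give identical graphs.

## Network statistics

Topological statistics are computed on the simplified graph (self-loops
dropped, parallel edges collapsed; the vertex set unchanged):

* local clustering C_i = 2E_i / (k_i(k_i − 1)), with C_i = 0 when
  k_i < 2 (the formula is 0/0 there);
* mean clustering C = ⟨C_i⟩ over **all** vertices;
* characteristic path length L = mean shortest-path hop distance over
  unordered pairs. Distances are hops, not geometric lengths. Disconnected
  graphs have no finite all-pairs mean, so L is computed on the largest
  connected component and the component's vertex fraction is reported
  alongside;
* small-worldness σ = (C/C_r)/(L/L_r), with C_r and L_r ensemble means
  over `n_random` (default 20) uniform G(n, m) random graphs with the same
  vertex and edge counts, generated from per-replicate derived seeds, with
  the same largest-component convention for L_r. σ > 1 is read as
  small-world. Whenever C_r = 0 or L or L_r is undefined, σ is NaN; NaNs
  propagate through time series as missing values, never as exceptions.
  The "equivalent random network" is defined here as same-N-same-m; a
  degree-preserving null is a different (unimplemented) choice.

Morphometric statistics (mean edge length and thickness, edge counts,
edge-length histograms with half-open bins and an overflow bin) are taken
over the **full** edge table, self-loops and parallel edges included,
because every traced vessel contributes to morphometry even when it is
topologically redundant.

## Synthetic scenes and ground truth

No public time-lapse data accompany the assays this package targets, so
benchmarking uses synthetic scenes with known truth graphs.

* **Geometry.** Random seed points with a minimum pairwise separation
  (default 30 px; keep ≥ 2× the tube width so junctions stay resolvable),
  edges from the Delaunay triangulation with the longest 15% removed
  (shortest dropped edges restored to keep the graph connected), and a
  minimum incidence angle of 35° enforced at each vertex so rendered tubes
  neither fuse along their flanks nor enclose sub-resolution faces.
  Degree-2 vertices left by pruning are traced through, which yields the
  gently bent polyline edges seen in real assays; pure-cycle components
  are kept as polygons.
* **Rendering.** Truth polylines are rasterised and dilated to the tube
  width by distance threshold (odd widths render exactly; even widths are
  not symmetric on a pixel grid, so tests sweep widths 3, 5, 7, 9).
  Foreground/background intensities are 0.85/0.08. Degradations mirror
  what the cleaning step removes: punched holes strictly inside tubes
  (radius w/3, area ≈ 0.35 w² < w²), off-tube speckles (radius w/4, area
  ≈ 0.2 w² < (w/2)²), and additive Gaussian noise clipped to [0, 1]. The
  default noise σ = 0.05 gives a tube contrast-to-noise ratio ≈ 15;
  the noisy-recovery tests use σ = 0.07 (SNR ≈ 11).
* **Remodeling.** Network maturation is modelled as the minimal mechanism
  producing the observed trend — vessel segments are removed and the two
  segments meeting at each resulting degree-2 junction splice into one
  longer vessel. Each step removes a fraction of edges (default 5%/frame);
  a removal only commits if the graph stays connected and the mean edge
  length does not decrease, so the signatures (edge count non-increasing,
  mean edge length non-decreasing) hold by construction, and total length
  changes only by outright removals (splice additivity is exact). Frame
  times default to 0–48 h in 2 h steps, the usual duration and a
  conventional sampling interval for these assays. A schedule whose
  removal quota would consume every remaining edge is refused.

All generators are pure functions of their arguments including the seed.
What passing tests on these scenes shows is that the extractor inverts
the renderer under controlled degradations; they do not certify
performance on real micrographs, which add uneven illumination, optics
(PSF), cell texture inside tubes, and drift that the generator
deliberately omits.

## Time-course analysis

Replicate series must share a common time grid (the assays are imaged on
a fixed interval; no cross-replicate interpolation is attempted).
Aggregation is mean ± SEM (sd/√r) per time point over replicates with
defined values, excluded pairwise; r = 1 yields SEM 0 with a warning so
single-replicate runs stay usable. Metric trends are summarised by
y(t) = a·e^{bt}, fitted by unweighted nonlinear least squares initialised
from the log-linear regression (an additive-offset variant is out of
scope); constant series are flagged degenerate with b = 0 rather than
failing. On synthetic remodeling series the edge count fits with b < 0
and the mean edge length with b > 0, and C and L both admit decaying
fits — the remodeling signatures. Circular layouts place vertices
uniformly on the unit circle in vertex-id order, with edges emitted as
chords annotated by length for colour mapping.

## The traffic analogy

The Braess-paradox module is a demonstrative analogy, not a calibrated
haemodynamic model: no mapping from vascular graphs to latency functions
is claimed. The worked diamond network has two start→end routes, each one
constant 45-min road plus one congestible road with latency ρ/100 min
(ρ = vehicles on that individual link). At demand 4000 the user
equilibrium splits 2000/2000 and costs 45 + 20 = 65 min per driver. The
bypass between the interior nodes is modelled as exactly zero latency
("approximately zero" in the analogy; zero reproduces the printed numbers
exactly) and creates a third route using *both* congestible roads — the
only reading under which the first adopter pays 20 + 0 + 20 = 40 min at
the old split and the new all-on-bypass equilibrium pays 40 + 0 + 40 =
80 min. (Whether the adopter's own vehicle is counted in ρ changes 40 to
40.02; the package evaluates the route at the pre-adoption link flows.)

The solver enumerates route support sets; for affine non-negative
latencies each support's equal-time condition plus demand conservation is
a square linear system, so the equilibrium is exact, and the returned
solution is verified post hoc (used routes equal within tolerance, no
unused route faster). An integer-split enumeration minimising the
Beckmann potential serves as the independent test oracle; it is never the
production path.

## Problem sizes and numerical notes

Default test and demo scenes are 256×256 px with ~14 seed points and
25 frames — enough for every structural regime (junctions of degree 3–6,
endpoints, parallel arcs, cycles) while keeping a full pipeline run in
seconds. The σ ensembles use n_reps = 20; the self-consistency suites use
G(200, 600) and Watts–Strogatz (100, 4, p = 0.1), the regime where σ > 1.
All-pairs distances use scipy's sparse-graph BFS. Seeds fan out from one
top-level seed via `numpy.random.SeedSequence` so any stage can be rerun
in isolation reproducibly; derived seeds stay below 2³¹.

## Known limitations

* Junction positions are branch-clump centroids; they can shift ~1 px
  from the geometric crossing, and two true junctions closer than about
  one tube width are merged by design.
* The chamfer length bias (< 8%) is not corrected per edge orientation.
* Tubes thinner than 3 px are refused rather than estimated: below that,
  thinning is not guaranteed to preserve one-pixel topology.
* The G(n, m) null for σ can have disconnected reps at low density; L_r
  then averages largest-component values, which slightly lowers L_r.
* The traffic solver enumerates supports (2^routes); it targets small
  demonstration networks, not general traffic assignment.
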