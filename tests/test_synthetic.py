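import numpy as np
import pytest
from scipy import ndimage as ndi

import vascnet as vn
from vascnet.graph import VascularGraph

from _oracles import brute_mean_clustering, graph_to_adj


# ------------------------------------------------------------ tube networks

def test_minimal_network_three_points():
    vg = vn.generate_tube_network(3, 128, 128, seed=0)
    assert vg.n_vertices == 3
    assert 2 <= vg.n_edges <= 3
    h, w = vg.shape
    for _, d in vg.g.nodes(data=True):
        assert 0 <= d["x"] < w and 0 <= d["y"] < h


def test_network_generation_is_seed_deterministic():
    a = vn.generate_tube_network(40, 512, 512, seed=1, min_separation=20)
    b = vn.generate_tube_network(40, 512, 512, seed=1, min_separation=20)
    assert a.n_vertices == b.n_vertices and a.n_edges == b.n_edges
    assert np.allclose(sorted(a.edge_lengths()), sorted(b.edge_lengths()))


def test_network_respects_min_separation_and_validity():
    vg = vn.generate_tube_network(12, 256, 256, seed=5, min_separation=30)
    coords = np.array([[d["x"], d["y"]] for _, d in vg.g.nodes(data=True)])
    d2 = ((coords[:, None] - coords[None]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    assert np.sqrt(d2.min()) >= 30
    # no degree-2 vertices: chains are traced through
    assert all(vg.g.degree(v) != 2 for v in vg.g)


def test_overdense_request_refused():
    with pytest.raises(ValueError):
        vn.generate_tube_network(500, 128, 128, seed=0, min_separation=30)


# ----------------------------------------------------------------- renderer

def test_single_segment_renders_one_component_of_expected_area():
    vg = VascularGraph(shape=(64, 160))
    vg.add_vertex(0, 20, 32, "endpoint")
    vg.add_vertex(1, 120, 32, "endpoint")
    vg.add_edge(0, 1)
    scene = vn.render_scene(vg, tube_width=5.0)
    mask = scene.image.pixels > 0.5
    _, n = ndi.label(mask)
    assert n == 1
    assert mask.sum() == pytest.approx(5 * 100, rel=0.1)


def test_holes_create_enclosed_background():
    vg = vn.generate_tube_network(10, 256, 256, seed=2)
    scene = vn.render_scene(vg, tube_width=7.0, hole_rate=5.0, seed=3)
    mask = scene.image.pixels > 0.5
    bg_labels, n_bg = ndi.label(~mask)
    border = set(np.concatenate([bg_labels[0], bg_labels[-1],
                                 bg_labels[:, 0], bg_labels[:, -1]]))
    enclosed = set(range(1, n_bg + 1)) - border
    assert len(enclosed) >= 1


def test_render_is_bit_identical_given_seed(truth_graph):
    a = vn.render_scene(truth_graph, 5.0, noise_sd=0.05, hole_rate=2.0,
                        speckle_count=5, seed=9)
    b = vn.render_scene(truth_graph, 5.0, noise_sd=0.05, hole_rate=2.0,
                        speckle_count=5, seed=9)
    assert np.array_equal(a.image.pixels, b.image.pixels)


def test_render_refuses_thin_tubes(truth_graph):
    with pytest.raises(ValueError):
        vn.render_scene(truth_graph, tube_width=2.0)


# --------------------------------------------------------------- remodeling

def test_zero_merge_fraction_keeps_all_frames_identical(truth_graph):
    sch = vn.RemodelingSchedule(n_frames=3, frame_times=[0, 2, 4],
                                merge_fraction_per_frame=0.0, rng_seed=1)
    scenes = vn.generate_remodeling_series(truth_graph, sch)
    counts = {(s.truth_graph.n_vertices, s.truth_graph.n_edges) for s in scenes}
    assert len(counts) == 1


def test_remodeling_monotone_signature(truth_graph):
    sch = vn.RemodelingSchedule(n_frames=6, frame_times=[0, 2, 4, 6, 8, 10],
                                merge_fraction_per_frame=0.15, rng_seed=7)
    scenes = vn.generate_remodeling_series(truth_graph, sch)
    edges = [s.truth_graph.n_edges for s in scenes]
    mlen = [s.truth_graph.edge_lengths().mean() for s in scenes]
    assert all(b <= a for a, b in zip(edges, edges[1:]))
    assert all(b >= a - 1e-9 for a, b in zip(mlen, mlen[1:]))
    assert edges[-1] < edges[0]  # something actually remodeled


def test_remodeling_emptying_schedule_refused():
    tiny = vn.generate_tube_network(3, 128, 128, seed=4)
    sch = vn.RemodelingSchedule(n_frames=8, frame_times=list(range(8)),
                                merge_fraction_per_frame=0.9, rng_seed=0)
    with pytest.raises(ValueError):
        vn.generate_remodeling_series(tiny, sch)


def test_schedule_validation():
    with pytest.raises(ValueError):
        vn.RemodelingSchedule(n_frames=3, frame_times=[0, 2], rng_seed=0)
    with pytest.raises(ValueError):
        vn.RemodelingSchedule(n_frames=3, frame_times=[0, 4, 2], rng_seed=0)


def test_splice_conservation_under_remodeling(truth_graph):
    """Total truth length changes only by edges removed outright."""
    sch = vn.RemodelingSchedule(n_frames=2, frame_times=[0, 2],
                                merge_fraction_per_frame=0.2, rng_seed=3)
    scenes = vn.generate_remodeling_series(truth_graph, sch)
    t0, t1 = (s.truth_graph for s in scenes)
    # every surviving edge length is a sum of original edge lengths: the
    # multiset of t1 lengths must be reproducible from t0 lengths
    before = sorted(t0.edge_lengths())
    after = t1.edge_lengths()
    assert after.sum() <= t0.edge_lengths().sum() + 1e-6
    for l in after:
        # each length is an exact subset-sum of the originals (to fp tol)
        assert _is_subset_sum(before, l), l


def _is_subset_sum(values, target, tol=1e-6, depth=0):
    if target < tol:
        return abs(target) < tol
    if depth > 12:
        return False
    for i, v in enumerate(values):
        if v <= target + tol:
            if abs(v - target) < tol:
                return True
            if _is_subset_sum(values[:i] + values[i + 1:], target - v, tol,
                              depth + 1):
                return True
    return False


# -------------------------------------------------------- reference graphs

def test_watts_strogatz_p0_is_regular_lattice():
    g = vn.generate_watts_strogatz(100, 4, 0.0, seed=1)
    assert all(d == 4 for _, d in g.degree())
    assert g.number_of_edges() == 100 * 4 // 2


@pytest.mark.parametrize("p", [0.0, 0.1, 0.5, 1.0])
def test_watts_strogatz_conserves_edge_count(p):
    g = vn.generate_watts_strogatz(60, 6, p, seed=2)
    assert g.number_of_edges() == 60 * 6 // 2


def test_watts_strogatz_invalid_args():
    for n, k, p in [(10, 3, 0.1), (10, 10, 0.1), (10, 4, 1.5)]:
        with pytest.raises(ValueError):
            vn.generate_watts_strogatz(n, k, p, seed=0)


def test_ring_lattice_clustering_closed_form():
    for k in (4, 6, 8):
        g = vn.generate_watts_strogatz(200, k, 0.0, seed=0)
        expect = 3 * (k - 2) / (4 * (k - 2) + 4)
        assert vn.mean_clustering(g) == pytest.approx(expect)


def test_gnm_exact_counts_and_forced_complete():
    g = vn.generate_equivalent_random(5, 10, seed=3)
    assert g.number_of_nodes() == 5 and g.number_of_edges() == 10
    assert all(d == 4 for _, d in g.degree())  # K5
    a = vn.generate_equivalent_random(100, 200, seed=1)
    b = vn.generate_equivalent_random(100, 200, seed=2)
    assert a.number_of_edges() == b.number_of_edges() == 200
    assert set(a.edges()) != set(b.edges())
    with pytest.raises(ValueError):
        vn.generate_equivalent_random(5, 11, seed=0)


def test_gnm_ensemble_clustering_matches_er_expectation():
    """Mean clustering of G(n, m) ~ edge density 2m/(n(n-1))."""
    n, m, reps = 200, 400, 100
    expect = 2 * m / (n * (n - 1))
    vals = [brute_mean_clustering(graph_to_adj(
        vn.generate_equivalent_random(n, m, seed=s))) for s in range(reps)]
    mean = np.mean(vals)
    se = np.std(vals, ddof=1) / np.sqrt(reps)
    assert abs(mean - expect) < 3 * se + 1e-4
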