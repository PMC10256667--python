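import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from lipnet import (
    NetworkMetrics,
    SceneParams,
    binarize_network,
    build_skeleton_graph,
    classify_skeleton_pixels,
    generate_scene,
    network_metrics,
    normalize_per_cell,
    render_tagged_skeleton,
    segment_cells,
    simplify_graph,
    skeletonize_binary,
)
from lipnet.exceptions import (
    DegenerateInputError,
    NonThinSkeletonError,
    NormalizationError,
)
from lipnet.ibna import (
    BACKGROUND,
    CLASS_COLORS,
    ENDPOINT,
    JUNCTION,
    SLAB,
    SkeletonEdge,
    SkeletonGraph,
    SkeletonNode,
    analyze_network,
    prune_short_branches,
)

from conftest import random_blob, random_thin_skeleton

_S8 = np.ones((3, 3), int)


def brute_force_classes(sk):
    """Independent 3x3 neighbor enumeration (diagonals count)."""
    out = np.zeros(sk.shape, dtype=np.uint8)
    h, w = sk.shape
    for r in range(h):
        for c in range(w):
            if not sk[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
                        n += 1
            out[r, c] = ENDPOINT if n <= 1 else (SLAB if n == 2 else JUNCTION)
    return out


def assert_graph_partitions_skeleton(graph, sk):
    """Every skeleton pixel in exactly one node or exactly one edge path."""
    seen: dict = {}
    for node in graph.nodes:
        for p in node.pixels:
            assert p not in seen, f"pixel {p} assigned twice"
            seen[p] = ("node", node.id)
    for k, e in enumerate(graph.edges):
        for p in e.path:
            assert p not in seen, f"pixel {p} assigned twice"
            seen[p] = ("edge", k)
    expected = {tuple(map(int, p)) for p in np.argwhere(sk)}
    assert set(seen) == expected


# --- binarization -----------------------------------------------------------


def test_binarize_bimodal_and_manual():
    plane = np.zeros((4, 4), dtype=np.uint8)
    plane[:2] = 100
    out = binarize_network(plane, method="otsu")
    np.testing.assert_array_equal(out, plane == 100)

    plane = np.array([[40, 60], [60, 40]], dtype=np.uint8)
    out = binarize_network(plane, method="manual", manual_t=50)
    np.testing.assert_array_equal(out, plane == 60)


def test_binarize_foreground_monotone_in_threshold(rng):
    plane = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    counts = [
        binarize_network(plane, method="manual", manual_t=t).sum() for t in range(0, 256, 8)
    ]
    assert all(c0 >= c1 for c0, c1 in zip(counts, counts[1:]))


def test_binarize_degenerate_and_bad_args():
    with pytest.raises(DegenerateInputError):
        binarize_network(np.full((3, 3), 9, np.uint8), method="otsu")
    with pytest.raises(ValueError):
        binarize_network(np.zeros((3, 3), np.uint8), method="manual")
    with pytest.raises(ValueError):
        binarize_network(np.zeros((3, 3), np.uint8), mask=np.zeros((3, 3), bool))


# --- skeletonization --------------------------------------------------------


def test_skeletonize_minimal_inputs_unchanged():
    single = np.zeros((5, 5), bool)
    single[2, 2] = True
    np.testing.assert_array_equal(skeletonize_binary(single), single)

    line = np.zeros((3, 9), bool)
    line[1, 1:8] = True
    np.testing.assert_array_equal(skeletonize_binary(line), line)
    assert not skeletonize_binary(np.zeros((4, 4), bool)).any()


def test_skeletonize_filled_rectangle_properties():
    rect = np.zeros((7, 11), bool)
    rect[2:5, 2:9] = True  # 3x7 filled block
    sk = skeletonize_binary(rect)
    assert (sk & ~rect).sum() == 0  # skeleton inside input
    assert ndi.label(sk, _S8)[1] == 1
    blocks = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
    assert not blocks.any()
    classes = classify_skeleton_pixels(sk)
    assert classes.counts()["endpoint"] == 2


def test_skeletonize_preserves_topology_on_random_blobs():
    for seed in range(30):
        blob = random_blob(seed)
        sk = skeletonize_binary(blob)
        assert (sk & ~blob).sum() == 0
        assert ndi.label(sk, _S8)[1] == ndi.label(blob, _S8)[1]


# --- classification ---------------------------------------------------------


def test_classify_plus_shape(plus_shape):
    classes = classify_skeleton_pixels(plus_shape)
    assert classes.plane[3, 3] == JUNCTION
    # the four inner arm pixels are diagonally adjacent to each other, so
    # they carry >2 neighbors and join the junction component
    assert classes.counts() == {"endpoint": 4, "slab": 0, "junction": 5}


def test_classify_line_and_t_shape(five_px_line, t_shape):
    assert classify_skeleton_pixels(five_px_line).counts() == {
        "endpoint": 2,
        "slab": 3,
        "junction": 0,
    }
    classes = classify_skeleton_pixels(t_shape)
    assert classes.plane[0, 1] == JUNCTION and classes.plane[1, 1] == JUNCTION
    assert classes.plane[0, 0] == SLAB and classes.plane[0, 2] == SLAB
    assert classes.plane[2, 1] == ENDPOINT


def test_classify_isolated_pixel_is_endpoint():
    sk = np.zeros((3, 3), bool)
    sk[1, 1] = True
    assert classify_skeleton_pixels(sk).counts()["endpoint"] == 1


def test_classify_rejects_non_thin_input():
    sk = np.ones((2, 2), bool)
    with pytest.raises(NonThinSkeletonError, match=r"\(0, 0\)"):
        classify_skeleton_pixels(sk)


def test_classification_matches_brute_force_and_partitions():
    for seed in range(60):
        sk = random_thin_skeleton(seed)
        classes = classify_skeleton_pixels(sk)
        np.testing.assert_array_equal(classes.plane, brute_force_classes(sk))
        counts = classes.counts()
        assert sum(counts.values()) == int(sk.sum())


# --- graph ------------------------------------------------------------------


def test_graph_five_px_line(five_px_line):
    classes = classify_skeleton_pixels(five_px_line)
    g = build_skeleton_graph(five_px_line, classes)
    assert len(g.nodes) == 2 and len(g.edges) == 1
    assert g.edges[0].length == pytest.approx(4.0)
    assert_graph_partitions_skeleton(g, five_px_line)
    m = network_metrics(g, classes)
    assert m.n_branches == 1 and m.n_actual_junctions == 0
    assert m.avg_branch_length == pytest.approx(4.0)


def test_graph_plus_shape(plus_shape):
    classes = classify_skeleton_pixels(plus_shape)
    g = build_skeleton_graph(plus_shape, classes)
    kinds = sorted(n.kind for n in g.nodes)
    assert kinds == ["endpoint"] * 4 + ["junction"]
    assert len(g.edges) == 4
    assert all(e.length == pytest.approx(1.0) for e in g.edges)
    assert_graph_partitions_skeleton(g, plus_shape)
    m = network_metrics(g, classes)
    assert (m.n_branches, m.n_actual_junctions) == (4, 1)
    assert m.avg_branch_length == pytest.approx(1.0)
    assert (m.n_endpoint_px, m.n_slab_px, m.n_junction_px) == (4, 0, 5)


def test_graph_diamond_cycle_phantom_node(diamond_cycle):
    classes = classify_skeleton_pixels(diamond_cycle)
    g = build_skeleton_graph(diamond_cycle, classes)
    assert len(g.nodes) == 1 and g.nodes[0].kind == "phantom-loop"
    assert g.nodes[0].pixels == ((0, 1),)  # smallest (row, col) of the cycle
    assert len(g.edges) == 1 and g.edges[0].u == g.edges[0].v
    assert g.edges[0].length == pytest.approx(4 * math.sqrt(2))
    assert_graph_partitions_skeleton(g, diamond_cycle)


def test_graph_partitions_random_skeletons():
    for seed in range(40):
        sk = random_thin_skeleton(seed + 500)
        classes = classify_skeleton_pixels(sk)
        g = build_skeleton_graph(sk, classes)
        assert_graph_partitions_skeleton(g, sk)
        m = network_metrics(g, classes)
        assert m.total_skeleton_px == int(sk.sum())


def test_simplify_graph_splices_degree2_junction_and_short_loops():
    # two long edges through a degree-2 "junction" cluster plus a micro-loop
    nodes = [
        SkeletonNode(0, "endpoint", ((0, 0),), (0.0, 0.0)),
        SkeletonNode(1, "junction", ((5, 5), (5, 6)), (5.0, 5.5)),
        SkeletonNode(2, "endpoint", ((9, 9),), (9.0, 9.0)),
    ]
    edges = [
        SkeletonEdge(0, 1, ((1, 1),), 6.0),
        SkeletonEdge(1, 2, ((7, 7),), 5.0),
        SkeletonEdge(1, 1, (), 2.8),  # artifact self-loop
    ]
    g = SkeletonGraph(nodes=nodes, edges=edges)
    out = simplify_graph(g, merge_len=4.0)
    assert out.n_actual_junctions == 0
    assert len(out.edges) == 1
    assert out.edges[0].length == pytest.approx(6.0 + 5.0 + 1.0)


def test_simplify_graph_contracts_short_junction_junction_edge():
    nodes = [
        SkeletonNode(0, "junction", ((2, 2),), (2.0, 2.0)),
        SkeletonNode(1, "junction", ((2, 5),), (2.0, 5.0)),
        SkeletonNode(2, "endpoint", ((0, 0),), (0.0, 0.0)),
        SkeletonNode(3, "endpoint", ((4, 0),), (4.0, 0.0)),
        SkeletonNode(4, "endpoint", ((0, 7),), (0.0, 7.0)),
        SkeletonNode(5, "endpoint", ((4, 7),), (4.0, 7.0)),
    ]
    edges = [
        SkeletonEdge(0, 1, ((2, 3), (2, 4)), 3.0),  # short bridge between junctions
        SkeletonEdge(0, 2, (), 6.0),
        SkeletonEdge(0, 3, (), 6.0),
        SkeletonEdge(1, 4, (), 6.0),
        SkeletonEdge(1, 5, (), 6.0),
    ]
    out = simplify_graph(SkeletonGraph(nodes=nodes, edges=edges), merge_len=4.0)
    assert out.n_actual_junctions == 1
    assert len(out.edges) == 4


def test_prune_short_branches_removes_terminal_spur():
    sk = np.zeros((9, 13), bool)
    sk[6, 1:12] = True  # long horizontal branch
    sk[3:6, 6] = True  # 3-px spur off the middle
    pruned = prune_short_branches(sk, min_length=3.0)
    assert not pruned[3, 6] and not pruned[4, 6]
    assert pruned[6, 1:12].all()


# --- metrics and normalization ---------------------------------------------


def test_network_metrics_empty_graph_flags_avg_length():
    sk = np.zeros((3, 3), bool)
    sk[1, 1] = True
    classes = classify_skeleton_pixels(sk)
    m = network_metrics(build_skeleton_graph(sk, classes), classes)
    assert m.n_branches == 0
    assert m.avg_branch_length is None


def test_normalize_per_cell():
    m = NetworkMetrics(
        n_branches=12,
        n_actual_junctions=6,
        n_endpoint_px=9,
        n_slab_px=90,
        n_junction_px=30,
        avg_branch_length=7.5,
        total_skeleton_px=129,
    )
    n = normalize_per_cell(m, 3)
    assert n.n_junction_px == pytest.approx(10.0)
    assert n.n_branches == pytest.approx(4.0)
    assert n.avg_branch_length == pytest.approx(7.5)  # already per-branch
    assert n.per_cell_normalized and n.n_cells_basis == 3

    ident = normalize_per_cell(m, 1)
    assert ident.n_branches == m.n_branches and ident.per_cell_normalized

    with pytest.raises(NormalizationError):
        normalize_per_cell(n, 2)  # double normalization
    with pytest.raises(NormalizationError):
        normalize_per_cell(m, 0)


# --- rendering --------------------------------------------------------------


def test_render_exact_palette(plus_shape):
    classes = classify_skeleton_pixels(plus_shape)
    rgb = render_tagged_skeleton(classes)
    assert rgb.shape == plus_shape.shape + (3,)
    assert (np.all(rgb == CLASS_COLORS[JUNCTION], axis=-1)).sum() == 5
    assert (np.all(rgb == CLASS_COLORS[ENDPOINT], axis=-1)).sum() == 4
    assert (np.all(rgb == CLASS_COLORS[BACKGROUND], axis=-1)).sum() == plus_shape.size - 9


def test_render_empty_is_black_and_histogram_matches():
    empty = classify_skeleton_pixels(np.zeros((4, 4), bool))
    assert not render_tagged_skeleton(empty).any()
    for seed in range(5):
        sk = random_thin_skeleton(seed + 900)
        classes = classify_skeleton_pixels(sk)
        rgb = render_tagged_skeleton(classes)
        counts = classes.counts()
        for cls, key in ((ENDPOINT, "endpoint"), (SLAB, "slab"), (JUNCTION, "junction")):
            assert (np.all(rgb == CLASS_COLORS[cls], axis=-1)).sum() == counts[key]


# --- segmentation -----------------------------------------------------------


def test_segmentation_recovers_truth_masks_noise_free():
    params = SceneParams(
        image_size=256, n_cells=3, snr=float("inf"), psf_sigma_px=0.0, seed=5
    )
    img, truth = generate_scene(params)
    seg = segment_cells(img, "nucleus", "clld", smooth_sigma=0.0)
    assert seg.n_cells == truth.n_cells == 3
    for i in range(seg.n_cells):
        overlap = truth.cell_labels[seg.cell_mask(i)]
        label = np.bincount(overlap[overlap > 0]).argmax()
        np.testing.assert_array_equal(seg.cell_mask(i), truth.cell_labels == label)
        np.testing.assert_array_equal(seg.nucleus_mask(i), truth.nucleus_labels == label)
        np.testing.assert_array_equal(
            seg.cytoplasm_mask(i), seg.cell_mask(i) & ~seg.nucleus_mask(i)
        )


def test_segmentation_blank_image_yields_zero_cells():
    from lipnet import MultiChannelImage

    img = MultiChannelImage(
        channels={
            "nucleus": np.zeros((32, 32), np.uint8),
            "clld": np.zeros((32, 32), np.uint8),
        }
    )
    seg = segment_cells(img, "nucleus", "clld")
    assert seg.n_cells == 0
    with pytest.raises(KeyError):
        segment_cells(img, "missing", "clld")


# --- driver robustness at realistic noise -----------------------------------


def test_count_fields_stable_across_replicates_at_moderate_noise():
    """Branch/junction/endpoint counts of replicated cells agree within 5%
    at snr 20 (pixel-class counts are noisier; see the methods note)."""
    from lipnet import generate_replicated_scene

    params = SceneParams(
        image_size=224,
        n_cells=1,
        network_branch_target=24,
        tubule_width_px=3,
        puncta_count=0,
        coloc_fraction=0.0,
        snr=20.0,
        psf_sigma_px=0.8,
        cell_radius_px=85.0,
        aunc_dot_count=0,
        branch_len_min=20,
        branch_len_max=36,
        seed=1,
    )
    img1, t1 = generate_replicated_scene(params, 1)
    img3, t3 = generate_replicated_scene(params, 3)

    def counts(img, truth):
        out = np.zeros(3)
        for i in range(truth.n_cells):
            m, *_ = analyze_network(
                img.channels["clld"],
                mask=truth.cytoplasm_masks[i],
                smooth_sigma=1.2,
                min_object_px=9,
                fill_holes_px=12,
                prune_px=4,
                junction_merge_px=4,
            )
            out += (m.n_branches, m.n_actual_junctions, m.n_endpoint_px)
        return out / truth.n_cells

    single = counts(img1, t1)
    multi = counts(img3, t3)
    np.testing.assert_allclose(multi, single, rtol=0.05)
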