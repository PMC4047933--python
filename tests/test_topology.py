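import itertools

import numpy as np
import pytest

from filagraph import (
    FilamentPath,
    SyntheticNetworkSpec,
    build_graph,
    compare_groups,
    disambiguate,
    length_distribution,
    path_length,
    render_network,
    smoothed_length,
    thin,
)
from filagraph.segment import estimate_foreground
from filagraph.skeleton import prune_spurs
from filagraph.topology import merge_collinear_fragments


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def test_straight_line_graph():
    skel = np.zeros((5, 14), dtype=bool)
    skel[2, 2:12] = True  # 10-px line
    graph = build_graph(thin(skel))
    kinds = [n.kind for n in graph.nodes]
    assert kinds.count("endpoint") == 2 and "junction" not in kinds
    assert len(graph.edges) == 1
    assert len(graph.edges[0].chain) == 10


def test_plus_sign_graph():
    skel = np.zeros((15, 15), dtype=bool)
    skel[7, 2:13] = True
    skel[2:13, 7] = True
    graph = build_graph(skel)
    junctions = [n for n in graph.nodes if n.kind == "junction"]
    # under 8-connectivity the four pixels around the centre have degree 4
    # too, so the crossing is one junction cluster containing the centre
    assert len(junctions) == 1 and (7, 7) in junctions[0].pixels
    assert len([n for n in graph.nodes if n.kind == "endpoint"]) == 4
    assert len(graph.edges) == 4


def test_ring_graph_is_single_cycle():
    from skimage.draw import circle_perimeter

    skel = np.zeros((20, 20), dtype=bool)
    rr, cc = circle_perimeter(9, 9, 6)
    skel[rr, cc] = True
    graph = build_graph(thin(skel))
    assert all(n.kind != "endpoint" for n in graph.nodes)
    cycles = [e for e in graph.edges if e.is_cycle]
    assert len(cycles) == 1
    assert len(cycles[0].chain) == int(thin(skel).values.sum())


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pixels,expected",
    [
        ([(0, c) for c in range(10)], 9.0),                       # axial
        ([(i, i) for i in range(10)], 9 * np.sqrt(2)),            # diagonal
        ([(0, c) for c in range(6)] + [(i, 5 + i) for i in range(1, 5)],
         5 + 4 * np.sqrt(2)),                                     # mixed
    ],
)
def test_path_length_chain_metric(pixels, expected):
    assert path_length(np.array(pixels)) == pytest.approx(expected)


def test_path_length_scaled_by_pixel_size():
    pixels = np.array([(0, c) for c in range(11)])
    assert path_length(pixels, pixel_size_um=0.2) == pytest.approx(2.0)


def test_smoothed_length_removes_staircase_bias():
    # digitised straight line at 22.5 degrees: the chain metric overshoots
    # by up to 8%, the smoothed polyline stays within ~1.5%
    theta = np.radians(22.5)
    n = 60
    pts = np.array(
        [(round(i * np.sin(theta)), round(i * np.cos(theta))) for i in range(n)]
    )
    pts = pts[np.concatenate([[True], (np.diff(pts, axis=0) != 0).any(axis=1)])]
    true_len = float(np.linalg.norm(pts[-1] - pts[0]))
    chain = path_length(pts)
    smooth = smoothed_length(pts)
    assert chain > true_len * 1.04
    assert smooth == pytest.approx(true_len, rel=0.015)


# ---------------------------------------------------------------------------
# disambiguation
# ---------------------------------------------------------------------------

def _turns_for_pairing(directions, pairing):
    """Total turn of a pairing; directions point away from the junction."""
    total = 0.0
    for i, j in pairing:
        cos = np.clip(-np.dot(directions[i], directions[j]), -1, 1)
        total += np.degrees(np.arccos(cos))
    return total


def test_x_crossing_resolves_to_two_straight_filaments():
    skel = np.zeros((25, 25), dtype=bool)
    skel[12, 2:23] = True
    skel[2:23, 12] = True
    graph = build_graph(skel)
    result = disambiguate(graph)
    fil = [p for p in result.filaments if len(p.pixels) > 2]
    assert len(fil) == 2
    ends = sorted(tuple(sorted((tuple(p.pixels[0]), tuple(p.pixels[-1])))) for p in fil)
    assert ends == [((2, 12), (22, 12)), ((12, 2), (12, 22))]

    # enumeration oracle: over the three pairings of the four branch
    # directions, the minimum-total-turn pairing joins opposite branches
    dirs = [np.array(d, float) for d in [(0, -1), (0, 1), (-1, 0), (1, 0)]]
    pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    totals = [_turns_for_pairing(dirs, p) for p in pairings]
    assert int(np.argmin(totals)) == 0


def test_y_junction_keeps_sharp_branch_separate():
    # two nearly collinear branches (turn ~10 deg) plus one at ~80 deg
    from filagraph.geometry import arc_points

    skel = np.zeros((41, 41), dtype=bool)
    centre = np.array([20.0, 20.0])
    for angle_deg, length in [(0.0, 16.0), (170.0, 16.0), (80.0, 14.0)]:
        theta = np.radians(angle_deg)
        for s in np.arange(0, length, 0.35):
            r = int(round(centre[0] + s * np.sin(theta)))
            c = int(round(centre[1] + s * np.cos(theta)))
            skel[r, c] = True
    graph = build_graph(thin(skel))
    result = disambiguate(graph)
    fil = sorted(
        (p for p in result.filaments if len(p.pixels) > 3),
        key=lambda p: -len(p.pixels),
    )
    assert len(fil) == 2
    assert len(fil[0].pixels) > 1.5 * len(fil[1].pixels)

    dirs = [
        np.array([np.sin(np.radians(a)), np.cos(np.radians(a))]) for a in (0, 170, 80)
    ]
    best = min(
        itertools.combinations(range(3), 2),
        key=lambda ij: _turns_for_pairing(dirs, [ij]),
    )
    assert best == (0, 1)  # the nearly collinear pair


def test_isolated_edge_passes_through():
    skel = np.zeros((8, 20), dtype=bool)
    skel[4, 3:17] = True
    result = disambiguate(build_graph(skel))
    assert len(result.filaments) == 1
    assert len(result.filaments[0].pixels) == 14


def test_conservation_invariants_on_random_skeletons():
    checked = 0
    for seed in range(25):
        spec = SyntheticNetworkSpec(
            image_height_px=64,
            image_width_px=64,
            n_filaments=5,
            length_mean_px=28.0,
            length_sd_px=10.0,
            seed=seed,
        )
        image, _ = render_network(spec)
        mask = estimate_foreground(image.pixels, min_object_px=10)
        skel = prune_spurs(thin(mask), 4.0)
        graph = build_graph(skel)
        result = disambiguate(graph)
        # pixel conservation: union of path pixels == skeleton pixels
        union = set()
        for p in result.paths:
            union.update(map(tuple, p.pixels))
        skel_set = set(zip(*np.nonzero(skel.values)))
        assert union == skel_set
        # length conservation: filament chain length equals outer edge length
        # plus the explicitly accounted junction handovers and bridges
        assert result.total_path_length_px == pytest.approx(
            result.total_outer_edge_length_px
            + result.junction_connect_length_px
            + result.bridge_length_px,
            abs=1e-6,
        )
        checked += 1
    assert checked == 25


def test_disambiguate_validates_turn_range():
    skel = np.zeros((5, 5), dtype=bool)
    skel[2, 1:4] = True
    graph = build_graph(skel)
    with pytest.raises(ValueError):
        disambiguate(graph, max_turn_deg=120.0)


def test_fragment_merge_rejoins_split_line():
    a = FilamentPath(pixels=np.array([(10, c) for c in range(2, 20)]))
    b = FilamentPath(pixels=np.array([(10, c) for c in range(26, 44)]))
    lik = np.full((20, 50), 1.0)
    merged = merge_collinear_fragments([a, b], lik, support_threshold=0.5)
    assert len(merged) == 1
    assert smoothed_length(merged[0]) == pytest.approx(41.0, abs=1.0)


def test_fragment_merge_respects_support():
    a = FilamentPath(pixels=np.array([(10, c) for c in range(2, 20)]))
    b = FilamentPath(pixels=np.array([(10, c) for c in range(26, 44)]))
    lik = np.full((20, 50), 1.0)
    lik[:, 20:26] = 0.0  # dark gap: not one filament
    merged = merge_collinear_fragments([a, b], lik, support_threshold=0.5)
    assert len(merged) == 2


# ---------------------------------------------------------------------------
# length statistics
# ---------------------------------------------------------------------------

def test_single_filament_distribution():
    dist = length_distribution([12.5], bin_width=5.0)
    assert dist.weighted_mean == pytest.approx(12.5)
    assert dist.weighted_mean_se == 0.0
    assert dist.counts.sum() == 1


def test_weighted_mean_single_image():
    dist = length_distribution([2.0, 4.0], bin_width=1.0)
    assert dist.weighted_mean == pytest.approx(3.0)


def test_weighted_mean_across_images():
    dist = length_distribution(
        [2.0, 2.0, 2.0, 5.0], bin_width=1.0, per_image_ids=[0, 0, 0, 1]
    )
    assert dist.weighted_mean == pytest.approx((3 * 2 + 1 * 5) / 4)
    assert dist.per_image_counts == [3, 1]


def test_min_length_filter_and_counts():
    dist = length_distribution([1.0, 2.0, 10.0, 20.0], bin_width=5.0, min_length=3.0)
    assert len(dist.lengths) == 2
    assert dist.counts.sum() == 2


def test_empty_distribution_flagged():
    dist = length_distribution([], bin_width=1.0)
    assert np.isnan(dist.weighted_mean)
    assert dist.per_image_counts == []


def test_compare_groups_identical_gives_p_one():
    a = length_distribution(
        [10.0, 11.0, 12.0], bin_width=1.0, per_image_ids=[0, 1, 2]
    )
    assert compare_groups(a, a) == pytest.approx(1.0)


def test_compare_groups_separated_significant_and_symmetric():
    a = length_distribution(
        [10.0, 10.1, 9.9], bin_width=1.0, per_image_ids=[0, 1, 2]
    )
    b = length_distribution(
        [1.0, 1.1, 0.9], bin_width=1.0, per_image_ids=[0, 1, 2]
    )
    p = compare_groups(a, b)
    assert p < 0.01
    assert compare_groups(b, a) == pytest.approx(p)


def test_compare_groups_needs_two_images():
    a = length_distribution([10.0], bin_width=1.0)
    with pytest.raises(ValueError):
        compare_groups(a, a)
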