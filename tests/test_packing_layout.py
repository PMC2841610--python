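import itertools
import math

import numpy as np
import pytest
from shapely.geometry import LineString

from helixpack.contact_labelling import InteractionGraph
from helixpack.io_formats import HelixSpan, Topology, ValidationError
from helixpack.packing_layout import (
    Arrangement,
    DisconnectedGraphError,
    Layout2D,
    LayoutParams,
    circular_init,
    count_same_side_crossovers,
    equivalent_arrangements,
    kamada_kawai,
    rescale_layout,
    select_arrangement,
)
from helixpack.rotation_optimizer import GAConfig


def _graph(n, *edges):
    return InteractionGraph(n=n, edges=frozenset(tuple(sorted(e)) for e in edges))


def _energy_of(layout, graph, params=LayoutParams()):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(1, graph.n + 1))
    g.add_edges_from(graph.edges)
    spl = dict(nx.all_pairs_shortest_path_length(g))
    e = 0.0
    for i in range(1, graph.n + 1):
        for j in range(i + 1, graph.n + 1):
            d = spl[i][j]
            dist = math.dist(layout.positions[i], layout.positions[j])
            e += params.K / d**2 * (dist - params.L0 * d) ** 2
    return e


class TestCircularInit:
    def test_square(self):
        lay = circular_init(4, 1.0)
        expect = {1: (1, 0), 2: (0, 1), 3: (-1, 0), 4: (0, -1)}
        for k, (x, y) in expect.items():
            assert lay.positions[k] == pytest.approx((x, y), abs=1e-12)

    def test_single_vertex(self):
        lay = circular_init(1, 2.5)
        assert lay.positions[1] == pytest.approx((2.5, 0.0))

    def test_adjacent_distances_equal(self):
        lay = circular_init(9, 3.0)
        dists = [
            math.dist(lay.positions[k], lay.positions[k % 9 + 1])
            for k in range(1, 10)
        ]
        assert max(dists) - min(dists) < 1e-9

    def test_invalid_n(self):
        with pytest.raises(ValidationError):
            circular_init(0)


class TestKamadaKawai:
    def test_two_vertices_relax_to_rest_length(self):
        lay, energy = kamada_kawai(_graph(2, (1, 2)))
        d = math.dist(lay.positions[1], lay.positions[2])
        assert abs(d - 1.0) < 1e-6
        assert energy < 1e-10

    def test_triangle_equilateral(self):
        lay, _ = kamada_kawai(_graph(3, (1, 2), (1, 3), (2, 3)))
        sides = [
            math.dist(lay.positions[a], lay.positions[b])
            for a, b in [(1, 2), (1, 3), (2, 3)]
        ]
        for s in sides:
            assert abs(s - 1.0) < 0.01

    def test_seven_helix_ring_energy_descends(self):
        g = _graph(7, *[(k, k % 7 + 1) for k in range(1, 8)])
        init = circular_init(7, 1.0)
        lay, final = kamada_kawai(g, init)
        assert final <= _energy_of(init, g) + 1e-12
        assert final == pytest.approx(_energy_of(lay, g), abs=1e-9)

    def test_disconnected_graph_rejected(self):
        with pytest.raises(DisconnectedGraphError):
            kamada_kawai(_graph(4, (1, 2), (3, 4)))

    def test_rescale_sets_min_distance(self):
        lay, _ = kamada_kawai(_graph(3, (1, 2), (2, 3)))
        scaled = rescale_layout(lay, 10.0)
        pts = scaled.positions_angstrom()
        dmin = min(
            math.dist(pts[a], pts[b])
            for a, b in itertools.combinations(pts, 2)
        )
        assert dmin == pytest.approx(10.0)


class TestEquivalentArrangements:
    def test_asymmetric_path_has_only_identity(self):
        # on the 4-path no two helices share a neighbour set, so only
        # the identity assignment exists
        perms = equivalent_arrangements(_graph(4, (1, 2), (2, 3), (3, 4)))
        assert perms == [{1: 1, 2: 2, 3: 3, 4: 4}]

    def test_three_path_end_helices_interchangeable(self):
        # both ends of the 3-path interact with helix 2 only, so the
        # end swap is the one alternative assignment
        perms = equivalent_arrangements(_graph(3, (1, 2), (2, 3)))
        assert len(perms) == 2
        assert perms[1] == {1: 3, 2: 2, 3: 1}

    def test_star_leaves_fully_interchangeable(self):
        g = _graph(4, (1, 2), (1, 3), (1, 4))
        perms = equivalent_arrangements(g)
        assert len(perms) == 6
        brute = [
            dict(zip(range(1, 5), p))
            for p in itertools.permutations(range(1, 5))
            if {tuple(sorted((dict(zip(range(1, 5), p))[a],
                              dict(zip(range(1, 5), p))[b])))
                for a, b in g.edges} == set(g.edges)
        ]
        assert sorted(perms, key=lambda d: tuple(d.values())) == sorted(
            brute, key=lambda d: tuple(d.values())
        )

    def test_two_helices_sharing_interactions_give_two_arrangements(self):
        # helices 1 and 2 are mutually adjacent and share neighbour 3:
        # exactly two assignments exist (identity and the 1<->2 swap)
        g = _graph(5, (1, 2), (1, 3), (2, 3), (3, 4), (4, 5))
        perms = equivalent_arrangements(g)
        assert len(perms) == 2
        assert {1: 2, 2: 1}.items() <= perms[1].items()

    def test_all_outputs_are_automorphisms(self):
        g = _graph(6, (1, 2), (1, 3), (1, 4), (4, 5), (4, 6))
        for perm in equivalent_arrangements(g):
            mapped = {
                tuple(sorted((perm[a], perm[b]))) for a, b in g.edges
            }
            assert mapped == set(g.edges)


def _shapely_crossovers(layout: Layout2D, n: int):
    """Independent oracle: same-side pairwise proper-crossing counts
    via the GEOS robust predicates."""
    loops = {
        i: LineString([layout.positions[i], layout.positions[i + 1]])
        for i in range(1, n)
    }
    counts = [0, 0]
    for side in (0, 1):
        ids = [i for i in loops if i % 2 == side]
        for a, b in itertools.combinations(ids, 2):
            if loops[a].crosses(loops[b]):
                counts[side] += 1
    return counts[0], counts[1], counts[0] + counts[1]


class TestCrossovers:
    def test_convex_ring_order_has_none(self):
        lay = circular_init(6, 1.0)
        assert count_same_side_crossovers(lay, 6) == (0, 0, 0)

    def test_constructed_same_side_crossing(self):
        # loops 1 (1->2) and 3 (3->4) are both on side 1 and cross
        lay = Layout2D(
            positions={1: (0.0, 0.0), 2: (2.0, 2.0), 3: (0.0, 2.0), 4: (2.0, 0.0)}
        )
        assert count_same_side_crossovers(lay, 4) == (0, 1, 1)

    def test_zero_length_loop_rejected(self):
        lay = Layout2D(positions={1: (0.0, 0.0), 2: (0.0, 0.0), 3: (1.0, 1.0)})
        with pytest.raises(ValidationError):
            count_same_side_crossovers(lay, 3)

    def test_matches_shapely_oracle_on_random_layouts(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(3, 11))
            lay = Layout2D(
                positions={
                    k: tuple(rng.uniform(-5, 5, size=2)) for k in range(1, n + 1)
                }
            )
            assert count_same_side_crossovers(lay, n) == _shapely_crossovers(lay, n)

    def test_invariant_under_similarity_transforms(self):
        rng = np.random.default_rng(5)
        lay = Layout2D(
            positions={k: tuple(rng.uniform(-3, 3, size=2)) for k in range(1, 8)}
        )
        base = count_same_side_crossovers(lay, 7)
        theta, scale, shift = 1.1, 3.7, np.array([11.0, -2.0])
        R = scale * np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = Layout2D(
            positions={
                k: tuple(R @ np.array(p) + shift) for k, p in lay.positions.items()
            }
        )
        assert count_same_side_crossovers(moved, 7) == base


class TestSelectArrangement:
    def test_single_arrangement_graph(self):
        g = _graph(4, (1, 2), (2, 3), (3, 4))
        arrs = select_arrangement(g)
        assert len(arrs) == 1
        assert arrs[0].permutation == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_fewest_crossovers_ranked_first(self):
        # two interchangeable helices: candidates are ranked by
        # ascending same-side crossover count
        g = _graph(5, (1, 2), (1, 3), (2, 3), (3, 4), (4, 5))
        arrs = select_arrangement(g)
        assert len(arrs) == 2
        assert arrs[0].crossovers_total <= arrs[1].crossovers_total

    def test_contact_distance_breaks_crossover_ties(self):
        # 5-helix star: the 24 leaf assignments are crossover-tied in
        # groups; contacts between helices 2 and 3 must pull them to
        # adjacent slots in the winning arrangement
        g = _graph(5, (1, 2), (1, 3), (1, 4), (1, 5))
        topo = Topology(
            helices=tuple(HelixSpan(1 + 20 * k, 12 + 20 * k, k + 1) for k in range(5))
        )
        contacts = [(26, 46), (27, 47)]
        arrs = select_arrangement(
            g,
            topology=topo,
            contacts=contacts,
            ga_config=GAConfig(population=40, generations=60, seed=0),
            seed=0,
        )
        top = arrs[0]
        min_cross = min(a.crossovers_total for a in arrs)
        tied = [a for a in arrs if a.crossovers_total == min_cross]
        assert top.crossovers_total == min_cross
        assert top.total_contact_distance == min(
            a.total_contact_distance for a in tied
        )
        d23 = math.dist(top.layout.angstrom(2), top.layout.angstrom(3))
        assert d23 < 16.0  # adjacent slots (14.1 A), not across (20 A)
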