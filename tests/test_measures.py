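"""The 12 network measures: hand-derived cases, oracle equivalence, invariances."""

import numpy as np
import pytest

from connharm import measures as ms
from connharm.measures import (
    MEASURE_NAMES,
    Partition,
    all_measures,
    assortativity,
    avg_betweenness,
    avg_clustering,
    avg_local_efficiency,
    avg_participation,
    avg_strength,
    char_path_and_edge_count,
    density,
    global_efficiency,
    measures_table,
    modularity_louvain,
    modularity_value,
    rich_club,
    rich_club_curve,
)
from connharm.simulate import GeneratorConfig, generate_cohort

from . import oracles
from .conftest import make_connectome


def _random_graphs(n_graphs=24, n_range=(2, 8), seed=11):
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(*n_range, endpoint=True))
        graphs.append(oracles.random_weighted_graph(rng, n, p_edge=float(rng.uniform(0.2, 0.9))))
    return graphs


# ---------------------------------------------------------------------------
# hand-derived and forced cases
# ---------------------------------------------------------------------------


class TestDensityStrength:
    def test_complete_k4(self, k4):
        assert density(k4) == 1.0

    def test_empty_84(self):
        assert density(np.zeros((84, 84))) == 0.0

    def test_path4_half(self, path4):
        assert density(path4) == 0.5

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            density(np.zeros((1, 1)))

    def test_strength_triangle(self, triangle):
        assert avg_strength(triangle) == 2.0

    def test_strength_single_edge(self):
        assert avg_strength(make_connectome([[0, 5], [5, 0]])) == 5.0

    def test_strength_k4_half_weights(self, k4):
        assert avg_strength(k4.weights * 0.5) == pytest.approx(1.5)


class TestEfficiency:
    def test_complete_graph_is_one(self, k4):
        assert global_efficiency(k4) == pytest.approx(1.0)

    def test_isolated_nodes_zero(self):
        assert global_efficiency(np.zeros((2, 2))) == 0.0

    def test_path3(self, path3):
        # inverse distances per unordered pair: 1, 1, 1/2 -> mean 5/6
        assert global_efficiency(path3) == pytest.approx(5 / 6)

    def test_local_triangle(self, triangle):
        assert avg_local_efficiency(triangle) == pytest.approx(1.0)

    def test_local_star_zero(self, star5):
        assert avg_local_efficiency(star5) == 0.0

    def test_local_path3_zero(self, path3):
        assert avg_local_efficiency(path3) == 0.0


class TestPaths:
    def test_complete_graph(self, k4):
        assert char_path_and_edge_count(k4) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_path3(self, path3):
        cpl, ec = char_path_and_edge_count(path3)
        assert cpl == pytest.approx(4 / 3)
        assert ec == pytest.approx(4 / 3)

    def test_path4_edge_count(self, path4):
        _, ec = char_path_and_edge_count(path4)
        assert ec == pytest.approx(10 / 6)

    def test_disconnected_pairs_excluded(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        cpl, ec = char_path_and_edge_count(w)
        assert cpl == pytest.approx(1.0)
        assert ec == pytest.approx(1.0)

    def test_no_finite_pair_is_undefined(self):
        cpl, ec = char_path_and_edge_count(np.zeros((3, 3)))
        assert np.isnan(cpl) and np.isnan(ec)

    def test_strong_edge_shortens_distance(self):
        # direct edge w=1 (length 1) loses to two-hop route via w=4 edges
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 4.0
        w[2, 1] = w[1, 2] = 4.0
        cpl, ec = char_path_and_edge_count(w)
        assert cpl == pytest.approx((0.5 + 0.25 + 0.25) / 3)


class TestClustering:
    def test_triangle(self, triangle):
        assert avg_clustering(triangle) == pytest.approx(1.0)

    def test_tree_zero(self, path4):
        assert avg_clustering(path4) == 0.0

    def test_k4_one_weak_edge(self, k4):
        w = k4.weights.copy()
        w[0, 1] = w[1, 0] = 0.5
        # frozen from the exhaustive triangle-enumeration oracle
        assert avg_clustering(w) == pytest.approx(0.8968502629920498, abs=1e-12)


class TestBetweenness:
    def test_path3_average(self, path3):
        assert avg_betweenness(path3) == pytest.approx(1 / 3)

    def test_complete_zero(self, k4):
        assert avg_betweenness(k4) == 0.0

    def test_star_center(self, star5):
        # C(4,2) = 6 leaf pairs all route through the center
        bc = oracles.betweenness(star5.weights)
        assert bc[0] == 6.0
        assert avg_betweenness(star5) == pytest.approx(6 / 5)


class TestAssortativity:
    def test_path4(self, path4):
        assert assortativity(path4) == pytest.approx(-0.5)

    def test_star(self, star5):
        assert assortativity(star5) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self, triangle):
        assert np.isnan(assortativity(triangle))


class TestModularity:
    def test_single_community_zero(self, k4):
        assert modularity_value(k4, [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_two_triangles_by_component(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            w[a, b] = w[b, a] = 1.0
        assert modularity_value(w, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_q_within_bounds_random(self):
        rng = np.random.default_rng(5)
        for w in _random_graphs(8, seed=21):
            if w.max() == 0:
                continue
            labels = rng.integers(0, 3, size=w.shape[0])
            q = modularity_value(w, labels)
            assert -1.0 <= q <= 1.0

    def test_louvain_matches_direct_q(self):
        for w in _random_graphs(8, seed=31):
            if w.max() == 0:
                continue
            partition, q = modularity_louvain(w, seed=4)
            direct = oracles.modularity(w, partition.labels(w.shape[0]))
            assert q == pytest.approx(direct, abs=1e-12)

    def test_empty_graph_undefined(self):
        partition, q = modularity_louvain(np.zeros((4, 4)))
        assert partition is None and np.isnan(q)

    def test_louvain_finds_planted_split(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            w[a, b] = w[b, a] = 1.0
        partition, q = modularity_louvain(w, seed=0)
        assert q == pytest.approx(0.5)
        labels = partition.labels(6)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1


class TestParticipation:
    def test_single_module_zero(self, k4):
        assert avg_participation(k4, [0, 0, 0, 0]) == 0.0

    def test_equal_split_half(self):
        # node 0 splits its strength equally between two modules
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        labels = [0, 0, 1]
        # P0 = 1 - (0.5^2 + 0.5^2) = 0.5; P1 = P2 = 0 (all strength internal
        # for node 1; node 2's single edge crosses -> P2 = 1 - 1 = 0)
        part = avg_participation(w, labels)
        assert part == pytest.approx(0.5 / 3)

    def test_matches_oracle_on_random(self):
        rng = np.random.default_rng(2)
        for w in _random_graphs(8, seed=41):
            labels = rng.integers(0, 3, size=w.shape[0])
            assert avg_participation(w, labels) == pytest.approx(
                oracles.participation(w, labels), abs=1e-9
            )


class TestRichClub:
    def test_complete_graph_one(self, k4):
        phi = rich_club_curve(k4)
        defined = phi[np.isfinite(phi)]
        assert np.allclose(defined, 1.0)
        assert rich_club(k4) == pytest.approx(1.0)

    def test_no_hub_undefined(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        assert np.isnan(rich_club(w))

    def test_weighted_core_fixture(self):
        # K3 core with weights {2,3,4} plus two weight-1 pendant edges:
        # phi(1) = 9/9 = 1, phi(2) = 2/4 = 0.5 (frozen from the oracle)
        w = np.zeros((5, 5))
        for (i, j), wt in {(0, 1): 2.0, (0, 2): 3.0, (1, 2): 4.0,
                           (3, 0): 1.0, (4, 1): 1.0}.items():
            w[i, j] = w[j, i] = wt
        np.testing.assert_allclose(rich_club_curve(w), [1.0, 0.5])
        assert rich_club(w, reduction="mean") == pytest.approx(0.75)
        assert rich_club(w, reduction="max_k") == pytest.approx(0.5)
        assert rich_club(w, reduction="fixed_k", k=1) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# oracle equivalence on random small graphs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("w", _random_graphs(), ids=lambda w: f"n{w.shape[0]}")
def test_oracle_equivalence_small_graphs(w):
    """Every path/triangle-based measure agrees with brute-force enumeration."""
    assert density(w) == pytest.approx(
        np.count_nonzero(np.triu(w, 1)) / (w.shape[0] * (w.shape[0] - 1) / 2),
        abs=1e-9,
    )
    assert avg_strength(w) == pytest.approx(float(np.mean(w.sum(1))), abs=1e-9)
    assert global_efficiency(w) == pytest.approx(oracles.global_efficiency(w), abs=1e-9)
    assert avg_local_efficiency(w) == pytest.approx(oracles.local_efficiency(w), abs=1e-9)
    cpl, ec = char_path_and_edge_count(w)
    o_cpl, o_ec = oracles.char_path_and_edge_count(w)
    np.testing.assert_allclose([cpl, ec], [o_cpl, o_ec], atol=1e-9)
    assert avg_clustering(w) == pytest.approx(oracles.onnela_clustering(w), abs=1e-9)
    assert avg_betweenness(w) == pytest.approx(
        float(np.mean(oracles.betweenness(w))), abs=1e-9
    )
    a, oa = assortativity(w), oracles.assortativity(w)
    assert (np.isnan(a) and np.isnan(oa)) or a == pytest.approx(oa, abs=1e-9)
    phi, ophi = rich_club_curve(w), oracles.rich_club_curve(w)
    np.testing.assert_allclose(phi, ophi, atol=1e-9, equal_nan=True)


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("w", _random_graphs(6, seed=51), ids=lambda w: f"n{w.shape[0]}")
def test_permutation_invariance(w):
    rng = np.random.default_rng(9)
    perm = rng.permutation(w.shape[0])
    wp = w[np.ix_(perm, perm)]
    for fn in (density, avg_strength, global_efficiency, avg_local_efficiency,
               avg_clustering, avg_betweenness):
        assert fn(wp) == pytest.approx(fn(w), abs=1e-9)
    a, ap = assortativity(w), assortativity(wp)
    assert (np.isnan(a) and np.isnan(ap)) or a == pytest.approx(ap, abs=1e-9)
    np.testing.assert_allclose(
        char_path_and_edge_count(wp), char_path_and_edge_count(w), atol=1e-9
    )


@pytest.mark.parametrize("w", _random_graphs(6, seed=61), ids=lambda w: f"n{w.shape[0]}")
def test_weight_scaling_behavior(w):
    """Scale-free measures ignore uniform weight scaling; strength is linear."""
    rng = np.random.default_rng(1)
    scale = 7.3
    ws = w * scale
    labels = rng.integers(0, 2, size=w.shape[0])
    assert density(ws) == pytest.approx(density(w), abs=1e-12)
    assert avg_clustering(ws) == pytest.approx(avg_clustering(w), abs=1e-9)
    assert avg_participation(ws, labels) == pytest.approx(
        avg_participation(w, labels), abs=1e-9
    )
    a, as_ = assortativity(w), assortativity(ws)
    assert (np.isnan(a) and np.isnan(as_)) or a == pytest.approx(as_, abs=1e-9)
    assert avg_strength(ws) == pytest.approx(scale * avg_strength(w), rel=1e-12)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


class TestAllMeasures:
    def test_complete_k4_composite(self, k4):
        mv = all_measures(k4)
        assert mv.density == 1.0
        assert mv.global_efficiency == pytest.approx(1.0)
        assert mv.char_path_length == pytest.approx(1.0)
        assert mv.avg_clustering == pytest.approx(1.0)

    def test_empty_graph_flags(self):
        mv = all_measures(np.zeros((5, 5)))
        assert mv.density == 0.0
        assert mv.avg_strength == 0.0
        assert np.isnan(mv.char_path_length)
        assert np.isnan(mv.modularity)
        assert np.isnan(mv.rich_club)

    def test_deterministic_given_seed(self):
        w = oracles.random_weighted_graph(np.random.default_rng(77), 10)
        a = all_measures(w, seed=3).to_array()
        b = all_measures(w, seed=3).to_array()
        np.testing.assert_array_equal(a, b)

    def test_vector_roundtrip_and_order(self):
        mv = all_measures(oracles.random_weighted_graph(np.random.default_rng(8), 7))
        arr = mv.to_array()
        assert arr.shape == (12,)
        again = ms.MeasureVector.from_array(arr)
        np.testing.assert_array_equal(again.to_array(), arr, err_msg=str(MEASURE_NAMES))

    def test_measures_table_schema(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_nodes=10, n_per_site=3, seed=2))
        table = measures_table(cohort)
        assert list(table.columns) == ["subject_id", "site", *MEASURE_NAMES]
        assert len(table) == 6
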