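"""Structure graphs, connectivity statistics, profiles and matching."""

import numpy as np
import pytest

from latnets import structure_statistics as ss
from latnets import tensor_factorization as tf
from latnets.causality_normalization import build_comparisons
from latnets.structure_statistics import StructureGraph
from latnets.tensor_factorization import ParafacModel, TensorAxes


def _axes(ic_counts, n_win=4, n_freq=3):
    return TensorAxes(
        comparisons=build_comparisons(),
        n_windows=n_win,
        n_freqs=n_freq,
        subjects=[f"S{i + 1}" for i in range(len(ic_counts))],
        ics_per_subject={
            f"S{i + 1}": list(range(k)) for i, k in enumerate(ic_counts)
        },
    )


def _model(axes, rank=2, seed=0):
    rng = np.random.default_rng(seed)
    conn = sum(len(v) * (len(v) - 1) for v in axes.ics_per_subject.values())
    return ParafacModel(
        mode0=rng.standard_normal((18, rank)),
        mode1=np.abs(rng.standard_normal((axes.n_windows * axes.n_freqs, rank))),
        mode2=np.abs(rng.standard_normal((conn, rank))),
        fit_percent=100.0,
    )


def _graph(weights, subject="S1", structure=0):
    w = np.asarray(weights, dtype=float)
    return StructureGraph(weights=w, subject=subject, structure=structure, ics=list(range(w.shape[0])))


class TestLoadingsToGraphs:
    def test_subject_block_sizes_at_study_scale(self):
        axes = _axes([49, 33, 36], n_win=2, n_freq=2)
        sl = axes.subject_slices()
        assert sl["S1"] == slice(0, 2352)
        assert sl["S2"] == slice(2352, 2352 + 1056)
        assert sl["S3"].stop - sl["S3"].start == 1260

    def test_graph_round_trip(self):
        axes = _axes([3])
        model = _model(axes, rank=2, seed=1)
        graphs = ss.loadings_to_graphs(model, axes)
        g = graphs[1]["S1"]
        flat = []
        for a in range(3):
            for b in range(3):
                if a != b:
                    flat.append(g.weights[a, b])
        np.testing.assert_allclose(flat, model.mode2[:, 1])

    def test_two_ics_give_two_weights(self):
        axes = _axes([2])
        model = _model(axes, rank=1)
        g = ss.loadings_to_graphs(model, axes)[0]["S1"]
        assert (g.weights != 0).sum() == 2

    def test_length_mismatch_rejected(self):
        axes = _axes([3])
        model = _model(axes)
        model.mode2 = model.mode2[:-1]
        with pytest.raises(ValueError, match="registry"):
            ss.loadings_to_graphs(model, axes)


class TestNodeStrengths:
    def test_single_edge(self):
        g = _graph([[0, 2.0], [0, 0]])
        s = ss.node_strengths(g)
        np.testing.assert_allclose(s["density"], [2.0, 2.0])
        np.testing.assert_allclose(s["outflow"], [2.0, -2.0])

    def test_outflow_conservation(self):
        rng = np.random.default_rng(2)
        w = np.abs(rng.standard_normal((5, 5)))
        np.fill_diagonal(w, 0)
        s = ss.node_strengths(_graph(w))
        assert abs(s["outflow"].sum()) < 1e-12
        assert np.all(s["density"] >= np.abs(s["outflow"]) - 1e-12)

    def test_uniform_complete_digraph(self):
        k, wgt = 4, 0.7
        w = np.full((k, k), wgt)
        np.fill_diagonal(w, 0)
        s = ss.node_strengths(_graph(w))
        np.testing.assert_allclose(s["density"], 2 * wgt * (k - 1))
        np.testing.assert_allclose(s["outflow"], 0.0, atol=1e-12)


class TestProjectToChannels:
    def test_single_ic_unit_weight(self):
        mixing = np.array([[1.0], [0.0], [0.0]])
        out = ss.project_to_channels(np.array([3.0]), mixing)
        np.testing.assert_allclose(out, [3.0, 0.0, 0.0])

    def test_linearity(self):
        rng = np.random.default_rng(3)
        mixing = rng.standard_normal((6, 4))
        v = rng.uniform(1, 2, 4)
        np.testing.assert_allclose(
            ss.project_to_channels(2 * v, mixing), 2 * ss.project_to_channels(v, mixing)
        )

    def test_overlapping_ics_sum_against_direct_oracle(self):
        mixing = np.array([[0.5, -0.8], [1.0, 0.4]])
        v = np.array([2.0, 3.0])
        # direct summation per the definition
        expected = np.zeros(2)
        for ic in range(2):
            wcol = np.abs(mixing[:, ic])
            expected += wcol / wcol.max() * v[ic]
        np.testing.assert_allclose(ss.project_to_channels(v, mixing), expected)

    def test_zero_weight_ic_rejected(self):
        with pytest.raises(ValueError):
            ss.project_to_channels(np.ones(2), np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestAreaMaxFlow:
    def test_single_edge_between_areas(self):
        g = _graph([[0, 3.0], [0, 0]])
        areas = {0: "V", 1: "PF"}
        m, flags = ss.area_max_flow(g, areas)
        assert m[0, 2] == 3.0  # V row, PF column
        assert m.sum() == 3.0
        assert "P" in flags["empty_areas"]

    def test_parallel_edges_take_max(self):
        g = _graph([[0, 0, 2.0], [0, 0, 5.0], [0, 0, 0]])
        areas = {0: "V", 1: "V", 2: "PF"}
        m, _ = ss.area_max_flow(g, areas)
        assert m[0, 2] == 5.0

    def test_entries_bounded_by_global_max(self):
        rng = np.random.default_rng(4)
        w = np.abs(rng.standard_normal((6, 6)))
        np.fill_diagonal(w, 0)
        g = _graph(w)
        areas = {i: a for i, a in enumerate(["V", "V", "P", "P", "M", "aT"])}
        m, _ = ss.area_max_flow(g, areas)
        assert m.max() <= w.max() + 1e-12


class TestTopSharedConnections:
    def test_identical_graphs_share_everything(self):
        rng = np.random.default_rng(5)
        w = np.abs(rng.standard_normal((6, 6)))
        np.fill_diagonal(w, 0)
        g = _graph(w)
        for q in (0.05, 0.1, 0.25):
            assert ss.top_shared_connections(g, g, q) == 1.0

    def test_disjoint_supports_share_nothing(self):
        w1 = np.zeros((4, 4))
        w2 = np.zeros((4, 4))
        w1[0, 1], w1[1, 2] = 5.0, 4.0
        w2[2, 3], w2[3, 0] = 5.0, 4.0
        w1 += 0.01 * (1 - np.eye(4)) - 0.01 * np.diag(np.zeros(4))
        w2 += 0.01 * (1 - np.eye(4))
        np.fill_diagonal(w1, 0)
        np.fill_diagonal(w2, 0)
        assert ss.top_shared_connections(_graph(w1), _graph(w2), 0.2) == 0.0

    def test_constructed_partial_overlap(self):
        # 10 strong edges each, 6 shared -> ratio 0.6, verified brute force
        rng = np.random.default_rng(6)
        k = 8
        base = 0.01 + 0.01 * np.abs(rng.standard_normal((k, k)))
        np.fill_diagonal(base, 0)
        edges = [(a, b) for a in range(k) for b in range(k) if a != b]
        rng.shuffle(edges)
        shared, only1, only2 = edges[:6], edges[6:10], edges[10:14]
        w1, w2 = base.copy(), base.copy()
        for e in shared + only1:
            w1[e] = 10 + rng.random()
        for e in shared + only2:
            w2[e] = 10 + rng.random()
        q = 10 / len(edges)
        got = ss.top_shared_connections(_graph(w1), _graph(w2), q)
        t1 = ss._top_edges(_graph(w1), q)
        t2 = ss._top_edges(_graph(w2), q)
        assert got == len(t1 & t2) / len(t1) == pytest.approx(0.6)


class TestUndirectedPathways:
    def test_identical_graphs_intersection_equals_union(self):
        rng = np.random.default_rng(7)
        w = np.abs(rng.standard_normal((5, 5)))
        np.fill_diagonal(w, 0)
        out = ss.undirected_pathways([_graph(w), _graph(w)], qs=(0.1, 0.25))
        for q in (0.1, 0.25):
            assert out[q]["intersection"] == out[q]["union"]

    def test_opposite_directions_count_as_shared(self):
        w1 = 0.01 * (1 - np.eye(3))
        w2 = 0.01 * (1 - np.eye(3))
        w1[0, 1] = 5.0
        w2[1, 0] = 5.0
        out = ss.undirected_pathways([_graph(w1), _graph(w2)], qs=(0.2,))
        assert frozenset({0, 1}) in out[0.2]["intersection"]


class TestProfiles:
    def test_separable_mode1_column_recovers_factors(self):
        axes = _axes([3], n_win=5, n_freq=4)
        u = np.abs(np.random.default_rng(8).standard_normal(5))
        v = np.abs(np.random.default_rng(9).standard_normal(4))
        model = _model(axes, rank=1)
        model.mode1 = np.outer(u, v).reshape(-1, 1)
        prof = ss.profiles(model, axes)[0]
        np.testing.assert_allclose(prof.temporal, u * v.sum(), atol=1e-12)
        np.testing.assert_allclose(prof.spectral, v * u.mean(), atol=1e-12)
        assert prof.temporal.min() >= 0 and prof.spectral.min() >= 0

    def test_profile_lengths_match_grid(self):
        axes = _axes([3], n_win=7, n_freq=5)
        prof = ss.profiles(_model(axes), axes)
        assert prof[0].temporal.shape == (7,)
        assert prof[0].spectral.shape == (5,)


class TestCompareStructures:
    def test_self_comparison_is_identity(self):
        axes = _axes([3, 4])
        model = _model(axes, rank=3, seed=10)
        out = ss.compare_structures(model, axes, model, axes)
        np.testing.assert_array_equal(out["assignment"], [0, 1, 2])
        for name in ("comparison", "temporal", "spectral", "outflow"):
            np.testing.assert_allclose(out["diagonal"][name], 1.0, atol=1e-12)

    def test_column_permutation_recovered(self):
        axes = _axes([4])
        model = _model(axes, rank=4, seed=11)
        perm = np.array([2, 0, 3, 1])
        permuted = ParafacModel(
            mode0=model.mode0[:, perm],
            mode1=model.mode1[:, perm],
            mode2=model.mode2[:, perm],
            fit_percent=100.0,
        )
        out = ss.compare_structures(model, axes, permuted, axes)
        # brute-force check over all 4! permutations that the assignment
        # maximizes the summed diagonal correlation
        import itertools

        total = sum(np.nan_to_num(c) for c in out["correlation"].values())
        best = max(
            itertools.permutations(range(4)),
            key=lambda p: sum(total[i, p[i]] for i in range(4)),
        )
        assert tuple(out["assignment"]) == best
        # assignment maps structure i of the reference onto the permuted
        # copy's column holding it: the inverse permutation
        assert np.array_equal(out["assignment"], np.argsort(perm))

    def test_outflow_vector_length_at_study_scale(self):
        axes = _axes([49, 33, 36], n_win=2, n_freq=2)
        model = _model(axes, rank=2, seed=12)
        vec = ss._outflow_vector(model, axes)
        assert vec.shape == (49 + 33 + 36, 2)
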