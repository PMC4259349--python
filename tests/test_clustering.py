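import itertools

import networkx as nx
import numpy as np
import pytest

from motifroles import (DirectedGraph, clustering_coefficients, degree_table,
                        functional_role_fingerprints, random_digraph,
                        toy_graph, transitivities, triangle_potential)


def _analysis(g):
    rfp = functional_role_fingerprints(g)
    return rfp, clustering_coefficients(rfp, degree_table(g))


class TestTrianglePotential:
    @pytest.mark.parametrize("name,b,D", [
        ("cycle3", 1, 2),
        ("complete_triad", 8, 8),
    ])
    def test_uniform_toys(self, name, b, D):
        g = toy_graph(name)
        tp = triangle_potential(g, functional_role_fingerprints(g))
        assert tp.closed.tolist() == [b] * 3
        assert tp.potential.tolist() == [D] * 3

    def test_two_path_middle_has_no_triangles(self):
        g = toy_graph("two_path")
        tp = triangle_potential(g, functional_role_fingerprints(g))
        middle = g.index_of("B")
        assert tp.closed[middle] == 0 and tp.potential[middle] == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_symmetrized_cube_diagonal(self, seed):
        """b from role counts equals diag((A+A^T)^3)/2 exactly."""
        g = random_digraph(40, 0.15, reciprocity=0.25, seed=seed)
        tp = triangle_potential(g, functional_role_fingerprints(g))
        s = g.adjacency + g.adjacency.T
        assert np.array_equal(tp.closed,
                              np.diagonal(np.linalg.matrix_power(s, 3)) // 2)
        assert (tp.closed <= tp.potential).all()


class TestClusteringToyValues:
    def test_ffl(self):
        g = toy_graph("ffl")
        _, rep = _analysis(g)
        a, b, c = (g.index_of(x) for x in "ABC")
        assert rep.vector("out")[a] == 0.5
        assert rep.vector("mid")[b] == 1.0
        assert rep.vector("in")[c] == 0.5
        assert (rep.vector("cyc") == 0).all()
        assert rep.vector("3ff")[a] == 0.5
        assert rep.vector("3ff")[b] == 1.0

    def test_cycle3(self):
        _, rep = _analysis(toy_graph("cycle3"))
        assert (rep.vector("cyc") == 1).all()
        for sub in ("in", "out", "mid"):
            assert (rep.vector(sub) == 0).all()

    def test_isolated_node_gets_zeros(self):
        base = toy_graph("ffl").adjacency
        a = np.zeros((4, 4), dtype=int)
        a[:3, :3] = base
        g = DirectedGraph(a)
        _, rep = _analysis(g)
        for sub in ("tot", "in", "out", "mid", "cyc", "3ff"):
            assert rep.vector(sub)[3] == 0.0

    def test_global_mean_variants(self):
        g = toy_graph("ffl")
        _, rep = _analysis(g)
        row = rep.global_means.set_index("subtype").loc["mid"]
        # only node B has two-path-middle potential
        assert row["n_star"] == 1
        assert row["mean_defined"] == 1.0
        assert row["mean_all"] == pytest.approx(1 / 3)


class TestFagioloAgreement:
    @pytest.mark.parametrize("seed", range(25))
    def test_closed_matrix_forms(self, seed):
        """Numerators equal Fagiolo's matrix-power diagonals exactly."""
        g = random_digraph(40, 0.12, reciprocity=0.3, seed=100 + seed)
        a = g.adjacency
        at = a.T
        f = functional_role_fingerprints(g)
        assert np.array_equal(f.role(18), np.diagonal(a @ a @ a))
        assert np.array_equal(f.role(17), np.diagonal(a.T @ a @ a.T))
        assert np.array_equal(f.role(11), np.diagonal(at @ a @ a))
        assert np.array_equal(f.role(14), np.diagonal(a @ a @ at))

    def test_total_matches_fagiolo_formula(self):
        for seed in range(10):
            g = random_digraph(40, 0.15, seed=seed)
            _, rep = _analysis(g)
            a = g.adjacency
            s = a + a.T
            dt = degree_table(g)
            num = np.diagonal(np.linalg.matrix_power(s, 3)) / 2
            den = (dt.d_tot * (dt.d_tot - 1) - 2 * dt.d_recip).to_numpy()
            expect = np.divide(num, den, out=np.zeros(g.n_nodes),
                               where=den > 0)
            assert rep.vector("tot") == pytest.approx(expect, abs=1e-12)


class TestTransitivities:
    def test_cycle3_cycle_transitivity_is_one(self):
        tr = transitivities(functional_role_fingerprints(toy_graph("cycle3")))
        assert tr.T_cyc == 1.0

    def test_complete_triad_all_ones(self):
        tr = transitivities(
            functional_role_fingerprints(toy_graph("complete_triad")))
        assert all(v == 1.0 for v in tr.as_dict().values())

    def test_ffl_three_feedforward(self):
        tr = transitivities(functional_role_fingerprints(toy_graph("ffl")))
        assert tr.T_3ff == pytest.approx(3 / 5)
        assert tr.T_cyc == 0.0

    def test_empty_graph_reports_zero_with_note(self):
        g = DirectedGraph(np.zeros((4, 4), dtype=int))
        tr = transitivities(functional_role_fingerprints(g))
        assert all(v == 0.0 for v in tr.as_dict().values())
        assert tr.notes

    def test_cycle_denominator_is_two_path_count(self):
        """All three motif-2 roles sum to the same network total."""
        for seed in range(5):
            g = random_digraph(30, 0.2, seed=seed)
            f = functional_role_fingerprints(g)
            t1, t4, t16 = (f.role(r).sum() for r in (1, 4, 16))
            assert t1 == t4 == t16

    @pytest.mark.parametrize("p", [0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
                                   0.6, 0.7, 0.8, 0.9])
    def test_everything_in_unit_interval(self, p):
        for seed in range(100):
            g = random_digraph(15, p, seed=seed)
            rfp = functional_role_fingerprints(g)
            rep = clustering_coefficients(rfp, degree_table(g))
            for sub in ("tot", "in", "out", "mid", "cyc", "3ff"):
                v = rep.vector(sub)
                assert (0 <= v).all() and (v <= 1).all(), (p, seed, sub)
            for val in transitivities(rfp).as_dict().values():
                assert 0.0 <= val <= 1.0, (p, seed)

    def test_mean_of_ratios_equals_ratio_of_totals_on_transitive_toys(self):
        """On vertex-transitive graphs the two global forms coincide."""
        for name in ("cycle3", "complete_triad"):
            g = toy_graph(name)
            rfp = functional_role_fingerprints(g)
            rep = clustering_coefficients(rfp, degree_table(g))
            tr = transitivities(rfp).as_dict()
            for sub in ("tot", "in", "out", "mid", "cyc", "3ff"):
                defined = rep.global_means.set_index("subtype")
                if defined.loc[sub, "n_star"] == 3:
                    assert tr[f"T_{sub}"] == pytest.approx(
                        rep.mean(sub, over="all"))

    @pytest.mark.parametrize("seed", range(10))
    def test_undirected_transitivity_matches_collapsed_graph(self, seed):
        g = random_digraph(30, 0.12, reciprocity=0.3, seed=seed)
        tr = transitivities(functional_role_fingerprints(g))
        und = nx.from_numpy_array((g.adjacency + g.adjacency.T > 0))
        assert tr.T_undirected == pytest.approx(nx.transitivity(und),
                                                abs=1e-12)

    def test_undirected_transitivity_direct_census(self):
        """3 * triangles / two-paths computed straight from the collapsed
        graph, independent of the conversion machinery."""
        g = random_digraph(20, 0.2, seed=3)
        und = (g.adjacency + g.adjacency.T > 0).astype(int)
        tris = paths = 0
        for i, j, k in itertools.combinations(range(20), 3):
            e = und[i, j] + und[i, k] + und[j, k]
            if e == 3:
                tris += 1
                paths += 3
            elif e == 2:
                paths += 1
        tr = transitivities(functional_role_fingerprints(g))
        assert tr.T_undirected == pytest.approx(3 * tris / paths)


class TestStructuralVariant:
    def test_structural_requires_opt_in(self):
        g = toy_graph("ffl")
        from motifroles import (apply_conversion, derive_role_conversion,
                                invert_conversion)
        s = apply_conversion(functional_role_fingerprints(g),
                             invert_conversion(derive_role_conversion()))
        with pytest.raises(ValueError, match="experimental"):
            clustering_coefficients(s, degree_table(g))
        rep = clustering_coefficients(s, degree_table(g),
                                      allow_structural=True)
        assert rep.flavor == "structural"
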