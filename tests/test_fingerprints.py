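import numpy as np
import pytest

from motifroles import (ConsistencyError, degree_table,
                        functional_role_fingerprints, layout_to_motif_counts,
                        motif_counts, motif_fingerprints, random_digraph,
                        role_counts, role_counts_from_motif_counts,
                        role_fingerprints_bruteforce, role_layout, toy_graph,
                        write_fingerprints)
from motifroles.graph import DirectedGraph


class TestFunctionalToyValues:
    def test_cycle3_two_path_middle(self):
        f = functional_role_fingerprints(toy_graph("cycle3"))
        assert f.role(16).tolist() == [1, 1, 1]

    def test_complete_triad_two_path_middle(self):
        # d_in*d_out - d_recip = 2*2 - 2
        f = functional_role_fingerprints(toy_graph("complete_triad"))
        assert f.role(16).tolist() == [2, 2, 2]

    def test_ffl_source_role_14(self):
        f = functional_role_fingerprints(toy_graph("ffl"))
        assert f.role(14)[0] == 1
        assert f.role(14)[1] == 0 and f.role(14)[2] == 0

    def test_recip_plus_out_roles(self):
        f = functional_role_fingerprints(toy_graph("recip_plus_out"))
        assert f.role(20)[1] == 1  # B: reciprocal partner plus out-edge
        assert f.role(7)[0] == 1   # A: dyad member whose partner points out


class TestStructuralToyValues:
    def test_complete_triad_only_role_30(self):
        s = role_fingerprints_bruteforce(toy_graph("complete_triad"),
                                         flavor="structural")
        assert s.role(30).tolist() == [1, 1, 1]
        assert s.values[:29].sum() == 0

    def test_cycle3_induced_has_no_open_roles(self):
        s = role_fingerprints_bruteforce(toy_graph("cycle3"),
                                         flavor="structural")
        assert s.role(18).tolist() == [1, 1, 1]
        assert s.values.sum() == 3  # nothing else

    def test_limit_guard(self):
        g = random_digraph(12, 0.3, seed=0)
        with pytest.raises(ValueError, match="fast path"):
            role_fingerprints_bruteforce(g, limit=10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5])
    def test_fast_equals_bruteforce_on_random_graphs(self, p):
        """The dense-algebra path must reproduce the O(N^3) census exactly."""
        offset = {0.05: 0, 0.2: 100, 0.5: 200}[p]
        for seed in range(17):
            g = random_digraph(25, p, seed=offset + seed)
            fast = functional_role_fingerprints(g).values
            brute = role_fingerprints_bruteforce(g, flavor="functional").values
            assert np.array_equal(fast, brute), f"p={p} seed={seed}"

    def test_fast_equals_bruteforce_on_toys(self, toy):
        fast = functional_role_fingerprints(toy).values
        brute = role_fingerprints_bruteforce(toy, flavor="functional").values
        assert np.array_equal(fast, brute)


class TestDegreeIdentities:
    @pytest.mark.parametrize("seed", range(5))
    def test_pair_roles_are_degree_functions(self, seed):
        g = random_digraph(40, 0.15, reciprocity=0.3, seed=seed)
        f = functional_role_fingerprints(g)
        dt = degree_table(g)
        d_in = dt.d_in.to_numpy()
        d_out = dt.d_out.to_numpy()
        d_rec = dt.d_recip.to_numpy()
        assert np.array_equal(f.role(10), d_in * (d_in - 1) // 2)
        assert np.array_equal(f.role(13), d_out * (d_out - 1) // 2)
        assert np.array_equal(f.role(16), d_in * d_out - d_rec)
        assert np.array_equal(f.role(28), d_rec * (d_rec - 1) // 2)


class TestFlavorRelations:
    @pytest.mark.parametrize("seed", range(5))
    def test_structural_bounded_by_functional_row30_equal(self, seed):
        g = random_digraph(20, 0.3, seed=seed)
        f = functional_role_fingerprints(g).values
        s = role_fingerprints_bruteforce(g, flavor="structural").values
        assert (s <= f).all()
        assert np.array_equal(s[29], f[29])

    def test_structural_column_sums_count_connected_triples(self):
        g = random_digraph(15, 0.3, seed=1)
        s = role_fingerprints_bruteforce(g, flavor="structural")
        import itertools
        import networkx as nx
        und = nx.from_numpy_array(g.adjacency + g.adjacency.T)
        for i in range(g.n_nodes):
            n_conn = sum(
                1 for t in itertools.combinations(range(g.n_nodes), 3)
                if i in t and nx.is_connected(und.subgraph(t)))
            assert s.values[:, i].sum() == n_conn

    def test_total_structural_motifs_bounded_by_triples(self):
        g = random_digraph(18, 0.4, seed=4)
        s = role_fingerprints_bruteforce(g, flavor="structural")
        total = motif_counts(motif_fingerprints(s)).values.sum()
        assert total <= 18 * 17 * 16 // 6


class TestAggregation:
    def test_cycle3_functional_motif_fingerprints(self):
        mfp = motif_fingerprints(
            functional_role_fingerprints(toy_graph("cycle3")))
        assert mfp.motif(2).tolist() == [3, 3, 3]

    def test_complete_triad_structural_motifs(self):
        s = role_fingerprints_bruteforce(toy_graph("complete_triad"),
                                         flavor="structural")
        mfp = motif_fingerprints(s)
        assert mfp.motif(13).tolist() == [1, 1, 1]
        assert mfp.values[:12].sum() == 0

    def test_empty_graph_all_zero(self):
        g = DirectedGraph(np.zeros((5, 5), dtype=int))
        mfp = motif_fingerprints(functional_role_fingerprints(g))
        assert mfp.values.sum() == 0
        assert role_counts(functional_role_fingerprints(g)).values.sum() == 0

    def test_motif_counts_cycle3(self):
        f = functional_role_fingerprints(toy_graph("cycle3"))
        counts = motif_counts(motif_fingerprints(f))
        expect = np.zeros(13, dtype=int)
        expect[1], expect[4] = 3, 1  # motifs 2 and 5
        assert counts.values.tolist() == expect.tolist()
        s = role_fingerprints_bruteforce(toy_graph("cycle3"),
                                         flavor="structural")
        sc = motif_counts(motif_fingerprints(s))
        assert sc.values[4] == 1 and sc.values.sum() == 1

    def test_complete_triad_contains_six_functional_two_paths(self):
        f = functional_role_fingerprints(toy_graph("complete_triad"))
        counts = motif_counts(motif_fingerprints(f))
        assert counts.values[1] == 6

    def test_non_integral_row_sum_raises(self):
        from motifroles.fingerprints import MotifFingerprintMatrix
        bad = np.zeros((13, 2), dtype=int)
        bad[0, 0] = 1
        with pytest.raises(ConsistencyError):
            motif_counts(MotifFingerprintMatrix("functional", bad))

    @pytest.mark.parametrize("seed", range(3))
    def test_plurality_conservation(self, catalog, seed):
        """Role counts of motif m, summed, equal 3x the motif count."""
        g = random_digraph(20, 0.25, seed=seed)
        f = functional_role_fingerprints(g)
        rc = role_counts(f)
        mc = motif_counts(motif_fingerprints(f))
        for m in range(1, 14):
            total = sum(rc.values[r - 1] for r in catalog.roles_of_motif(m))
            assert total == 3 * mc.values[m - 1]


class TestRoleLayout:
    def test_cycle3_layout_and_recovery(self):
        f = functional_role_fingerprints(toy_graph("cycle3"))
        layout = role_layout(role_counts(f))
        assert layout.values[4].tolist() == [3, 0, 0]  # motif 5 row
        rec = layout_to_motif_counts(layout)
        assert rec.values[4] == 1

    def test_two_path_layout_row(self):
        f = functional_role_fingerprints(toy_graph("two_path"))
        layout = role_layout(role_counts(f))
        assert sorted(layout.values[1].tolist()) == [1, 1, 1]

    def test_layout_row_structure(self, catalog):
        """3-entry rows constant; 2-entry rows have one entry twice the
        other; 1-entry rows carry the motif count three times."""
        g = random_digraph(20, 0.3, reciprocity=0.4, seed=9)
        f = functional_role_fingerprints(g)
        layout = role_layout(role_counts(f))
        mc = layout_to_motif_counts(layout)
        for m in range(1, 14):
            row = [v for v in layout.values[m - 1] if v > 0]
            count = mc.values[m - 1]
            if count == 0:
                continue
            if len(row) == 3:
                assert len(set(row)) == 1
            elif len(row) == 2:
                assert max(row) == 2 * min(row)
            else:
                assert row == [3 * count]

    def test_round_trip_on_toys(self, toy, catalog):
        f = functional_role_fingerprints(toy)
        rc = role_counts(f)
        layout = role_layout(rc)
        mc = layout_to_motif_counts(layout)
        back = role_counts_from_motif_counts(mc)
        assert np.array_equal(back.values, rc.values)
        assert np.array_equal(role_layout(back).values, layout.values)


class TestExport:
    def test_tsv_round_trippable(self, tmp_path):
        g = toy_graph("ffl")
        f = functional_role_fingerprints(g)
        p = tmp_path / "fp.tsv"
        write_fingerprints(f, g, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("#") and "functional" in lines[0]
        assert lines[1].split("\t")[:2] == ["node_id", "node_label"]
        assert len(lines) == 2 + 3
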