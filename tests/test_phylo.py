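import numpy as np
import pytest

from mitodesc import phylo
from mitodesc import synthetic_data as syn
from conftest import (all_unrooted_topologies, random_unrooted_tree,
                      tree_path_distances)


def matrix(names, rows):
    return phylo.AlignedMatrix(names=list(names), rows=list(rows))


class TestAlignedMatrix:
    def test_unequal_rows_rejected(self):
        with pytest.raises(phylo.PhyloError):
            matrix(["a", "b"], ["AAA", "AA"])

    def test_concatenate_lengths_and_metadata(self):
        b1 = matrix(["a", "b"], ["A" * 10, "C" * 10])
        b2 = matrix(["b", "a"], ["D" * 20, "E" * 20])
        cat = phylo.concatenate_pcgs([("g1", b1), ("g2", b2)])
        assert cat.n_columns == 30
        assert cat.block_ranges == {"g1": (0, 10), "g2": (10, 30)}
        assert cat.row("a") == "A" * 10 + "E" * 20

    def test_concatenate_disjoint_taxa_rejected(self):
        b1 = matrix(["a", "b"], ["AA", "CC"])
        b2 = matrix(["c", "d"], ["DD", "EE"])
        with pytest.raises(phylo.PhyloError, match="g2"):
            phylo.concatenate_pcgs([("g1", b1), ("g2", b2)])

    def test_block_positions_map_back(self):
        rng = np.random.default_rng(0)
        blocks = []
        for g in range(13):
            n = int(rng.integers(5, 30))
            rows = ["".join(rng.choice(list("ACDEFG"), n)) for _ in range(4)]
            blocks.append((f"g{g}", matrix(["w", "x", "y", "z"], rows)))
        cat = phylo.concatenate_pcgs(blocks)
        for g, m in blocks:
            lo, hi = cat.block_ranges[g]
            assert cat.row("w")[lo:hi] == m.row("w")


class TestDistances:
    def test_identical_rows(self):
        D = phylo.aa_distance(matrix(["a", "b"], ["AAAA", "AAAA"]), "p")
        assert D[0, 1] == 0.0

    def test_p_distance_with_gaps(self):
        m = matrix(["a", "b"], ["AACCAAAAAA--", "AAAAAAAACC--"])
        D = phylo.aa_distance(m, "p")
        assert D[0, 1] == pytest.approx(0.4)

    def test_poisson_closed_form(self):
        m = matrix(["a", "b"], ["AACCAAAAAA", "AACCAAAACC"])
        D = phylo.aa_distance(m, "poisson")
        assert D[0, 1] == pytest.approx(-np.log(0.8), abs=1e-9)

    def test_saturated_pair_is_missing(self):
        m = matrix(["a", "b"], ["AAAA", "CCCC"])
        D = phylo.aa_distance(m, "poisson")
        assert np.isnan(D[0, 1])
        with pytest.raises(phylo.PhyloError):
            phylo.neighbor_joining(D, m.names)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        t = phylo.neighbor_joining(D, ["A", "B", "C"])
        lengths = {l.name: l.length for l in t.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_additive_five_taxon_exact(self):
        rng = np.random.default_rng(4)
        names = [f"t{k}" for k in range(5)]
        tree = random_unrooted_tree(names, rng)
        D = tree_path_distances(tree, names)
        rec = phylo.neighbor_joining(D, names)
        assert phylo.same_topology(tree, rec)
        # branch lengths are recovered too: the path metric matches
        Drec = tree_path_distances(rec, names)
        assert np.allclose(D, Drec, atol=1e-9)

    def test_degenerate_equal_distances_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = phylo.neighbor_joining(D, list("abcd"))
        t2 = phylo.neighbor_joining(D, list("abcd"))
        assert phylo.same_topology(t1, t2)
        assert len(t1.taxa()) == 4

    def test_additive_recovery_property(self):
        rng = np.random.default_rng(99)
        for rep in range(15):
            n = int(rng.integers(4, 13))
            names = [f"t{k:02d}" for k in range(n)]
            tree = random_unrooted_tree(names, rng)
            D = tree_path_distances(tree, names)
            assert phylo.same_topology(
                tree, phylo.neighbor_joining(D, names)), f"rep {rep}"


class TestFitch:
    def test_single_column(self):
        t = phylo.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        m = matrix(list("abcd"), ["A", "A", "T", "T"])
        assert phylo.fitch_score(t, m) == 1

    def test_constant_column(self):
        t = phylo.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        m = matrix(list("abcd"), ["A", "A", "A", "A"])
        assert phylo.fitch_score(t, m) == 0

    def test_gap_is_wildcard(self):
        t = phylo.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        m = matrix(list("abcd"), ["A", "-", "T", "T"])
        assert phylo.fitch_score(t, m) == 1

    def test_rerooting_invariance_and_bound(self):
        rng = np.random.default_rng(17)
        names = [f"t{k}" for k in range(6)]
        tree = random_unrooted_tree(names, rng)
        rows = ["".join(rng.choice(list("ACDEF"), 30)) for _ in names]
        m = matrix(names, rows)
        base = phylo.fitch_score(tree, m)
        assert base <= (len(names) - 1) * m.n_columns
        for og in names:
            rooted = phylo.root_with_outgroup(tree, og)
            assert phylo.fitch_score(rooted, m) == base


class TestNNISearch:
    def test_identity_on_optimal_tree(self):
        t = phylo.read_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        m = matrix(list("abcde"), ["AABBC", "AABBC", "BBAAC",
                                   "BBAAC", "ABABC"])
        out = phylo.nni_search(t, m)
        assert phylo.fitch_score(out, m) <= phylo.fitch_score(t, m)

    def test_mp_search_attains_exhaustive_optimum(self):
        rng = np.random.default_rng(42)
        names = [f"x{k}" for k in range(5)]
        topos = all_unrooted_topologies(names)
        assert len(topos) == 15
        for rep in range(8):
            rows = ["".join(rng.choice(list("ACDEF"), 20)) for _ in names]
            m = matrix(names, rows)
            best = min(phylo.fitch_score(t, m) for t in topos)
            found = phylo.fitch_score(phylo.mp_search(m), m)
            assert found == best, f"rep {rep}"


class TestBootstrapConsensus:
    def test_perfect_signal_gives_full_support(self):
        # every column supports the ab|cd split; the p model keeps the
        # saturated cross-pair distances finite
        m = matrix(list("abcd"), ["AAAAAAAAAA", "AAAAAAAAAC",
                                  "CCCCCCCCCA", "CCCCCCCCCC"])
        cons = phylo.bootstrap_support(m, builder="nj", replicates=20, seed=1,
                                       model="p")
        sups = cons.split_supports()
        assert sups and all(s == 100.0 for s in sups.values())

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(5)
        names = [f"t{k}" for k in range(5)]
        tree = random_unrooted_tree(names, rng)
        m = syn.simulate_alignment(tree, 100, seed=2)
        cons = phylo.bootstrap_support(m, builder="nj", replicates=1, seed=9)
        for s in cons.split_supports().values():
            assert s in (0.0, 100.0)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        names = [f"t{k}" for k in range(6)]
        tree = random_unrooted_tree(names, rng)
        m = syn.simulate_alignment(tree, 300, seed=3)
        a = phylo.bootstrap_support(m, replicates=30, seed=4)
        b = phylo.bootstrap_support(m, replicates=30, seed=4)
        assert phylo.write_newick(a) == phylo.write_newick(b)

    def test_consensus_contains_only_majority_splits(self):
        freqs = {frozenset(["b", "c"]): 0.8, frozenset(["d", "e"]): 0.45}
        cons = phylo.majority_consensus(freqs, list("abcde"))
        assert cons.splits() == {frozenset(["b", "c"])}
        assert cons.split_supports()[frozenset(["b", "c"])] == 80.0


class TestNewick:
    def test_round_trip_simple(self):
        text = "((A:1,B:1)85:0.5,C:2);"
        assert phylo.write_newick(phylo.read_newick(text)) == text

    def test_unrooted_trifurcation_preserved(self):
        text = "(A:1,B:2,C:3);"
        t = phylo.read_newick(text)
        assert len(t.root.children) == 3
        assert phylo.write_newick(t) == text

    def test_random_tree_round_trip_isomorphic(self):
        rng = np.random.default_rng(12)
        names = [f"t{k:02d}" for k in range(17)]
        tree = random_unrooted_tree(names, rng)
        back = phylo.read_newick(phylo.write_newick(tree))
        assert phylo.same_topology(tree, back)
        assert np.allclose(
            tree_path_distances(tree, names),
            tree_path_distances(back, names), atol=1e-5)

    def test_malformed_rejected(self):
        with pytest.raises(phylo.PhyloError):
            phylo.read_newick("((A,B)")

    def test_nj_topology_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(8)
        names = [f"t{k}" for k in range(7)]
        tree = random_unrooted_tree(names, rng)
        D = tree_path_distances(tree, names)
        ours = phylo.neighbor_joining(D, names)
        # independent oracle: dendropy's NJ on the same matrix
        csv = "," + ",".join(names) + "\n" + "\n".join(
            names[i] + "," + ",".join(str(D[i, j]) for j in range(len(names)))
            for i in range(len(names)))
        import io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        dtree = pdm.nj_tree()
        dsplits = set()
        taxa = sorted(names)
        ref = taxa[0]
        for edge in dtree.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node is dtree.seed_node:
                continue
            below = frozenset(l.taxon.label
                              for l in edge.head_node.leaf_iter())
            if 1 < len(below) < len(taxa) - 1:
                side = frozenset(taxa) - below if ref in below else below
                dsplits.add(side)
        assert ours.splits() == dsplits
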