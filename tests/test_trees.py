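"""Tree metrics: Newick I/O, resolution, RF/KF distances, NJ surrogate."""

import math

import numpy as np
import pytest

from gbsphylo import (
    branch_length_summary,
    evolve_loci,
    kf_branch_score,
    nj_bootstrap_tree,
    nj_tree,
    prune_to_one_per_species,
    read_newick,
    resolution_quotient,
    rf_distance,
    simulate_species_tree,
    write_newick,
)
from gbsphylo.replication import UndefinedRateError
from gbsphylo.trees import bipartition_map

from conftest import brute_kf, brute_rf, brute_splits, random_newick


class TestNewickIO:
    def test_supports_parsed_from_internal_labels(self):
        st = read_newick("((a:1,b:1)90:1,c:2);")
        splits = bipartition_map(st)
        # the one cherry is trivial on 3 tips; use a 4-tip case for support
        st4 = read_newick("((a:1,b:1)90:1,(c:1,d:1)55:1);")
        supports = {s["support"] for s in bipartition_map(st4).values()}
        assert supports == {90.0}  # the two root-child edges describe one split
        assert not splits

    def test_round_trip_on_random_trees(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 10))
            labels = [f"x{i}" for i in range(n)]
            st = read_newick(random_newick(labels, rng))
            back = read_newick(write_newick(st))
            m1 = bipartition_map(st, include_trivial=True)
            m2 = bipartition_map(back, include_trivial=True)
            assert set(m1) == set(m2)
            for split in m1:
                assert m1[split]["length"] == pytest.approx(m2[split]["length"], rel=1e-10)

    def test_pp_scale_support_bound_enforced(self):
        with pytest.raises(ValueError):
            read_newick("((a:1,b:1)1.3:1,(c:1,d:1):1);", support_scale="PP")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("((a:1,a:1):1,c:2);")


class TestResolutionQuotient:
    def test_fully_supported_binary_tree_scores_one(self):
        st = read_newick("(((a:1,b:1)100:1,c:1)100:1,(d:1,e:1)100:1);")
        assert resolution_quotient(st, 70.0) == 1.0

    def test_star_tree_scores_zero(self):
        st = read_newick("(a:1,b:1,c:1,d:1,e:1);")
        assert resolution_quotient(st, 70.0) == 0.0

    def test_strict_threshold_on_six_tip_tree(self):
        st = read_newick(
            "(((a:1,b:1)71:1,(c:1,d:1)65:1)90:1,e:1,f:1);"
        )
        assert resolution_quotient(st, 70.0) == pytest.approx(2 / 3)

    def test_unsupported_branches_never_count(self):
        st = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert resolution_quotient(st, 0.0) == 0.0

    def test_invariant_to_rerooting(self):
        text = "(((a:1,b:1)80:1,(c:1,d:1)60:2)90:1,(e:1,f:1)40:1);"
        st = read_newick(text)
        q0 = resolution_quotient(st, 70.0)
        t2 = read_newick(text)
        edge = [nd.edge for nd in t2.tree.leaf_node_iter()][2]
        t2.tree.reroot_at_edge(edge, update_bipartitions=False)
        assert resolution_quotient(t2, 70.0) == q0

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            resolution_quotient(read_newick("((a:1,b:1):1,c:1);"), 70.0)

    def test_threshold_above_scale_rejected(self):
        st = read_newick("((a:1,b:1)0.9:1,(c:1,d:1)0.8:1);", support_scale="PP")
        with pytest.raises(ValueError):
            resolution_quotient(st, 70.0)


class TestTreeDistances:
    def test_identical_trees(self):
        a = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        b = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert rf_distance(a, b) == (0, 0.0)
        assert kf_branch_score(a, b) == 0.0

    def test_conflicting_quartets(self):
        a = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        b = read_newick("((a:1,c:1):1,(b:1,d:1):1);")
        rf, norm = rf_distance(a, b)
        assert rf == 2 and norm == 1.0

    def test_kf_single_branch_difference(self):
        a = read_newick("((a:0.3,b:0.1):0.2,(c:0.1,d:0.1):0.2);")
        b = read_newick("((a:0.8,b:0.1):0.2,(c:0.1,d:0.1):0.2);")
        assert kf_branch_score(a, b) == pytest.approx(0.5)

    def test_kf_conflicting_quartets_closed_form(self):
        p, q = 0.4, 0.7
        a = read_newick(f"((a:1,b:1):{p / 2},(c:1,d:1):{p / 2});")
        b = read_newick(f"((a:1,c:1):{q / 2},(b:1,d:1):{q / 2});")
        assert kf_branch_score(a, b) == pytest.approx(math.hypot(p, q))

    def test_tip_set_mismatch_lists_offenders(self):
        a = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        b = read_newick("((a:1,b:1):1,(c:1,e:1):1);")
        with pytest.raises(ValueError, match="'d'"):
            rf_distance(a, b)

    def test_rf_and_kf_match_brute_force_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 9))
            labels = [f"x{i}" for i in range(n)]
            a = read_newick(random_newick(labels, rng))
            b = read_newick(random_newick(labels, rng))
            rf, _ = rf_distance(a, b)
            assert rf == brute_rf(a.tree, b.tree)
            assert kf_branch_score(a, b) == pytest.approx(brute_kf(a.tree, b.tree))

    def test_distances_match_dendropy_on_shared_namespace(self, rng):
        """Independent library cross-check of the RF computation."""
        import dendropy
        from dendropy.calculate import treecompare

        for _ in range(20):
            n = int(rng.integers(5, 10))
            labels = [f"x{i}" for i in range(n)]
            ns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=random_newick(labels, rng),
                                   schema="newick", taxon_namespace=ns)
            t2 = dendropy.Tree.get(data=random_newick(labels, rng),
                                   schema="newick", taxon_namespace=ns)
            ours, _ = rf_distance(read_newick(t1.as_string(schema="newick")),
                                  read_newick(t2.as_string(schema="newick")))
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            assert ours == treecompare.symmetric_difference(t1, t2)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 11))
            labels = [f"x{i}" for i in range(n)]
            trees = [read_newick(random_newick(labels, rng)) for _ in range(3)]
            for d in (lambda x, y: rf_distance(x, y)[0], kf_branch_score):
                dab = d(trees[0], trees[1])
                dba = d(trees[1], trees[0])
                assert dab == pytest.approx(dba)
                dbc = d(trees[1], trees[2])
                dac = d(trees[0], trees[2])
                assert dac <= dab + dbc + 1e-9


class TestBranchLengthSummary:
    def test_uniform_rooted_four_tip_tree(self):
        st = read_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        s = branch_length_summary(st)
        assert s.total == pytest.approx(0.6)
        assert s.mean == pytest.approx(0.1)
        assert s.median_rel_terminal == pytest.approx(0.1 / 0.6)
        assert s.median_rel_internal == pytest.approx(0.1 / 0.6)

    def test_caterpillar_relative_medians(self):
        st = read_newick("((a:1,b:1):5,(c:1,d:1):5);")  # internal split length 10
        s = branch_length_summary(st)
        assert s.median_rel_terminal == pytest.approx(1 / 14)
        # the root bifurcation is two edges of 5; their median is 5/14
        assert s.median_rel_internal == pytest.approx(5 / 14)

    def test_scale_invariance_of_relative_medians(self, rng):
        labels = [f"x{i}" for i in range(8)]
        text = random_newick(labels, rng)
        s1 = branch_length_summary(read_newick(text))
        scaled = read_newick(text)
        for nd in scaled.tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= 3.0
        s2 = branch_length_summary(scaled)
        assert s2.total == pytest.approx(3 * s1.total)
        assert s2.median_rel_terminal == pytest.approx(s1.median_rel_terminal)
        assert s2.median_rel_internal == pytest.approx(s1.median_rel_internal)

    def test_zero_total_length_is_undefined(self):
        with pytest.raises(UndefinedRateError):
            branch_length_summary(read_newick("((a:0,b:0):0,c:0);"))


class TestPruneToOnePerSpecies:
    def test_all_singletons_is_identity(self):
        st = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        pruned = prune_to_one_per_species(st, {t: t for t in "abcd"})
        assert rf_distance(st, pruned) == (0, 0.0)

    def test_path_lengths_preserved_after_pruning(self):
        st = read_newick("(((a1:0.2,a2:0.3):0.5,b:1.0):0.4,(c:0.6,d:0.7):0.3);")
        table = {"a1": "A", "a2": "A", "b": "B", "c": "C", "d": "D"}
        pruned = prune_to_one_per_species(st, table)
        assert sorted(pruned.tip_labels) == ["a1", "b", "c", "d"]
        pdm_full = st.tree.phylogenetic_distance_matrix()
        pdm_sub = pruned.tree.phylogenetic_distance_matrix()

        def dist(pdm, tree, x, y):
            tx = [t for t in tree.tree.taxon_namespace if t.label == x][0]
            ty = [t for t in tree.tree.taxon_namespace if t.label == y][0]
            return pdm.patristic_distance(tx, ty)

        for x in ("b", "c", "d"):
            assert dist(pdm_sub, pruned, "a1", x) == pytest.approx(
                dist(pdm_full, st, "a1", x)
            )

    def test_uncovered_tip_rejected(self):
        st = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ValueError):
            prune_to_one_per_species(st, {"a": "A", "b": "B", "c": "C"})


class TestNeighborJoining:
    def _supermatrix(self, seed=21, n_taxa=6, mu=0.05):
        tree = simulate_species_tree(n_taxa, 1.0, seed)
        truth = evolve_loci(tree, 40, 60, mu, 0.0, seed + 1)
        matrix = {
            t: "".join(truth.consensus(t, locus) for locus in truth.loci)
            for t in truth.taxa
        }
        return tree, matrix

    def test_recovers_generating_topology(self):
        tree, matrix = self._supermatrix()
        nj = nj_tree(matrix)
        rf, _ = rf_distance(read_newick(write_newick(tree)), nj)
        assert rf == 0

    def test_identical_sequences_give_zero_branch_lengths(self):
        matrix = {f"s{i}": "ACGT" * 10 for i in range(5)}
        nj = nj_tree(matrix)
        for nd in nj.tree.preorder_node_iter():
            if nd.edge.length is not None:
                assert nd.edge.length == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_supports_deterministic_for_seed(self):
        _, matrix = self._supermatrix()
        a = write_newick(nj_bootstrap_tree(matrix, n_bootstrap=20, seed=3))
        b = write_newick(nj_bootstrap_tree(matrix, n_bootstrap=20, seed=3))
        assert a == b

    def test_zero_overlap_pair_is_named(self):
        matrix = {"s1": "ACGTN", "s2": "NNNNA", "s3": "ACGTA", "s4": "ACGTA"}
        matrix["s1"] = "ACGTN"
        matrix["s2"] = "NNNNC"
        with pytest.raises(ValueError, match="s1.*s2"):
            nj_tree(matrix)
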