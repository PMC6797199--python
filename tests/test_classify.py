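import itertools

import dendropy
import numpy as np
import pytest

from httscan.classify import (SubfamilyPartition, clade_divergence,
                              collapse_intraspecific, delineate_subfamilies,
                              prune_leaves, root_at_outgroup,
                              subfamily_summary)
from httscan.core_io import Config
from httscan.distances import AADistanceMatrix


def tree_from(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def matrix(labels, dists):
    """Build an AADistanceMatrix from {(a, b): d} (symmetric fill)."""
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in dists.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return AADistanceMatrix(labels=tuple(labels), d=d, p=d.copy())


class TestRootAtOutgroup:
    def test_reroot_makes_outgroup_sister_to_rest(self):
        tree = root_at_outgroup(tree_from("(A:1,B:1,(C:1,Out:4):1);"), "Out")
        kids = tree.seed_node.child_nodes()
        sides = [sorted(l.taxon.label for l in c.leaf_iter()) for c in kids]
        assert ["Out"] in sides
        assert sorted(itertools.chain(*sides)) == ["A", "B", "C", "Out"]
        out_leaf = next(l for l in tree.leaf_node_iter()
                        if l.taxon.label == "Out")
        assert out_leaf.edge.length == pytest.approx(2.0)  # midpoint split

    def test_total_branch_length_preserved(self):
        nwk = "(A:1,B:2,(C:3,Out:4):5);"
        before = tree_from(nwk)
        total0 = sum(e.length or 0 for e in before.preorder_edge_iter())
        after = root_at_outgroup(before, "Out")
        total1 = sum(e.length or 0 for e in after.preorder_edge_iter())
        assert total1 == pytest.approx(total0)

    def test_missing_label_errors(self):
        with pytest.raises(ValueError):
            root_at_outgroup(tree_from("(A:1,B:1);"), "Z")


class TestCollapseIntraspecific:
    def test_shorter_path_to_mrca_kept(self):
        tree = tree_from("((sp1_a:0.01,sp1_b:0.05):0.2,sp2_c:0.3);")
        species = {"sp1_a": "sp1", "sp1_b": "sp1", "sp2_c": "sp2"}
        kept, dropped = collapse_intraspecific(tree, species)
        assert sorted(kept) == ["sp1_a", "sp2_c"]
        assert dropped == ["sp1_b"]

    def test_nested_single_species_clade_uses_path_length(self):
        tree = tree_from("(((sp1_a:0.01,sp1_b:0.02):0.001,sp1_c:0.005):0.1,"
                         "sp2_d:0.2);")
        species = {k: k.split("_")[0]
                   for k in ("sp1_a", "sp1_b", "sp1_c", "sp2_d")}
        kept, dropped = collapse_intraspecific(tree, species)
        # paths to the maximal sp1 clade MRCA: a=0.011, b=0.021, c=0.005
        assert "sp1_c" in kept
        assert sorted(dropped) == ["sp1_a", "sp1_b"]

    def test_all_distinct_species_untouched(self):
        tree = tree_from("((sp1_a:1,sp2_b:1):1,sp3_c:2);")
        species = {"sp1_a": "sp1", "sp2_b": "sp2", "sp3_c": "sp3"}
        kept, dropped = collapse_intraspecific(tree, species)
        assert sorted(kept) == ["sp1_a", "sp2_b", "sp3_c"]
        assert dropped == []


class TestDelineate:
    def test_threshold_separation(self, cfg):
        tree = tree_from("((A:1,B:1):1,C:2);")
        mat = matrix(["A", "B", "C"],
                     {("A", "B"): 0.1, ("A", "C"): 0.6, ("B", "C"): 0.6})
        part = delineate_subfamilies(tree, mat, cfg)
        assert part.k == 2
        assert part.assignments["A"] == part.assignments["B"]
        assert part.assignments["C"] != part.assignments["A"]

    def test_single_subfamily_when_all_close(self, cfg):
        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        mat = matrix(["A", "B", "C", "D"],
                     {p: 0.05 for p in itertools.combinations("ABCD", 2)})
        part = delineate_subfamilies(tree, mat, cfg)
        assert part.k == 1

    def test_missing_leaf_errors(self, cfg):
        tree = tree_from("((A:1,B:1):1,C:2);")
        mat = matrix(["A", "B"], {("A", "B"): 0.1})
        with pytest.raises(ValueError, match="missing"):
            delineate_subfamilies(tree, mat, cfg)

    def test_monotone_refinement_in_threshold(self):
        rng = np.random.default_rng(5)
        from httscan.synthetic import simulate_tree
        for seed in range(10):
            tree = simulate_tree(8, 1.0, seed)
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            mat = random_matrix(labels, rng)
            ks = []
            for thr in (0.6, 0.3, 0.15):
                cfg = Config(subfamily_threshold=thr)
                ks.append(delineate_subfamilies(tree, mat, cfg).k)
            assert ks == sorted(ks)

    def test_partition_covers_all_leaves_with_clades(self, cfg):
        from httscan.synthetic import simulate_tree
        rng = np.random.default_rng(17)
        tree = simulate_tree(8, 1.0, 3)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        part = delineate_subfamilies(tree, random_matrix(labels, rng), cfg)
        assert sorted(part.assignments) == sorted(labels)
        clades = all_clades(tree)
        for i in range(1, part.k + 1):
            assert frozenset(part.members(i)) in clades


def random_matrix(labels, rng):
    n = len(labels)
    d = np.abs(rng.normal(0.3, 0.2, size=(n, n)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return AADistanceMatrix(labels=tuple(labels), d=d, p=d.copy())


def all_clades(tree):
    return {frozenset(l.taxon.label for l in node.leaf_iter())
            for node in tree.preorder_node_iter()}


def oracle_partition(tree, mat, cfg):
    """Independent delineation: take maximal qualifying clades by set
    inclusion, then singletons for uncovered leaves, numbered in traversal
    order of their MRCA."""
    qualifying = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        stat = clade_divergence(sorted(leaves), mat, cfg.subfamily_statistic)
        if len(leaves) == 1 or stat < cfg.subfamily_threshold:
            qualifying.append(leaves)
    maximal = [q for q in qualifying
               if not any(q < other for other in qualifying)]
    # order by first appearance in preorder traversal
    assignments = {}
    k = 0
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if leaves in maximal and leaves.isdisjoint(assignments):
            k += 1
            for lab in leaves:
                assignments[lab] = k
    return SubfamilyPartition(assignments=assignments, k=k)


def test_delineation_matches_maximal_clade_oracle(cfg):
    from httscan.synthetic import simulate_tree
    rng = np.random.default_rng(23)
    for seed in range(30):
        tree = simulate_tree(8, 1.0, seed)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        mat = random_matrix(labels, rng)
        got = delineate_subfamilies(tree, mat, cfg)
        want = oracle_partition(tree, mat, cfg)
        assert got.assignments == want.assignments


def test_collapse_then_delineate_commutes(cfg):
    # collapsing intraspecific duplicates then delineating equals delineating
    # first and restricting to the kept leaves
    from httscan.synthetic import simulate_tree
    rng = np.random.default_rng(29)
    for seed in range(5):
        tree = simulate_tree(6, 1.0, seed)
        # rename tips to create intraspecific pairs: sp1..sp3 twice
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"sp{i % 3 + 1}_{i}"
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        species = {lab: lab.split("_")[0] for lab in labels}
        mat = random_matrix(labels, rng)
        kept, dropped = collapse_intraspecific(tree, species)
        pruned = prune_leaves(tree, dropped)
        part_after = delineate_subfamilies(pruned, mat, cfg)
        part_full = delineate_subfamilies(tree, mat, cfg)
        # grouping structure must agree when restricted to kept leaves
        def groups(part, subset):
            by = {}
            for lab in subset:
                by.setdefault(part.assignments[lab], set()).add(lab)
            return sorted(map(frozenset, by.values()), key=sorted)
        assert groups(part_after, kept) == groups(part_full, kept)


class TestSummary:
    def test_between_and_within_means(self, cfg):
        tree = tree_from("((A:1,B:1):1,C:2);")
        mat = matrix(["A", "B", "C"],
                     {("A", "B"): 0.1, ("A", "C"): 0.5, ("B", "C"): 0.7})
        part = delineate_subfamilies(tree, mat, cfg)
        between, within = subfamily_summary(part, mat)
        assert between[0, 1] == pytest.approx(0.6)   # mean of 0.5, 0.7
        assert within[0] == pytest.approx(0.1)
        assert np.isnan(within[1])                   # monotypic subfamily
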