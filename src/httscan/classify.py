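"""Tree operations: outgroup rooting, intraspecific collapsing and subfamily
delineation by reciprocal monophyly.

Subfamilies follow the classic criterion for TE classification: a reciprocally
monophyletic set of sequences whose amino-acid divergence is below a threshold
(default 30%, Poisson-corrected) forms one subfamily. Delineation walks the
rooted tree from the root; the first (largest) clade on each path that passes
the divergence criterion is emitted whole, so subfamilies are maximal clades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from httscan.core_io import Config
from httscan.distances import AADistanceMatrix

__all__ = [
    "SubfamilyPartition",
    "root_at_outgroup",
    "collapse_intraspecific",
    "delineate_subfamilies",
    "subfamily_summary",
    "clade_divergence",
]


@dataclass(frozen=True)
class SubfamilyPartition:
    """Assignment of every leaf to a subfamily index 1..k (traversal order)."""

    assignments: dict[str, int]
    k: int

    def members(self, index: int) -> list[str]:
        return [leaf for leaf, i in self.assignments.items() if i == index]


def _leaf_with_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    matches = [leaf for leaf in tree.leaf_node_iter()
               if leaf.taxon is not None and leaf.taxon.label == label]
    if not matches:
        raise ValueError(f"outgroup label {label!r} not found among leaves")
    if len(matches) > 1:
        raise ValueError(f"outgroup label {label!r} matches {len(matches)} leaves")
    return matches[0]


def root_at_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root (or re-root) a tree on the branch subtending the outgroup leaf.

    The outgroup's branch is split at its midpoint; ingroup topology is
    unchanged. Returns a new tree, leaving the input untouched.
    """
    tree = tree.clone(depth=1)
    leaf = _leaf_with_label(tree, outgroup_label)
    edge_len = leaf.edge.length if leaf.edge.length is not None else 0.0
    tree.reroot_at_edge(leaf.edge, length1=edge_len / 2.0,
                        length2=edge_len / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    # rerooting can leave a degree-2 node where the old root was
    tree.suppress_unifurcations()
    return tree


def prune_leaves(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Return a copy of the tree with the given leaves removed."""
    tree = tree.clone(depth=1)
    taxa = [t for t in tree.taxon_namespace if t.label in set(labels)]
    tree.prune_taxa(taxa)
    tree.suppress_unifurcations()
    return tree


def collapse_intraspecific(
        tree: dendropy.Tree,
        species_of: dict[str, str]) -> tuple[list[str], list[str]]:
    """Second filtering round: one representative per maximal single-species clade.

    For every maximal clade (>= 2 leaves) whose leaves all belong to one
    species, only the leaf with the shortest path (sum of branch lengths) to
    the clade's MRCA is kept -- the copy most similar to the inferred ancestral
    sequence. Ties break lexicographically by leaf label. Returns
    (kept, dropped) leaf labels.
    """
    kept: list[str] = []
    dropped: list[str] = []

    def leaf_species(node: dendropy.Node) -> set[str]:
        return {species_of[leaf.taxon.label]
                for leaf in node.leaf_iter()}

    def depths_from(node: dendropy.Node) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(n: dendropy.Node, acc: float) -> None:
            if n.is_leaf():
                out[n.taxon.label] = acc
                return
            for child in n.child_nodes():
                walk(child, acc + (child.edge.length or 0.0))

        walk(node, 0.0)
        return out

    def visit(node: dendropy.Node) -> None:
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if len(leaves) >= 2 and len(leaf_species(node)) == 1:
            depths = depths_from(node)
            rep = min(leaves, key=lambda lab: (depths[lab], lab))
            kept.append(rep)
            dropped.extend(sorted(set(leaves) - {rep}))
            return
        if node.is_leaf():
            kept.append(node.taxon.label)
            return
        for child in node.child_nodes():
            visit(child)

    root = tree.seed_node
    visit(root)
    return kept, dropped


def clade_divergence(leaves: list[str], aadist: AADistanceMatrix,
                     statistic: str = "mean") -> float:
    """Divergence statistic of a leaf set: mean (or max) pairwise distance.

    Monotypic sets have divergence 0. NaN distances propagate to NaN, which
    never satisfies a "< threshold" test (the clade is then split further).
    """
    if len(leaves) < 2:
        return 0.0
    idx = [aadist.labels.index(l) for l in leaves]
    sub = aadist.d[np.ix_(idx, idx)]
    vals = sub[np.triu_indices(len(idx), k=1)]
    if np.isnan(vals).any():
        return math.nan
    return float(vals.max() if statistic == "max" else vals.mean())


def delineate_subfamilies(tree: dendropy.Tree, aadist: AADistanceMatrix,
                          cfg: Config) -> SubfamilyPartition:
    """Partition leaves into subfamilies: maximal clades whose internal
    amino-acid divergence is below ``cfg.subfamily_threshold``.

    Pre-order traversal from the root; a clade passing the criterion is
    emitted as one subfamily and not descended into, so every subfamily is
    reciprocally monophyletic and maximal. Leaves reached singly become
    monotypic subfamilies. Numbering follows traversal order (polytomy
    children in input order), hence deterministic for a fixed input.
    """
    leaf_labels = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(leaf_labels) - set(aadist.labels)
    if missing:
        raise ValueError(f"leaves missing from distance matrix: {sorted(missing)}")

    assignments: dict[str, int] = {}
    counter = 0

    def visit(node: dendropy.Node) -> None:
        nonlocal counter
        leaves = [l.taxon.label for l in node.leaf_iter()]
        stat = clade_divergence(leaves, aadist, cfg.subfamily_statistic)
        if node.is_leaf() or stat < cfg.subfamily_threshold:
            counter += 1
            for lab in leaves:
                assignments[lab] = counter
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.seed_node)
    return SubfamilyPartition(assignments=assignments, k=counter)


def subfamily_summary(
        partition: SubfamilyPartition,
        aadist: AADistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-subfamily mean pairwise distance summaries.

    Returns ``(between, within)``: ``between`` is a k x k matrix whose [i, j]
    entry (i != j, 0-based for subfamilies i+1, j+1) is the mean distance over
    all cross pairs; ``within`` is length k, NaN for monotypic subfamilies.
    """
    k = partition.k
    groups = [partition.members(i + 1) for i in range(k)]
    idx = {lab: aadist.labels.index(lab) for lab in partition.assignments}
    between = np.full((k, k), math.nan)
    within = np.full(k, math.nan)
    for i, gi in enumerate(groups):
        if len(gi) >= 2:
            ii = [idx[l] for l in gi]
            vals = aadist.d[np.ix_(ii, ii)][np.triu_indices(len(ii), k=1)]
            within[i] = float(np.mean(vals))
        for j in range(i + 1, k):
            gj = groups[j]
            vals = aadist.d[np.ix_([idx[l] for l in gi],
                                   [idx[l] for l in gj])].ravel()
            between[i, j] = between[j, i] = float(np.mean(vals))
        between[i, i] = within[i]
    return between, within
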