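"""Dendrograms, Newick trees and topological (unit-branch) distances.

The morphological tree is an average-linkage (UPGMA) dendrogram built from
the Euclidean morphological distance matrix.  Externally inferred trees
(e.g. maximum-likelihood gene trees) are ingested as Newick.  For
congruence testing on tree shape, the "topological distance" between two
leaves is the cophenetic distance with all branch lengths set to 1 — i.e.
the number of edges on the path connecting them, with the root counted as
an ordinary path vertex.  Allele-level leaf distances collapse to sample
level by averaging over allele pairs, with a homozygote's single allele
implicitly duplicated.

Trees are dendropy ``Tree`` objects throughout.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .matrices import DistanceMatrix

__all__ = [
    "average_linkage_tree",
    "upgma_merge_history",
    "cophenetic_matrix",
    "cluster_labels",
    "topological_distances",
    "collapse_allele_distances",
    "read_newick",
    "write_newick",
]


# ----------------------------------------------------------------------
# UPGMA
# ----------------------------------------------------------------------

def upgma_merge_history(d: DistanceMatrix) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
    """Run unweighted average-linkage agglomeration.

    Returns the merge history as (members_left, members_right, height)
    with height = half the average between-cluster distance at the merge.
    Ties are broken by the lexicographic order of the candidate pair's
    member-label tuples, so the result is deterministic across platforms.
    """
    vals = d.values
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("distance matrix has NaN or negative entries")
    if d.n < 2:
        raise ValueError("need at least 2 labels")
    # cluster id -> (sorted member labels, member indices)
    clusters: dict[int, tuple[tuple[str, ...], list[int]]] = {
        i: ((lab,), [i]) for i, lab in enumerate(d.labels)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(vals[i, j]) for i in range(d.n) for j in range(i + 1, d.n)
    }
    history = []
    next_id = d.n
    while len(clusters) > 1:
        best = None
        for (i, j), dij in dist.items():
            key = (dij, tuple(sorted((clusters[i][0], clusters[j][0]))))
            if best is None or key < best[0]:
                best = (key, (i, j))
        (dij, _), (i, j) = best
        mi, mj = clusters[i], clusters[j]
        left, right = sorted((mi[0], mj[0]))
        history.append((left, right, dij / 2.0))
        merged = (tuple(sorted(mi[0] + mj[0])), mi[1] + mj[1])
        ni, nj = len(mi[1]), len(mj[1])
        del clusters[i], clusters[j]
        new_dist = {}
        for (a, b), dab in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = dab
        for k in clusters:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[(min(k, next_id), max(k, next_id))] = (ni * dik + nj * djk) / (ni + nj)
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return history


def average_linkage_tree(d: DistanceMatrix) -> dendropy.Tree:
    """UPGMA dendrogram as an ultrametric dendropy tree.

    Edge lengths are differences of merge heights, so the path length
    between two leaves equals their cophenetic distance (the average
    between-cluster distance at their merge).
    """
    history = upgma_merge_history(d)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[tuple[str, ...], tuple[dendropy.Node, float]] = {}
    for lab in d.labels:
        leaf = dendropy.Node()
        leaf.taxon = taxa.new_taxon(lab)
        nodes[(lab,)] = (leaf, 0.0)
    root = None
    for left, right, height in history:
        nl, hl = nodes.pop(left)
        nr, hr = nodes.pop(right)
        parent = dendropy.Node()
        parent.add_child(nl)
        parent.add_child(nr)
        nl.edge.length = height - hl
        nr.edge.length = height - hr
        key = tuple(sorted(left + right))
        nodes[key] = (parent, height)
        root = parent
    tree.seed_node = root
    return tree


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances using stored branch lengths."""
    return _pdm(tree, unit_lengths=False)


def cluster_labels(d: DistanceMatrix, k: int) -> dict[str, int]:
    """Cut the UPGMA dendrogram into ``k`` flat clusters.

    Replays the merge history and stops when k clusters remain; returns a
    label -> cluster-index map (indices ordered by first member label).
    """
    if not 1 <= k <= d.n:
        raise ValueError("k out of range")
    members: dict[tuple[str, ...], set[str]] = {(l,): {l} for l in d.labels}
    for left, right, _h in upgma_merge_history(d):
        if len(members) == k:
            break
        ml = members.pop(left)
        mr = members.pop(right)
        members[tuple(sorted(left + right))] = ml | mr
    out: dict[str, int] = {}
    for ci, key in enumerate(sorted(members)):
        for lab in members[key]:
            out[lab] = ci
    return out


# ----------------------------------------------------------------------
# Topological distances
# ----------------------------------------------------------------------

def _pdm(tree: dendropy.Tree, unit_lengths: bool) -> DistanceMatrix:
    t = tree.clone(depth=1)
    labels = []
    for leaf in t.leaf_node_iter():
        lab = leaf.taxon.label if leaf.taxon else None
        if lab is None:
            raise ValueError("tree has an unlabeled leaf")
        labels.append(lab)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    if unit_lengths:
        for edge in t.preorder_edge_iter():
            edge.length = 1.0
    else:
        for edge in t.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
    pdm = t.phylogenetic_distance_matrix()
    labels = sorted(labels)
    n = len(labels)
    taxa = {tx.label: tx for tx in t.taxon_namespace}
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, vals)


def topological_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Edge-count distances between leaves (cophenetic with unit lengths).

    Stored branch lengths are ignored; entry (i, j) is the number of edges
    on the unique path between leaves i and j in the rooted tree (paths
    through the root traverse both of its incident edges).
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    return _pdm(tree, unit_lengths=True)


def collapse_allele_distances(
    d: DistanceMatrix, genotype_map: dict[str, list[str]]
) -> DistanceMatrix:
    """Average allele-level distances down to sample level.

    ``genotype_map`` maps each sample id to its 1 or 2 allele leaf labels.
    The sample-pair entry is the mean over allele pairs; a homozygote's
    single allele carries the weight of two identical alleles (which
    leaves the mean unchanged).  The diagonal is 0.
    """
    allele_owner: dict[str, str] = {}
    for sid, alleles in genotype_map.items():
        for a in alleles:
            allele_owner[a] = sid
    unmapped = [l for l in d.labels if l not in allele_owner]
    if unmapped:
        raise ValueError(f"allele labels not mapped to any sample: {unmapped}")
    samples = sorted(genotype_map)
    idx = {lab: i for i, lab in enumerate(d.labels)}
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ai = [idx[a] for a in genotype_map[samples[i]] if a in idx]
            aj = [idx[a] for a in genotype_map[samples[j]] if a in idx]
            if not ai or not aj:
                raise ValueError(f"no allele leaves present for {samples[i]} or {samples[j]}")
            out[i, j] = out[j, i] = float(np.mean(d.values[np.ix_(ai, aj)]))
    return DistanceMatrix(samples, out)


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

def read_newick(text_or_path: str) -> dendropy.Tree:
    """Parse a Newick tree (string or path); duplicate leaves are rejected."""
    text = text_or_path
    try:
        import os

        if os.path.exists(text_or_path):
            with open(text_or_path) as fh:
                text = fh.read()
    except (TypeError, ValueError):
        pass
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in Newick tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths; round-trips topology and labels."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
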