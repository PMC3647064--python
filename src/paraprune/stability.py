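"""Leaf stability indices over tree sets.

The leaf stability index (LSI) quantifies how consistently a taxon is
placed across a set of trees (typically bootstrap replicates).  The
"maximum" triplet variant is implemented: for a focal taxon t and each
unordered pair {i, j} of taxa co-occurring with it, the three possible
triplet resolutions — (t,i)|j, (t,j)|i, (i,j)|t — are counted across the
trees containing all of t, i and j, and the pair contributes the relative
frequency of the most frequent resolution.  The LSI is the mean of these
maxima over pairs; 1 means the taxon's position is perfectly stable.

Trees lacking any of the three taxa are excluded from that pair's
denominator, as are trees in which the triplet is unresolved (the three
taxa meet at one polytomy — on unrooted trees read with a trifurcating
base this happens for triplets spanning the base); a pair that is never
resolved contributes nothing.  This keeps the index at exactly 1 for a
set of identical trees.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .tree import SupportTree

__all__ = ["leaf_stability", "leaf_stability_table", "triplet_resolution_counts"]


def _mrca_depth_matrix(tree: SupportTree, index: dict[str, int]) -> np.ndarray:
    """Pairwise MRCA depth (root = 0) for the tree's leaves, -1 elsewhere.

    For each internal node v at depth d, every leaf pair split between two
    different children of v has its MRCA at v.  O(n^2) per tree.
    """
    n = len(index)
    M = np.full((n, n), -1, dtype=np.int32)
    dtree = tree.dendropy_tree

    depth: dict[int, int] = {id(dtree.seed_node): 0}
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + 1

    leafsets: dict[int, list[int]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = [index[node.taxon.label]]
            continue
        children = [leafsets.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for x in children[a]:
                    for y in children[b]:
                        M[x, y] = M[y, x] = d
        merged = [x for ch in children for x in ch]
        leafsets[id(node)] = merged
    for t, i in index.items():
        M[i, i] = np.iinfo(np.int32).max
    return M


def triplet_resolution_counts(
    trees: Sequence[SupportTree], t: str, i: str, j: str
) -> tuple[int, int, int, int]:
    """Counts of resolutions ((t,i)|j, (t,j)|i, (i,j)|t) and of usable trees."""
    c_ti = c_tj = c_ij = n_trees = 0
    for tree in trees:
        taxa = tree.taxa
        if not {t, i, j} <= taxa:
            continue
        n_trees += 1
        index = {name: k for k, name in enumerate(sorted(taxa))}
        M = _mrca_depth_matrix(tree, index)
        d_ti = M[index[t], index[i]]
        d_tj = M[index[t], index[j]]
        d_ij = M[index[i], index[j]]
        if d_ti > d_tj and d_ti > d_ij:
            c_ti += 1
        elif d_tj > d_ti and d_tj > d_ij:
            c_tj += 1
        elif d_ij > d_ti and d_ij > d_tj:
            c_ij += 1
        # all equal: polytomy, unresolved
    return c_ti, c_tj, c_ij, n_trees


def leaf_stability(trees: Sequence[SupportTree], taxon: str) -> float:
    """Maximum-variant leaf stability index of ``taxon`` over ``trees``."""
    containing = [tree for tree in trees if taxon in tree.taxa]
    if not containing:
        raise KeyError(f"taxon {taxon!r} absent from all trees")
    others = sorted(set().union(*(t.taxa for t in containing)) - {taxon})
    if len(others) < 2:
        raise ValueError(f"taxon {taxon!r} co-occurs with fewer than 2 other taxa")

    # Cache the depth matrix per tree; reuse across pairs.
    cached = []
    for tree in trees:
        taxa = tree.taxa
        index = {name: k for k, name in enumerate(sorted(taxa))}
        cached.append((taxa, index, _mrca_depth_matrix(tree, index)))

    maxima = []
    for i, j in combinations(others, 2):
        c_ti = c_tj = c_ij = 0
        for taxa, index, M in cached:
            if not {taxon, i, j} <= taxa:
                continue
            d_ti = M[index[taxon], index[i]]
            d_tj = M[index[taxon], index[j]]
            d_ij = M[index[i], index[j]]
            if d_ti > d_tj and d_ti > d_ij:
                c_ti += 1
            elif d_tj > d_ti and d_tj > d_ij:
                c_tj += 1
            elif d_ij > d_ti and d_ij > d_tj:
                c_ij += 1
        n_resolved = c_ti + c_tj + c_ij
        if n_resolved == 0:
            continue
        maxima.append(max(c_ti, c_tj, c_ij) / n_resolved)
    if not maxima:
        raise ValueError(f"no co-occurring taxon pair for {taxon!r}")
    return float(np.mean(maxima))


def leaf_stability_table(
    tree_sets: dict[str, Sequence[SupportTree]],
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """LSI per taxon for each labelled tree set, plus consecutive deltas.

    ``tree_sets`` maps a dataset label (e.g. all-data vs pruned variants)
    to its tree set.  The delta columns expose per-taxon changes between
    consecutive datasets — taxa shifting by more than ~0.05 are the ones
    whose placement the pruning actually affected.
    """
    if taxa is None:
        taxa = sorted(set().union(*(t.taxa for ts in tree_sets.values() for t in ts)))
    data: dict[str, list[float]] = {}
    for label, trees in tree_sets.items():
        col = []
        for taxon in taxa:
            try:
                col.append(leaf_stability(trees, taxon))
            except (KeyError, ValueError):
                col.append(float("nan"))
        data[label] = col
    df = pd.DataFrame(data, index=list(taxa))
    labels = list(tree_sets)
    for a, b in zip(labels, labels[1:]):
        df[f"delta_{b}-{a}"] = df[b] - df[a]
    return df
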