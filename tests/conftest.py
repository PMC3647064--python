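"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from paraprune.substitution_models import SubstitutionModel, lg_model
from paraprune.tree import SupportTree
from paraprune.types import AMINO_ACIDS, PartitionAlignment

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_model(rng: np.random.Generator) -> SubstitutionModel:
    """Random valid reversible amino-acid model (for oracle comparisons)."""
    tri = rng.uniform(0.05, 3.0, size=190)
    freqs = rng.dirichlet(np.ones(20) * 5.0)
    return SubstitutionModel(
        exchangeabilities=tri,
        frequencies=freqs,
        alpha=float(rng.uniform(0.3, 2.0)),
        pinv=float(rng.uniform(0.0, 0.4)),
        n_categories=int(rng.integers(1, 4)),
    )


def random_sequences(rng, taxa, length, gap_prob=0.08) -> dict[str, str]:
    out = {}
    for t in taxa:
        chars = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
        for i in range(length):
            if rng.random() < gap_prob:
                chars[i] = "-"
        out[t] = "".join(chars)
    return out


def exhaustive_site_lnl(tree: SupportTree, aln: PartitionAlignment,
                        model: SubstitutionModel) -> np.ndarray:
    """Per-site lnL by brute-force summation over all internal-node states.

    Independent of the pruning implementation: enumerates every assignment
    of the 20 states to the internal nodes and sums path products, then
    applies the gamma/invariant mixture directly.  Only feasible for trees
    with <= 3 internal nodes.
    """
    dt = tree.dendropy_tree
    internal = [n for n in dt.preorder_node_iter() if not n.is_leaf()]
    assert len(internal) <= 3, "oracle limited to <=3 internal nodes"
    n_sites = aln.length
    out = np.zeros(n_sites)
    pmats: dict[float, np.ndarray] = {}

    def P(t):
        if t not in pmats:
            pmats[t] = model.transition_matrix(t)
        return pmats[t]

    for s in range(n_sites):
        obs = {t: aln.sequences[t][s] for t in tree.taxa}
        residues = {c for c in obs.values() if c in AA_INDEX}
        cat_liks = []
        for rate in model.category_rates:
            total = 0.0
            for states in itertools.product(range(20), repeat=len(internal)):
                smap = dict(zip((id(n) for n in internal), states))
                p = model.frequencies[smap[id(dt.seed_node)]]
                for node in dt.preorder_node_iter():
                    if node.parent_node is None:
                        continue
                    t_edge = (node.edge.length or 0.0) * rate
                    parent_state = smap[id(node.parent_node)]
                    if node.is_leaf():
                        c = obs[node.taxon.label]
                        p *= 1.0 if c not in AA_INDEX else P(t_edge)[parent_state, AA_INDEX[c]]
                    else:
                        p *= P(t_edge)[parent_state, smap[id(node)]]
                total += p
            cat_liks.append(total)
        var = float(np.mean(cat_liks))
        if not residues:
            out[s] = 0.0
        elif len(residues) == 1:
            x = AA_INDEX[next(iter(residues))]
            out[s] = np.log(model.pinv * model.frequencies[x] + (1 - model.pinv) * var)
        else:
            out[s] = np.log((1 - model.pinv) * var)
    return out


def triplet_lsi_oracle(trees, taxon: str) -> float:
    """Leaf stability by explicit triplet enumeration via dendropy MRCAs.

    Independent of the package implementation: resolves each triplet with
    dendropy's own MRCA machinery and node levels.
    """
    containing = [t for t in trees if taxon in t.taxa]
    assert containing
    others = sorted(set().union(*(t.taxa for t in containing)) - {taxon})
    maxima = []
    for i, j in itertools.combinations(others, 2):
        counts = {"ti": 0, "tj": 0, "ij": 0}
        for st in trees:
            if not {taxon, i, j} <= st.taxa:
                continue
            dt = st.dendropy_tree
            dt.is_rooted = True  # resolve triplets against the read rooting
            depth = {}
            for node in dt.preorder_node_iter():
                depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1

            def mrca_depth(a, b):
                node = dt.mrca(taxa=[l.taxon for l in dt.leaf_node_iter()
                                     if l.taxon.label in (a, b)])
                return depth[id(node)]

            d_ti, d_tj, d_ij = mrca_depth(taxon, i), mrca_depth(taxon, j), mrca_depth(i, j)
            if d_ti > max(d_tj, d_ij):
                counts["ti"] += 1
            elif d_tj > max(d_ti, d_ij):
                counts["tj"] += 1
            elif d_ij > max(d_ti, d_tj):
                counts["ij"] += 1
        n_resolved = sum(counts.values())
        if n_resolved:
            maxima.append(max(counts.values()) / n_resolved)
    return float(np.mean(maxima))


def random_support_tree(rng, n_leaves: int, partition_id: str = "p",
                        support_low: int = 0) -> SupportTree:
    """Random binary tree with random supports and branch lengths."""
    import dendropy

    taxa = [f"L{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=ns,
        num_extant_tips=n_leaves, rng=_PyRandom(rng),
    )
    for edge in tree.preorder_edge_iter():
        edge.length = float(rng.uniform(0.01, 1.0))
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.support = int(rng.integers(support_low, 101))
    st = SupportTree(tree, partition_id)
    return st


class _PyRandom:
    """Adapter: numpy Generator -> the random.Random API dendropy expects."""

    def __init__(self, rng):
        self._rng = rng

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(len(seq)))]

    def random(self):
        return float(self._rng.random())

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def expovariate(self, lam):
        return float(self._rng.exponential(1.0 / lam))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma))

    def shuffle(self, x):
        self._rng.shuffle(x)
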