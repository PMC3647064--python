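"""Per-site log-likelihoods and site-wise likelihood differences (ΔpsL).

This module is an *evaluator*: trees, branch lengths and model parameters
(gamma shape, invariant proportion) are inputs, never optimized.  Its
purpose is the ΔpsL diagnostic — the per-site difference in log-likelihood
between two topological hypotheses, aggregated per partition through the
supermatrix chart — which localizes the support for a clade to particular
genes.  A clade whose support is concentrated in one partition, rather
than spread along the alignment, is a candidate artifact of that
partition (e.g. misassigned paralogs).

Likelihoods use Felsenstein's pruning algorithm, vectorized over sites,
under a reversible amino-acid model with K discrete-gamma rate categories
and a proportion of invariant sites::

    L_site = pinv * pi_x * [site constant with residue x]
             + (1 - pinv) * (1/K) * sum_k L_pruning(rate_k)

Gaps and ``X`` are uninformative (partial-likelihood vector of ones); a
site with no data at all has likelihood 1 (lnL = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .substitution_models import SubstitutionModel
from .tree import SupportTree
from .types import AMINO_ACIDS, MISSING_CHARS, PartitionAlignment, SupermatrixSpec

__all__ = ["SiteLikelihoodVector", "site_log_likelihoods", "delta_psl", "DeltaPsl"]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_SCALE_EVERY = 8  # rescale partials every few levels to avoid underflow


@dataclass
class SiteLikelihoodVector:
    """Per-site natural-log likelihoods aligned to alignment columns."""

    lnl: np.ndarray
    partition_id: str = ""

    @property
    def total(self) -> float:
        return float(self.lnl.sum())


def _encode(alignment: PartitionAlignment) -> dict[str, np.ndarray]:
    """Taxon -> per-site partial-likelihood leaf matrices (sites x 20)."""
    out = {}
    for taxon, seq in alignment.sequences.items():
        M = np.zeros((alignment.length, 20))
        for s, c in enumerate(seq.upper()):
            if c in MISSING_CHARS:
                M[s, :] = 1.0
            else:
                idx = _AA_INDEX.get(c)
                if idx is None:
                    M[s, :] = 1.0  # unknown symbol treated as missing
                else:
                    M[s, idx] = 1.0
        out[taxon] = M
    return out


def _prune_log(tree: SupportTree, leaves: dict[str, np.ndarray],
               model: SubstitutionModel, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """(scaled site likelihoods, per-site log scale factors) for one rate."""
    n_sites = next(iter(leaves.values())).shape[0]
    log_scale = np.zeros(n_sites)
    partials: dict[int, np.ndarray] = {}
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            partials[id(node)] = leaves[node.taxon.label]
            continue
        prod = np.ones((n_sites, 20))
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * rate
            P = model.transition_matrix(t)
            prod *= partials.pop(id(child)) @ P.T
        m = prod.max(axis=1)
        nz = m > 0
        div = np.where(nz, m, 1.0)
        partials[id(node)] = prod / div[:, None]
        log_scale += np.log(div)
    root = partials[id(dtree.seed_node)]
    return root @ model.frequencies, log_scale


def site_log_likelihoods(
    tree: SupportTree,
    alignment: PartitionAlignment,
    model: SubstitutionModel,
) -> SiteLikelihoodVector:
    """ln L per alignment column for fixed tree, branch lengths and model."""
    missing = tree.taxa - set(alignment.sequences)
    if missing:
        raise KeyError(
            f"taxa in tree but not alignment: {sorted(missing)}"
        )
    leaves = _encode(alignment)
    leaves = {t: leaves[t] for t in tree.taxa}
    n_sites = alignment.length

    # variable part: mean over gamma categories, accumulated in log space
    cat_lnl = []
    for rate in model.category_rates:
        lik, log_scale = _prune_log(tree, leaves, model, float(rate))
        with np.errstate(divide="ignore"):
            cat_lnl.append(np.log(lik) + log_scale)
    cat_lnl = np.vstack(cat_lnl)
    K = cat_lnl.shape[0]
    mmax = cat_lnl.max(axis=0)
    finite = np.isfinite(mmax)
    var_lnl = np.where(
        finite,
        np.where(finite, mmax, 0.0)
        + np.log(np.exp(cat_lnl - np.where(finite, mmax, 0.0)).sum(axis=0) / K),
        -np.inf,
    )

    # invariant part: constant sites (all non-missing residues identical)
    const_state = np.full(n_sites, -1, dtype=int)  # -1: not constant; -2: no data
    seqs = [alignment.sequences[t].upper() for t in tree.taxa]
    for s in range(n_sites):
        residues = {seq[s] for seq in seqs} - set(MISSING_CHARS)
        residues = {r for r in residues if r in _AA_INDEX}
        if not residues:
            const_state[s] = -2
        elif len(residues) == 1:
            const_state[s] = _AA_INDEX[next(iter(residues))]

    pinv = model.pinv
    lnl = np.empty(n_sites)
    for s in range(n_sites):
        if const_state[s] == -2:
            lnl[s] = 0.0  # no data: L = 1
        elif const_state[s] >= 0:
            var = np.exp(var_lnl[s]) if np.isfinite(var_lnl[s]) else 0.0
            lnl[s] = np.log(
                pinv * model.frequencies[const_state[s]] + (1 - pinv) * var
            )
        else:
            lnl[s] = np.log1p(-pinv) + var_lnl[s]
    return SiteLikelihoodVector(lnl=lnl, partition_id=alignment.partition_id)


@dataclass
class DeltaPsl:
    """Per-site ΔpsL = lnL(H1) - lnL(H2) with per-partition aggregation."""

    delta: np.ndarray
    lnl1: np.ndarray
    lnl2: np.ndarray
    partition_sums: dict[str, float]
    boundaries: list[tuple[str, int, int]]

    @property
    def total(self) -> float:
        return float(self.delta.sum())

    def top_partition(self) -> str:
        """Partition whose summed ΔpsL is largest (strongest H1 support)."""
        return max(self.partition_sums, key=lambda p: self.partition_sums[p])


def delta_psl(
    tree_h1: SupportTree,
    tree_h2: SupportTree,
    alignment: PartitionAlignment,
    model: SubstitutionModel,
    chart: list[tuple[str, int, int]] | None = None,
) -> DeltaPsl:
    """Site-wise log-likelihood difference between two hypotheses.

    Both trees must cover the same taxa.  ``chart`` (0-based half-open
    segments) attributes sites to partitions for the per-partition sums;
    without it the whole alignment is one segment.
    """
    if tree_h1.taxa != tree_h2.taxa:
        only1 = sorted(tree_h1.taxa - tree_h2.taxa)
        only2 = sorted(tree_h2.taxa - tree_h1.taxa)
        raise ValueError(
            f"leaf sets differ: only in H1 {only1}; only in H2 {only2}"
        )
    v1 = site_log_likelihoods(tree_h1, alignment, model)
    v2 = site_log_likelihoods(tree_h2, alignment, model)
    delta = v1.lnl - v2.lnl
    if chart is None:
        chart = [(alignment.partition_id or "all", 0, alignment.length)]
    sums = {pid: float(delta[start:end].sum()) for pid, start, end in chart}
    return DeltaPsl(
        delta=delta, lnl1=v1.lnl, lnl2=v2.lnl,
        partition_sums=sums, boundaries=list(chart),
    )


def plot_delta_psl(result: DeltaPsl, path, highlight: set[str] | None = None) -> None:
    """Bar plot of per-site ΔpsL with partition boundaries marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    highlight = highlight or set()
    fig, ax = plt.subplots(figsize=(10, 3.5))
    sites = np.arange(len(result.delta))
    ax.bar(sites, result.delta, width=1.0, color="0.3")
    for pid, start, end in result.boundaries:
        if pid in highlight:
            ax.axvspan(start, end, color="0.85", zorder=0)
        ax.axvline(end, color="0.6", lw=0.5)
        ax.text((start + end) / 2, ax.get_ylim()[1] * 0.9, pid,
                ha="center", fontsize=6)
    ax.set_xlabel("alignment site")
    ax.set_ylabel(r"$\Delta$psL")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
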