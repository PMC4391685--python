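"""Neighbor-joining tree construction and bootstrap support.

The NJ implementation follows Saitou & Nei's agglomeration with the
Studier-Keppler Q-criterion; it is exact on additive distance matrices
(the output tree's path lengths reproduce the input).  Bootstrap support
resamples alignment columns with replacement, recomputes distances and an
NJ tree per replicate, and annotates each internal edge of the
original-data tree with the percentage of replicates containing the same
leaf bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceModel, compute_distances
from .errors import TreeError
from .io_formats import Alignment, DistanceMatrix, bipartitions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: number of column-resampling replicates and seed."""

    replicates: int = 1000
    seed: int = 0
    support_rule: str = "proportion-on-original-topology"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _clamp_pair(li: float, lj: float):
    """Zero out a negative NJ branch, moving the deficit to its sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(
    D: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Build an unrooted NJ tree over the labels of ``D``.

    Ties in the Q-criterion break on the lowest (i, j) pair in current
    label order, so the result is deterministic.  For n >= 3 the returned
    tree has a trifurcating seed node (unrooted convention); for n = 2 the
    single edge is split evenly between the two leaves.
    """
    n = D.n
    if n < 2:
        raise TreeError("neighbor joining needs at least 2 taxa")
    if np.any(~np.isfinite(D.values)):
        raise TreeError("distance matrix contains non-finite entries")
    tns = taxon_namespace or dendropy.TaxonNamespace()
    nodes = []
    for lab in D.labels:
        taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    d = D.values.astype(float).copy()
    active = list(range(n))

    if n == 2:
        half = d[0, 1] / 2.0
        root = dendropy.Node()
        for node in nodes:
            root.add_child(node)
            node.edge.length = half
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = False
        return tree

    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    node_of = dict(enumerate(nodes))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for a in range(r):
            i = active[a]
            for b in range(a + 1, r):
                j = active[b]
                q = (r - 2) * dist[i, j] - R[i] - R[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        li = dist[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dist[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(node_of[i])
        node_of[i].edge.length = li
        parent.add_child(node_of[j])
        node_of[j].edge.length = lj
        u = next_id
        next_id += 1
        node_of[u] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
            dist[u, k] = dist[k, u] = duk
        dist[u, u] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    root = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(node_of[idx])
        node_of[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree, as a DistanceMatrix."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted((lf.taxon for lf in tree.leaf_node_iter()), key=lambda t: t.label)
    labels = tuple(t.label for t in leaves)
    n = len(labels)
    vals = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            vals[a, b] = vals[b, a] = pdm.patristic_distance(leaves[a], leaves[b])
    return DistanceMatrix(labels, vals)


def bootstrap_support(
    aln: Alignment, model: DistanceModel, cfg: BootstrapConfig
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports on internal nodes.

    Replicate r draws its column sample from an independent stream seeded by
    (cfg.seed, r), so supports are reproducible and independent of execution
    order.  Replicates in which some pair loses all comparable sites are
    skipped with a warning; more than 10% skipped is an error.
    """
    from .errors import DistanceError

    D = compute_distances(aln, model)
    tree = neighbor_joining(D)
    original = {
        split: node
        for split, node in _splits_to_nodes(tree).items()
    }
    counts = {split: 0 for split in original}
    used = skipped = 0
    for r in range(cfg.replicates):
        rng = np.random.default_rng([cfg.seed, r])
        cols = rng.integers(0, aln.length, size=aln.length)
        repl = aln.take_columns(cols)
        try:
            Dr = compute_distances(repl, model)
        except DistanceError as exc:
            logger.warning("bootstrap replicate %d skipped: %s", r, exc)
            skipped += 1
            continue
        repl_splits = bipartitions(neighbor_joining(Dr, tree.taxon_namespace))
        for split in counts:
            if split in repl_splits:
                counts[split] += 1
        used += 1
    if skipped > 0.10 * cfg.replicates:
        raise TreeError(
            f"{skipped}/{cfg.replicates} bootstrap replicates skipped (>10%)"
        )
    for split, node in original.items():
        node.support = 100.0 * counts[split] / used
        node.label = f"{node.support:.0f}"
    return tree


def _splits_to_nodes(tree: dendropy.Tree) -> dict:
    """Map each non-trivial bipartition to the internal node that induces it."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    first = min(all_leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = clade if first not in clade else all_leaves - clade
        if 1 < len(side) < len(all_leaves) - 1:
            out[side] = node
    return out
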