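"""Cohesin phylogeny: p-distances, neighbor joining, Newick output.

Distances are 1 - fractional identity from global pairwise alignment; trees
are built with the canonical neighbor-joining algorithm (Q-criterion), with
deterministic lexicographic tie-breaking and clamping of negative branch
lengths.  The tree's role here is type clustering of cohesins, not
publication phylogenetics: no substitution-model correction, no bootstrap.
"""
from __future__ import annotations

import io

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .dockerin import TypeCall, classify_type
from .pairwise import global_identity


def pairwise_distances(named_seqs: list[tuple[str, str]]) -> DistanceMatrix:
    """Symmetric p-distance matrix (1 - identity fraction) over labelled sequences."""
    labels = [name for name, _ in named_seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, length = global_identity(named_seqs[i][1], named_seqs[j][1])
            d[i, j] = d[j, i] = 1.0 - ident / length
    return DistanceMatrix(d, labels)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree of *dm*.

    Standard Q-matrix minimization; ties broken by the lexicographically
    smallest (label, label) pair, where an internal node inherits the smallest
    leaf label of its subtree.  Negative branch lengths are clamped to zero
    with the deficit moved to the sibling branch so the pair distance is kept.
    For n >= 4 the result is an unrooted binary tree serialized with a
    trifurcating root.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    d = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[(a, b)] = float(dm[i, j])
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    # sort key of an active node = smallest original label in its subtree
    keys: dict[str, str] = {lab: lab for lab in labels}
    active = list(labels)
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                pair_key = tuple(sorted((keys[a], keys[b])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or pair_key < best[1])):
                    best_q = q
                    best = ((a, b), pair_key)
        (a, b), _ = best
        la = d[(a, b)] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[(a, b)] - la
        la, lb = _clamp_pair(la, lb)
        u = f"__internal_{counter}"
        counter += 1
        node = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = la
        nodes[b].length = lb
        nodes[u] = node
        keys[u] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            duc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
            d[(u, c)] = d[(c, u)] = max(0.0, duc)
        d[(u, u)] = 0.0
        active = [c for c in active if c not in (a, b)] + [u]
    # terminal three-point formulas
    x, y, z = sorted(active, key=lambda c: keys[c])
    lx = (d[(x, y)] + d[(x, z)] - d[(y, z)]) / 2
    ly = (d[(x, y)] + d[(y, z)] - d[(x, z)]) / 2
    lz = (d[(x, z)] + d[(y, z)] - d[(x, y)]) / 2
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    nodes[x].length = max(0.0, lx)
    nodes[y].length = max(0.0, ly)
    nodes[z].length = max(0.0, lz)
    return root


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue()


def from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text))


def assign_cohesin_type(cohesin: str, type1_refs: list[str],
                        type2_refs: list[str], min_margin: float = 5.0) -> TypeCall:
    """Type a cohesin by nearest-reference identity (same contract as the
    dockerin classifier, applied to cohesin reference sets)."""
    return classify_type(cohesin, type1_refs, type2_refs, min_margin)
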