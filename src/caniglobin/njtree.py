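"""Saitou–Nei neighbor joining with deterministic tie-breaking, plus
nonparametric (column-resampling) bootstrap support.

The tree is unrooted; internally it is stored rooted at the last join for
traversal. Bipartitions are normalised to the side *not* containing the
lexicographically smallest taxon, so splits compare across replicates.
Negative NJ branch lengths are clamped to zero with the deficit moved to
the sibling edge (total path length through the join preserved), and joins
tied on the Q criterion pick the lowest-index pair, so output is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import distance_matrix, tn93_distance


@dataclass
class Node:
    name: str | None = None  # leaf name; None for internal nodes
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


class Tree:
    """An unrooted phylogeny stored as a trifurcating (or star) root."""

    def __init__(self, root: Node, taxa: list[str]):
        self.root = root
        self.taxa = sorted(taxa)
        self._ref = self.taxa[0]
        self.support: dict[frozenset, float] = {}

    # -- splits -------------------------------------------------------------
    def _normalize(self, side: frozenset) -> frozenset:
        if self._ref in side:
            return frozenset(self.taxa) - side
        return side

    def edges(self) -> dict[frozenset, float]:
        """All edges as {normalised leaf-set below the edge: branch length}.

        Parallel edges around the root (in a 2-taxon tree) are summed.
        """
        out: dict[frozenset, float] = {}

        def walk(node: Node):
            for child, length in node.children:
                split = self._normalize(frozenset(child.leaves()))
                out[split] = out.get(split, 0.0) + length
                walk(child)

        walk(self.root)
        return out

    def bipartitions(self, *, tol: float = 1e-12) -> set[frozenset]:
        """Non-trivial splits (both sides >= 2 taxa) on edges of positive
        length. Zero-length internal edges are collapsed: an alignment of
        identical sequences therefore yields a star tree with no splits.
        """
        n = len(self.taxa)
        return {
            s
            for s, length in self.edges().items()
            if 2 <= len(s) <= n - 2 and length > tol
        }

    # -- newick -------------------------------------------------------------
    def newick(self, *, include_support: bool = False) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                body = f"({inner})"
                if include_support and length is not None:
                    split = self._normalize(frozenset(node.leaves()))
                    if split in self.support:
                        body += f"{self.support[split]:.0f}"
            if length is None:
                return body
            return f"{body}:{length:.6f}"

        inner = ",".join(fmt(c, l) for c, l in self.root.children)
        return f"({inner});"


def nj_tree(dm: np.ndarray, labels: list[str]) -> Tree:
    """Neighbor joining (Saitou & Nei 1987) on a symmetric distance matrix.

    Ties in the Q criterion join the pair with the lowest (insertion-order)
    indices. For three taxa the closed form v_i = (d_ij + d_ik - d_jk)/2 is
    used directly. Negative branch lengths are clamped to zero with the
    deficit moved to the sibling edge.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if n != dm.shape[1] or n != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.isnan(dm).any():
        raise ValueError("distance matrix contains undefined entries")

    nodes: list[Node] = [Node(name=l) for l in labels]
    active = list(range(n))
    d = dm.copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        # lowest-index tie-break: scan in (i, j) lexicographic order
        best, best_q = None, np.inf
        for a in range(m):
            for b in range(a + 1, m):
                if qmat[a, b] < best_q - 1e-12:
                    best_q = qmat[a, b]
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(parent)
        k = len(nodes) - 1
        # grow the matrix with the new node's distances
        new_row = np.zeros(k + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            d[k, c] = d[c, k] = 0.5 * (d[i, c] + d[j, c] - dij)
        active = [c for c in active if c not in (i, j)] + [k]

    i, j, k = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node(
        children=[
            (nodes[i], max(vi, 0.0)),
            (nodes[j], max(vj, 0.0)),
            (nodes[k], max(vk, 0.0)),
        ]
    )
    return Tree(root, labels)


def nj_from_alignment(names: list[str], seqs: list[str], metric=tn93_distance) -> Tree:
    return nj_tree(distance_matrix(seqs, names, metric), names)


def bootstrap_support(
    names: list[str],
    seqs: list[str],
    *,
    b: int = 500,
    seed: int = 0,
    metric=tn93_distance,
) -> Tree:
    """NJ tree with bootstrap support on internal edges.

    Columns are resampled with replacement ``b`` times; support is the
    percentage of replicates whose NJ tree contains each original
    bipartition. Replicates whose distances saturate are discarded from the
    denominator. The conventional display floor for support values is 60.
    """
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must be aligned (equal length)")
    if length == 0:
        raise ValueError("alignment has no columns")
    tree = nj_from_alignment(names, seqs, metric)
    targets = tree.bipartitions()
    counts = {split: 0 for split in targets}
    rng = np.random.default_rng(seed)
    mat = np.array([list(s) for s in seqs], dtype="U1")
    valid = 0
    for _ in range(b):
        cols = rng.integers(0, length, size=length)
        rep_seqs = ["".join(row) for row in mat[:, cols]]
        try:
            rep = nj_from_alignment(names, rep_seqs, metric)
        except ValueError:
            continue
        valid += 1
        rep_splits = rep.bipartitions()
        for split in targets:
            if split in rep_splits:
                counts[split] += 1
    if valid == 0:
        raise ValueError("all bootstrap replicates had undefined distances")
    tree.support = {s: 100.0 * c / valid for s, c in counts.items()}
    return tree
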