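"""Binary cell-population trees by recursive spectral bipartition.

The tree is grown from the root (all cells) by repeatedly splitting each
node's cells in two along the sign of the second left singular vector of
the row-normalized expression submatrix (LSA-style spectral bipartition).
A split is kept only if its Newman-Girvan modularity Q, evaluated on a
truncated-cosine similarity graph over the node's cells, exceeds a
threshold (strictly Q > 0 by default): once no split beats what random
assignment would achieve, the node is a leaf. The accepted Q is stored as
the node's "distance", which later drives distance-based pruning and
branch-length scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

from .matrix_io import CountMatrix, Normalization, StateError

__all__ = [
    "ClusterNode",
    "ClusterTree",
    "SimilarityGraph",
    "DegenerateSplitError",
    "cosine_similarity_graph",
    "newman_girvan_modularity",
    "spectral_bipartition",
    "build_tree",
]

#: relative second-singular-value tolerance below which a submatrix is
#: considered rank-1 (all rows effectively identical -> nothing to split)
_RANK_TOL = 1e-8


class DegenerateSplitError(ValueError):
    """The split vector carries no usable signal (rank-1 submatrix)."""


@dataclass
class ClusterNode:
    """One population in the tree.

    ``distance`` is the modularity of the split that created this node's
    children; it is 0.0 at leaves. ``cells`` is non-empty only at leaves;
    an internal node's population is the disjoint union of its leaves'.
    """

    node_id: int
    distance: float = 0.0
    children: list["ClusterNode"] = field(default_factory=list)
    cells: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_cells(self) -> list[str]:
        """All barcodes under this node, leaf order."""
        if self.is_leaf:
            return list(self.cells)
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_cells())
        return out

    def n_cells(self) -> int:
        if self.is_leaf:
            return len(self.cells)
        return sum(c.n_cells() for c in self.children)


class TreeValidationError(ValueError):
    pass


class ClusterTree:
    """A validated binary tree of nested cell populations."""

    def __init__(self, root: ClusterNode):
        self.root = root
        self.id_index: dict[int, ClusterNode] = {}
        self._parent: dict[int, int | None] = {}
        self._validate()

    def _validate(self) -> None:
        seen_barcodes: set[str] = set()
        stack: list[tuple[ClusterNode, int | None]] = [(self.root, None)]
        while stack:
            node, parent_id = stack.pop()
            if node.node_id in self.id_index:
                raise TreeValidationError(f"duplicate node_id {node.node_id}")
            if len(node.children) not in (0, 2):
                raise TreeValidationError(
                    f"node {node.node_id} has {len(node.children)} children; "
                    "expected 0 or 2"
                )
            if node.distance < 0:
                raise TreeValidationError(f"node {node.node_id} has negative distance")
            if node.is_leaf:
                if not node.cells:
                    raise TreeValidationError(f"leaf {node.node_id} owns no cells")
                dup = seen_barcodes.intersection(node.cells)
                if dup or len(set(node.cells)) != len(node.cells):
                    bad = sorted(dup or {"(within-leaf duplicate)"})[0]
                    raise TreeValidationError(
                        f"barcode {bad!r} appears in more than one leaf "
                        f"(node {node.node_id})"
                    )
                seen_barcodes.update(node.cells)
            self.id_index[node.node_id] = node
            self._parent[node.node_id] = parent_id
            for child in node.children:
                stack.append((child, node.node_id))

    # -- queries -------------------------------------------------------

    def node(self, node_id: int) -> ClusterNode:
        try:
            return self.id_index[node_id]
        except KeyError:
            raise KeyError(f"no node with id {node_id}") from None

    def parent_id(self, node_id: int) -> int | None:
        self.node(node_id)
        return self._parent[node_id]

    def depth(self, node_id: int) -> int:
        d = 0
        p = self.parent_id(node_id)
        while p is not None:
            d += 1
            p = self.parent_id(p)
        return d

    def nodes(self) -> Iterator[ClusterNode]:
        """Breadth-first traversal from the root."""
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            yield node
            queue.extend(node.children)

    def leaves(self) -> list[ClusterNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def n_nodes(self) -> int:
        return len(self.id_index)

    def barcodes(self) -> list[str]:
        return self.root.leaf_cells()

    def node_cells(self, node_id: int) -> list[str]:
        return self.node(node_id).leaf_cells()


def renumber_bfs(root: ClusterNode) -> ClusterNode:
    """Assign integer ids breadth-first from root = 0 (in place)."""
    queue = [root]
    next_id = 0
    while queue:
        node = queue.pop(0)
        node.node_id = next_id
        next_id += 1
        queue.extend(node.children)
    return root


# -- similarity graph ---------------------------------------------------


@dataclass
class SimilarityGraph:
    """Symmetric non-negative weighted graph over a set of cells."""

    weights: np.ndarray
    barcodes: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def total_weight(self) -> float:
        """2m: the sum over all ordered pairs."""
        return float(self.weights.sum())


def _l2_normalize_rows(x: sp.csr_matrix) -> tuple[sp.csr_matrix, np.ndarray]:
    norms = np.sqrt(np.asarray(x.multiply(x).sum(axis=1)).ravel())
    return x, norms


def cosine_similarity_graph(m: CountMatrix, cell_subset: Sequence[str] | None = None) -> SimilarityGraph:
    """Truncated-cosine similarity graph over a subset of cells.

    w(i, j) = max(0, cosine(row_i, row_j)) for i != j; the diagonal is 0.
    Negative cosines (possible for centred/transformed inputs) are clipped
    so weights stay non-negative, as modularity requires.
    """
    subset = list(cell_subset) if cell_subset is not None else list(m.barcodes)
    if not subset:
        raise ValueError("empty cell subset")
    sub = m.subset_cells(subset)
    x = sub.counts.astype(float)
    _, norms = _l2_normalize_rows(x)
    if (norms == 0).any():
        bad = sub.barcodes[int(np.argmax(norms == 0))]
        raise ValueError(f"cell {bad!r} has zero-norm expression row")
    xn = sp.diags(1.0 / norms) @ x
    w = np.asarray((xn @ xn.T).todense())
    np.clip(w, 0.0, None, out=w)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # exact symmetry against fp round-off
    return SimilarityGraph(w, subset)


def newman_girvan_modularity(g: SimilarityGraph,
                             partition: Mapping[str, int] | Sequence[int]) -> float:
    """Newman-Girvan modularity Q = sum_i (e_ii - a_i^2) of a partition.

    e_ii is the fraction of total edge weight falling inside community i
    and a_i the fraction of edge ends attached to it. Q is 0 for the
    single-community partition and positive when communities capture more
    weight than a random degree-preserving rewiring would.
    """
    n = len(g.barcodes)
    if isinstance(partition, Mapping):
        comm = np.array([partition[b] for b in g.barcodes])
    else:
        comm = np.asarray(list(partition))
        if comm.shape != (n,):
            raise ValueError("partition must cover all graph vertices")
    total = g.total_weight
    if total == 0:
        warnings.warn("empty graph: modularity undefined, returning 0")
        return 0.0
    q = 0.0
    for c in np.unique(comm):
        idx = comm == c
        e_ii = g.weights[np.ix_(idx, idx)].sum() / total
        a_i = g.weights[idx, :].sum() / total
        q += e_ii - a_i * a_i
    return float(q)


def _second_left_singular_vector(x: sp.csr_matrix) -> np.ndarray:
    """Second left singular vector of x; raises on effectively rank-1 input.

    Dense LAPACK SVD below a size threshold (bit-reproducible), Lanczos
    with a fixed start vector above it. Sign convention: the component of
    largest magnitude is made positive.
    """
    n, p = x.shape
    if min(n, p) < 2:
        raise DegenerateSplitError("submatrix has no second singular direction")
    if min(n, p) <= 512:
        u, s, _ = np.linalg.svd(np.asarray(x.todense()), full_matrices=False)
        s1, s2 = s[0], s[1]
        u2 = u[:, 1]
    else:
        v0 = np.full(min(n, p), 1.0 / np.sqrt(min(n, p)))
        u, s, _ = scipy.sparse.linalg.svds(x.astype(float), k=2, v0=v0)
        order = np.argsort(s)[::-1]
        s1, s2 = s[order[0]], s[order[1]]
        u2 = u[:, order[1]]
    if s1 == 0 or s2 / s1 < _RANK_TOL:
        raise DegenerateSplitError("second singular value vanishes (rank-1 rows)")
    pivot = int(np.argmax(np.abs(u2)))
    if u2[pivot] < 0:
        u2 = -u2
    return u2


def spectral_bipartition(m: CountMatrix, cell_subset: Sequence[str] | None = None) -> tuple[list[str], list[str]]:
    """Split cells by the sign of the second left singular vector.

    The submatrix over ``cell_subset`` is row-l2-normalized and its second
    left singular vector computed; non-negative components go to side A,
    negative to side B (zeros to A as the deterministic tie-break).
    Raises :class:`DegenerateSplitError` when the rows are effectively
    identical, which callers treat as "do not split".
    """
    subset = list(cell_subset) if cell_subset is not None else list(m.barcodes)
    if len(subset) < 2:
        raise ValueError("need at least 2 cells to bipartition")
    sub = m.subset_cells(subset)
    x = sub.counts.astype(float)
    _, norms = _l2_normalize_rows(x)
    if (norms == 0).any():
        bad = sub.barcodes[int(np.argmax(norms == 0))]
        raise ValueError(f"cell {bad!r} has zero-norm expression row")
    xn = sp.csr_matrix(sp.diags(1.0 / norms) @ x)
    u2 = _second_left_singular_vector(xn)
    side_a = [b for b, v in zip(subset, u2) if v >= 0]
    side_b = [b for b, v in zip(subset, u2) if v < 0]
    if not side_a or not side_b:
        # tied singular subspaces can yield a one-signed basis vector;
        # fall back to splitting at the mean, which is deterministic and
        # reduces to the sign rule for a centred vector
        spread = np.ptp(u2)
        if spread < _RANK_TOL:
            raise DegenerateSplitError("split vector is constant")
        mid = float(np.mean(u2))
        side_a = [b for b, v in zip(subset, u2) if v >= mid]
        side_b = [b for b, v in zip(subset, u2) if v < mid]
        if not side_a or not side_b:
            raise DegenerateSplitError("split vector cannot be bisected")
    return side_a, side_b


def build_tree(m: CountMatrix, min_modularity: float = 0.0,
               min_split_size: int = 2, max_depth: int | None = None) -> ClusterTree:
    """Recursively bipartition cells into a binary population tree.

    At each node the spectral split of the node's cells is proposed and
    kept iff its modularity on the node-local cosine graph strictly
    exceeds ``min_modularity`` — otherwise the split is indistinguishable
    from random and the node becomes a leaf (distance 0). Accepted nodes
    store Q as their split distance. Node ids are breadth-first from 0.

    Expects a TF-IDF-normalized, filtered matrix.
    """
    if m.n_cells == 0:
        raise ValueError("empty matrix")
    if m.normalized is not Normalization.TFIDF:
        raise StateError("build_tree expects a TF-IDF-normalized matrix")

    def grow(cells: list[str], depth: int) -> ClusterNode:
        node = ClusterNode(node_id=-1)
        splittable = (
            len(cells) >= max(2, min_split_size)
            and (max_depth is None or depth < max_depth)
        )
        if splittable:
            try:
                side_a, side_b = spectral_bipartition(m, cells)
            except DegenerateSplitError:
                splittable = False
        if splittable:
            graph = cosine_similarity_graph(m, cells)
            labels = {b: 0 for b in side_a} | {b: 1 for b in side_b}
            q = newman_girvan_modularity(graph, labels)
            if q > min_modularity:
                node.distance = q
                node.children = [grow(side_a, depth + 1), grow(side_b, depth + 1)]
                return node
        node.cells = list(cells)
        return node

    root = grow(list(m.barcodes), 0)
    renumber_bfs(root)
    return ClusterTree(root)
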