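"""Structural tree editing: collapse by size, distance or depth; re-root.

All operations are pure — they return a new tree and leave the input
untouched — and are recorded as :class:`PruneStep` entries so a whole
editing session (the "breadcrumb" trail) can be replayed or partially
undone by replaying a prefix of the history.

Collapsing a node merges every descendant barcode into it and turns it
into a leaf with distance 0; node ids of surviving nodes are preserved so
overlays and statistics computed before pruning still cross-reference.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .cluster_tree import ClusterNode, ClusterTree

__all__ = [
    "PruneKind", "PruneStep", "PruneHistory",
    "prune_min_cells", "prune_min_distance", "prune_depth", "set_root",
    "apply_history", "distance_distribution",
]


class PruneKind(str, Enum):
    MIN_CELLS = "min_cells"
    MIN_DISTANCE_SEARCH = "min_distance_search"
    DEPTH = "depth"
    SET_ROOT = "set_root"


@dataclass
class PruneStep:
    kind: PruneKind
    value: float | int

    def __post_init__(self) -> None:
        self.kind = PruneKind(self.kind)
        if self.kind in (PruneKind.MIN_CELLS, PruneKind.DEPTH, PruneKind.SET_ROOT):
            self.value = int(self.value)
        if self.kind is PruneKind.MIN_CELLS and self.value < 1:
            raise ValueError("min_cells threshold must be >= 1")
        if self.kind is PruneKind.MIN_DISTANCE_SEARCH and self.value < 0:
            raise ValueError("distance cutoff must be >= 0")
        if self.kind is PruneKind.DEPTH and self.value < 0:
            raise ValueError("depth must be >= 0")

    def to_obj(self) -> dict:
        return {"kind": self.kind.value, "value": self.value}

    @classmethod
    def from_obj(cls, obj: dict) -> "PruneStep":
        return cls(kind=obj["kind"], value=obj["value"])


@dataclass
class PruneHistory:
    steps: list[PruneStep] = field(default_factory=list)

    def to_obj(self) -> list[dict]:
        return [s.to_obj() for s in self.steps]

    @classmethod
    def from_obj(cls, obj: Iterable[dict]) -> "PruneHistory":
        return cls([PruneStep.from_obj(o) for o in obj])


def _collapse(node: ClusterNode) -> None:
    """Turn node into a leaf owning all descendant cells (in place)."""
    if not node.is_leaf:
        node.cells = node.leaf_cells()
        node.children = []
        node.distance = 0.0


def prune_min_cells(t: ClusterTree, n: int) -> ClusterTree:
    """Collapse children into the parent wherever either child is small.

    Bottom-up: whenever either child of a node holds fewer than ``n``
    cells, both children are merged into the parent. A binary tree cannot
    drop a single child, so the whole split is undone; afterwards every
    node except possibly the root holds at least ``n`` cells. Cell
    content is conserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = copy.deepcopy(t.root)

    def walk(node: ClusterNode) -> None:
        if node.is_leaf:
            return
        for child in node.children:
            walk(child)
        if any(child.n_cells() < n for child in node.children):
            _collapse(node)

    walk(root)
    return ClusterTree(root)


def prune_min_distance(t: ClusterTree, cutoff: float) -> ClusterTree:
    """Collapse every subtree whose split distance falls below ``cutoff``.

    Top-down search from the root: an internal node with
    ``distance < cutoff`` (strict) has its entire subtree merged into it;
    descendants of collapsed nodes are not visited. A cutoff of 0 is the
    identity since distances are non-negative.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    root = copy.deepcopy(t.root)

    def walk(node: ClusterNode) -> None:
        if node.is_leaf:
            return
        if node.distance < cutoff:
            _collapse(node)
            return
        for child in node.children:
            walk(child)

    walk(root)
    return ClusterTree(root)


def prune_depth(t: ClusterTree, d: int) -> ClusterTree:
    """Truncate the tree at depth ``d``: nodes there become leaves."""
    if d < 0:
        raise ValueError("depth must be >= 0")
    root = copy.deepcopy(t.root)

    def walk(node: ClusterNode, depth: int) -> None:
        if depth >= d:
            _collapse(node)
            return
        for child in node.children:
            walk(child, depth + 1)

    walk(root, 0)
    return ClusterTree(root)


def set_root(t: ClusterTree, node_id: int) -> ClusterTree:
    """Extract the subtree rooted at ``node_id`` as a standalone tree.

    Node ids and distances are preserved; cells outside the subtree are
    dropped.
    """
    node = t.node(node_id)  # raises KeyError for unknown ids
    return ClusterTree(copy.deepcopy(node))


def apply_history(t: ClusterTree, h: PruneHistory) -> ClusterTree:
    """Replay an ordered list of edits; a prefix replay implements undo."""
    out = t
    for i, step in enumerate(h.steps):
        try:
            if step.kind is PruneKind.MIN_CELLS:
                out = prune_min_cells(out, int(step.value))
            elif step.kind is PruneKind.MIN_DISTANCE_SEARCH:
                out = prune_min_distance(out, float(step.value))
            elif step.kind is PruneKind.DEPTH:
                out = prune_depth(out, int(step.value))
            elif step.kind is PruneKind.SET_ROOT:
                out = set_root(out, int(step.value))
        except (KeyError, ValueError) as e:
            raise ValueError(f"history step {i} ({step.kind.value}) failed: {e}") from e
    return out


def distance_distribution(t: ClusterTree) -> list[tuple[int, float]]:
    """All internal-node (node_id, distance) pairs, largest distance first.

    The empirical distribution a user inspects to choose a pruning cutoff.
    """
    pairs = [(n.node_id, n.distance) for n in t.nodes() if not n.is_leaf]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))
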