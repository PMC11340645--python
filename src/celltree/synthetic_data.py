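"""Synthetic count matrices and trees with known ground truth.

``simulate_block_counts`` plants disjoint transcriptional blocks
(cell types) in a negative-binomial count matrix: every block gets its
own disjoint set of marker features whose mean is ``marker_fold`` times
the baseline inside the block. This gives downstream modules a fully
in-silico recovery benchmark — the planted labels are the truth the
clustering should rediscover. ``simulate_random_tree`` fabricates valid
cluster trees directly, for exercising pruning, overlays and rendering
without touching a matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster_tree import ClusterNode, ClusterTree, renumber_bfs
from .matrix_io import CountMatrix, Normalization, write_mtx_bundle

__all__ = ["BlockSpec", "simulate_block_counts", "simulate_random_tree",
           "write_labels_csv", "ConfigError"]


class ConfigError(ValueError):
    """Infeasible simulation specification."""


@dataclass
class BlockSpec:
    """Parameters of a planted-block count matrix.

    Defaults emulate a small, well-separated scRNA-seq experiment:
    negative-binomial noise with moderate overdispersion
    (var = mu + mu^2 / dispersion), baseline mean 2 counts per feature
    and 25 disjoint markers per block boosted ``marker_fold``-fold.
    """

    n_cells_per_block: tuple[int, ...] = (50, 50, 50)
    n_features: int = 500
    n_marker_features_per_block: int = 25
    marker_fold: float = 8.0
    baseline_mean: float = 2.0
    dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_cells_per_block or any(n < 1 for n in self.n_cells_per_block):
            raise ConfigError("each block needs at least one cell")
        if self.marker_fold < 1:
            raise ConfigError("marker_fold must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_mean and dispersion must be positive")
        needed = len(self.n_cells_per_block) * self.n_marker_features_per_block
        if needed > self.n_features:
            raise ConfigError(
                f"{needed} marker features requested but only "
                f"{self.n_features} features available"
            )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # numpy parameterizes NB by (n, p) with mean = n (1-p)/p
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_block_counts(spec: BlockSpec) -> tuple[CountMatrix, dict[str, str]]:
    """Draw a planted-block count matrix and its true cell labels.

    Returns the raw cells x features matrix and a barcode -> block-name
    map. Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_blocks = len(spec.n_cells_per_block)
    n_cells = sum(spec.n_cells_per_block)

    mean = np.full((n_cells, spec.n_features), spec.baseline_mean)
    row = 0
    true_labels: dict[str, str] = {}
    barcodes: list[str] = []
    for b, n in enumerate(spec.n_cells_per_block):
        markers = slice(b * spec.n_marker_features_per_block,
                        (b + 1) * spec.n_marker_features_per_block)
        mean[row:row + n, markers] *= spec.marker_fold
        for i in range(n):
            bc = f"cell_{row + i:05d}"
            barcodes.append(bc)
            true_labels[bc] = f"block{b}"
        row += n

    counts = _nb_counts(rng, mean, spec.dispersion)
    features = [f"feat_{j:04d}" for j in range(spec.n_features)]
    m = CountMatrix(counts, barcodes, features, Normalization.RAW)
    return m, true_labels


def simulate_random_tree(n_leaves: int, cells_per_leaf: int = 10,
                         seed: int = 0) -> ClusterTree:
    """Random full binary tree with ``n_leaves`` leaves.

    Split distances are uniform in (0, 1); each leaf owns
    ``cells_per_leaf`` synthetic barcodes. Ids are breadth-first from 0.
    """
    if n_leaves < 1:
        raise ConfigError("n_leaves must be >= 1")
    if cells_per_leaf < 1:
        raise ConfigError("cells_per_leaf must be >= 1")
    rng = np.random.default_rng(seed)
    counter = iter(range(n_leaves * cells_per_leaf))

    def grow(leaves: int) -> ClusterNode:
        node = ClusterNode(node_id=-1)
        if leaves == 1:
            node.cells = [f"cell_{next(counter):05d}" for _ in range(cells_per_leaf)]
            return node
        node.distance = float(rng.uniform(np.nextafter(0, 1), 1.0))
        left = int(rng.integers(1, leaves))
        node.children = [grow(left), grow(leaves - left)]
        return node

    root = grow(n_leaves)
    renumber_bfs(root)
    return ClusterTree(root)


def write_labels_csv(labels: dict[str, str], path: str | os.PathLike,
                     colors: dict[str, str] | None = None) -> None:
    """Write an ``item,label[,color]`` CSV usable by tree_io.read_labels_csv."""
    with open(path, "w", encoding="utf-8") as fh:
        if colors:
            fh.write("item,label,color\n")
            for item, lab in labels.items():
                fh.write(f"{item},{lab},{colors[lab]}\n")
        else:
            fh.write("item,label\n")
            for item, lab in labels.items():
                fh.write(f"{item},{lab}\n")
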