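"""Per-node overlays and the persistent feature store.

The store materializes the count matrix as one little-endian float64
binary column per feature plus a text index, so that after a single
matrix import any feature vector can be served without re-reading the
matrix — the contract that makes batch rendering O(1) in matrix reads.

Overlay computations summarize a cell-level quantity at every tree node:
mean feature expression, label composition, joint high/low classification
of two features, and node-vs-node differential expression (log2 fold
change on upper-quartile-normalized counts, Mann-Whitney U p-values,
Benjamini-Hochberg q-values).
"""

from __future__ import annotations

import difflib
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from ._instrument import count_event
from .cluster_tree import ClusterTree
from .matrix_io import CountMatrix, Normalization, StateError
from .tree_io import LabelMap

__all__ = [
    "FeatureStore", "build_feature_store", "open_feature_store",
    "NodeOverlay", "OverlayKind",
    "node_feature_means", "node_label_composition",
    "two_feature_classification", "node_statistics",
    "differential_log2fc", "benjamini_hochberg",
]

_INDEX = "index.tsv"
_BARCODES = "barcodes.tsv"


class FeatureLookupError(KeyError):
    pass


class OverlayKind(str, Enum):
    MEAN_FEATURE = "mean_feature"
    LABEL_MAJORITY = "label_majority"
    TWO_FEATURE = "two_feature"


@dataclass
class NodeOverlay:
    """A per-node summary ready to color a tree with.

    ``values`` maps every node id to either a real (mean overlays) or a
    category -> proportion dict (two-feature overlays).
    """

    values: dict[int, object]
    kind: OverlayKind
    metadata: dict = field(default_factory=dict)


class FeatureStore:
    """Columnar on-disk feature cache (index.tsv + one .bin per feature).

    Each ``.bin`` holds the feature's dense cell vector as little-endian
    8-byte reals in store barcode order. Opening a store never touches
    the source matrix.
    """

    def __init__(self, path: str | os.PathLike):
        count_event("store_open")
        self.path = Path(path)
        index_path = self.path / _INDEX
        if not index_path.exists():
            raise FileNotFoundError(f"no feature store at {self.path}")
        self.barcodes: list[str] = (
            (self.path / _BARCODES).read_text(encoding="utf-8").splitlines()
        )
        self._columns: dict[str, str] = {}
        for line in index_path.read_text(encoding="utf-8").splitlines():
            name, fname = line.split("\t")
            self._columns[name] = fname

    @property
    def feature_names(self) -> list[str]:
        return list(self._columns)

    def __contains__(self, feature: str) -> bool:
        return feature in self._columns

    def search(self, substring: str) -> list[str]:
        """Case-insensitive substring search over feature names."""
        s = substring.lower()
        return [f for f in self._columns if s in f.lower()]

    def get_feature_vector(self, feature: str) -> np.ndarray:
        """Dense vector for one feature, aligned to ``self.barcodes``."""
        if feature not in self._columns:
            near = difflib.get_close_matches(feature, self._columns, n=5) \
                or self.search(feature)[:5]
            hint = f"; close matches: {', '.join(near)}" if near else ""
            raise FeatureLookupError(f"feature {feature!r} not in store{hint}")
        raw = (self.path / self._columns[feature]).read_bytes()
        return np.frombuffer(raw, dtype="<f8").copy()

    def get_feature_series(self, feature: str) -> pd.Series:
        return pd.Series(self.get_feature_vector(feature), index=self.barcodes,
                         name=feature)


def build_feature_store(m: CountMatrix, path: str | os.PathLike,
                        overwrite: bool = False) -> FeatureStore:
    """Persist every feature column of ``m`` under ``path``.

    This is the single import: every later overlay reads from the store
    only. Refuses a non-empty target directory unless ``overwrite``.
    """
    p = Path(path)
    if p.exists() and any(p.iterdir()) and not overwrite:
        raise FileExistsError(f"{p} exists and is not empty (pass overwrite=True)")
    p.mkdir(parents=True, exist_ok=True)
    (p / _BARCODES).write_text("".join(b + "\n" for b in m.barcodes),
                               encoding="utf-8")
    csc = m.counts.tocsc()
    with open(p / _INDEX, "w", encoding="utf-8") as idx:
        for j, name in enumerate(m.feature_names):
            fname = f"feature_{j:06d}.bin"
            col = np.zeros(m.n_cells)
            start, end = csc.indptr[j], csc.indptr[j + 1]
            col[csc.indices[start:end]] = csc.data[start:end]
            (p / fname).write_bytes(col.astype("<f8").tobytes())
            idx.write(f"{name}\t{fname}\n")
    return FeatureStore(p)


def open_feature_store(path: str | os.PathLike) -> FeatureStore:
    return FeatureStore(path)


def get_feature_vector(s: FeatureStore, feature: str) -> np.ndarray:
    return s.get_feature_vector(feature)


def _as_value_map(v, barcodes: Sequence[str]) -> dict[str, float]:
    if isinstance(v, pd.Series):
        v = v.to_dict()
    if isinstance(v, Mapping):
        missing = [b for b in barcodes if b not in v]
        if missing:
            raise KeyError(f"barcode {missing[0]!r} missing from value vector")
        return v
    raise TypeError("expected a barcode-indexed Series or mapping")


def node_feature_means(t: ClusterTree, v: Mapping[str, float] | pd.Series) -> NodeOverlay:
    """Mean of a cell-level value over every node's population.

    Leaves average their own cells; internal nodes average the union of
    their descendants (equivalently, the cell-count-weighted mean of
    their children's means).
    """
    vals = _as_value_map(v, t.barcodes())
    means: dict[int, object] = {}

    def walk(node) -> tuple[float, int]:
        if node.is_leaf:
            tot, n = sum(vals[b] for b in node.cells), len(node.cells)
        else:
            parts = [walk(c) for c in node.children]
            tot, n = sum(p[0] for p in parts), sum(p[1] for p in parts)
        means[node.node_id] = tot / n
        return tot, n

    walk(t.root)
    name = v.name if isinstance(v, pd.Series) else None
    return NodeOverlay(means, OverlayKind.MEAN_FEATURE, {"feature": name})


def node_label_composition(t: ClusterTree, labels: LabelMap) -> dict[int, dict[str, int]]:
    """Label -> cell-count histogram at every node (internal = sum of children)."""
    comp: dict[int, dict[str, int]] = {}

    def walk(node) -> dict[str, int]:
        counts: dict[str, int] = {}
        if node.is_leaf:
            for b in node.cells:
                if b not in labels.label_of:
                    raise KeyError(f"barcode {b!r} has no label")
                lab = labels.label_of[b]
                counts[lab] = counts.get(lab, 0) + 1
        else:
            for child in node.children:
                for lab, c in walk(child).items():
                    counts[lab] = counts.get(lab, 0) + c
        comp[node.node_id] = counts
        return counts

    walk(t.root)
    return comp


_TWO_FEATURE_CATEGORIES = (
    "A-high/B-high", "A-high/B-low", "A-low/B-high", "A-low/B-low",
    "indeterminate",
)


def two_feature_classification(t: ClusterTree, vA, vB,
                               hiA: float, loA: float,
                               hiB: float, loB: float) -> NodeOverlay:
    """Joint high/low classification of two features, per node.

    A cell is A-high iff vA >= hiA, A-low iff vA <= loA (same for B);
    cells in neither joint corner are "indeterminate". The overlay holds
    each node's category proportions (summing to 1).
    """
    if loA > hiA or loB > hiB:
        raise ValueError("low threshold exceeds high threshold")
    barcodes = t.barcodes()
    a = _as_value_map(vA, barcodes)
    b = _as_value_map(vB, barcodes)

    def classify(bc: str) -> str:
        a_hi, a_lo = a[bc] >= hiA, a[bc] <= loA
        b_hi, b_lo = b[bc] >= hiB, b[bc] <= loB
        if a_hi and b_hi:
            return "A-high/B-high"
        if a_hi and b_lo:
            return "A-high/B-low"
        if a_lo and b_hi:
            return "A-low/B-high"
        if a_lo and b_lo:
            return "A-low/B-low"
        return "indeterminate"

    cat_of = {bc: classify(bc) for bc in barcodes}
    values: dict[int, object] = {}
    for node in t.nodes():
        cells = node.leaf_cells()
        props = {c: 0.0 for c in _TWO_FEATURE_CATEGORIES}
        for bc in cells:
            props[cat_of[bc]] += 1.0
        values[node.node_id] = {c: v / len(cells) for c, v in props.items()}
    meta = {"hiA": hiA, "loA": loA, "hiB": hiB, "loB": loB,
            "categories": list(_TWO_FEATURE_CATEGORIES)}
    return NodeOverlay(values, OverlayKind.TWO_FEATURE, meta)


def node_statistics(t: ClusterTree, node_id: int,
                    labels: LabelMap | None = None,
                    overlay: NodeOverlay | None = None) -> dict:
    """The tooltip record for one node: size, distance, depth, composition."""
    node = t.node(node_id)
    rec: dict = {
        "node_id": node_id,
        "cell_count": node.n_cells(),
        "distance": node.distance,
        "depth": t.depth(node_id),
        "is_leaf": node.is_leaf,
    }
    if labels is not None:
        rec["label_composition"] = node_label_composition(t, labels)[node_id]
    if overlay is not None:
        rec["overlay_value"] = overlay.values[node_id]
        rec["overlay_kind"] = overlay.kind.value
    return rec


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_log2fc(m_uq: CountMatrix, cells_A: Sequence[str],
                        cells_B: Sequence[str], pseudocount: float = 1.0,
                        alternative: str = "two-sided") -> pd.DataFrame:
    """Per-feature differential expression between two disjoint cell sets.

    log2fc = log2((mean_A + pseudocount) / (mean_B + pseudocount)), means
    taken over all cells of each group including zeros, on
    upper-quartile-normalized counts. p from the Mann-Whitney U test with
    tie correction (``alternative`` passed through; the one-sided variant
    tests A > B), q by Benjamini-Hochberg over all features.
    """
    if m_uq.normalized is not Normalization.UPPER_QUARTILE:
        raise StateError("differential_log2fc expects upper-quartile-normalized counts")
    set_a, set_b = set(cells_A), set(cells_B)
    if not set_a or not set_b:
        raise ValueError("both cell sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"cell sets overlap: {sorted(set_a & set_b)[:3]}")

    sub_a = m_uq.subset_cells(list(cells_A)).counts
    sub_b = m_uq.subset_cells(list(cells_B)).counts
    xa = np.asarray(sub_a.todense())
    xb = np.asarray(sub_b.todense())
    mean_a = xa.mean(axis=0)
    mean_b = xb.mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pvals = np.empty(m_uq.n_features)
    for j in range(m_uq.n_features):
        a_col, b_col = xa[:, j], xb[:, j]
        if np.all(a_col == a_col[0]) and np.all(b_col == a_col[0]):
            pvals[j] = 1.0  # constant feature: no evidence either way
            continue
        alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
        pvals[j] = scipy.stats.mannwhitneyu(a_col, b_col, alternative=alt,
                                            method="auto").pvalue
    qvals = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "q": qvals},
        index=pd.Index(m_uq.feature_names, name="feature"),
    )
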