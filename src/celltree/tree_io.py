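"""Tree and label serialization.

Trees are written as recursive JSON in the ``cluster_tree.json`` style:
``{"_id": int, "_distance": float, "_cells": [{"barcode": str}, ...]}``
at leaves and ``{"_id", "_distance", "children": [left, right]}`` at
internal nodes. The schema is this package's documented dialect. Cell
labels come from a CSV with header ``item,label[,color]``; colors are
auto-assigned from a fixed categorical palette when absent.
"""

from __future__ import annotations

import gzip
import json
import os
import re
from dataclasses import dataclass, field
from pathlib import Path

from ._instrument import count_event
from .cluster_tree import ClusterNode, ClusterTree, TreeValidationError

__all__ = ["write_tree_json", "read_tree_json", "LabelMap", "read_labels_csv"]

# matplotlib's tab10, hard-coded so label colors never depend on a
# plotting backend being importable
PALETTE = [
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
]

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


def _node_to_obj(node: ClusterNode) -> dict:
    obj: dict = {"_id": node.node_id,
                 "_distance": float(f"{node.distance:.12g}")}
    if node.is_leaf:
        obj["_cells"] = [{"barcode": b} for b in node.cells]
    else:
        obj["children"] = [_node_to_obj(c) for c in node.children]
    return obj


def write_tree_json(t: ClusterTree, path: str | os.PathLike) -> None:
    """Serialize a tree to the recursive JSON dialect (UTF-8, stable keys)."""
    obj = _node_to_obj(t.root)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=False)
        fh.write("\n")


def _obj_to_node(obj: dict) -> ClusterNode:
    if not isinstance(obj, dict) or "_id" not in obj:
        raise TreeValidationError("node object missing '_id'")
    node = ClusterNode(node_id=int(obj["_id"]),
                       distance=float(obj.get("_distance", 0.0)))
    children = obj.get("children", [])
    if children and "_cells" in obj:
        raise TreeValidationError(
            f"node {node.node_id} has both children and cells"
        )
    if children:
        if len(children) != 2:
            raise TreeValidationError(
                f"node {node.node_id} has {len(children)} children; expected 2"
            )
        node.children = [_obj_to_node(c) for c in children]
    else:
        node.cells = [c["barcode"] for c in obj.get("_cells", [])]
    return node


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_tree_json(path: str | os.PathLike) -> ClusterTree:
    """Parse and validate a tree JSON file.

    Rejects nodes with one or more than two children, duplicate node ids
    and barcodes appearing in more than one leaf, naming the offending
    node in the error.
    """
    count_event("tree_parse")
    with _open_maybe_gzip(Path(path)) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"malformed tree JSON in {path}: {e}") from e
    return ClusterTree(_obj_to_node(obj))


@dataclass
class LabelMap:
    """Barcode -> label assignment plus a label -> #RRGGBB color map."""

    label_of: dict[str, str]
    color_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab in set(self.label_of.values()):
            if not lab:
                raise ValueError("empty label string")
        missing = sorted(set(self.label_of.values()) - set(self.color_of))
        for i, lab in enumerate(missing):
            self.color_of[lab] = PALETTE[i % len(PALETTE)]
        for lab, col in self.color_of.items():
            if not _HEX_RE.match(col):
                raise ValueError(f"label {lab!r} has invalid color {col!r}")

    def labels(self) -> list[str]:
        return sorted(set(self.label_of.values()))


def read_labels_csv(path: str | os.PathLike) -> LabelMap:
    """Read an ``item,label[,color]`` CSV into a LabelMap.

    Without a color column, colors are assigned from the fixed palette in
    label-sorted order, so the same label set always gets the same colors.
    """
    with _open_maybe_gzip(Path(path)) as fh:
        header = fh.readline().strip().lower().split(",")
        if header[:2] != ["item", "label"]:
            raise ValueError(
                f"{path}: expected header 'item,label[,color]', got {','.join(header)!r}"
            )
        has_color = len(header) > 2 and header[2] == "color"
        label_of: dict[str, str] = {}
        color_of: dict[str, str] = {}
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            item, label = parts[0], parts[1]
            if item in label_of:
                if label_of[item] != label:
                    raise ValueError(
                        f"{path}:{ln}: item {item!r} re-labeled "
                        f"{label!r} (was {label_of[item]!r})"
                    )
                raise ValueError(f"{path}:{ln}: duplicate item {item!r}")
            label_of[item] = label
            if has_color and len(parts) > 2 and parts[2]:
                color_of[label] = parts[2]
    labels = sorted(set(label_of.values()) - set(color_of))
    for i, lab in enumerate(labels):
        color_of[lab] = PALETTE[i % len(PALETTE)]
    return LabelMap(label_of, color_of)
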