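"""Headless, config-driven figure generation.

A :class:`BatchJob` names a tree file, a feature store and a list of
features; :func:`run_batch` renders one figure per feature. The tree is
parsed once and the store opened once per run — the source count matrix
is never touched, honoring the import-once contract — and figures are
rendered and written one at a time so memory stays constant in the
number of features.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

from .overlay import FeatureStore, node_feature_means
from .prune import apply_history
from .render import RenderConfig, radial_layout, render_png, render_svg
from .tree_io import read_tree_json

__all__ = ["BatchJob", "BatchResult", "PartialBatchError", "run_batch"]


@dataclass
class BatchJob:
    tree_path: str | os.PathLike
    store_path: str | os.PathLike
    out_dir: str | os.PathLike
    feature_list: list[str]
    base_config: RenderConfig = field(default_factory=RenderConfig)
    format: str = "svg"

    def __post_init__(self) -> None:
        if self.format not in ("svg", "png"):
            raise ValueError(f"format must be svg or png, got {self.format!r}")


@dataclass
class BatchResult:
    written: list[Path]
    failures: dict[str, str]


class PartialBatchError(RuntimeError):
    """Some features failed; the rest were still rendered."""

    def __init__(self, result: BatchResult):
        self.result = result
        fails = "; ".join(f"{k}: {v}" for k, v in result.failures.items())
        super().__init__(
            f"{len(result.failures)} of "
            f"{len(result.failures) + len(result.written)} features failed ({fails})"
        )


def _safe_filename(feature: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", feature)


def run_batch(job: BatchJob) -> list[Path]:
    """Render one figure per feature after a single tree parse + store open.

    Figures land in ``out_dir`` as ``<feature>.<ext>``. A feature that
    cannot be rendered (e.g. absent from the store) is recorded and the
    batch continues; if any failed, a :class:`PartialBatchError` carrying
    both the written paths and the per-feature errors is raised at the
    end.
    """
    tree = read_tree_json(job.tree_path)
    tree = apply_history(tree, job.base_config.prune_history)
    store = FeatureStore(job.store_path)
    layout = radial_layout(tree, job.base_config.scale_by_distance)
    out_dir = Path(job.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    failures: dict[str, str] = {}
    for feature in job.feature_list:
        try:
            series = store.get_feature_series(feature)
            overlay = node_feature_means(tree, series)
            doc = render_svg(tree, layout, job.base_config, overlays=overlay)
            out = out_dir / f"{_safe_filename(feature)}.{job.format}"
            if job.format == "svg":
                doc.save(out)
            else:
                out.write_bytes(render_png(doc, job.base_config.width_px))
            written.append(out)
        except Exception as e:  # noqa: BLE001 - record and continue
            failures[feature] = str(e)
    if failures:
        raise PartialBatchError(BatchResult(written, failures))
    return written
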