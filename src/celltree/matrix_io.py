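"""Sparse count-matrix I/O, filtering and normalization.

Count matrices are held as cells x features sparse matrices together with
their barcode and feature-name axes, mirroring the 10x/Cell Ranger MTX
triplet bundle (``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``).
Normalizations implemented here are the ones used upstream of tree
building (TF-IDF) and differential expression (upper-quartile).
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from ._instrument import count_event

__all__ = [
    "Normalization",
    "CountMatrix",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "filter_matrix",
    "tfidf_normalize",
    "upper_quartile_normalize",
    "InputError",
    "FormatError",
    "StateError",
    "EmptyResultError",
]


class InputError(ValueError):
    """A required input is missing or unusable."""


class FormatError(ValueError):
    """An input file violates its format contract."""


class StateError(ValueError):
    """Operation applied to a matrix in the wrong normalization state."""


class EmptyResultError(ValueError):
    """Filtering removed every cell."""


class Normalization(str, Enum):
    RAW = "raw"
    TFIDF = "tfidf"
    UPPER_QUARTILE = "upper_quartile"


@dataclass
class CountMatrix:
    """Cells x features sparse counts with named axes.

    Invariants: ``counts.shape == (len(barcodes), len(feature_names))``,
    all values non-negative (integers when raw), no duplicate barcodes or
    feature names.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    feature_names: list[str]
    normalized: Normalization = Normalization.RAW

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = list(self.barcodes)
        self.feature_names = list(self.feature_names)
        if self.counts.shape != (len(self.barcodes), len(self.feature_names)):
            raise FormatError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.barcodes)} barcodes x {len(self.feature_names)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FormatError("duplicate feature names")
        data = self.counts.data
        if data.size and (np.isnan(data).any() or (data < 0).any()):
            raise FormatError("matrix contains negative or NaN entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def feature_vector(self, name: str) -> np.ndarray:
        """Dense column for one feature, aligned to ``barcodes``."""
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in matrix") from None
        return np.asarray(self.counts[:, j].todense()).ravel()

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        try:
            rows = [index[b] for b in barcodes]
        except KeyError as e:
            raise KeyError(f"barcode {e.args[0]!r} not in matrix") from None
        return replace(self, counts=self.counts[rows], barcodes=list(barcodes))


def _open_text(path: Path):
    """Open path (or path.gz) as text, gzip-transparently."""
    p = Path(path)
    if not p.exists() and p.with_suffix(p.suffix + ".gz").exists():
        p = p.with_suffix(p.suffix + ".gz")
    if not p.exists():
        raise InputError(f"missing file: {path}")
    if p.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(p, "rb"), encoding="utf-8")
    return open(p, "r", encoding="utf-8")


def _read_id_column(path: Path, column: int | None = None) -> list[str]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if column is not None and len(fields) > column:
                out.append(fields[column])
            else:
                out.append(fields[0])
    return out


def read_mtx_bundle(dir_path: str | os.PathLike, orientation: str = "features_by_cells") -> CountMatrix:
    """Read a 10x-style MTX triplet bundle into a raw CountMatrix.

    ``matrix.mtx`` is MatrixMarket coordinate format; by the 10x convention
    it is stored features x cells and transposed on read. Pass
    ``orientation="cells_by_features"`` for bundles already row-major in
    cells. ``features.tsv`` may carry 2-3 tab-separated columns (id, name,
    type); the second column is used as the feature name when present.
    """
    count_event("matrix_read")
    d = Path(dir_path)
    mtx_path = d / "matrix.mtx"
    if not mtx_path.exists() and (d / "matrix.mtx.gz").exists():
        mtx_path = d / "matrix.mtx.gz"
    if not mtx_path.exists():
        raise InputError(f"missing file: {d / 'matrix.mtx'}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as e:  # scipy raises plain ValueError on bad headers
        raise FormatError(f"cannot parse {mtx_path}: {e}") from e
    mat = sp.csr_matrix(mat)

    barcodes = _read_id_column(d / "barcodes.tsv")
    features = _read_id_column(d / "features.tsv", column=1)

    if orientation == "features_by_cells":
        mat = sp.csr_matrix(mat.T)
    elif orientation != "cells_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    if mat.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"matrix declares {mat.shape[0]} cells x {mat.shape[1]} features but "
            f"barcodes.tsv has {len(barcodes)} rows and features.tsv {len(features)}"
        )
    return CountMatrix(mat, barcodes, features, Normalization.RAW)


def write_mtx_bundle(m: CountMatrix, dir_path: str | os.PathLike,
                     orientation: str = "features_by_cells") -> None:
    """Write the bundle back out (features x cells by default, 10x style)."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    mat = m.counts.T if orientation == "features_by_cells" else m.counts
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(mat))
    (d / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    (d / "features.tsv").write_text(
        "".join(f"{f}\t{f}\tGene Expression\n" for f in m.feature_names)
    )


def filter_matrix(m: CountMatrix, min_transcripts: int = 250,
                  min_cells_per_feature: int = 1) -> CountMatrix:
    """Drop low-coverage cells, then features undetected in surviving cells.

    Cells with total counts < ``min_transcripts`` are removed first
    (threshold inclusive: a cell with exactly ``min_transcripts`` counts
    survives); features detected in fewer than ``min_cells_per_feature``
    of the remaining cells are then removed. Single pass, axis order kept.
    """
    if m.normalized is not Normalization.RAW:
        raise StateError("filter_matrix requires a raw matrix")
    keep_cells = m.row_sums() >= min_transcripts
    if not keep_cells.any():
        raise EmptyResultError(
            f"no cell reaches {min_transcripts} transcripts"
        )
    counts = m.counts[keep_cells]
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_feats = detected >= min_cells_per_feature
    counts = counts[:, keep_feats]
    return CountMatrix(
        counts,
        [b for b, k in zip(m.barcodes, keep_cells) if k],
        [f for f, k in zip(m.feature_names, keep_feats) if k],
        Normalization.RAW,
    )


def tfidf_normalize(m: CountMatrix) -> CountMatrix:
    """Term-frequency x inverse-document-frequency weighting.

    value(c, g) = (count(c, g) / total(c)) * ln(N / df_g), with N the
    number of cells and df_g the number of cells detecting feature g.
    Natural log; features present in every cell therefore zero out.
    Requires a raw matrix with no zero-total cells (filter first).
    """
    if m.normalized is not Normalization.RAW:
        raise StateError("tfidf_normalize requires a raw matrix")
    totals = m.row_sums()
    if (totals == 0).any():
        raise StateError("zero-total cell; run filter_matrix first")
    tf = sp.diags(1.0 / totals) @ m.counts
    df = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    if (df == 0).any():
        raise StateError("feature detected in no cell; run filter_matrix first")
    idf = np.log(m.n_cells / df)
    out = sp.csr_matrix(tf @ sp.diags(idf))
    out.eliminate_zeros()
    return replace(m, counts=out, normalized=Normalization.TFIDF)


def upper_quartile_normalize(m: CountMatrix) -> CountMatrix:
    """Per-cell upper-quartile scaling used before fold-change computation.

    Each cell is divided by the 75th percentile of its *nonzero* counts
    (linear-interpolation percentile) and rescaled by the median of those
    per-cell quartiles so magnitudes stay comparable across cells.
    """
    if m.normalized is not Normalization.RAW:
        raise StateError("upper_quartile_normalize requires a raw matrix")
    csr = m.counts.tocsr()
    divisors = np.empty(m.n_cells)
    for i in range(m.n_cells):
        row = csr.data[csr.indptr[i]:csr.indptr[i + 1]]
        nz = row[row > 0]
        if nz.size == 0:
            raise StateError(f"cell {m.barcodes[i]!r} has no nonzero counts")
        divisors[i] = np.percentile(nz, 75)
    scale = np.median(divisors)
    out = sp.csr_matrix(sp.diags(scale / divisors) @ csr)
    return replace(m, counts=out, normalized=Normalization.UPPER_QUARTILE)
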