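"""Reading and writing the matrix and table formats the pipeline touches.

Two count-matrix layouts are supported:

* ``mtx_triplet`` — the 10x-style directory triplet: ``matrix.mtx[.gz]``
  (Matrix Market, genes x cells on disk), ``barcodes.tsv[.gz]`` and
  ``features.tsv[.gz]`` / ``genes.tsv[.gz]``.  The matrix is transposed on
  load so that cells are rows everywhere in memory.
* ``dense_tsv`` — a small dense TSV with a header row of gene ids and one
  row per cell (first column: cell id).  Used for hand-written fixtures.

Cell order on disk is preserved exactly; it is the contract by which labels,
embeddings and silhouette reports are aligned to the matrix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "read_counts",
    "write_counts_mtx",
    "read_labels",
    "write_labels",
]


@dataclass
class ExpressionMatrix:
    """Raw counts, cells x genes, with cell and gene identifiers.

    Invariants (checked by :meth:`validate`): the counts are non-negative
    integers, identifiers are unique, and their lengths match the matrix
    shape.  ``counts`` is stored CSR.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise IntegrityError(
                f"{len(self.cell_ids)} cell ids for a matrix with {n} rows"
            )
        if len(self.gene_ids) != g:
            raise IntegrityError(
                f"{len(self.gene_ids)} gene ids for a matrix with {g} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integral counts")

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Row subset preserving cell order; ``mask`` is boolean or index."""
        return ExpressionMatrix(
            self.counts[mask], self.cell_ids[mask], self.gene_ids
        )


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_one(directory: Path, stems: Iterable[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FormatError(
        f"none of {list(stems)} (or .gz) found in {directory}"
    )


def _read_id_column(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    """First column = identifier; second, if present, = display name."""
    ids, names = [], []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            ids.append(fields[0])
            names.append(fields[1] if len(fields) > 1 else fields[0])
    return np.asarray(ids, dtype=object), np.asarray(names, dtype=object)


def read_counts(path: str | Path, layout: str = "auto") -> ExpressionMatrix:
    """Load a count matrix as cells x genes.

    Parameters
    ----------
    path
        Directory with the MTX triplet, or a dense TSV file.
    layout
        ``"mtx_triplet"``, ``"dense_tsv"`` or ``"auto"`` (directory implies
        the triplet, file implies the TSV).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if layout == "auto":
        layout = "mtx_triplet" if path.is_dir() else "dense_tsv"
    if layout == "mtx_triplet":
        return _read_mtx_triplet(path)
    if layout == "dense_tsv":
        return _read_dense_tsv(path)
    raise FormatError(f"unknown layout {layout!r}")


def _read_mtx_triplet(directory: Path) -> ExpressionMatrix:
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")
    mtx = _find_one(directory, ["matrix.mtx"])
    barcodes = _find_one(directory, ["barcodes.tsv"])
    features = _find_one(directory, ["features.tsv", "genes.tsv"])
    try:
        with _open_maybe_gz(mtx) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    mat = sp.csr_matrix(mat).T  # disk convention is genes x cells
    cell_ids, _ = _read_id_column(barcodes)
    gene_ids, _ = _read_id_column(features)
    if len(cell_ids) != mat.shape[0]:
        raise IntegrityError(
            f"{len(cell_ids)} barcodes but matrix has {mat.shape[0]} cells"
        )
    if len(gene_ids) != mat.shape[1]:
        raise IntegrityError(
            f"{len(gene_ids)} features but matrix has {mat.shape[1]} genes"
        )
    return ExpressionMatrix(mat, cell_ids, gene_ids)


def _read_dense_tsv(path: Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"non-numeric entries in {path}")
    return ExpressionMatrix(
        sp.csr_matrix(values),
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
    )


def write_counts_mtx(matrix: ExpressionMatrix, directory: str | Path) -> None:
    """Write the 10x-style triplet (plain text, genes x cells on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), sp.coo_matrix(matrix.counts.T)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in matrix.cell_ids)
    )
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\n" for g in matrix.gene_ids)
    )


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a ``cell_id<TAB>label`` table; duplicate cell ids are an error."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["cell_id", "label"]
    if list(df.columns)[:2] != expected:
        raise FormatError(
            f"label table must have columns {expected}, got {list(df.columns)}"
        )
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicated cell_id {dup!r} in {path}")
    return df[expected]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    """Write a ``cell_id<TAB>label`` table (header always present)."""
    if list(labels.columns)[:2] != ["cell_id", "label"]:
        raise ValidationError("label table must have columns cell_id, label")
    labels[["cell_id", "label"]].to_csv(path, sep="\t", index=False)
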