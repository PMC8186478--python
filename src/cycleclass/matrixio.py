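"""Reading and writing the on-disk formats the toolkit touches.

Count matrices travel either as Matrix Market triplet files with
``genes.tsv`` / ``barcodes.tsv`` sidecars (the 10x-style layout) or as
dense delimited tables with genes as rows and a header row of cell ids.
Everything is gene x cell internally.  Result tables (markers, CV
reports, enrichment results) are written as deterministic CSVs with a
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ValidationError

logger = logging.getLogger("cycleclass")

__all__ = [
    "CountMatrix",
    "CellAnnotation",
    "read_count_matrix",
    "write_count_matrix",
    "read_dense_matrix",
    "write_dense_matrix",
    "write_tables",
]


@dataclass
class CountMatrix:
    """Gene x cell matrix of nonnegative integer UMI counts.

    ``values`` has one row per entry of ``gene_ids`` and one column per
    entry of ``cell_ids``; both identifier lists must be unique.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                raise ValidationError("counts must be integers")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValidationError("counts must be nonnegative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene identifiers are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell identifiers are not unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellAnnotation:
    """Per-cell metadata table: cluster / phase / dataset plus extras."""

    table: pd.DataFrame
    cell_id_column: str = "cell_id"

    def __post_init__(self):
        if self.cell_id_column not in self.table.columns:
            raise ValidationError(f"annotation lacks a {self.cell_id_column!r} column")
        ids = self.table[self.cell_id_column]
        if ids.duplicated().any():
            raise ValidationError("annotation has duplicated cell ids")

    def check_paired(self, counts: CountMatrix) -> None:
        missing = set(self.table[self.cell_id_column]) - set(counts.cell_ids)
        if missing:
            raise ValidationError(
                f"{len(missing)} annotated cells absent from the count matrix"
            )


def _read_sidecar(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar file: {path}")
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicated {what} identifier in {path}")
    return ids


def read_count_matrix(path, format: str = "mtx-triplet") -> CountMatrix:
    """Read a count matrix from disk.

    ``mtx-triplet`` expects a directory holding ``matrix.mtx``,
    ``genes.tsv`` and ``barcodes.tsv`` (genes.tsv rows correspond to
    matrix rows).  ``dense-delimited`` expects a single CSV/TSV with
    genes as rows and a header of cell ids; blank cells are treated as
    corruption, not zeros.
    """
    path = Path(path)
    if format == "mtx-triplet":
        mtx = path / "matrix.mtx" if path.is_dir() else path
        base = mtx.parent
        if not mtx.exists():
            raise FormatError(f"missing matrix file: {mtx}")
        try:
            values = scipy.io.mmread(mtx)
        except Exception as exc:  # pragma: no cover - scipy message forwarded
            raise FormatError(f"cannot parse Matrix Market file {mtx}: {exc}") from exc
        values = np.asarray(
            values.todense() if scipy.sparse.issparse(values) else values
        )
        genes = _read_sidecar(base / "genes.tsv", "gene")
        cells = _read_sidecar(base / "barcodes.tsv", "cell")
        if values.shape != (len(genes), len(cells)):
            raise FormatError(
                f"{mtx} is {values.shape[0]}x{values.shape[1]} but sidecars list "
                f"{len(genes)} genes ({base / 'genes.tsv'}) and "
                f"{len(cells)} cells ({base / 'barcodes.tsv'})"
            )
        return CountMatrix(values=values, gene_ids=genes, cell_ids=cells)
    if format == "dense-delimited":
        return read_dense_matrix(path)
    raise FormatError(f"unknown format {format!r}")


def read_dense_matrix(path) -> CountMatrix:
    """Read a dense gene x cell table (genes as rows, cell-id header)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ValidationError(
            f"blank/NA cells in {path} (e.g. column {bad!r}); refusing to zero-fill"
        )
    return CountMatrix(
        values=df.to_numpy(),
        gene_ids=list(df.index.astype(str)),
        cell_ids=list(df.columns.astype(str)),
    )


def write_count_matrix(counts: CountMatrix, out_dir) -> Path:
    """Write Matrix Market triplet + genes.tsv + barcodes.tsv; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(out_dir / "matrix.mtx", sparse, field="integer")
    (out_dir / "genes.tsv").write_text("".join(f"{g}\n" for g in counts.gene_ids))
    (out_dir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.cell_ids))
    return out_dir


def write_dense_matrix(counts: CountMatrix, path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    counts.to_frame().to_csv(path, sep=sep)
    return path


def _config_hash(metadata: dict) -> str:
    blob = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tables(
    tables: dict[str, pd.DataFrame],
    out_dir,
    seed: int | None = None,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Write result tables as CSVs with stable column order; return a manifest.

    The manifest (also written as ``manifest.csv``) lists every file
    with its row count.  Seed and a hash of the run configuration are
    logged so a run can be tied back to its inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False)
        rows.append({"file": fname, "rows": len(df)})
    manifest = pd.DataFrame(rows, columns=["file", "rows"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    logger.info(
        "wrote %d tables to %s (seed=%s, config=%s)",
        len(rows),
        out_dir,
        seed,
        _config_hash(metadata or {}),
    )
    return manifest
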