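"""Normalization, variable-gene selection and query/model gene alignment.

Counts are normalized per cell to a fixed total (default 10,000) and
log(1+x)-transformed with the natural log -- the dominant convention
for UMI data.  Classifier features are the most variable genes of the
normalized matrix (default 1,536).  A query matrix is aligned to a
trained model's feature space by (optionally) renaming genes through a
one-to-one homology map, restricting/reordering to the model features,
and filling absent features so that they standardize to z = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .matrixio import CountMatrix

logger = logging.getLogger("cycleclass")

DEFAULT_SCALE_FACTOR = 10_000.0
DEFAULT_N_HVG = 1536  # top most-variant genes used as classifier features

__all__ = [
    "NormalizedMatrix",
    "HomologyTable",
    "normalize_log",
    "select_hvg",
    "align_genes",
    "DEFAULT_SCALE_FACTOR",
    "DEFAULT_N_HVG",
]


@dataclass
class NormalizedMatrix:
    """Gene x cell matrix of log-normalized expression (natural log).

    ``missing_genes`` is populated by :func:`align_genes` for model
    features absent from the query; their rows carry the fill value and
    must standardize to z = 0 downstream.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_factor: float = DEFAULT_SCALE_FACTOR
    log_base: str = "e"
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match identifier lists"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def missing_fraction(self) -> float:
        return len(self.missing_genes) / max(1, self.n_genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class HomologyTable:
    """One-to-one gene homology map (source species id -> target id).

    Pairs whose source or target occurs more than once are dropped at
    construction so the retained mapping is one-to-one both ways.
    """

    pairs: pd.DataFrame  # columns: source_id, target_id

    def __post_init__(self):
        df = self.pairs
        if isinstance(df, dict):
            df = pd.DataFrame(
                {"source_id": list(df.keys()), "target_id": list(df.values())}
            )
        df = df.iloc[:, :2].copy()
        df.columns = ["source_id", "target_id"]
        df = df.astype(str).drop_duplicates()
        # keep only pairs that are unique in both directions
        df = df[~df["source_id"].duplicated(keep=False)]
        df = df[~df["target_id"].duplicated(keep=False)]
        self.pairs = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "HomologyTable":
        df = pd.read_csv(Path(path), sep="\t", header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValidationError(f"homology table {path} needs two columns")
        return cls(pairs=df)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["source_id"], self.pairs["target_id"]))


def normalize_log(
    counts: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """Per-cell total-count normalization followed by natural log(1+x).

    Each cell's counts are divided by the cell total, multiplied by
    ``scale_factor`` and log1p-transformed.  Cells with zero total are
    dropped (a count of dropped cells is logged).
    """
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be positive")
    totals = counts.values.sum(axis=0)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("every cell has zero total count")
    if n_dropped:
        logger.info("normalize_log: dropped %d zero-total cells", n_dropped)
    vals = counts.values[:, keep].astype(float)
    vals = np.log1p(vals / totals[keep] * scale_factor)
    return NormalizedMatrix(
        values=vals,
        gene_ids=list(counts.gene_ids),
        cell_ids=[c for c, k in zip(counts.cell_ids, keep) if k],
        scale_factor=float(scale_factor),
    )


def select_hvg(norm: NormalizedMatrix, n_genes: int = DEFAULT_N_HVG) -> list[str]:
    """Top ``n_genes`` most variable genes, in descending-variance order.

    Variance is the plain variance of log-normalized expression across
    cells; ties are broken lexicographically by gene id so the ranking
    is deterministic and invariant to cell order.
    """
    if n_genes <= 0:
        raise ParameterError("n_genes must be positive")
    if n_genes > norm.n_genes:
        raise ParameterError(
            f"requested {n_genes} genes but matrix has only {norm.n_genes}"
        )
    variances = norm.values.var(axis=1)
    order = sorted(range(norm.n_genes), key=lambda i: (-variances[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in order[:n_genes]]


def align_genes(
    query: NormalizedMatrix,
    model_features: list[str],
    homology: HomologyTable | None = None,
    feature_fill: dict[str, float] | None = None,
    max_missing: float = 0.95,
) -> NormalizedMatrix:
    """Restrict and reorder a query matrix to a model's feature space.

    Query genes are first renamed through ``homology`` when given
    (unmapped genes are dropped and counted in the log).  The output has
    exactly ``model_features`` as rows, in model order.  Features absent
    from the query are filled with ``feature_fill[gene]`` when provided
    (typically the model's training mean, so standardization yields
    z = 0) or 0.0 otherwise, and recorded in ``missing_genes`` so the
    classifier can force their standardized contribution to zero.
    """
    model_features = [str(g) for g in model_features]
    if not model_features:
        raise ParameterError("model_features is empty")

    gene_ids = list(query.gene_ids)
    values = query.values
    if homology is not None:
        mapping = homology.as_dict()
        keep = [i for i, g in enumerate(gene_ids) if g in mapping]
        n_unmapped = len(gene_ids) - len(keep)
        if n_unmapped:
            logger.info("align_genes: dropped %d unmapped query genes", n_unmapped)
        values = values[keep, :]
        gene_ids = [mapping[gene_ids[i]] for i in keep]

    index = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in model_features if g not in index]
    missing_fraction = len(missing) / len(model_features)
    if missing_fraction > max_missing:
        raise ValidationError(
            f"{missing_fraction:.0%} of model features missing from the query "
            f"(> {max_missing:.0%}); classification would be meaningless"
        )
    if missing:
        logger.info(
            "align_genes: %d/%d model features missing (%.1f%%)",
            len(missing),
            len(model_features),
            100 * missing_fraction,
        )

    out = np.zeros((len(model_features), values.shape[1]), dtype=float)
    for row, g in enumerate(model_features):
        i = index.get(g)
        if i is not None:
            out[row, :] = values[i, :]
        elif feature_fill is not None and g in feature_fill:
            out[row, :] = feature_fill[g]
    return NormalizedMatrix(
        values=out,
        gene_ids=model_features,
        cell_ids=list(query.cell_ids),
        scale_factor=query.scale_factor,
        log_base=query.log_base,
        missing_genes=missing,
    )
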