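"""Glioma application: neoplastic-cluster filtering, stem-like-cell
calling, phase enrichment and consensus signatures.

Tumor scRNA-seq datasets contain terminally differentiated,
non-neoplastic cells; clusters dominated by lineage markers --
oligodendrocytes (MBP, PLP1), astrocytes (ETNPPL), neurons (RBFOX3),
immune cells (AIF1, CD14, CX3CR1, PTPRC) -- are excluded before
phase analysis.  "High expression" is formalized as a cluster whose
mean expression of a panel gene is an outlier across clusters (z-score
>= 2) while at least half of its cells express the gene.

Putative stem-like cells are called by the presence logic
(FUT4 > 0 or L1CAM > 0 or PROM1 > 0) and SOX2 > 0 and TLR4 == 0,
evaluated on raw counts.  Their enrichment in each phase, and any other
set-overlap question, funnels through the shared hypergeometric kernel.
A consensus signature is the intersection of per-dataset marker tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .matrixio import CountMatrix
from .preprocess import NormalizedMatrix
from .stats import EnrichmentResult, hypergeometric_tail

logger = logging.getLogger("cycleclass")

__all__ = [
    "MarkerPanel",
    "StemLogicConfig",
    "filter_neoplastic_clusters",
    "stem_like_mask",
    "overlap_enrichment",
    "consensus_markers",
]


@dataclass
class MarkerPanel:
    """Lineage -> marker-gene sets used to flag non-neoplastic clusters."""

    lineages: dict[str, set[str]] = field(
        default_factory=lambda: {
            "oligodendrocyte": {"MBP", "PLP1"},
            "astrocyte": {"ETNPPL"},
            "neuron": {"RBFOX3"},
            "immune": {"AIF1", "CD14", "CX3CR1", "PTPRC"},
        }
    )

    def __post_init__(self):
        for lineage, genes in self.lineages.items():
            if not genes:
                raise ValidationError(f"lineage {lineage!r} has an empty gene set")

    def all_genes(self) -> list[tuple[str, str]]:
        return [
            (lineage, gene)
            for lineage, genes in sorted(self.lineages.items())
            for gene in sorted(genes)
        ]


@dataclass
class StemLogicConfig:
    """Presence-based stem-like-cell rule on raw counts.

    A cell is stem-like iff any of ``any_of`` is expressed (> 0), the
    ``required`` gene is expressed, and the ``excluded`` gene is not.
    """

    any_of: set[str] = field(default_factory=lambda: {"FUT4", "L1CAM", "PROM1"})
    required: str = "SOX2"
    excluded: str = "TLR4"

    def __post_init__(self):
        named = set(self.any_of) | {self.required} | {self.excluded}
        if len(named) != len(self.any_of) + 2:
            raise ValidationError("stem-logic gene sets overlap")


def filter_neoplastic_clusters(
    norm: NormalizedMatrix,
    cluster_labels,
    panel: MarkerPanel | None = None,
    z_min: float = 2.0,
    frac_min: float = 0.5,
) -> tuple[set[str], pd.DataFrame]:
    """Exclude clusters dominated by differentiated-lineage markers.

    For each cluster and panel gene the rule computes (a) the z-score of
    the cluster's mean expression relative to all clusters' means and
    (b) the fraction of the cluster's cells expressing the gene (> 0).
    A cluster is excluded when any panel gene satisfies z >= ``z_min``
    and fraction >= ``frac_min``.  Returns the retained cell-id set and
    an exclusion report naming the triggering gene per excluded cluster.
    """
    panel = panel or MarkerPanel()
    y = np.asarray(
        cluster_labels.labels
        if hasattr(cluster_labels, "labels")
        else cluster_labels
    ).astype(str)
    if len(y) != norm.n_cells:
        raise ParameterError(f"{len(y)} labels for {norm.n_cells} cells")
    clusters = sorted(set(y))
    if len(clusters) < 2:
        raise ValidationError("need at least 2 clusters to compare")

    index = {g: i for i, g in enumerate(norm.gene_ids)}
    excluded: dict[str, tuple[str, str, float, float]] = {}
    for lineage, gene in panel.all_genes():
        row = index.get(gene)
        if row is None:
            warnings.warn(f"panel gene {gene!r} absent from matrix; skipped")
            continue
        expr = norm.values[row, :]
        means = np.array([expr[y == c].mean() for c in clusters])
        sd = means.std()  # across-cluster spread; ddof=0
        if sd == 0:
            continue
        z = (means - means.mean()) / sd
        for c, zc in zip(clusters, z):
            if c in excluded:
                continue
            frac = float(np.mean(expr[y == c] > 0))
            if zc >= z_min and frac >= frac_min:
                excluded[c] = (lineage, gene, float(zc), frac)

    report = pd.DataFrame(
        [
            {
                "cluster": c,
                "lineage": lineage,
                "trigger_gene": gene,
                "z": z,
                "expressing_fraction": frac,
            }
            for c, (lineage, gene, z, frac) in sorted(excluded.items())
        ],
        columns=["cluster", "lineage", "trigger_gene", "z", "expressing_fraction"],
    )
    retained = {
        cid for cid, cl in zip(norm.cell_ids, y) if cl not in excluded
    }
    logger.info(
        "filter_neoplastic_clusters: excluded %d/%d clusters",
        len(excluded),
        len(clusters),
    )
    return retained, report


def stem_like_mask(counts: CountMatrix, logic: StemLogicConfig | None = None):
    """Boolean per-cell mask of putative stem-like cells.

    Evaluates (any ``any_of`` gene > 0) and ``required`` > 0 and
    ``excluded`` == 0 on raw counts.  All named genes must be present;
    a missing gene is a hard error naming it.
    """
    logic = logic or StemLogicConfig()
    index = {g: i for i, g in enumerate(counts.gene_ids)}
    for gene in sorted(logic.any_of) + [logic.required, logic.excluded]:
        if gene not in index:
            raise ValidationError(f"stem-logic gene {gene!r} absent from the matrix")
    any_rows = [index[g] for g in sorted(logic.any_of)]
    any_expressed = (counts.values[any_rows, :] > 0).any(axis=0)
    required = counts.values[index[logic.required], :] > 0
    excluded = counts.values[index[logic.excluded], :] == 0
    return np.asarray(any_expressed & required & excluded)


def overlap_enrichment(universe, set_a, set_b) -> EnrichmentResult:
    """Hypergeometric over-enrichment of the overlap of two sets.

    ``set_a`` and ``set_b`` must be subsets of ``universe``; the test is
    P(X >= |A ∩ B|) with X hypergeometric(|U|, |A|, |B|).  Used both for
    cell sets (stem-like cells vs. a phase's cells) and gene sets
    (arrest-phenotype genes vs. cluster markers).
    """
    universe = set(universe)
    set_a = set(set_a)
    set_b = set(set_b)
    if not set_a <= universe:
        raise ParameterError("set_a is not a subset of the universe")
    if not set_b <= universe:
        raise ParameterError("set_b is not a subset of the universe")
    return hypergeometric_tail(
        len(universe), len(set_a), len(set_b), len(set_a & set_b)
    )


def consensus_markers(marker_tables: list[pd.DataFrame], phase: str) -> list[str]:
    """Genes called markers of ``phase`` in every table, sorted.

    Each table is a ``find_markers`` output; the result is the
    intersection of the per-table ``is_marker`` gene sets for the phase,
    in deterministic lexicographic order.
    """
    if not marker_tables:
        raise ParameterError("need at least one marker table")
    sets = []
    for i, table in enumerate(marker_tables):
        if phase not in set(table["cluster"].astype(str)):
            raise ParameterError(f"phase {phase!r} absent from marker table #{i}")
        sub = table[(table["cluster"].astype(str) == phase) & table["is_marker"]]
        sets.append(set(sub["gene"].astype(str)))
    common = set.intersection(*sets)
    return sorted(common)
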