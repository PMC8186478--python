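"""Phase medoids, the Canberra phase network, and marker discovery.

Each phase is summarized by its medoid -- the vector of mean normalized
expression of every gene across the phase's cells.  Pairwise Canberra
distances between medoids, thresholded at a cutoff, yield an undirected
network whose edges recover the order of cell-cycle progression (a
closed cycle has mean degree 2, which motivates the default
target-degree mode).  Marker genes per cluster come from one-vs-rest
Welch t-tests on normalized values with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .classifier import PhaseLabeling
from .errors import ParameterError, ValidationError
from .preprocess import NormalizedMatrix
from .stats import bh_adjust

logger = logging.getLogger("cycleclass")

DEFAULT_LOGFC_MIN = 0.3
DEFAULT_ALPHA = 0.05
DEFAULT_TARGET_DEGREE = 2.0

__all__ = [
    "MedoidNetwork",
    "canberra_distance",
    "phase_medoid_network",
    "find_markers",
    "DEFAULT_LOGFC_MIN",
    "DEFAULT_ALPHA",
]


def canberra_distance(x, y) -> float:
    """Canberra distance sum_i |x_i - y_i| / (|x_i| + |y_i|).

    Terms with a zero denominator (x_i = y_i = 0) are undefined by the
    formula and contribute 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("vectors differ in length")
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    mask = den > 0
    return float(np.sum(num[mask] / den[mask]))


@dataclass
class MedoidNetwork:
    """Per-phase medoids with their Canberra distance network.

    ``medoids`` is phases x genes; ``distances`` is a symmetric
    phase x phase DataFrame with zero diagonal; ``edges`` lists the
    unordered phase pairs whose distance is <= the cutoff ``tau``.
    """

    medoids: pd.DataFrame
    distances: pd.DataFrame
    edges: list[tuple[str, str]]
    tau: float
    mode: str

    @property
    def mean_degree(self) -> float:
        return 2.0 * len(self.edges) / len(self.medoids)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"phase_a": a, "phase_b": b, "distance": self.distances.loc[a, b]}
            for a, b in self.edges
        ]
        return pd.DataFrame(rows, columns=["phase_a", "phase_b", "distance"])


def _labels_array(labels) -> np.ndarray:
    y = labels.labels if isinstance(labels, PhaseLabeling) else labels
    return np.asarray(y).astype(str)


def phase_medoid_network(
    norm: NormalizedMatrix,
    labels,
    mode: str = "target_degree",
    tau: float | None = None,
    target_degree: float = DEFAULT_TARGET_DEGREE,
    genes: list[str] | None = None,
) -> MedoidNetwork:
    """Build the medoid similarity network between phases.

    In ``cutoff`` mode every phase pair at Canberra distance <= ``tau``
    becomes an edge.  In ``target_degree`` mode (default) the cutoff is
    the smallest observed pairwise distance for which the mean degree
    reaches ``target_degree`` (default 2.0, the degree of a closed
    cycle).  ``genes`` optionally restricts the medoid gene space (e.g.
    to the classifier features, for comparability).
    """
    y = _labels_array(labels)
    if len(y) != norm.n_cells:
        raise ParameterError(f"{len(y)} labels for {norm.n_cells} cells")

    values = norm.values
    gene_ids = list(norm.gene_ids)
    if genes is not None:
        index = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ParameterError(f"gene {missing[0]!r} not in the matrix")
        rows = [index[g] for g in genes]
        values = values[rows, :]
        gene_ids = list(genes)

    phases = sorted(set(y))
    if len(phases) < 2:
        raise ValidationError("need at least 2 phases to build a network")
    medoids = pd.DataFrame(
        np.vstack([values[:, y == p].mean(axis=1) for p in phases]),
        index=phases,
        columns=gene_ids,
    )

    dist = pd.DataFrame(0.0, index=phases, columns=phases)
    for i, a in enumerate(phases):
        for b in phases[i + 1 :]:
            d = canberra_distance(medoids.loc[a], medoids.loc[b])
            dist.loc[a, b] = dist.loc[b, a] = d

    pair_dists = [
        (float(dist.loc[a, b]), a, b)
        for i, a in enumerate(phases)
        for b in phases[i + 1 :]
    ]
    if mode == "cutoff":
        if tau is None:
            raise ParameterError("cutoff mode requires tau")
        chosen_tau = float(tau)
    elif mode == "target_degree":
        n_needed = int(np.ceil(target_degree * len(phases) / 2.0))
        ordered = sorted(d for d, _, _ in pair_dists)
        if n_needed > len(ordered):
            chosen_tau = ordered[-1]
        else:
            chosen_tau = ordered[max(0, n_needed - 1)]
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    edges = [(a, b) for d, a, b in pair_dists if d <= chosen_tau]
    return MedoidNetwork(
        medoids=medoids, distances=dist, edges=edges, tau=chosen_tau, mode=mode
    )


def find_markers(
    norm: NormalizedMatrix,
    labels,
    logfc_min: float = DEFAULT_LOGFC_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One-vs-rest marker discovery per cluster.

    For each cluster, a Welch (unequal-variance) t-test compares each
    gene's normalized expression in the cluster against all other cells;
    the average log fold-change is mean(in) - mean(out) in natural-log
    space.  P-values are Benjamini-Hochberg adjusted within each
    cluster's gene family, and ``is_marker`` requires both
    avg_logFC >= ``logfc_min`` and adjusted p <= ``alpha``.  Clusters
    whose in- or out-group has fewer than 2 cells are skipped (logged).
    """
    y = _labels_array(labels)
    if len(y) != norm.n_cells:
        raise ParameterError(f"{len(y)} labels for {norm.n_cells} cells")
    values = norm.values
    rows = []
    for cluster in sorted(set(y)):
        mask = y == cluster
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in < 2 or n_out < 2:
            logger.info(
                "find_markers: skipping cluster %r (in=%d, out=%d)",
                cluster,
                n_in,
                n_out,
            )
            continue
        a = values[:, mask]
        b = values[:, ~mask]
        logfc = a.mean(axis=1) - b.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical genes
        p_adj = bh_adjust(p)
        is_marker = (logfc >= logfc_min) & (p_adj <= alpha)
        for g, lf, pv, pa, m in zip(norm.gene_ids, logfc, p, p_adj, is_marker):
            rows.append(
                {
                    "cluster": cluster,
                    "gene": g,
                    "avg_logFC": float(lf),
                    "p": float(pv),
                    "p_adj": float(pa),
                    "is_marker": bool(m),
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "avg_logFC", "p", "p_adj", "is_marker"]
    )
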