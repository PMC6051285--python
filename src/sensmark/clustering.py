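"""Hierarchical clustering of marker matrices and plot-data exports.

Mutation profiles are clustered on pairwise Hamming distances (counts of
discordant positions) with average linkage; expression and copy number use
Ward's variance-minimizing criterion on Euclidean distances (the ward.D2
convention).  Exports are plain tables — merge lists, leaf-ordered heatmap
data, volcano and size/color scatter rows — so downstream plotting is
image-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .datatypes import DataType, GenomicsMatrix

log = logging.getLogger("sensmark")

#: volcano significance defaults
VOLCANO_P_MAX = 0.05
VOLCANO_EFFECT_MIN = 1.0


@dataclass
class ClusteringResult:
    axis: str                   # "features" or "samples"
    ids: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    leaf_order: list[str]
    metric: str                 # "hamming" or "euclidean_ward"

    def merge_table(self) -> pd.DataFrame:
        lm = self.linkage_matrix
        return pd.DataFrame(
            {
                "id1": lm[:, 0].astype(int),
                "id2": lm[:, 1].astype(int),
                "height": lm[:, 2],
                "size": lm[:, 3].astype(int),
            }
        )


def cluster(matrix: GenomicsMatrix, axis: str = "features") -> ClusteringResult:
    """Cluster one axis of the matrix with the data-type-appropriate metric."""
    if axis not in ("features", "samples"):
        raise ValueError("axis must be 'features' or 'samples'")
    X = matrix.values.to_numpy(float)
    ids = matrix.feature_ids if axis == "features" else matrix.sample_ids
    if axis == "samples":
        X = X.T
    if len(ids) < 2:
        return ClusteringResult(axis, ids, np.empty((0, 4)), list(ids), "trivial")
    if matrix.data_type is DataType.MUTATION:
        # Hamming as a count of discordant positions, average linkage
        dist = pdist(X, metric="hamming") * X.shape[1]
        lm = linkage(dist, method="average")
        metric = "hamming"
    else:
        lm = linkage(X, method="ward")  # Euclidean, ward.D2 criterion
        metric = "euclidean_ward"
    order = [ids[i] for i in leaves_list(lm)]
    return ClusteringResult(axis, list(ids), lm, order, metric)


def heatmap_data(matrix: GenomicsMatrix, row_zscore: bool = False) -> pd.DataFrame:
    """Matrix reordered by feature and sample dendrogram leaf orders."""
    vals = matrix.values
    if row_zscore:
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=0).replace(0, 1.0)
        vals = vals.sub(mu, axis=0).div(sd, axis=0)
        matrix = GenomicsMatrix(matrix.data_type, vals)
    feat = cluster(matrix, "features")
    samp = cluster(matrix, "samples")
    return vals.loc[feat.leaf_order, samp.leaf_order]


def volcano_data(
    table: pd.DataFrame,
    p_max: float = VOLCANO_P_MAX,
    effect_min_abs: float = VOLCANO_EFFECT_MIN,
) -> pd.DataFrame:
    """Per-gene (effect, -log10 p) rows with a significance flag.

    Default thresholds are p < 0.05 and |effect| > 1.
    """
    sig_up = (table["p_value"] < p_max) & (table["effect"] > effect_min_abs)
    sig_down = (table["p_value"] < p_max) & (table["effect"] < -effect_min_abs)
    flag = np.where(sig_up, "significant-up",
                    np.where(sig_down, "significant-down", ""))
    return pd.DataFrame(
        {
            "gene": table["gene"],
            "effect": table["effect"],
            "neg_log10_p": -np.log10(table["p_value"]),
            "significance": flag,
        }
    )


def scatter_data(
    expr: GenomicsMatrix, cn: GenomicsMatrix, genes, samples
) -> pd.DataFrame:
    """Long-format rows joining copy number (dot size) and expression (color).

    Values pass through unchanged; genes missing from either matrix are
    dropped with a warning.
    """
    genes = list(genes)
    samples = list(samples)
    shared = [g for g in genes if g in expr.values.index and g in cn.values.index]
    dropped = [g for g in genes if g not in shared]
    if dropped:
        log.warning("scatter: genes missing from a matrix, dropped: %s", dropped)
    shared_samples = [
        s for s in samples if s in expr.values.columns and s in cn.values.columns
    ]
    if not shared or not shared_samples:
        raise ValueError("no shared genes/samples between expression and copy number")
    rows = []
    for g in shared:
        for s in shared_samples:
            rows.append(
                {
                    "gene": g,
                    "sample": s,
                    "size": cn.values.at[g, s],
                    "color": expr.values.at[g, s],
                }
            )
    return pd.DataFrame(rows, columns=["gene", "sample", "size", "color"])
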