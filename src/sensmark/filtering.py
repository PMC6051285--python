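"""Stepwise complexity-reduction filtering applied before any marker engine.

Three stages run in a fixed order: (1) removal of genes constant across
samples (never/always mutated genes, single-category copy-number genes,
zero-variance expression genes); (2) an expression floor — a gene survives
only if its maximum log2 value across samples reaches a user-selectable
threshold; (3) a point-biserial Pearson correlation between each gene and the
Sensitive/Resistant contrast, removing genes with |r| below a cutoff
(default 0.1).  Each stage records what it removed in a FilterReport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import SENSITIVE, DataType, GenomicsMatrix, GroupLabels

DEFAULT_CORRELATION_CUTOFF = 0.1


@dataclass
class FilterConfig:
    expression_floor: float | None = None  # log2 units; None disables the stage
    correlation_cutoff: float = DEFAULT_CORRELATION_CUTOFF

    def __post_init__(self) -> None:
        if self.correlation_cutoff < 0:
            raise ValueError("correlation_cutoff must be >= 0")


@dataclass
class FilterReport:
    """Per-stage removal bookkeeping; counts reconcile exactly."""

    n_input: int = 0
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, removed: list[str]) -> None:
        self.stages.append({"stage": name, "n_removed": len(removed),
                            "removed": list(removed)})

    @property
    def n_removed(self) -> int:
        return sum(s["n_removed"] for s in self.stages)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s["stage"], "n_removed": s["n_removed"],
             "feature_ids": ",".join(s["removed"])}
            for s in self.stages
        ]
        rows.append({"stage": "retained", "n_removed": self.n_retained,
                     "feature_ids": ""})
        return pd.DataFrame(rows, columns=["stage", "n_removed", "feature_ids"])


def drop_invariant_features(
    matrix: GenomicsMatrix, report: FilterReport | None = None
) -> tuple[GenomicsMatrix, FilterReport]:
    """Remove genes constant across all samples, preserving gene order."""
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples to assess variation")
    report = report if report is not None else FilterReport(n_input=matrix.n_features)
    vals = matrix.values.to_numpy(float)
    constant = np.all(vals == vals[:, [0]], axis=1)
    removed = matrix.values.index[constant].tolist()
    report.add_stage("invariant", removed)
    return GenomicsMatrix(matrix.data_type, matrix.values.loc[~constant]), report


def expression_floor_filter(
    matrix: GenomicsMatrix, floor: float, report: FilterReport | None = None
) -> tuple[GenomicsMatrix, FilterReport]:
    """Drop genes never expressed above ``floor`` (max across samples < floor)."""
    if matrix.data_type is not DataType.EXPRESSION:
        raise TypeError("expression floor applies only to expression matrices")
    report = report if report is not None else FilterReport(n_input=matrix.n_features)
    keep = matrix.values.max(axis=1).to_numpy() >= floor
    removed = matrix.values.index[~keep].tolist()
    report.add_stage("floor", removed)
    return GenomicsMatrix(matrix.data_type, matrix.values.loc[keep]), report


def point_biserial(matrix: GenomicsMatrix, labels: GroupLabels) -> pd.Series:
    """Pearson correlation of each gene with the group contrast (Sensitive=1).

    Genes with zero variance get NaN.  Only |r| is ever used downstream, so
    the encoding choice cannot change results.
    """
    lab = labels.for_samples(matrix.sample_ids)
    if len(set(lab.labels)) < 2:
        raise ValueError("both Sensitive and Resistant labels are required")
    X = matrix.values[lab.sample_ids].to_numpy(float)
    y = (lab.labels == SENSITIVE).to_numpy(float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return pd.Series(r, index=matrix.values.index, name="point_biserial_r")


def point_biserial_filter(
    matrix: GenomicsMatrix,
    labels: GroupLabels,
    cutoff: float = DEFAULT_CORRELATION_CUTOFF,
    report: FilterReport | None = None,
) -> tuple[GenomicsMatrix, FilterReport]:
    """Remove genes with |point-biserial r| < cutoff or undefined r."""
    report = report if report is not None else FilterReport(n_input=matrix.n_features)
    r = point_biserial(matrix, labels)
    keep = (r.abs() >= cutoff) & r.notna()
    removed = matrix.values.index[~keep].tolist()
    report.add_stage("correlation", removed)
    return GenomicsMatrix(matrix.data_type, matrix.values.loc[keep]), report


def stepwise_filter(
    matrix: GenomicsMatrix, labels: GroupLabels, config: FilterConfig | None = None
) -> tuple[GenomicsMatrix, FilterReport]:
    """Run invariant -> floor -> correlation filtering with one shared report."""
    config = config or FilterConfig()
    if matrix.data_type is DataType.EXPRESSION:
        matrix = matrix.drop_na_features()
    report = FilterReport(n_input=matrix.n_features)
    matrix, report = drop_invariant_features(matrix, report)
    if config.expression_floor is not None and matrix.data_type is DataType.EXPRESSION:
        matrix, report = expression_floor_filter(matrix, config.expression_floor, report)
    matrix, report = point_biserial_filter(matrix, labels, config.correlation_cutoff, report)
    return matrix, report
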