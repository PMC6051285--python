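"""Stability elastic-net feature ranking.

The Sensitive/Resistant contrast is regressed on standardized features with
an elastic-net penalty, repeatedly (default 100 runs) over stratified
bootstrap resamples of the samples; the penalty strength is re-selected by
internal cross-validation inside every run.  A feature's rank is the
percentage of runs in which its coefficient is nonzero, accompanied by its
average coefficient over the runs where it was retained (sign preserved).
The procedure requires at least 4 samples in each group and is fully
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV, LogisticRegressionCV

from .datatypes import SENSITIVE, GenomicsMatrix, GroupLabels

MIN_GROUP_SIZE = 4


@dataclass
class EnetConfig:
    """Configuration of the stability elastic net.

    l1_ratio mixes lasso (1) and ridge (0) penalties; the per-run penalty
    strength is chosen on an ``n_alphas``-point grid by ``cv_folds``-fold
    cross-validation on the resample.  ``bootstrap=False`` with ``n_runs=1``
    degenerates to a single plain elastic-net fit.  ``family='logistic'``
    switches from the squared-error 0/1 regression to a penalized logistic
    fit.
    """

    n_runs: int = 100
    l1_ratio: float = 0.5
    n_alphas: int = 50
    cv_folds: int = 3
    bootstrap: bool = True
    family: str = "gaussian"  # or "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not (0 < self.l1_ratio <= 1):
            raise ValueError("l1_ratio must be in (0, 1]")
        if self.family not in ("gaussian", "logistic"):
            raise ValueError("family must be 'gaussian' or 'logistic'")


def _stratified_bootstrap(rng, s_idx, r_idx):
    """Resample within each class, preserving group sizes (>= 2 per class)."""
    while True:
        s = rng.choice(s_idx, size=len(s_idx), replace=True)
        r = rng.choice(r_idx, size=len(r_idx), replace=True)
        if len(np.unique(s)) >= 2 and len(np.unique(r)) >= 2:
            return np.concatenate([s, r])


def _fit_one(X, y, config: EnetConfig, random_state: int) -> np.ndarray:
    # standardize within the resample; constant columns get coefficient 0
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    if config.family == "gaussian":
        model = ElasticNetCV(
            l1_ratio=config.l1_ratio,
            alphas=config.n_alphas,  # grid size; sklearn derives the values
            cv=min(config.cv_folds, len(y)),
            max_iter=20000,
            random_state=random_state,
        )
        model.fit(Z, y)
        coef = model.coef_
    else:
        model = LogisticRegressionCV(
            penalty="elasticnet",
            solver="saga",
            l1_ratios=[config.l1_ratio],
            Cs=config.n_alphas,
            cv=min(config.cv_folds, len(y)),
            max_iter=20000,
            random_state=random_state,
        )
        model.fit(Z, y)
        coef = model.coef_.ravel()
    coef = coef.copy()
    coef[sd == 0] = 0.0
    return coef


def stability_elastic_net(
    matrix: GenomicsMatrix, labels: GroupLabels, config: EnetConfig | None = None
) -> pd.DataFrame:
    """Run the stability elastic net; returns an elastic_net marker table.

    Columns: gene, method, frequency_pct, mean_beta (average standardized
    coefficient over the runs where the gene was retained), n_runs.
    """
    config = config or EnetConfig()
    lab = labels.for_samples(matrix.sample_ids)
    ns, nr = len(lab.sensitive_ids), len(lab.resistant_ids)
    if ns < MIN_GROUP_SIZE or nr < MIN_GROUP_SIZE:
        raise ValueError(
            f"elastic net requires a minimum of {MIN_GROUP_SIZE} samples per "
            f"group (got Sensitive={ns}, Resistant={nr})"
        )
    if matrix.n_features == 0:
        raise ValueError("no features left after filtering")
    order = lab.sensitive_ids + lab.resistant_ids
    # canonical internal gene order so results are exactly invariant to the
    # caller's feature ordering (coordinate descent is order-sensitive at tol)
    gene_order = np.argsort(np.asarray(matrix.feature_ids))
    X = matrix.values[order].to_numpy(float).T[:, gene_order]  # samples x genes
    y = np.concatenate([np.ones(ns), np.zeros(nr)])
    s_idx = np.arange(ns)
    r_idx = np.arange(ns, ns + nr)
    rng = np.random.default_rng(config.seed)
    p = matrix.n_features
    nonzero_count = np.zeros(p)
    beta_sum = np.zeros(p)
    for _ in range(config.n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        if config.bootstrap:
            take = _stratified_bootstrap(rng, s_idx, r_idx)
        else:
            take = np.arange(ns + nr)
        coef = _fit_one(X[take], y[take], config, run_seed)
        sel = coef != 0
        nonzero_count += sel
        beta_sum += np.where(sel, coef, 0.0)
    inverse = np.empty_like(gene_order)
    inverse[gene_order] = np.arange(p)
    nonzero_count = nonzero_count[inverse]
    beta_sum = beta_sum[inverse]
    with np.errstate(invalid="ignore"):
        mean_beta = np.where(nonzero_count > 0, beta_sum / np.maximum(nonzero_count, 1), 0.0)
    freq = 100.0 * nonzero_count / config.n_runs
    out = pd.DataFrame(
        {
            "gene": matrix.feature_ids,
            "method": "elastic_net",
            "p_value": np.nan,
            "effect": mean_beta,
            "effect_type": "mean_beta",
            "frequency_pct": freq,
            "mean_beta": mean_beta,
            "n_runs": config.n_runs,
        }
    )
    return out


def filter_enet_markers(table: pd.DataFrame, frequency_min_pct: float) -> pd.DataFrame:
    """Keep genes retained in more than ``frequency_min_pct`` % of runs."""
    keep = table["frequency_pct"] > frequency_min_pct
    return (
        table.loc[keep]
        .sort_values(["frequency_pct", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
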