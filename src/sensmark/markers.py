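"""Differential-marker engines for the Sensitive vs Resistant contrast.

Four engines produce a per-gene marker table (a DataFrame with columns
``gene, method, p_value, effect, effect_type`` plus method-specific extras):

* ``anova_markers`` — one-way two-group ANOVA (identically t² of the pooled
  two-sample t) for expression or copy number; effect is the Sensitive minus
  Resistant mean difference, reported as log2FC on log2-scale expression.
* ``moderated_t_markers`` — empirical-Bayes moderated t for expression:
  per-gene residual variances are shrunk toward a pooled prior whose
  hyperparameters (d0, s0²) are estimated across genes by the method of
  moments on log sample variances.
* ``hypergeometric_markers`` — exact enrichment/depletion tails of the
  mutated-in-Sensitive count; two-sided p is twice the smaller tail, capped
  at 1.
* ``odds_ratio_markers`` — 2x2 odds ratio on log10 scale with the
  Haldane–Anscombe 0.5 correction when any cell is zero; the accompanying
  p-value is the hypergeometric one.

``filter_markers`` applies strict significance / effect-size thresholds and
sorts by ascending p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import DataType, GenomicsMatrix, GroupLabels

#: smallest reportable p-value — keeps p in (0, 1] even for infinite statistics
P_FLOOR = 1e-300

MARKER_COLUMNS = ["gene", "method", "p_value", "effect", "effect_type"]


def _split_groups(matrix: GenomicsMatrix, labels: GroupLabels):
    lab = labels.for_samples(matrix.sample_ids)
    s_ids, r_ids = lab.sensitive_ids, lab.resistant_ids
    if not s_ids or not r_ids:
        raise ValueError("both Sensitive and Resistant groups must be non-empty")
    Xs = matrix.values[s_ids].to_numpy(float)
    Xr = matrix.values[r_ids].to_numpy(float)
    return Xs, Xr


def anova_markers(matrix: GenomicsMatrix, labels: GroupLabels) -> pd.DataFrame:
    """One-way two-group ANOVA per gene (df 1, nS+nR-2)."""
    if matrix.data_type is DataType.MUTATION:
        raise TypeError("ANOVA applies to expression or copy-number matrices")
    Xs, Xr = _split_groups(matrix, labels)
    ns, nr = Xs.shape[1], Xr.shape[1]
    if ns < 2 or nr < 2:
        raise ValueError("ANOVA requires >= 2 samples per group")
    ms, mr = Xs.mean(axis=1), Xr.mean(axis=1)
    # between-group SS with 1 df; within-group SS with ns+nr-2 df
    grand = (Xs.sum(axis=1) + Xr.sum(axis=1)) / (ns + nr)
    ss_between = ns * (ms - grand) ** 2 + nr * (mr - grand) ** 2
    ss_within = ((Xs - ms[:, None]) ** 2).sum(axis=1) + ((Xr - mr[:, None]) ** 2).sum(axis=1)
    df_within = ns + nr - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_between / (ss_within / df_within)
    F = np.where(ss_between == 0, 0.0, F)  # identical means -> F = 0, p = 1
    p = stats.f.sf(F, 1, df_within)
    p = np.clip(p, P_FLOOR, 1.0)
    effect_type = "log2FC" if matrix.data_type is DataType.EXPRESSION else "mean_diff"
    return pd.DataFrame(
        {
            "gene": matrix.feature_ids,
            "method": "anova",
            "p_value": p,
            "effect": ms - mr,
            "effect_type": effect_type,
            "mean_sensitive": ms,
            "mean_resistant": mr,
            "F": F,
        }
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0²) for gene-wise variances.

    Fits a scaled inverse-chi-square prior to the observed sample variances
    via the mean and variance of log(s²); returns d0 = inf when the observed
    spread of log variances is no larger than expected from the chi-square
    sampling noise alone (complete shrinkage).
    """
    s2 = np.asarray(s2, float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all gene variances are zero; cannot estimate prior")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    target = evar - special.polygamma(1, df / 2.0)
    if target > 0:
        d0 = 2.0 * _trigamma_inverse(target)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_t_markers(
    matrix: GenomicsMatrix,
    labels: GroupLabels,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t per gene.

    ``prior_df`` overrides the estimated d0: 0 disables shrinkage (ordinary
    pooled t), ``inf`` shrinks completely to the prior variance with a
    normal-reference p-value.
    """
    if matrix.data_type is not DataType.EXPRESSION:
        raise TypeError("moderated t applies to expression matrices")
    if matrix.n_features < 2:
        raise ValueError("moderation pools across genes; need >= 2 genes")
    Xs, Xr = _split_groups(matrix, labels)
    ns, nr = Xs.shape[1], Xr.shape[1]
    if ns < 2 or nr < 2:
        raise ValueError("moderated t requires >= 2 samples per group")
    ms, mr = Xs.mean(axis=1), Xr.mean(axis=1)
    df = ns + nr - 2
    s2 = (((Xs - ms[:, None]) ** 2).sum(axis=1)
          + ((Xr - mr[:, None]) ** 2).sum(axis=1)) / df
    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0_sq = estimate_variance_prior(s2, df)[1] if d0 > 0 else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / ns + 1.0 / nr))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ms - mr) / se
    t = np.where((ms == mr) & (se == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "gene": matrix.feature_ids,
            "method": "moderated_t",
            "p_value": p,
            "effect": ms - mr,
            "effect_type": "log2FC",
            "mean_sensitive": ms,
            "mean_resistant": mr,
            "t": t,
            "prior_df": d0,
            "prior_var": s0_sq,
        }
    )


def _mutation_counts(matrix: GenomicsMatrix, labels: GroupLabels):
    if matrix.data_type is not DataType.MUTATION:
        raise TypeError("mutation engines require a binary mutation matrix")
    Xs, Xr = _split_groups(matrix, labels)
    a = Xs.sum(axis=1).astype(int)  # mutated & Sensitive
    b = Xr.sum(axis=1).astype(int)  # mutated & Resistant
    ns, nr = Xs.shape[1], Xr.shape[1]
    return a, b, ns, nr


def hypergeometric_markers(matrix: GenomicsMatrix, labels: GroupLabels) -> pd.DataFrame:
    """Exact hypergeometric enrichment/depletion test per mutated gene.

    With a mutated among the nS Sensitive, K mutated overall and N samples,
    the enrichment tail is P(X >= a) and the depletion tail P(X <= a) for
    X ~ Hypergeom(N, K, nS); the reported two-sided p is twice the smaller
    tail, capped at 1.
    """
    a, b, ns, nr = _mutation_counts(matrix, labels)
    N = ns + nr
    K = a + b
    p_enr = stats.hypergeom.sf(a - 1, N, K, ns)
    p_dep = stats.hypergeom.cdf(a, N, K, ns)
    p = np.minimum(1.0, 2.0 * np.minimum(p_enr, p_dep))
    p = np.clip(p, P_FLOOR, 1.0)
    frac_s = a / ns
    frac_r = b / nr
    direction = np.where(frac_s >= frac_r, "Sensitive-enriched", "Resistant-enriched")
    return pd.DataFrame(
        {
            "gene": matrix.feature_ids,
            "method": "hypergeometric",
            "p_value": p,
            "effect": frac_s - frac_r,
            "effect_type": "mutation_rate_diff",
            "a_mut_sensitive": a,
            "b_mut_resistant": b,
            "n_sensitive": ns,
            "n_resistant": nr,
            "p_enrichment": p_enr,
            "p_depletion": p_dep,
            "direction": direction,
        }
    )


def odds_ratio_markers(matrix: GenomicsMatrix, labels: GroupLabels) -> pd.DataFrame:
    """log10 odds ratio per mutated gene, 0.5-corrected when any cell is zero.

    The p-value column carries the companion hypergeometric test's p so the
    table supports the usual joint p / |log10 OR| filter.
    """
    a, b, ns, nr = _mutation_counts(matrix, labels)
    c = ns - a  # wild-type & Sensitive
    d = nr - b  # wild-type & Resistant
    cells = np.stack([a, b, c, d]).astype(float)
    zero = (cells == 0).any(axis=0)
    cells = cells + np.where(zero, 0.5, 0.0)
    orat = (cells[0] * cells[3]) / (cells[1] * cells[2])
    hyper = hypergeometric_markers(matrix, labels)
    return pd.DataFrame(
        {
            "gene": matrix.feature_ids,
            "method": "odds_ratio",
            "p_value": hyper["p_value"].to_numpy(),
            "effect": np.log10(orat),
            "effect_type": "log10_odds_ratio",
            "odds_ratio": orat,
            "a_mut_sensitive": a,
            "b_mut_resistant": b,
            "c_wt_sensitive": c,
            "d_wt_resistant": d,
            "zero_cell_corrected": zero,
        }
    )


def filter_markers(
    table: pd.DataFrame, p_max: float = 1.0, effect_min_abs: float = 0.0
) -> pd.DataFrame:
    """Keep rows with p_value < p_max and |effect| > effect_min_abs.

    Comparisons are strict; output is sorted by ascending p (ties broken by
    gene name for determinism).
    """
    if p_max < 0 or effect_min_abs < 0:
        raise ValueError("thresholds must be >= 0")
    keep = (table["p_value"] < p_max) & (table["effect"].abs() > effect_min_abs)
    out = table.loc[keep].sort_values(
        ["p_value", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    return out
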