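"""Association of predicted Sensitive/Resistant labels with clinical annotations.

Continuous variables are compared by a two-sided Mann–Whitney test (exact
null distribution when both groups have <= 8 observations and no ties, the
tie-corrected normal approximation otherwise); categorical variables by a
Pearson chi-square test on the R x 2 contingency table without continuity
correction; survival by the two-group log-rank test with Kaplan–Meier step
coordinates exported for plotting.  Variables are ranked by raw p-value
(the primary ordering), with Benjamini–Hochberg q-values appended as an
extra column.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    RESISTANT,
    SENSITIVE,
    ClinicalAnnotationTable,
    GroupLabels,
    VariableType,
)

log = logging.getLogger("sensmark")

ASSOCIATION_COLUMNS = ["variable", "test", "p_value", "bh_qvalue", "summary_json", "flags"]

EXACT_MW_MAX_N = 8


def _aligned_groups(values: pd.Series, labels: GroupLabels):
    """Split one annotation column by predicted group, dropping missing values."""
    common = values.index.intersection(labels.labels.index)
    vals = values.loc[common]
    n_missing = int(vals.isna().sum())
    if n_missing:
        log.warning("variable %r: dropping %d missing value(s)", values.name, n_missing)
    vals = vals.dropna()
    lab = labels.labels.loc[vals.index]
    return vals[lab == SENSITIVE], vals[lab == RESISTANT]


def associate_continuous(values: pd.Series, labels: GroupLabels) -> dict | None:
    """Two-sided Mann–Whitney row for one continuous variable, or None if
    one predicted group is empty after missing-value removal."""
    s, r = _aligned_groups(pd.to_numeric(values, errors="coerce"), labels)
    if len(s) == 0 or len(r) == 0:
        log.warning("variable %r skipped: a predicted group is empty", values.name)
        return None
    has_ties = len(np.unique(np.concatenate([s, r]))) < len(s) + len(r)
    exact = max(len(s), len(r)) <= EXACT_MW_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        s, r, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    summary = {
        "n_sensitive": int(len(s)),
        "n_resistant": int(len(r)),
        "mean_sensitive": float(s.mean()),
        "mean_resistant": float(r.mean()),
        "median_sensitive": float(s.median()),
        "median_resistant": float(r.median()),
        "U": float(res.statistic),
    }
    return {
        "variable": values.name,
        "test": "mann_whitney",
        "p_value": min(float(res.pvalue), 1.0),
        "summary_json": json.dumps(summary),
        "flags": "exact" if exact else "asymptotic",
    }


def associate_categorical(values: pd.Series, labels: GroupLabels) -> dict | None:
    """Pearson chi-square row for one categorical variable (R x 2 table)."""
    s, r = _aligned_groups(values.astype("object").where(values.notna()), labels)
    if len(s) == 0 or len(r) == 0:
        log.warning("variable %r skipped: a predicted group is empty", values.name)
        return None
    cats = sorted(set(s) | set(r), key=str)
    if len(cats) < 2:
        log.warning("variable %r skipped: a single category present", values.name)
        return None
    table = np.array(
        [[(s == c).sum(), (r == c).sum()] for c in cats], dtype=float
    )
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    flags = "low_expected_count" if (expected < 5).any() else ""
    summary = {
        "categories": [str(c) for c in cats],
        "counts_sensitive": [int(x) for x in table[:, 0]],
        "counts_resistant": [int(x) for x in table[:, 1]],
        "chi2": float(chi2),
        "df": int(dof),
    }
    return {
        "variable": values.name,
        "test": "chi_square",
        "p_value": min(float(p), 1.0) if p > 0 else 1e-300,
        "summary_json": json.dumps(summary),
        "flags": flags,
    }


def associate_survival(
    time: pd.Series, event: pd.Series, labels: GroupLabels
) -> tuple[dict | None, pd.DataFrame | None]:
    """Two-group log-rank row plus Kaplan–Meier step coordinates.

    Returns (row, km_frame); both are None when the test is degenerate (a
    group empty, or no events anywhere).
    """
    df = pd.DataFrame(
        {
            "time": pd.to_numeric(time, errors="coerce"),
            "event": pd.to_numeric(event, errors="coerce"),
        }
    ).dropna()
    common = df.index.intersection(labels.labels.index)
    df = df.loc[common]
    lab = labels.labels.loc[df.index]
    s_mask = (lab == SENSITIVE).to_numpy()
    r_mask = (lab == RESISTANT).to_numpy()
    if s_mask.sum() == 0 or r_mask.sum() == 0:
        log.warning("survival variable %r skipped: a group is empty", time.name)
        return None, None
    if df["event"].sum() == 0:
        log.warning("survival variable %r skipped: no events observed", time.name)
        return None, None
    res = logrank_test(
        df["time"][s_mask], df["time"][r_mask],
        event_observed_A=df["event"][s_mask],
        event_observed_B=df["event"][r_mask],
    )
    km_rows = []
    for name, mask in ((SENSITIVE, s_mask), (RESISTANT, r_mask)):
        kmf = KaplanMeierFitter()
        kmf.fit(df["time"][mask], df["event"][mask])
        sf = kmf.survival_function_
        for t, p_surv in zip(sf.index, sf.iloc[:, 0]):
            km_rows.append({"group": name, "time": float(t), "survival": float(p_surv)})
    summary = {
        "n_sensitive": int(s_mask.sum()),
        "n_resistant": int(r_mask.sum()),
        "events_sensitive": int(df["event"][s_mask].sum()),
        "events_resistant": int(df["event"][r_mask].sum()),
        "chi2": float(res.test_statistic),
    }
    row = {
        "variable": time.name,
        "test": "log_rank",
        "p_value": min(float(res.p_value), 1.0),
        "summary_json": json.dumps(summary),
        "flags": "",
    }
    return row, pd.DataFrame(km_rows, columns=["group", "time", "survival"])


def rank_associations(rows: list[dict]) -> pd.DataFrame:
    """Sort rows by ascending raw p (ties by variable name) and append BH q."""
    if not rows:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    df = pd.DataFrame(rows)
    qvals = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["bh_qvalue"] = qvals
    df = df.sort_values(["p_value", "variable"], kind="mergesort").reset_index(drop=True)
    return df[ASSOCIATION_COLUMNS]


def associate_all(
    clinical: ClinicalAnnotationTable, labels: GroupLabels
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Test every declared variable against the predicted groups.

    Returns the ranked association table and a dict of KM step frames keyed
    by survival variable name.
    """
    rows: list[dict] = []
    km_frames: dict[str, pd.DataFrame] = {}
    for name, vtype in clinical.variable_types.items():
        if name not in clinical.data.columns:
            continue
        col = clinical.data[name]
        if vtype is VariableType.CONTINUOUS:
            row = associate_continuous(col, labels)
        elif vtype is VariableType.CATEGORICAL:
            row = associate_categorical(col, labels)
        elif vtype is VariableType.SURVIVAL_TIME:
            event_col = clinical.event_column_for(name)
            row, km = associate_survival(col, clinical.data[event_col], labels)
            if km is not None:
                km_frames[name] = km
        else:  # survival_event columns are consumed by their time column
            continue
        if row is not None:
            rows.append(row)
    return rank_associations(rows), km_frames
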