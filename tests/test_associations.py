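"""Clinical association tests against enumeration and closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sensmark import (
    associate_categorical,
    associate_continuous,
    associate_survival,
    rank_associations,
)

from conftest import make_labels


def series(vals, name="var", ids=None):
    ids = ids or [f"s{i}" for i in range(len(vals))]
    return pd.Series(vals, index=ids, name=name)


def mw_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumeration over all assignments."""
    pooled = list(x) + list(y)
    nx = len(x)

    def ustat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = ustat(x, y)
    mu = nx * len(y) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = ustat(xs, ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_worked_example_exact(self, labels_3v3):
        # S=(1,2,3), R=(4,5,6): U = 0, exact two-sided p = 2*2/20 = 0.1
        row = associate_continuous(series([1, 2, 3, 4, 5, 6], "age"), labels_3v3)
        assert row["p_value"] == pytest.approx(0.1, abs=1e-9)
        assert row["p_value"] == pytest.approx(
            mw_exact_oracle([1, 2, 3], [4, 5, 6]), abs=1e-9
        )
        assert row["flags"] == "exact"

    def test_identical_multisets_p1(self, labels_3v3):
        row = associate_continuous(series([5, 6, 7, 5, 6, 7], "age"), labels_3v3)
        assert row["p_value"] == pytest.approx(1.0)

    def test_exact_matches_enumeration_random(self, labels_3v3):
        rng = np.random.default_rng(0)
        for _ in range(5):
            vals = rng.normal(size=6).round(3)
            row = associate_continuous(series(vals, "v"), labels_3v3)
            assert row["p_value"] == pytest.approx(
                mw_exact_oracle(vals[:3], vals[3:]), abs=1e-9
            )

    def test_asymptotic_close_to_exact_at_8v8(self):
        rng = np.random.default_rng(1)
        labs = make_labels(["Sensitive"] * 8 + ["Resistant"] * 8,
                           samples=[f"s{i}" for i in range(16)])
        vals = rng.normal(size=16)
        row = associate_continuous(series(vals, "v"), labs)  # exact path (n<=8)
        approx = stats.mannwhitneyu(vals[:8], vals[8:], alternative="two-sided",
                                    method="asymptotic").pvalue
        assert row["flags"] == "exact"
        assert abs(row["p_value"] - approx) < 0.02

    def test_monotone_transform_invariance(self, labels_3v3):
        vals = [0.3, 2.2, 1.1, 5.0, 4.1, 3.3]
        p1 = associate_continuous(series(vals, "v"), labels_3v3)["p_value"]
        p2 = associate_continuous(series(np.exp(vals), "v"), labels_3v3)["p_value"]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_skipped(self):
        labs = make_labels(["Sensitive", "Sensitive"])
        vals = series([np.nan, 1.0], "v")
        assert associate_continuous(vals, labs) is None


class TestChiSquare:
    def _labels_for(self, counts_s, counts_r, cats):
        vals, labels = [], []
        for c, ns_, nr_ in zip(cats, counts_s, counts_r):
            vals += [c] * (ns_ + nr_)
            labels += ["Sensitive"] * ns_ + ["Resistant"] * nr_
        ids = [f"s{i}" for i in range(len(vals))]
        return series(vals, "grade", ids), make_labels(labels, ids)

    def test_diagonal_table(self):
        vals, labs = self._labels_for([10, 0], [0, 10], ["A", "B"])
        row = associate_categorical(vals, labs)
        assert row is not None
        # Pearson chi2 on [[10,0],[0,10]] = 20, df 1
        assert row["p_value"] == pytest.approx(stats.chi2.sf(20, 1), rel=1e-9)
        assert row["p_value"] == pytest.approx(7.7e-6, rel=0.01)

    def test_proportional_table_p1(self):
        vals, labs = self._labels_for([4, 8], [2, 4], ["A", "B"])
        row = associate_categorical(vals, labs)
        assert row["p_value"] == pytest.approx(1.0)

    def test_4x2_matches_direct_formula(self):
        counts_s, counts_r = [5, 3, 8, 2], [2, 6, 4, 7]
        vals, labs = self._labels_for(counts_s, counts_r, list("ABCD"))
        row = associate_categorical(vals, labs)
        obs = np.array([counts_s, counts_r], float).T
        tot = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / tot
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert row["p_value"] == pytest.approx(stats.chi2.sf(chi2, 3), rel=1e-9)

    def test_single_category_skipped(self):
        vals, labs = self._labels_for([5], [5], ["A"])
        assert associate_categorical(vals, labs) is None

    def test_low_expected_count_flagged(self):
        vals, labs = self._labels_for([3, 1], [1, 2], ["A", "B"])
        assert associate_categorical(vals, labs)["flags"] == "low_expected_count"


def logrank_oracle(times, events, group):
    """Hand-computed observed-minus-expected log-rank chi-square (1 df)."""
    df = pd.DataFrame({"t": times, "e": events, "g": group})
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(df.loc[df.e == 1, "t"].unique()):
        at_risk = df[df.t >= t]
        n = len(at_risk)
        n1 = (at_risk.g == 1).sum()
        d = ((df.t == t) & (df.e == 1)).sum()
        d1 = ((df.t == t) & (df.e == 1) & (df.g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_p1(self, labels_3v3):
        t = series([5, 10, 15, 5, 10, 15], "os")
        e = series([1, 1, 0, 1, 1, 0], "os_event")
        row, km = associate_survival(t, e, labels_3v3)
        assert row["p_value"] == pytest.approx(1.0)
        assert set(km["group"]) == {"Sensitive", "Resistant"}

    def test_six_subject_hand_example(self, labels_3v3):
        times = [2, 5, 8, 1, 4, 9]
        events = [1, 1, 0, 1, 1, 1]
        row, _ = associate_survival(series(times, "os"),
                                    series(events, "ev"), labels_3v3)
        chi2 = logrank_oracle(times, events, [1, 1, 1, 0, 0, 0])
        assert json_chi2(row) == pytest.approx(chi2, abs=1e-9)
        assert row["p_value"] == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-9)

    def test_all_censored_skipped(self, labels_3v3):
        t = series([5, 10, 15, 4, 8, 12], "os")
        e = series([0, 0, 0, 0, 0, 0], "ev")
        row, km = associate_survival(t, e, labels_3v3)
        assert row is None and km is None

    def test_km_curves_are_step_functions(self, labels_3v3):
        t = series([2, 5, 8, 1, 4, 9], "os")
        e = series([1, 1, 0, 1, 1, 1], "ev")
        _, km = associate_survival(t, e, labels_3v3)
        for _, grp in km.groupby("group"):
            surv = grp.sort_values("time")["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()
            assert surv[0] == pytest.approx(1.0)


def json_chi2(row):
    import json

    return json.loads(row["summary_json"])["chi2"]


class TestRanking:
    def _rows(self, ps):
        return [
            {"variable": f"v{i}", "test": "mann_whitney", "p_value": p,
             "summary_json": "{}", "flags": ""}
            for i, p in enumerate(ps)
        ]

    def test_sorted_ascending_by_p(self):
        table = rank_associations(self._rows([0.5, 0.001, 0.04]))
        assert table["p_value"].tolist() == [0.001, 0.04, 0.5]

    def test_bh_by_hand(self):
        table = rank_associations(self._rows([0.001, 0.04, 0.5]))
        # BH: 0.001*3/1=0.003, 0.04*3/2=0.06, 0.5*3/3=0.5
        assert table["bh_qvalue"].tolist() == pytest.approx([0.003, 0.06, 0.5])

    def test_ties_broken_by_variable_name(self):
        rows = self._rows([0.1, 0.1, 0.05])
        table = rank_associations(rows)
        assert table["variable"].tolist() == ["v2", "v0", "v1"]

    def test_label_swap_leaves_p_unchanged(self, labels_3v3):
        vals = series([1.0, 3.0, 2.0, 6.0, 4.0, 5.0], "v")
        p1 = associate_continuous(vals, labels_3v3)["p_value"]
        p2 = associate_continuous(vals, labels_3v3.swapped())["p_value"]
        assert p1 == pytest.approx(p2, abs=1e-12)
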