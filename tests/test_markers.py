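"""Marker engines against closed-form and brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sensmark import (
    DataType,
    anova_markers,
    filter_markers,
    hypergeometric_markers,
    moderated_t_markers,
    odds_ratio_markers,
)
from sensmark.markers import estimate_variance_prior

from conftest import make_labels, make_matrix


def pooled_t_oracle(xs, xr):
    """Ordinary two-sample pooled-variance t (independent oracle)."""
    ns, nr = len(xs), len(xr)
    sp2 = ((ns - 1) * np.var(xs, ddof=1) + (nr - 1) * np.var(xr, ddof=1)) / (ns + nr - 2)
    return (np.mean(xs) - np.mean(xr)) / math.sqrt(sp2 * (1 / ns + 1 / nr))


class TestAnova:
    def test_worked_example(self, labels_3v3):
        # S=(1,2,3), R=(4,5,6): t = -3/sqrt(1*(2/3)), F = t^2 = 13.5
        m = make_matrix([[1, 2, 3, 4, 5, 6]], genes=["g"])
        table = anova_markers(m, labels_3v3)
        t = pooled_t_oracle([1, 2, 3], [4, 5, 6])
        assert table["F"][0] == pytest.approx(13.5, abs=1e-9)
        assert table["F"][0] == pytest.approx(t**2, abs=1e-9)
        assert table["p_value"][0] == pytest.approx(stats.f.sf(13.5, 1, 4), abs=1e-9)
        assert table["p_value"][0] == pytest.approx(0.0213, abs=5e-4)
        assert table["effect"][0] == pytest.approx(-3.0)

    def test_identical_means_give_f0_p1(self, labels_2v2):
        m = make_matrix([[1.0, 3.0, 3.0, 1.0]], genes=["g"])
        table = anova_markers(m, labels_2v2)
        assert table["F"][0] == 0.0
        assert table["p_value"][0] == 1.0

    def test_f_equals_t_squared_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 11))
        labs = make_labels(["Sensitive"] * 5 + ["Resistant"] * 6,
                           samples=[f"s{i}" for i in range(11)])
        table = anova_markers(make_matrix(X), labs)
        for i in range(60):
            t = pooled_t_oracle(X[i, :5], X[i, 5:])
            assert table["F"][i] == pytest.approx(t**2, rel=1e-10)

    def test_small_group_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        labs = make_labels(["Sensitive", "Resistant", "Resistant"])
        with pytest.raises(ValueError):
            anova_markers(m, labs)

    def test_label_swap_negates_effect_keeps_p(self, labels_3v3):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(25, 6)))
        t1 = anova_markers(m, labels_3v3)
        t2 = anova_markers(m, labels_3v3.swapped())
        np.testing.assert_allclose(t1["effect"], -t2["effect"], rtol=1e-12)
        np.testing.assert_allclose(t1["p_value"], t2["p_value"], rtol=1e-12)


def eb_moderated_oracle(X, ns, nr):
    """Independent empirical-Bayes moderated-t implementation (loop form)."""
    from scipy.special import digamma, polygamma

    ms = X[:, :ns].mean(axis=1)
    mr = X[:, ns:].mean(axis=1)
    df = ns + nr - 2
    s2 = np.array(
        [
            (np.sum((X[g, :ns] - ms[g]) ** 2) + np.sum((X[g, ns:] - mr[g]) ** 2)) / df
            for g in range(X.shape[0])
        ]
    )
    z = np.log(s2)
    e = z - digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1)
    target = evar - polygamma(1, df / 2)
    if target > 0:
        # invert trigamma by bisection (deliberately different from the
        # package's Newton solver)
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if polygamma(1, mid) > target:
                lo = mid
            else:
                hi = mid
        d0 = 2 * mid
        s0 = math.exp(np.mean(e) + digamma(d0 / 2) - math.log(d0 / 2))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_tot = d0 + df
        tstat = (ms - mr) / np.sqrt(s2_post * (1 / ns + 1 / nr))
        p = 2 * stats.t.sf(np.abs(tstat), df_tot)
    else:
        s0 = math.exp(np.mean(e))
        tstat = (ms - mr) / np.sqrt(s0 * (1 / ns + 1 / nr))
        p = 2 * stats.norm.sf(np.abs(tstat))
    return tstat, p


class TestModeratedT:
    def test_no_shrinkage_equals_pooled_t(self, labels_3v3):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        table = moderated_t_markers(make_matrix(X), labels_3v3, prior_df=0)
        for i in range(30):
            t = pooled_t_oracle(X[i, :3], X[i, 3:])
            assert table["t"][i] == pytest.approx(t, rel=1e-10)
            assert table["p_value"][i] == pytest.approx(
                2 * stats.t.sf(abs(t), 4), rel=1e-10
            )

    def test_matches_independent_eb_oracle(self):
        rng = np.random.default_rng(3)
        # heterogeneous gene variances so shrinkage is non-trivial
        sds = rng.uniform(0.3, 3.0, 50)
        X = rng.normal(size=(50, 10)) * sds[:, None]
        labs = make_labels(["Sensitive"] * 5 + ["Resistant"] * 5,
                           samples=[f"s{i}" for i in range(10)])
        table = moderated_t_markers(make_matrix(X), labs)
        t_or, p_or = eb_moderated_oracle(X, 5, 5)
        np.testing.assert_allclose(table["t"], t_or, atol=1e-6)
        np.testing.assert_allclose(table["p_value"], p_or, atol=1e-6)

    def test_logfc_is_difference_of_log2_means(self, labels_2v2):
        m = make_matrix([[6.0, 6.0, 2.0, 2.0], [1.0, 2.0, 1.5, 2.5]])
        table = moderated_t_markers(m, labels_2v2)
        assert table["effect"][0] == pytest.approx(4.0)

    def test_all_zero_variance_is_estimation_error(self, labels_2v2):
        m = make_matrix([[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 4.0, 4.0]])
        with pytest.raises(ValueError):
            moderated_t_markers(m, labels_2v2)

    def test_complete_shrinkage_uses_normal_reference(self, labels_3v3):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        table = moderated_t_markers(make_matrix(X), labels_3v3, prior_df=np.inf)
        expected = 2 * stats.norm.sf(np.abs(table["t"]))
        np.testing.assert_allclose(table["p_value"], expected, rtol=1e-12)


def hypergeom_tail_oracle(N, K, n, a):
    """Brute-force tail sums of the hypergeometric pmf."""

    def pmf(x):
        return (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)

    lo = max(0, n - (N - K))
    hi = min(K, n)
    p_ge = sum(pmf(x) for x in range(max(a, lo), hi + 1))
    p_le = sum(pmf(x) for x in range(lo, min(a, hi) + 1))
    return p_ge, p_le


class TestHypergeometric:
    def test_worked_example(self):
        # N=10, K=4, nS=5, a=4: P(X>=4) = C(4,4)C(6,1)/C(10,5) = 6/252
        mut = np.zeros((1, 10), int)
        mut[0, :4] = 1  # 4 mutated, all Sensitive
        labs = make_labels(["Sensitive"] * 5 + ["Resistant"] * 5,
                           samples=[f"s{i}" for i in range(10)])
        table = hypergeometric_markers(make_matrix(mut, DataType.MUTATION), labs)
        assert table["p_enrichment"][0] == pytest.approx(6 / 252, abs=1e-12)
        assert table["direction"][0] == "Sensitive-enriched"

    def test_two_sided_capped_at_one(self):
        # a at its expectation in a symmetric design
        mut = np.array([[1, 0, 1, 0]])
        table = hypergeometric_markers(
            make_matrix(mut, DataType.MUTATION),
            make_labels(["Sensitive", "Sensitive", "Resistant", "Resistant"]),
        )
        assert table["p_value"][0] == 1.0

    def test_tails_match_bruteforce_all_small_tables(self):
        for N in (6, 10, 16, 20):
            for ns in (2, N // 2, N - 2):
                labs = make_labels(
                    ["Sensitive"] * ns + ["Resistant"] * (N - ns),
                    samples=[f"s{i}" for i in range(N)],
                )
                for K in range(0, N + 1, 3):
                    for a in range(0, min(K, ns) + 1):
                        if K - a > N - ns:
                            continue
                        row = np.zeros(N, int)
                        row[:a] = 1
                        row[ns:ns + (K - a)] = 1
                        table = hypergeometric_markers(
                            make_matrix(row[None, :], DataType.MUTATION), labs
                        )
                        p_ge, p_le = hypergeom_tail_oracle(N, K, ns, a)
                        assert table["p_enrichment"][0] == pytest.approx(p_ge, abs=1e-9)
                        assert table["p_depletion"][0] == pytest.approx(p_le, abs=1e-9)

    def test_non_binary_input_rejected(self, labels_2v2):
        m = make_matrix([[1.0, 0.5, 0.0, 0.0]])
        with pytest.raises(TypeError):
            hypergeometric_markers(m, labels_2v2)


class TestOddsRatio:
    def _table_for(self, a, b, c, d):
        row = [1] * a + [0] * c + [1] * b + [0] * d
        labs = make_labels(
            ["Sensitive"] * (a + c) + ["Resistant"] * (b + d),
            samples=[f"s{i}" for i in range(a + b + c + d)],
        )
        m = make_matrix(np.array(row)[None, :], DataType.MUTATION,
                        samples=labs.sample_ids)
        return odds_ratio_markers(m, labs)

    def test_closed_form(self):
        t = self._table_for(4, 1, 1, 4)
        assert t["odds_ratio"][0] == pytest.approx(16.0)
        assert t["effect"][0] == pytest.approx(np.log10(16.0), abs=1e-9)

    def test_haldane_correction_on_zero_cell(self):
        t = self._table_for(3, 0, 1, 4)
        assert t["odds_ratio"][0] == pytest.approx((3.5 * 4.5) / (0.5 * 1.5))
        assert t["effect"][0] == pytest.approx(np.log10(21.0), abs=1e-9)
        assert bool(t["zero_cell_corrected"][0])

    def test_no_association_gives_log_or_zero(self):
        t = self._table_for(2, 2, 3, 3)
        assert t["effect"][0] == pytest.approx(0.0, abs=1e-12)

    def test_p_column_is_hypergeometric_companion(self, panel):
        mut, labs = panel["mutation"], panel["labels"]
        np.testing.assert_allclose(
            odds_ratio_markers(mut, labs)["p_value"],
            hypergeometric_markers(mut, labs)["p_value"],
        )

    def test_label_swap_negates_log_or(self, panel):
        mut, labs = panel["mutation"], panel["labels"]
        t1 = odds_ratio_markers(mut, labs)
        t2 = odds_ratio_markers(mut, labs.swapped())
        np.testing.assert_allclose(t1["effect"], -t2["effect"], atol=1e-12)
        np.testing.assert_allclose(t1["p_value"], t2["p_value"], atol=1e-12)


class TestFilterMarkers:
    def test_strict_thresholds(self):
        table = pd.DataFrame(
            {"gene": ["a", "b"], "method": "anova",
             "p_value": [1e-5, 1e-3], "effect": [2.0, 2.0],
             "effect_type": "log2FC"}
        )
        out = filter_markers(table, p_max=1e-4, effect_min_abs=1.5)
        assert out["gene"].tolist() == ["a"]

    def test_identity_thresholds_sort_by_p(self):
        table = pd.DataFrame(
            {"gene": ["a", "b", "c"], "method": "anova",
             "p_value": [0.5, 0.001, 0.04], "effect": [1.0, 1.0, 1.0],
             "effect_type": "log2FC"}
        )
        out = filter_markers(table, p_max=1.0, effect_min_abs=0.0)
        assert out["gene"].tolist() == ["b", "c", "a"]

    def test_paper_style_thresholds_expressible(self, panel):
        table = anova_markers(panel["expression"], panel["labels"])
        out = filter_markers(table, p_max=1e-4, effect_min_abs=1.5)
        assert (out["p_value"] < 1e-4).all()
        assert (out["effect"].abs() > 1.5).all()
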