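"""Association tests, BH, enrichment and per-sample signature scores."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rbsubtyper as rb
from rbsubtyper.matrix import OmicsMatrix


def _mat(arr, features=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr, index=features, columns=samples),
                       "expression")


def fisher_oracle(table):
    """Exact-fraction enumeration of the two-sided Fisher p-value."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestContingencyTests:
    # clinical contingency tables of the retinoblastoma cohort with the
    # p-values they are known to produce (chi-squared, no correction)
    @pytest.mark.parametrize("table,expected", [
        ([[12, 4], [26, 54]], 1.506e-3),       # laterality x subtype
        ([[14, 6], [17, 44]], 7.681e-4),       # RB1 germline mutation
        ([[7, 31], [19, 11], [6, 7]], 7.332e-4),  # growth pattern
        ([[18, 40], [16, 12]], 0.0203),        # necrosis
        ([[17, 31], [21, 27]], 0.4038),        # sex
    ])
    def test_cohort_chi2_pvalues(self, table, expected):
        _, _, p = rb.chi2_test(table)
        assert p == pytest.approx(expected, rel=5e-3)

    def test_chi2_balanced_table_stat_zero(self):
        stat, df, p = rb.chi2_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0 and df == 1

    def test_chi2_growth_pattern_df(self):
        _, df, _ = rb.chi2_test([[7, 31], [19, 11], [6, 7]])
        assert df == 2

    def test_chi2_zero_margin_errors(self):
        with pytest.raises(ValueError):
            rb.chi2_test([[0, 0], [5, 5]])

    @pytest.mark.parametrize("table,expected", [
        ([[5, 14], [3, 90]], 0.003428),   # optic-nerve margin (stage II)
        ([[4, 15], [2, 91]], 0.007394),   # pre-enucleation chemotherapy
        ([[4, 7], [9, 83]], 0.0312),      # massive choroidal invasion
    ])
    def test_metastatic_series_fisher_pvalues(self, table, expected):
        assert rb.fisher_exact_2x2(table) == pytest.approx(expected, rel=5e-3)

    def test_fisher_balanced_table_is_one(self):
        assert rb.fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(
            1.0, abs=1e-12)

    def test_fisher_agrees_with_enumeration_oracle(self, rng):
        for _ in range(300):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum() == 0:
                continue
            assert rb.fisher_exact_2x2(t) == pytest.approx(
                fisher_oracle(t.tolist()), abs=1e-10)

    def test_fisher_negative_count_errors(self):
        with pytest.raises(ValueError):
            rb.fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_kruskal_identical_values(self):
        with pytest.warns(UserWarning):
            H, df, p = rb.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert H == 0.0 and p == 1.0

    def test_kruskal_matches_permutation_oracle(self, rng):
        a = [1.2, 3.4, 2.2, 5.1, 0.3, 2.8]
        b = [4.0, 6.1, 5.5, 7.2, 3.9, 6.6]
        H, _, p = rb.kruskal_wallis([a, b])
        pooled = np.array(a + b)
        n_perm, hits = 20000, 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            Hp, _ = stats.kruskal(perm[:6], perm[6:])
            hits += Hp >= H - 1e-12
        assert p == pytest.approx(hits / n_perm, abs=0.01)

    def test_kruskal_power_under_shift(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 20)
            b = rng.normal(2, 1, 20)
            _, _, p = rb.kruskal_wallis([a, b])
            hits += p < 0.05
        assert hits / 100 >= 0.9


class TestBhAndEnrichment:
    def test_stepup_arithmetic(self):
        out = rb.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_values(self):
        assert rb.bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(rb.bh_adjust([0.3, 0.3, 0.3]),
                                   [0.3, 0.3, 0.3])

    def test_idempotent_and_monotone(self, rng):
        p = rng.uniform(size=50)
        adj = rb.bh_adjust(p)
        np.testing.assert_allclose(rb.bh_adjust(adj), rb.bh_adjust(adj))
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            rb.bh_adjust([0.5, 1.2])

    def test_enrichment_disjoint_near_one(self):
        p = rb.hypergeometric_enrichment(set(range(10)), set(range(100, 110)),
                                         1000)
        assert p > 0.6

    def test_enrichment_perfect_overlap_tiny(self):
        p = rb.hypergeometric_enrichment(set(range(10)), set(range(10)), 1000)
        assert p < 1e-20

    def test_enrichment_at_expectation_moderate(self):
        # query half the universe, annotated 20: expected overlap 10
        p = rb.hypergeometric_enrichment(set(range(500)), set(range(490, 510)),
                                         1000)
        assert 0.2 < p < 0.8


class TestDifferentialFeatures:
    def test_planted_cpgs_recovered(self, cohort):
        meth, truth = cohort["methylation"], cohort["truth"]
        out = rb.differential_features(meth, truth.subtype,
                                       delta_threshold=0.2)
        planted = set(truth.diff_cpgs.index)
        sig = set(out.index[out["significant"]])
        recall = len(sig & planted) / len(planted)
        null_cpgs = set(meth.features) - planted
        fpr = len(sig & null_cpgs) / len(null_cpgs)
        assert recall >= 0.9
        assert fpr <= 0.05

    def test_direction_matches_planted_sign(self, cohort):
        meth, truth = cohort["methylation"], cohort["truth"]
        out = rb.differential_features(meth, truth.subtype,
                                       delta_threshold=0.2)
        hyper = truth.diff_cpgs.index[truth.diff_cpgs["direction"] == "hyper"]
        sig_hyper = [c for c in hyper if out.loc[c, "significant"]]
        assert all(out.loc[c, "direction"] == "up" for c in sig_hyper)

    def test_shuffled_labels_near_zero_significant(self, cohort, rng):
        meth, truth = cohort["methylation"], cohort["truth"]
        shuffled = pd.Series(rng.permutation(truth.subtype.to_numpy()),
                             index=truth.subtype.index)
        out = rb.differential_features(meth, shuffled, delta_threshold=0.2)
        assert out["significant"].mean() <= 0.05

    def test_identical_classes_nothing_significant(self, rng):
        X = rng.normal(size=(50, 20))
        m = _mat(np.hstack([X, X]))
        labels = pd.Series([1] * 20 + [2] * 20, index=m.samples)
        out = rb.differential_features(m, labels)
        assert out["significant"].sum() == 0


class TestSignatureScores:
    def test_two_sample_cohort_indices_zero_one(self, rng):
        X = rng.normal(size=(30, 2))
        w = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        idx = rb.stemness_index(_mat(X), w)
        assert sorted(idx.to_numpy()) == [0.0, 1.0]

    def test_rank_matching_sample_is_maximum(self, rng):
        n_genes = 60
        w = pd.Series(np.linspace(-2, 2, n_genes),
                      index=[f"g{i}" for i in range(n_genes)])
        X = rng.normal(size=(n_genes, 10))
        X[:, 4] = np.exp(w.to_numpy() * 2)  # rank-preserving transform of w
        m = _mat(X)
        idx = rb.stemness_index(m, w)
        assert idx["s4"] == 1.0

    def test_stemlike_subtype_separates(self, cohort):
        expr, truth = cohort["expression"], cohort["truth"]
        w = rb.synthetic_stemness_weights(truth, expr)
        idx = rb.stemness_index(expr, w)
        g1 = idx[truth.subtype == 1]
        g2 = idx[truth.subtype == 2]
        assert g2.mean() > g1.mean()
        p = stats.mannwhitneyu(g1, g2).pvalue
        assert p < 0.01

    def test_stemness_affine_invariance_per_sample(self, rng):
        X = rng.normal(size=(40, 6))
        w = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        a = rb.stemness_index(_mat(X), w)
        # adding genes absent from the weight vector changes nothing
        X2 = np.vstack([X, rng.normal(size=(10, 6))])
        b = rb.stemness_index(_mat(X2), w)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_ssgsea_top_genes_give_cohort_maximum(self, rng):
        X = rng.normal(size=(100, 8))
        X[:10, 3] += 10.0  # set genes top-expressed in sample 3
        m = _mat(X)
        scores = rb.ssgsea_score(m, [f"g{i}" for i in range(10)])
        assert scores.idxmax() == "s3"

    def test_ssgsea_alpha_zero_matches_bruteforce(self, rng):
        X = rng.normal(size=(40, 5))
        m = _mat(X)
        gene_set = [f"g{i}" for i in range(0, 40, 7)]
        scores = rb.ssgsea_score(m, gene_set, alpha=0.0, normalize=False)
        in_set = np.array([g in set(gene_set) for g in m.features])
        for j, s in enumerate(m.samples):
            order = np.argsort(-X[:, j], kind="stable")
            hit = in_set[order]
            p_hit = np.cumsum(hit) / hit.sum()
            p_miss = np.cumsum(~hit) / (~hit).sum()
            assert scores[s] == pytest.approx(np.sum(p_hit - p_miss),
                                              abs=1e-10)

    def test_ssgsea_null_set_no_class_difference(self, rng):
        pvals = []
        for r in range(20):
            X = rng.normal(size=(80, 20))
            m = _mat(X)
            gene_set = [f"g{i}" for i in rng.choice(80, 10, replace=False)]
            sc = rb.ssgsea_score(m, gene_set)
            p = stats.mannwhitneyu(sc[:10], sc[10:]).pvalue
            pvals.append(p)
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_ssgsea_requires_five_genes(self, rng):
        with pytest.raises(ValueError):
            rb.ssgsea_score(_mat(rng.normal(size=(20, 4))), ["g0", "g1"])

    def test_meta_score_standardized(self, cohort):
        expr, truth = cohort["expression"], cohort["truth"]
        sc = rb.meta_score(expr, truth.neuronal_genes)
        assert sc.mean() == pytest.approx(0.0, abs=1e-10)
        assert sc.std(ddof=0) == pytest.approx(1.0)
        assert sc[truth.subtype == 2].mean() > 0

    def test_meta_score_constant_cohort_warns_zero(self):
        m = _mat(np.ones((5, 4)))
        with pytest.warns(UserWarning):
            sc = rb.meta_score(m, ["g0", "g1"])
        assert (sc == 0).all()

    @pytest.mark.parametrize("i,p,expected", [
        (3, 100, 300.0), (0, 55, 0.0), (2, 45, 90.0)])
    def test_quick_score_product(self, i, p, expected):
        assert rb.quick_score(i, p) == expected

    def test_quick_score_range_validation(self):
        with pytest.raises(ValueError):
            rb.quick_score(4, 50)
        with pytest.raises(ValueError):
            rb.quick_score(2, 120)


class TestAssociationReport:
    def test_report_covers_planted_covariates(self, cohort):
        truth = cohort["truth"]
        clinical = rb.generate_clinical_table(truth, seed=5)
        rep = rb.association_report(
            clinical.drop(columns=["subtype"]), truth.subtype)
        assert {"laterality", "growth_pattern", "necrosis", "sex",
                "age_months"} <= set(rep.index)
        assert rep.loc["age_months", "p"] < 0.01
        assert rep.loc["laterality", "p"] < 0.05
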