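"""Ensemble clustering, co-classification, consensus and stability."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import rbsubtyper as rb
from rbsubtyper.matrix import OmicsMatrix, Partition


def _mat(arr, features=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr, index=features, columns=samples),
                       "expression")


def _part(labels, samples=None):
    samples = samples or [f"s{i}" for i in range(len(labels))]
    return Partition(pd.Series(labels, index=samples))


def _pair_similarity_oracle(a, b):
    """Brute-force pair-retention similarity by enumerating all pairs."""
    idx = range(len(a))
    SA = {(i, j) for i, j in itertools.combinations(idx, 2) if a[i] == a[j]}
    SB = {(i, j) for i, j in itertools.combinations(idx, 2) if b[i] == b[j]}
    if not SA and not SB:
        return 1.0
    rA = len(SA & SB) / len(SA) if SA else 0.0
    rB = len(SA & SB) / len(SB) if SB else 0.0
    return 0.5 * (rA + rB)


def _two_group_matrix(rng, n_per=10, n_genes=40, shift=4.0):
    # two anti-correlated marker blocks, one per group
    X = rng.normal(size=(n_genes, 2 * n_per))
    X[: n_genes // 2, :n_per] += shift
    X[n_genes // 2:, n_per:] += shift
    return _mat(X)


class TestHclustPartition:
    def test_separated_groups_recovered(self, rng):
        m = _two_group_matrix(rng)
        p = rb.hclust_partition(m, list(m.features), "average", 2)
        truth = [1] * 10 + [2] * 10
        assert adjusted_rand_score(truth, p.labels.to_numpy()) == 1.0

    def test_k_equals_n_all_singletons(self, rng):
        m = _mat(rng.normal(size=(10, 6)))
        p = rb.hclust_partition(m, list(m.features), "complete", 6)
        assert p.labels.nunique() == 6

    def test_duplicate_sample_always_coclusters(self, rng):
        X = rng.normal(size=(20, 8))
        X[:, 7] = X[:, 0]  # duplicate of sample 0
        m = _mat(X)
        for k in range(2, 7):
            p = rb.hclust_partition(m, list(m.features), "average", k)
            assert p.labels.iloc[0] == p.labels.iloc[7]

    def test_zero_variance_sample_rejected(self, rng):
        X = rng.normal(size=(12, 5))
        X[:, 3] = 2.0
        with pytest.raises(ValueError, match="s3"):
            rb.hclust_partition(_mat(X), [f"g{i}" for i in range(12)],
                                "average", 2)

    def test_labels_contiguous_from_one(self, rng):
        m = _mat(rng.normal(size=(15, 9)))
        p = rb.hclust_partition(m, list(m.features), "ward", 3)
        assert sorted(p.labels.unique()) == [1, 2, 3]


class TestEnsembleAndCoclassification:
    def test_ensemble_size_is_subsets_times_linkages(self, rng):
        m = _two_group_matrix(rng)
        subs = [list(m.features[:20]), list(m.features[10:30]),
                list(m.features)]
        ens = rb.build_partition_ensemble(m, subs, rb.ConsensusConfig(), 2)
        assert len(ens) == 9  # 3 subsets x 3 linkages
        subs8 = [list(m.features)] * 8
        assert len(rb.build_partition_ensemble(
            m, subs8, rb.ConsensusConfig(), 2)) == 24

    def test_single_member_consensus_is_that_partition(self, rng):
        m = _two_group_matrix(rng)
        cfg = rb.ConsensusConfig(linkages=["average"])
        ens = rb.build_partition_ensemble(m, [list(m.features)], cfg, 2)
        assert len(ens) == 1
        cons = rb.consensus_partition(ens, 2)
        assert adjusted_rand_score(ens[0].labels, cons.labels) == 1.0

    def test_hand_enumerated_coclassification_counts(self):
        pa = _part([1, 1, 2], ["a", "b", "c"])
        pb = _part([1, 2, 2], ["a", "b", "c"])
        cm = rb.coclassification_matrix([pa, pb])
        assert cm.counts.loc["a", "b"] == 1
        assert cm.counts.loc["b", "c"] == 1
        assert cm.counts.loc["a", "c"] == 0
        assert (np.diag(cm.counts) == 2).all()

    def test_identical_partitions_give_binary_counts(self):
        ens = [_part([1, 1, 2, 2])] * 24
        cm = rb.coclassification_matrix(ens)
        assert set(np.unique(cm.counts)) <= {0.0, 24.0}

    def test_counts_invariant_to_cluster_relabeling(self):
        pa = _part([1, 1, 2, 3])
        pb = Partition(pd.Series([3, 3, 1, 2],
                                 index=[f"s{i}" for i in range(4)]))
        ca = rb.coclassification_matrix([pa])
        cb = rb.coclassification_matrix([pb])
        pd.testing.assert_frame_equal(ca.counts, cb.counts)

    def test_sample_mismatch_errors(self):
        with pytest.raises(ValueError):
            rb.coclassification_matrix(
                [_part([1, 2], ["a", "b"]), _part([1, 2], ["a", "c"])])

    def test_consensus_order_invariant(self, rng):
        m = _two_group_matrix(rng)
        subs = [list(m.features[:25]), list(m.features[5:35])]
        ens = rb.build_partition_ensemble(m, subs, rb.ConsensusConfig(), 3)
        c1 = rb.consensus_partition(ens, 3)
        c2 = rb.consensus_partition(ens[::-1], 3)
        assert adjusted_rand_score(c1.labels, c2.labels) == 1.0

    def test_consensus_recovers_planted_subtypes(self):
        aris = []
        for s in range(3):
            cfg = rb.CohortConfig(seed=s)
            expr, _, _, truth = rb.generate_cohort(cfg)
            subs = [s_ for s_ in rb.feature_subsets(expr) if len(s_) >= 5]
            ens = rb.build_partition_ensemble(expr, subs,
                                              rb.ConsensusConfig(), 2)
            cons = rb.consensus_partition(ens, 2)
            aris.append(adjusted_rand_score(truth.subtype, cons.labels))
        assert np.mean(aris) >= 0.9


class TestSymmetricDifferenceSimilarity:
    def test_identical_partitions_score_one(self):
        p = _part([1, 2, 1, 3, 2])
        assert rb.symmetric_difference_similarity(p, p) == 1.0

    def test_against_all_singletons_is_zero(self):
        pa = _part([1, 1, 2, 2])
        pb = _part([1, 2, 3, 4])
        assert rb.symmetric_difference_similarity(pa, pb) == 0.0

    def test_both_all_singletons_is_one(self):
        pa = _part([1, 2, 3])
        pb = _part([3, 1, 2])
        assert rb.symmetric_difference_similarity(pa, pb) == 1.0

    def test_hand_worked_five_twelfths(self):
        # {abc|d} vs {ab|cd}: retention 1/3 one way, 1/2 the other
        pa = _part([1, 1, 1, 2], ["a", "b", "c", "d"])
        pb = _part([1, 1, 2, 2], ["a", "b", "c", "d"])
        assert rb.symmetric_difference_similarity(pa, pb) == pytest.approx(5 / 12)

    @given(st.lists(st.integers(1, 4), min_size=2, max_size=12),
           st.lists(st.integers(1, 4), min_size=2, max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle_and_bounds(self, la, lb):
        n = min(len(la), len(lb))
        a, b = la[:n], lb[:n]
        pa, pb = _part(a), _part(b)
        val = rb.symmetric_difference_similarity(pa, pb)
        assert 0.0 <= val <= 1.0
        assert val == pytest.approx(_pair_similarity_oracle(
            pa.labels.to_numpy(), pb.labels.to_numpy()))
        assert val == pytest.approx(rb.symmetric_difference_similarity(pb, pa))

    def test_jaccard_variant(self):
        pa = _part([1, 1, 1, 2], ["a", "b", "c", "d"])
        pb = _part([1, 1, 2, 2], ["a", "b", "c", "d"])
        # SA = {ab,ac,bc}, SB = {ab,cd}; intersection {ab}, union 4
        assert rb.symmetric_difference_similarity(
            pa, pb, variant="jaccard") == pytest.approx(1 / 4)


class TestPerturbationAndStability:
    def test_fixed_seed_reproducible(self, rng):
        m = _mat(rng.normal(size=(30, 10)))
        cfg = rb.StabilityConfig(n_iterations=1)
        a = rb.perturb_with_noise(m, cfg, np.random.default_rng(5))
        b = rb.perturb_with_noise(m, cfg, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_noise_sd_matches_configuration(self, rng):
        m = _mat(rng.normal(0, 2.0, size=(1000, 50)))
        cfg = rb.StabilityConfig(noise_sigma_factor=1.5)
        noisy = rb.perturb_with_noise(m, cfg, np.random.default_rng(0))
        resid = (noisy.values - m.values).to_numpy()
        med_var = np.median(m.values.var(axis=1, ddof=1))
        expected = 1.5 * np.sqrt(med_var)
        assert resid.std() == pytest.approx(expected, rel=0.02)
        assert resid.mean() == pytest.approx(0.0, abs=0.02)

    def test_literal_sigma_mode(self, rng):
        m = _mat(rng.normal(0, 2.0, size=(500, 40)))
        cfg = rb.StabilityConfig(noise_sigma_factor=1.5, sigma_mode="literal")
        noisy = rb.perturb_with_noise(m, cfg, np.random.default_rng(0))
        med_var = np.median(m.values.var(axis=1, ddof=1))
        resid = (noisy.values - m.values).to_numpy()
        assert resid.std() == pytest.approx(1.5 * med_var, rel=0.05)

    def test_tiny_noise_leaves_partition_stable(self, rng):
        m = _two_group_matrix(rng, shift=6.0)
        cfg = rb.StabilityConfig(n_iterations=5, noise_sigma_factor=1e-9)
        _, agg = rb.stability_score(m, [list(m.features)],
                                    rb.ConsensusConfig(linkages=["average"]),
                                    cfg, k=2, seed=0)
        assert agg == 1.0

    def test_planted_structure_more_stable_at_true_k(self):
        cfg = rb.CohortConfig(seed=3)
        expr, _, _, _ = rb.generate_cohort(cfg)
        subs = [s for s in rb.feature_subsets(expr) if len(s) >= 5][-3:]
        st_cfg = rb.StabilityConfig(n_iterations=8)
        cc = rb.ConsensusConfig(linkages=["average", "ward"])
        _, s2 = rb.stability_score(expr, subs, cc, st_cfg, k=2, seed=0)
        _, s5 = rb.stability_score(expr, subs, cc, st_cfg, k=5, seed=0)
        assert s2 >= 0.9
        assert s5 < s2

    def test_pure_noise_unstable(self, rng):
        m = _mat(rng.normal(size=(60, 30)))
        st_cfg = rb.StabilityConfig(n_iterations=8)
        cc = rb.ConsensusConfig(linkages=["average"])
        _, agg = rb.stability_score(m, [list(m.features)], cc, st_cfg,
                                    k=2, seed=1)
        assert agg < 0.9
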