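import numpy as np
import pandas as pd
import pytest

from vplung.consensus import (
    OUTLIER,
    DegenerateClusteringError,
    FeatureMatrix,
    cluster_consensus,
    consensus_cluster,
    consensus_matrix,
    final_partition,
    quality_curve,
    resample_partitions,
)


def brute_force_consensus(partitions, n):
    """Independent oracle: explicit double loop over item pairs."""
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            m = s = 0
            for idx, labels in partitions:
                pos = {item: k for item, k in zip(idx, labels)}
                if i in pos and j in pos:
                    s += 1
                    if pos[i] == pos[j]:
                        m += 1
            D[i, j] = m / s if s else 0.0
    np.fill_diagonal(D, 1.0)
    return D


def brute_force_mk(D, labels):
    out = {}
    for lab in set(labels.tolist()) - {OUTLIER}:
        members = [i for i, l in enumerate(labels) if l == lab]
        if len(members) < 2:
            out[lab] = 1.0
            continue
        vals = [D[i, j] for a, i in enumerate(members)
                for j in members[a + 1:]]
        out[lab] = float(np.mean(vals))
    return out


FOUR_ITEM_PARTITIONS = [
    (np.arange(4), np.array([0, 0, 1, 1])),   # {ab|cd}
    (np.arange(4), np.array([0, 0, 0, 1])),   # {abc|d}
]


class TestConsensusMatrix:
    def test_hand_worked_four_items(self):
        D, M, I, never = consensus_matrix(FOUR_ITEM_PARTITIONS, 4)
        a, b, c, d = 0, 1, 2, 3
        assert D[a, b] == 1.0
        assert D[a, c] == 0.5
        assert D[c, d] == 0.5
        assert D[a, d] == 0.0
        assert not never.any()
        assert np.allclose(D, D.T)

    def test_identical_full_partitions_give_binary_consensus(self):
        parts = [(np.arange(6), np.array([0, 0, 0, 1, 1, 1]))] * 5
        D, *_ = consensus_matrix(parts, 6)
        within = D[:3, :3]
        across = D[:3, 3:]
        assert (within == 1.0).all() and (across == 0.0).all()

    def test_never_cosampled_flagged_as_zero(self):
        parts = [(np.array([0, 1]), np.array([0, 0])),
                 (np.array([2, 3]), np.array([0, 1]))]
        D, M, I, never = consensus_matrix(parts, 4)
        assert never[0, 2] and D[0, 2] == 0.0

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(5, 16))
            parts = []
            for _ in range(int(rng.integers(3, 21))):
                m = int(rng.integers(3, n + 1))
                idx = np.sort(rng.choice(n, m, replace=False))
                parts.append((idx, rng.integers(0, 3, size=m)))
            D, *_ = consensus_matrix(parts, n)
            assert np.allclose(D, brute_force_consensus(parts, n))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        idx = np.arange(8)
        labels = rng.integers(0, 3, 8)
        perm = {0: 2, 1: 0, 2: 1}
        D1, *_ = consensus_matrix([(idx, labels)], 8)
        D2, *_ = consensus_matrix(
            [(idx, np.array([perm[l] for l in labels]))], 8)
        assert np.array_equal(D1, D2)


class TestFinalPartition:
    def test_perfect_consensus_reproduced_without_outliers(self):
        parts = [(np.arange(6), np.array([0, 0, 0, 1, 1, 1]))] * 4
        D, *_ = consensus_matrix(parts, 6)
        labels = final_partition(D, 2)
        assert OUTLIER not in labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_hand_worked_example_clusters(self):
        D, *_ = consensus_matrix(FOUR_ITEM_PARTITIONS, 4)
        labels = final_partition(D, 2, tau=0.5)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert OUTLIER not in labels

    def test_zero_affinity_item_is_outlier(self):
        D = np.eye(6)
        D[:5, :5] = 1.0  # five mutually consistent items, one stranger
        labels = final_partition(D, 2, tau=0.5)
        assert (labels[:5] != OUTLIER).all()
        # the stranger either forms a singleton cluster or is an outlier;
        # with k=2 it is its own cluster - force the outlier path with k=3
        D2 = np.eye(7)
        D2[:3, :3] = 1.0
        D2[3:6, 3:6] = 1.0
        D2[6, :6] = D2[:6, 6] = 0.2
        D2[6, 6] = 1.0
        # item 6 merges into some cluster but sits loosely in it
        labels2 = final_partition(D2, 2, tau=0.5)
        assert labels2[6] == OUTLIER

    def test_all_outliers_is_degenerate(self):
        D = np.full((4, 4), 0.1)
        np.fill_diagonal(D, 1.0)
        with pytest.raises(DegenerateClusteringError):
            final_partition(D, 2, tau=0.5)


class TestClusterConsensus:
    def test_hand_worked_values(self):
        D, *_ = consensus_matrix(FOUR_ITEM_PARTITIONS, 4)
        labels = final_partition(D, 2, tau=0.5)
        m_k, mean_c = cluster_consensus(D, labels)
        assert sorted(m_k.values()) == [0.5, 1.0]
        assert mean_c == 0.75

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(6, 14))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 1.0)
            labels = rng.integers(0, 3, n)
            m_k, mean_c = cluster_consensus(D, labels)
            oracle = brute_force_mk(D, labels)
            for k, v in m_k.items():
                assert v == pytest.approx(oracle[k])
            assert mean_c == pytest.approx(np.mean(list(oracle.values())))

    def test_singleton_cluster_scores_one(self):
        D = np.eye(3)
        m_k, _ = cluster_consensus(D, np.array([0, 0, 1]))
        assert m_k[1] == 1.0


def blobs(n_per, k, sep=8.0, seed=0, dim=4):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(i * sep, 1.0, size=(n_per, dim))
                   for i in range(k)])
    return X


class TestResampling:
    def test_mask_size_and_determinism(self):
        X = blobs(10, 3)
        p1 = resample_partitions(X, k=3, n_resamples=8, frac=0.8, seed=4)
        p2 = resample_partitions(X, k=3, n_resamples=8, frac=0.8, seed=4)
        for (i1, l1), (i2, l2) in zip(p1, p2):
            assert np.array_equal(i1, i2) and np.array_equal(l1, l2)
        assert all(len(idx) == int(np.ceil(0.8 * 30)) for idx, _ in p1)

    def test_separable_blobs_full_sample_identical_partitions(self):
        X = blobs(8, 3)
        parts = resample_partitions(X, k=3, n_resamples=6, frac=1.0, seed=1)
        D, *_ = consensus_matrix(parts, X.shape[0])
        assert set(np.unique(D)) <= {0.0, 1.0}

    def test_k_larger_than_subsample_rejected(self):
        with pytest.raises(ValueError):
            resample_partitions(blobs(2, 2, dim=2), k=5, n_resamples=2,
                                frac=0.5, seed=0)


class TestQualityCurve:
    def test_true_k_scores_high_and_decays_past_it(self):
        X = blobs(15, 3, seed=7)
        res3 = consensus_cluster(X, 3, n_resamples=60, seed=2)
        res5 = consensus_cluster(X, 5, n_resamples=60, seed=2)
        assert res3.mean_consensus > 0.95
        assert res3.mean_consensus > res5.mean_consensus

    def test_bounds_determinism_and_sample_count(self):
        X = blobs(10, 2, sep=4.0, seed=3)
        qc1 = quality_curve(X, [2, 3], repeats=10, inner_resamples=20, seed=9)
        qc2 = quality_curve(X, [2, 3], repeats=10, inner_resamples=20, seed=9)
        assert qc1.mean == qc2.mean
        for k in (2, 3):
            v = qc1.samples[k]
            assert len(v) == 10
            assert ((0 <= v) & (v <= 1)).all()
        assert all(ci >= 0 for ci in qc1.ci_halfwidth)

    def test_k_range_validated(self):
        with pytest.raises(ValueError):
            quality_curve(blobs(10, 2), [1, 2], repeats=2)


class TestFeatureMatrix:
    def test_zscoring(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 10.0, 10.0]},
                          index=["x", "y", "z"])
        fm = FeatureMatrix.from_frame(df)
        assert np.allclose(fm.X[:, 0].mean(), 0.0)
        assert np.allclose(fm.X[:, 0].std(), 1.0)
        assert np.allclose(fm.X[:, 1], 0.0)  # constant feature centered

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError):
            FeatureMatrix.from_frame(df)
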