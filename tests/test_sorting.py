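import numpy as np
import pytest

from neurocodec.spike_sorting import (
    ClusterModel,
    FeatureMatrix,
    af_train,
    align_max_slope,
    classify,
    cluster_model_from_labels,
    kmeans_train,
    mac_project,
    pca_train,
    sorting_accuracy,
)
from neurocodec.synthetic_data import default_templates


def spikes_from_template(template, n, noise_sd, rng):
    return template.waveform[None, :] + rng.normal(0, noise_sd, size=(n, 64))


class TestAlignment:
    def test_already_centered_is_fixed_point(self):
        wf = default_templates(1)[0].waveform
        aligned = align_max_slope(wf)
        assert np.array_equal(align_max_slope(aligned), aligned)

    @pytest.mark.parametrize("shift", [-5, -2, 2, 5])
    def test_shifted_copies_align_identically(self, shift):
        wf = default_templates(1)[0].waveform
        shifted = np.roll(wf, shift)
        a, b = align_max_slope(wf), align_max_slope(shifted)
        # identical wherever both windows carry real (non-padded) samples
        core = slice(8, 56)
        assert np.array_equal(a[core], b[core])

    def test_constant_waveform_defined_output(self):
        out = align_max_slope(np.full(64, 3))
        assert out.shape == (64,)
        # argmax tie-break picks index 0, which lands at index 20
        assert (out[:20] == 0).all() and (out[20:] == 3).all()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            align_max_slope(np.zeros(32))


class TestPca:
    def test_rank_one_data_explained_by_first_component(self, rng):
        base = rng.normal(0, 1, 64)
        S = np.outer(rng.normal(0, 5, 100), base)
        F = pca_train(S, 3)
        proj = mac_project(S, F)
        var = proj.var(axis=0)
        assert var[0] / var.sum() >= 0.999

    def test_rows_orthonormal(self, rng):
        S = rng.normal(0, 1, size=(200, 64))
        F = pca_train(S, 5)
        assert np.allclose(F.projection @ F.projection.T, np.eye(5), atol=1e-6)

    def test_reconstruction_error_nonincreasing_in_features(self, rng):
        S = rng.normal(0, 1, size=(100, 64)) + np.linspace(0, 3, 64)
        centered = S - S.mean(axis=0)
        errs = []
        for nf in (1, 3, 6, 10):
            P = pca_train(S, nf).projection
            errs.append(((centered - centered @ P.T @ P) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_feature_cap(self, rng):
        S = rng.normal(0, 1, size=(50, 64))
        with pytest.raises(ValueError):
            pca_train(S, 11)


class TestAf:
    def test_discriminative_sample_selected_first(self, rng):
        base = np.zeros(64)
        S, labels = [], []
        for lab, offset in ((0, 0.0), (1, 30.0)):
            for _ in range(40):
                wf = base + rng.normal(0, 1, 64)
                wf[37] += offset  # classes differ only at sample 37
                S.append(wf)
                labels.append(lab)
        F = af_train(np.array(S), np.array(labels), 1)
        assert F.projection[0, 37] == 1.0

    def test_feature_cap(self, rng):
        S = rng.normal(0, 1, size=(30, 64))
        with pytest.raises(ValueError):
            af_train(S, np.zeros(30), 8)

    def test_projection_equals_direct_indexing(self, rng):
        S = rng.normal(0, 1, size=(30, 64))
        labels = rng.integers(0, 2, size=30)
        F = af_train(S, labels, 4)
        picks = np.flatnonzero(F.projection.sum(axis=0))
        assert np.allclose(mac_project(S, F), S[:, picks])


class TestMacProject:
    def test_identity_like_rows_pick_samples(self, rng):
        S = rng.normal(0, 1, size=(10, 64))
        proj = np.zeros((3, 64))
        proj[[0, 1, 2], [0, 1, 2]] = 1.0
        F = FeatureMatrix(projection=proj, kind="af")
        assert np.allclose(mac_project(S, F), S[:, :3])

    @pytest.mark.parametrize("block", [1, 7, 16, 64])
    def test_blocked_equals_naive_triple_loop(self, rng, block):
        S = rng.normal(0, 1, size=(8, 64))
        F = pca_train(rng.normal(0, 1, size=(30, 64)), 4)
        naive = np.array(
            [[sum(S[i, k] * F.projection[j, k] for k in range(64)) for j in range(4)] for i in range(8)]
        )
        assert np.allclose(mac_project(S, F, block=block), naive)

    def test_zero_spikes_zero_features(self):
        F = FeatureMatrix(projection=np.ones((2, 64)), kind="af")
        assert not mac_project(np.zeros((5, 64)), F).any()

    def test_dimension_mismatch(self):
        F = FeatureMatrix(projection=np.ones((2, 64)), kind="af")
        with pytest.raises(ValueError):
            mac_project(np.zeros((5, 32)), F)


class TestKmeans:
    def test_recovers_three_point_masses(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([c + rng.normal(0, 1e-7, size=(40, 2)) for c in centers])
        model = kmeans_train(X, seed=1)
        assert model.k == 3
        found = model.means[np.lexsort(model.means.T)]
        expected = centers[np.lexsort(centers.T)]
        assert np.allclose(found, expected, atol=1e-6)

    def test_deterministic_for_seed(self, rng):
        X = rng.normal(0, 1, size=(120, 3))
        m1 = kmeans_train(X, seed=9, k=4)
        m2 = kmeans_train(X.copy(), seed=9, k=4)
        assert np.array_equal(m1.means, m2.means)

    def test_k_capped_at_eight(self, rng):
        centers = 40 * np.arange(10)[:, None] * np.ones((1, 2))
        X = np.vstack([c + rng.normal(0, 0.1, size=(30, 2)) for c in centers])
        model = kmeans_train(X, seed=0)
        assert model.k == 8

    def test_cap_violations_rejected(self, rng):
        X = rng.normal(0, 1, size=(50, 2))
        with pytest.raises(ValueError):
            kmeans_train(X, k_max=9, seed=0)
        with pytest.raises(ValueError):
            kmeans_train(X[:3], k=5, seed=0)


class TestClassify:
    def test_feature_at_mean_wins(self):
        model = ClusterModel(means=np.array([[0.0, 0.0], [5.0, 5.0]]))
        assert classify(np.array([[5.0, 5.0]]), model)[0] == 1

    def test_equidistant_tie_goes_to_lower_id(self):
        model = ClusterModel(means=np.array([[0.0], [2.0]]))
        assert classify(np.array([[1.0]]), model)[0] == 0

    def test_identity_covariance_matches_euclidean(self, rng):
        means = rng.normal(0, 5, size=(4, 3))
        covs = np.stack([np.eye(3)] * 4)
        X = rng.normal(0, 4, size=(200, 3))
        eu = classify(X, ClusterModel(means=means, metric="euclidean"))
        ma = classify(X, ClusterModel(means=means, covariances=covs, metric="mahalanobis"))
        assert np.array_equal(eu, ma)

    def test_mahalanobis_beats_euclidean_on_anisotropic_noise(self, rng):
        cov = np.array([[10.0, 9.5], [9.5, 10.0]])
        means = np.array([[0.0, 0.0], [5.0, 0.0]])
        X = np.vstack([rng.multivariate_normal(m, cov, 400) for m in means])
        y = np.repeat([0, 1], 400)
        acc_eu = sorting_accuracy(classify(X, cluster_model_from_labels(X, y, "euclidean")), y)
        acc_ma = sorting_accuracy(classify(X, cluster_model_from_labels(X, y, "mahalanobis")), y)
        assert acc_ma >= acc_eu + 5.0


class TestAccuracy:
    def test_permuted_perfect_labeling_is_100(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([2, 2, 0, 0, 1, 1])
        assert sorting_accuracy(pred, truth) == 100.0

    def test_random_two_balanced_classes_near_half(self, rng):
        n = 20_000
        truth = np.repeat([0, 1], n // 2)
        pred = rng.integers(0, 2, size=n)
        assert sorting_accuracy(pred, truth) == pytest.approx(50.0, abs=2.0)

    def test_single_class_single_cluster(self):
        assert sorting_accuracy(np.zeros(10), np.full(10, 7)) == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sorting_accuracy(np.zeros(3), np.zeros(4))
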