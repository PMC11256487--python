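"""SPD geometry, the MDM classifier and its cross-validated evaluation."""

import math

import numpy as np
import pytest

from remoteeg.datasets import synthetic_oddball_epochs
from remoteeg.errors import ConvergenceError
from remoteeg.erp_stats import EpochSet
from remoteeg.riemann_mdm import (
    chi_square_confusion,
    erp_super_trial_covariance,
    euclidean_distance,
    evaluate_cv,
    fit_mdm,
    geometric_mean,
    is_spd,
    predict_and_score,
    rank_auc,
    riemannian_distance,
)


def _random_spd(rng, d=3, n=50):
    x = rng.standard_normal((d, n))
    return np.cov(x) + 0.1 * np.eye(d)


class TestSuperTrialCovariance:
    def test_epoch_equal_to_prototype_duplicates_blocks(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 100))
        cov = erp_super_trial_covariance(x, x, shrinkage=0.0)
        c = 2
        blocks = [cov[:c, :c], cov[:c, c:], cov[c:, :c], cov[c:, c:]]
        for b in blocks[1:]:
            assert np.allclose(b, blocks[0])

    def test_full_shrinkage_gives_scaled_identity(self):
        rng = np.random.default_rng(1)
        cov = erp_super_trial_covariance(
            rng.standard_normal((2, 50)), rng.standard_normal((2, 50)), shrinkage=1.0
        )
        assert np.allclose(cov, cov[0, 0] * np.eye(4))
        assert cov[0, 0] > 0

    def test_zero_epoch_block_is_shrinkage_times_scale(self):
        rng = np.random.default_rng(2)
        proto = rng.standard_normal((2, 200))
        lam = 0.1
        cov = erp_super_trial_covariance(np.zeros((2, 200)), proto, shrinkage=lam)
        z = np.vstack([proto, np.zeros((2, 200))])
        scale = np.trace(np.cov(z)) / 4
        assert np.allclose(cov[2:, 2:], lam * scale * np.eye(2), atol=1e-12)

    def test_rank_deficiency_error_mentions_shrinkage(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="shrinkage"):
            erp_super_trial_covariance(
                rng.standard_normal((4, 6)), rng.standard_normal((4, 6)), shrinkage=0.0
            )

    def test_output_is_spd(self):
        rng = np.random.default_rng(4)
        cov = erp_super_trial_covariance(
            rng.standard_normal((4, 257)), rng.standard_normal((4, 257)), shrinkage=0.1
        )
        assert cov.shape == (8, 8)
        assert is_spd(cov)


class TestRiemannianDistance:
    def test_identity_of_indiscernibles(self):
        rng = np.random.default_rng(0)
        a = _random_spd(rng)
        assert riemannian_distance(a, a) == pytest.approx(0.0, abs=1e-7)

    def test_closed_form_scaled_identity(self):
        d = riemannian_distance(np.eye(4), math.e**2 * np.eye(4))
        assert d == pytest.approx(2 * math.sqrt(4), abs=1e-8)

    def test_closed_form_diagonal(self):
        d = riemannian_distance(np.diag([1.0, 4.0]), np.diag([2.0, 2.0]))
        assert d == pytest.approx(math.sqrt(2) * math.log(2), abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = _random_spd(rng), _random_spd(rng)
        assert riemannian_distance(a, b) == pytest.approx(riemannian_distance(b, a), rel=1e-10)

    def test_congruence_invariance(self):
        rng = np.random.default_rng(2)
        a, b = _random_spd(rng), _random_spd(rng)
        g = rng.standard_normal((3, 3))
        d0 = riemannian_distance(a, b)
        d1 = riemannian_distance(g.T @ a @ g, g.T @ b @ g)
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_rejects_non_spd(self):
        with pytest.raises(ValueError, match="positive-definite"):
            riemannian_distance(np.diag([1.0, -1.0]), np.eye(2))


class TestGeometricMean:
    def test_single_matrix_is_its_own_mean(self):
        rng = np.random.default_rng(0)
        a = _random_spd(rng)
        assert np.allclose(geometric_mean([a]), a)

    def test_commuting_case_elementwise(self):
        mean = geometric_mean([np.diag([1.0, 1.0]), np.diag([4.0, 9.0])])
        assert np.allclose(mean, np.diag([2.0, 3.0]), atol=1e-6)

    def test_congruence_equivariance(self):
        rng = np.random.default_rng(1)
        mats = [_random_spd(rng) for _ in range(4)]
        g = rng.standard_normal((3, 3))
        lhs = geometric_mean([g.T @ m @ g for m in mats])
        rhs = g.T @ geometric_mean(mats) @ g
        assert np.allclose(lhs, rhs, atol=1e-6)

    def test_local_minimality_of_frechet_objective(self):
        rng = np.random.default_rng(2)
        mats = [_random_spd(rng) for _ in range(5)]
        center = geometric_mean(mats)

        def objective(m):
            return sum(riemannian_distance(m, a) ** 2 for a in mats)

        f0 = objective(center)
        for _ in range(10):
            v = rng.standard_normal(center.shape)
            v = 0.05 * (v + v.T) / 2
            perturbed = center + v @ center @ v.T + v  # stays symmetric
            perturbed = perturbed + (1e-6 - min(0, np.linalg.eigvalsh(perturbed).min())) * np.eye(3)
            assert objective(perturbed) >= f0 - 1e-8

    def test_nonconvergence_reports_final_norm(self):
        rng = np.random.default_rng(3)
        mats = [_random_spd(rng) for _ in range(4)]
        with pytest.raises(ConvergenceError) as exc:
            geometric_mean(mats, tol=1e-16, max_iter=2)
        assert exc.value.final_norm is not None


def _cluster_epochs(seed=0, n_per=12, separation=4.0):
    """Two well-separated classes of short random epochs."""
    rng = np.random.default_rng(seed)
    n_t = 64
    a = rng.standard_normal((n_per, 2, n_t))
    b = separation * rng.standard_normal((n_per, 2, n_t))
    return EpochSet(
        epochs=np.concatenate([a, b]),
        times=np.arange(n_t) / 256.0,
        labels=np.asarray(["oddball"] * n_per + ["standard"] * n_per, dtype=object),
        fs=256.0,
    )


class TestMdmFitPredict:
    def test_distinct_classes_have_distinct_means(self):
        ep = _cluster_epochs()
        model = fit_mdm(ep)
        assert not np.allclose(model.means["oddball"], model.means["standard"])

    def test_euclidean_mean_is_arithmetic(self):
        ep = _cluster_epochs(n_per=2)
        model = fit_mdm(ep, metric="euclidean")
        from remoteeg.riemann_mdm import _covariances

        covs = _covariances(ep, model.prototype, model.shrinkage)
        assert np.allclose(model.means["oddball"], covs[:2].mean(axis=0))

    def test_fit_is_invariant_to_epoch_order(self):
        ep = _cluster_epochs()
        rng = np.random.default_rng(1)
        perm = rng.permutation(ep.n_epochs)
        shuffled = EpochSet(
            epochs=ep.epochs[perm], times=ep.times, labels=ep.labels[perm], fs=ep.fs
        )
        m1, m2 = fit_mdm(ep), fit_mdm(shuffled)
        for c in m1.classes:
            assert np.allclose(m1.means[c], m2.means[c], atol=1e-6)

    def test_single_class_rejected(self):
        ep = _cluster_epochs()
        with pytest.raises(ValueError, match="class"):
            fit_mdm(ep, labels=["oddball"] * ep.n_epochs)

    def test_epoch_matching_class_mean_is_classified_there(self):
        ep = _cluster_epochs()
        model = fit_mdm(ep)
        labels, scores = predict_and_score(model, ep)
        acc = np.mean(labels == ep.labels)
        assert acc > 0.9  # separable by construction
        assert np.mean(scores[ep.labels == "oddball"]) > np.mean(
            scores[ep.labels == "standard"]
        )

    def test_tie_broken_lexicographically_with_warning(self):
        ep = _cluster_epochs()
        model = fit_mdm(ep)
        # force both class means equal: every epoch is equidistant
        model.means["standard"] = model.means["oddball"].copy()
        with pytest.warns(UserWarning, match="equidistant"):
            labels, _ = predict_and_score(model, ep)
        assert set(labels.tolist()) == {"oddball"}  # lexicographically first

    def test_scores_invariant_under_congruence(self):
        ep = _cluster_epochs(n_per=6)
        model = fit_mdm(ep)
        _, s0 = predict_and_score(model, ep)
        rng = np.random.default_rng(5)
        g = rng.standard_normal((2, 2)) + 2 * np.eye(2)
        # congruence on the signal space: epochs and prototype transform alike
        ep_t = EpochSet(
            epochs=np.einsum("ij,ejt->eit", g, ep.epochs),
            times=ep.times,
            labels=ep.labels,
            fs=ep.fs,
        )
        model_t = fit_mdm(ep_t, shrinkage=0.0)
        model_0 = fit_mdm(ep, shrinkage=0.0)
        _, s1 = predict_and_score(model_t, ep_t)
        _, s2 = predict_and_score(model_0, ep)
        assert np.allclose(s1, s2, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        ep = _cluster_epochs()
        model = fit_mdm(ep)
        small = EpochSet(
            epochs=ep.epochs[:, :, :32],
            times=ep.times[:32],
            labels=ep.labels,
            fs=ep.fs,
        )
        with pytest.raises(ValueError, match="match"):
            predict_and_score(model, small)


class TestEvaluation:
    def test_chi_square_closed_form(self):
        chi2, p = chi_square_confusion(np.array([[45, 5], [5, 45]]))
        assert chi2 == pytest.approx(64.0, abs=1e-9)
        assert p < 1e-10

    def test_rank_auc_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(200)
        y = rng.integers(0, 2, 200).astype(bool)
        assert rank_auc(scores, y) == pytest.approx(
            sklearn_metrics.roc_auc_score(y, scores), abs=1e-12
        )

    def test_perfectly_separable_scores_one(self):
        ep = _cluster_epochs(seed=1, n_per=15, separation=20.0)
        report = evaluate_cv(ep, k_folds=5, seed=0)
        assert report.accuracy == 1.0
        assert report.auc == 1.0
        assert report.confusion.sum() == ep.n_epochs
        assert np.trace(report.confusion) == ep.n_epochs

    def test_class_smaller_than_folds_rejected(self):
        ep = _cluster_epochs(n_per=3)
        with pytest.raises(ValueError, match="k_folds"):
            evaluate_cv(ep, k_folds=5)

    def test_default_synthetic_dataset_is_separable(self):
        ep = synthetic_oddball_epochs(seed=7)
        report = evaluate_cv(ep, seed=7)
        assert report.accuracy >= 0.70
        assert report.auc >= 0.75
        assert report.chi2_p < 1e-4

    def test_shuffled_labels_are_chance_level(self):
        accs = []
        for seed in range(5):
            ep = synthetic_oddball_epochs(
                seed=seed, n_oddball=50, n_standard=50, template=np.zeros((4, 257))
            )
            rng = np.random.default_rng(seed)
            report = evaluate_cv(ep, labels=rng.permutation(ep.labels), seed=seed)
            accs.append(report.accuracy)
        assert 0.40 <= np.mean(accs) <= 0.60
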