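"""FLD decoding: closed-form oracles, cross-validation bookkeeping,
cross-task generalization, and invariances."""

import numpy as np
import pytest
import scipy.stats

from attnping.decode import (
    BatchFLDSolver,
    cross_task_generalize,
    fld_fit,
    fld_predict,
    loro_decode,
)
from attnping.patterns import znormalize
from conftest import make_pattern_set


def _two_class_data(rng, n_per=20, dim=6, sep=3.0):
    mu = np.zeros(dim)
    mu2 = mu.copy()
    mu2[0] = sep
    X = np.vstack(
        [rng.normal(size=(n_per, dim)) + mu, rng.normal(size=(n_per, dim)) + mu2]
    )
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestFLDFit:
    def test_identity_covariance_weight_parallel_to_mean_difference(self):
        rng = np.random.default_rng(0)
        X, y = _two_class_data(rng, n_per=400, dim=5, sep=4.0)
        m = fld_fit(X, y, shrinkage=0.0)
        d = X[y == "a"].mean(0) - X[y == "b"].mean(0)
        cos = m.weights @ d / np.linalg.norm(m.weights) / np.linalg.norm(d)
        assert cos > 0.98

    def test_closed_form_shrinkage_oracle(self):
        """Weights equal an independently computed direct solve of
        [(1-a)S + a tr(S)/V I] w = mu1 - mu2."""
        rng = np.random.default_rng(1)
        X, y = _two_class_data(rng, n_per=15, dim=8)
        alpha = 0.1
        m = fld_fit(X, y, shrinkage=alpha)
        X1, X2 = X[y == "a"], X[y == "b"]
        scatter = sum(
            ((b - b.mean(0)).T @ (b - b.mean(0)) for b in (X1, X2)),
            start=np.zeros((8, 8)),
        )
        S = scatter / (len(X) - 2)
        sigma = (1 - alpha) * S + alpha * np.trace(S) / 8 * np.eye(8)
        w_oracle = np.linalg.inv(sigma) @ (X1.mean(0) - X2.mean(0))
        np.testing.assert_allclose(m.weights, w_oracle, rtol=1e-10)

    def test_separable_two_point_classes(self):
        X = np.array([[0.0, 0.1], [0.0, -0.1], [5.0, 0.1], [5.0, -0.1]])
        y = np.array(["a", "a", "b", "b"])
        m = fld_fit(X, y, shrinkage=0.5)
        pred, _ = fld_predict(m, X)
        np.testing.assert_array_equal(pred, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fld_fit(np.zeros((4, 2)), np.array(["a"] * 4))

    def test_singular_unshrunk_covariance_rejected(self):
        X = np.zeros((6, 4))
        X[:3, 0] = 1.0
        y = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fld_fit(X, y, shrinkage=0.0)


class TestFLDPredict:
    def test_class_mean_classified_correctly(self):
        rng = np.random.default_rng(2)
        X, y = _two_class_data(rng)
        m = fld_fit(X, y, shrinkage=0.1)
        pred, _ = fld_predict(m, X[y == "a"].mean(0, keepdims=True))
        assert pred[0] == "a"

    def test_zero_decision_value_goes_to_first_class(self):
        m = fld_fit(
            np.array([[1.0, 0], [1.1, 0], [-1.0, 0], [-1.1, 0]]),
            np.array(["a", "a", "b", "b"]),
            shrinkage=0.5,
        )
        # midpoint of the class means has decision value exactly 0
        mid = np.array([[0.0, 0.0]])
        pred, dec = fld_predict(m, mid)
        assert dec[0] == pytest.approx(0.0, abs=1e-12)
        assert pred[0] == "a"

    def test_predictions_match_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        X, y = _two_class_data(rng)
        Xt = rng.normal(size=(30, 6))
        m = fld_fit(X, y, shrinkage=0.2)
        pred, dec = fld_predict(m, Xt)
        dec_oracle = Xt @ m.weights + m.bias
        np.testing.assert_allclose(dec, dec_oracle, atol=1e-12)
        np.testing.assert_array_equal(pred, np.where(dec_oracle >= 0, "a", "b"))

    def test_voxel_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        X, y = _two_class_data(rng)
        m = fld_fit(X, y)
        with pytest.raises(ValueError, match="voxels"):
            fld_predict(m, rng.normal(size=(3, 9)))

    def test_positive_weight_scaling_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(5)
        X, y = _two_class_data(rng)
        Xt = rng.normal(size=(40, 6))
        m = fld_fit(X, y, shrinkage=0.1)
        pred1, _ = fld_predict(m, Xt)
        m.weights = m.weights * 37.5
        m.bias = m.bias * 37.5
        pred2, _ = fld_predict(m, Xt)
        np.testing.assert_array_equal(pred1, pred2)


class TestLORODecode:
    def _run_set(self, rng, n_runs=6, n_per_run=10, dim=5, sep=0.0):
        n = n_runs * n_per_run
        labels = np.tile(["leftward"] * (n_per_run // 2) + ["rightward"] * (n_per_run // 2), n_runs)
        X = rng.normal(size=(n, dim))
        X[np.array(labels) == "leftward", 0] += sep
        return make_pattern_set(X, labels=labels, runs=np.repeat(np.arange(n_runs), n_per_run))

    def test_fold_count_equals_run_count(self):
        ps = self._run_set(np.random.default_rng(6))
        res = loro_decode(ps, 0.1)
        assert res.n_folds == 6
        assert sorted(res.fold_test_runs) == list(range(6))

    def test_null_labels_give_chance_accuracy(self):
        """Labels independent of patterns: pooled accuracy within the 95%
        binomial band around 0.5."""
        accs = [
            loro_decode(self._run_set(np.random.default_rng(100 + i)), 0.1).pooled_accuracy
            for i in range(10)
        ]
        n_total = 60 * 10
        band = scipy.stats.binom.ppf([0.025, 0.975], n_total, 0.5) / n_total
        assert band[0] <= np.mean(accs) <= band[1]

    def test_noiseless_separable_data_decodes_perfectly(self):
        ps = self._run_set(np.random.default_rng(7), sep=50.0)
        assert loro_decode(ps, 0.1).pooled_accuracy == 1.0

    def test_trial_order_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ps = self._run_set(rng, sep=1.0)
        res1 = loro_decode(ps, 0.1)
        perm = rng.permutation(ps.n_trials)
        res2 = loro_decode(ps.select(perm), 0.1)
        assert res1.pooled_accuracy == pytest.approx(res2.pooled_accuracy)

    def test_missing_class_in_fold_is_an_error(self):
        X = np.random.default_rng(9).normal(size=(8, 3))
        labels = ["leftward"] * 4 + ["leftward", "leftward", "rightward", "rightward"]
        ps = make_pattern_set(X, labels=labels, runs=np.repeat([0, 1], 4))
        with pytest.raises(ValueError, match="fold"):
            loro_decode(ps, 0.1)

    def test_brute_force_oracle_equivalence(self):
        """Pooled accuracy equals a from-the-formula FLD reimplementation on
        a small instance."""
        rng = np.random.default_rng(10)
        ps = self._run_set(rng, n_runs=4, n_per_run=10, dim=6, sep=0.8)
        res = loro_decode(ps, 0.1)

        labels = ps.meta["orientation"].to_numpy()
        runs = ps.meta["run"].to_numpy()
        correct = 0
        for r in range(4):
            tr, te = runs != r, runs == r
            X, y = ps.matrix[tr], labels[tr]
            mu1, mu2 = X[y == "leftward"].mean(0), X[y == "rightward"].mean(0)
            sc = np.zeros((6, 6))
            for c in ("leftward", "rightward"):
                b = X[y == c] - X[y == c].mean(0)
                sc += b.T @ b
            S = sc / (len(X) - 2)
            sig = 0.9 * S + 0.1 * np.trace(S) / 6 * np.eye(6)
            w = np.linalg.inv(sig) @ (mu1 - mu2)
            dec = ps.matrix[te] @ w - 0.5 * w @ (mu1 + mu2)
            pred = np.where(dec >= 0, "leftward", "rightward")
            correct += int(np.sum(pred == labels[te]))
        assert res.pooled_accuracy == pytest.approx(correct / ps.n_trials)


class TestCrossTaskGeneralization:
    def test_invalid_period_rejected(self, tiny_subject):
        from attnping.pipeline import prepare_subject

        prep = prepare_subject(tiny_subject.patterns)
        with pytest.raises(ValueError, match="period"):
            cross_task_generalize(
                prep["V1"]["perception"], prep["V1"]["preparation"], "delay"
            )

    def test_self_test_is_optimistic(self):
        """Testing on the training set scores at least as well as held-out
        testing of the same data, on average over seeded replicates."""
        self_accs, cv_accs = [], []
        for i in range(10):
            rng = np.random.default_rng(11 + i)
            n = 40
            labels = np.array(["leftward", "rightward"] * (n // 2))
            X = rng.normal(size=(n, 5))
            X[labels == "leftward", 0] += 1.0
            train = make_pattern_set(X, labels=labels, runs=np.repeat([0, 1], 20),
                                     task="perception", period="perception")
            self_test = make_pattern_set(X, labels=labels, period="preparation")
            self_accs.append(
                cross_task_generalize(train, self_test, "preparation", 0.1).pooled_accuracy
            )
            cv_accs.append(loro_decode(train, 0.1).pooled_accuracy)
        assert np.mean(self_accs) >= np.mean(cv_accs)

    def test_generalization_tracks_latent_gain(self):
        """Median cross-task accuracy is nondecreasing in the ping gain
        lambda and near chance at lambda=0."""
        from attnping import EffectParams, SimConfig, make_ground_truth, simulate_subject
        from attnping.pipeline import prepare_subject

        medians = []
        for lam in (0.0, 0.5, 1.0):
            accs = []
            for s in range(6):
                cfg = SimConfig(
                    n_subjects_per_session=1, n_shared_subjects=0, n_voxels=24,
                    rois=("V1",), n_attention_runs=3, n_perception_runs=2,
                    trials_per_attention_run=24, trials_per_perception_run=16,
                    seed=0,
                )
                eff = EffectParams(lam={"V1": lam}, ping_gain_jitter_sd=0.0)
                gt = make_ground_truth(cfg, eff, seed=40 + s)
                ds = simulate_subject(gt, cfg, "Ping", "S0", seed=90 + s,
                                      propensity=1.0, accuracy=0.9)
                prep = prepare_subject(ds.patterns)["V1"]
                accs.append(
                    cross_task_generalize(
                        prep["perception"], prep["preparation"], "preparation", 0.1
                    ).pooled_accuracy
                )
            medians.append(np.median(accs))
        # near-chance without the latent component, clearly above with it,
        # nondecreasing across the grid up to replicate noise
        assert 0.35 < medians[0] < 0.65
        assert medians[2] > 0.65
        assert medians[0] <= medians[1] + 0.04 <= medians[2] + 0.08


class TestBatchSolver:
    def test_batch_weights_equal_naive_refits(self):
        """The eigendecomposition + Sherman-Morrison batch path reproduces
        fld_fit exactly for every relabeling."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(26, 7))
        labels = np.array(["a", "b"] * 13)
        perms = np.vstack([rng.permutation(labels) for _ in range(20)])
        solver = BatchFLDSolver(X, alpha=0.15)
        W, bias = solver.weights(perms == "a")
        for p in range(20):
            m = fld_fit(X, perms[p], shrinkage=0.15, classes=("a", "b"))
            np.testing.assert_allclose(W[p], m.weights, atol=1e-9)
            assert bias[p] == pytest.approx(m.bias, abs=1e-9)
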