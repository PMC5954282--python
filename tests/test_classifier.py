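"""Fold plans, the elastic-net solver (against two independent oracles),
the one-SE rule, score combination and the LOPO runner."""

import numpy as np
import pandas as pd
import pytest

import uipseq as u
from uipseq.classifier import (
    ClassifierError,
    binomial_deviance,
    _fista_enet,
)


# ---------------------------------------------------------------------------
# Independent oracle: split-variable full-gradient optimizer
# ---------------------------------------------------------------------------


def lbfgs_enet_oracle(Xs, y, lam, mixing):
    """Elastic-net logistic via w = u - v (u, v >= 0) and L-BFGS-B: a
    smooth, bound-constrained reformulation of the L1 term, solved with a
    full-gradient quasi-Newton method entirely independent of FISTA."""
    from scipy.optimize import minimize

    n, p = Xs.shape
    ypm = 2.0 * y - 1.0
    l1 = lam * mixing
    l2 = lam * (1.0 - mixing)

    def fun(theta):
        u_, v_, b = theta[:p], theta[p : 2 * p], theta[-1]
        w = u_ - v_
        z = Xs @ w + b
        sig = 1.0 / (1.0 + np.exp(-ypm * z))
        loss = np.mean(np.logaddexp(0.0, -ypm * z))
        f = loss + l1 * (u_.sum() + v_.sum()) + 0.5 * l2 * (w @ w)
        resid = -ypm * (1.0 - sig) / n
        gw = Xs.T @ resid + l2 * w
        gb = resid.sum()
        grad = np.concatenate([gw + l1, -gw + l1, [gb]])
        return f, grad

    theta0 = np.zeros(2 * p + 1)
    bounds = [(0, None)] * (2 * p) + [(None, None)]
    res = minimize(fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20000, "ftol": 1e-14, "gtol": 1e-10})
    return res.x[:p] - res.x[p : 2 * p], res.x[-1]


def _toy_problem(rng, n=60, p=10, informative=2, effect=2.0):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:informative] = effect
    logits = X @ beta
    y = (logits + rng.normal(scale=0.5, size=n) > 0).astype(int)
    cols = [f"g{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)]), y


class TestFoldPlans:
    def _labels(self, n_pat=10):
        return pd.Series(
            [i % 2 for i in range(n_pat)], index=[f"P{i}" for i in range(n_pat)]
        )

    def test_lopo_one_fold_per_patient(self):
        plan = u.make_fold_plan(self._labels(90), mode="lopo")
        assert len(plan.folds) == 90
        assert all(len(f.heldout_patients) == 1 for f in plan.folds)

    def test_kfold_balanced_sizes(self):
        plan = u.make_fold_plan(self._labels(90), mode="kfold", k=5, seed=0)
        sizes = [len(f.heldout_patients) for f in plan.folds]
        assert sizes == [18] * 5

    def test_patients_never_straddle(self):
        plan = u.make_fold_plan(self._labels(20), mode="kfold", k=4, seed=1)
        for f in plan.folds:
            assert not set(f.train_patients) & set(f.heldout_patients)
        held = [p for f in plan.folds for p in f.heldout_patients]
        assert sorted(held) == sorted(self._labels(20).index)

    def test_seeded_determinism(self):
        a = u.make_fold_plan(self._labels(30), mode="kfold", k=5, seed=3)
        b = u.make_fold_plan(self._labels(30), mode="kfold", k=5, seed=3)
        assert a.folds == b.folds

    def test_single_class_fold_warns_but_kept(self):
        labels = pd.Series([1, 1, 0], index=["P0", "P1", "P2"])
        with pytest.warns(UserWarning, match="single class"):
            plan = u.make_fold_plan(labels, mode="lopo")
        assert len(plan.folds) == 3


class TestElasticNetLogit:
    def test_separable_toy_reaches_training_auc_one(self, rng):
        X, y = _toy_problem(rng, effect=4.0)
        res = u.ElasticNetLogit(X, y, lam=1e-3, mixing=0.5).fit(tol=1e-8)
        auc, _ = u.roc_auc(res.linear_predictor(X), y)
        assert auc == 1.0

    def test_large_lambda_zeroes_all_weights(self, rng):
        X, y = _toy_problem(rng)
        res = u.ElasticNetLogit(X, y, lam=50.0, mixing=1.0).fit()
        assert (res.params == 0).all()
        scores = res.linear_predictor(X)
        assert np.allclose(scores, res.intercept)

    @pytest.mark.parametrize("lam,mixing", [(0.05, 1.0), (0.05, 0.5), (0.2, 0.25)])
    def test_matches_full_gradient_oracle(self, rng, lam, mixing):
        X, y = _toy_problem(rng)
        Xs = (X - X.mean()) / X.std()
        w_or, b_or = lbfgs_enet_oracle(Xs.to_numpy(), y, lam, mixing)
        w, b, _, conv = _fista_enet(Xs.to_numpy(), y.astype(float), lam, mixing,
                                    tol=1e-10, max_iter=100000)
        assert conv
        np.testing.assert_allclose(w, w_or, atol=1e-4)
        assert b == pytest.approx(b_or, abs=1e-4)

    def test_matches_sklearn_saga(self, rng):
        from sklearn.linear_model import LogisticRegression

        X, y = _toy_problem(rng, n=80, p=15)
        lam, mixing = 0.05, 0.5
        Xs = ((X - X.mean()) / X.std()).to_numpy()
        clf = LogisticRegression(
            C=1.0 / (len(y) * lam), l1_ratio=mixing, solver="saga",
            tol=1e-10, max_iter=200000, random_state=0,
        ).fit(Xs, y)
        w, b, _, _ = _fista_enet(Xs, y.astype(float), lam, mixing,
                                 tol=1e-10, max_iter=100000)
        np.testing.assert_allclose(w, clf.coef_[0], atol=2e-4)

    def test_standardization_folded_back(self, rng):
        """Scoring raw expression equals scoring standardized expression."""
        X, y = _toy_problem(rng)
        X = X * 7.0 + 3.0
        res = u.ElasticNetLogit(X, y, lam=0.05, mixing=0.5).fit()
        clf = res.to_classifier()
        expr = X.T
        direct = res.linear_predictor(X)
        via_artifact = clf.score(expr.loc[clf.genes])
        np.testing.assert_allclose(direct[via_artifact.index], via_artifact, rtol=1e-9)

    def test_single_class_rejected(self, rng):
        X, _ = _toy_problem(rng)
        with pytest.raises(ClassifierError):
            u.ElasticNetLogit(X, np.ones(len(X)), 0.1, 0.5)

    def test_recovers_planted_signature(self, small_pipeline):
        """Most selected genes carry planted class-discriminative signal
        (a class effect, or a subtype shift marking a non-UIP condition)."""
        p = small_pipeline
        clf = u.train_penalized_logistic(p["expr"], p["labels"], 0.02, 0.5)
        truth = p["cohort"].gene_truth
        assert len(clf.genes) > 0
        planted = truth["informative"] | truth["subtype_shifted"]
        assert planted.loc[clf.genes].mean() >= 0.8
        # the class-informative set dominates the selection
        assert truth.loc[clf.genes, "informative"].mean() >= 0.5

    def test_summary_mentions_sparsity(self, rng):
        X, y = _toy_problem(rng)
        res = u.ElasticNetLogit(X, y, lam=0.05, mixing=1.0).fit()
        assert "nonzero weights" in res.summary()


class TestScoreAndSerialization:
    def test_dot_product_example(self):
        clf = u.TrainedClassifier(genes=["g1", "g2"], weights=[1.0, -1.0],
                                  intercept=0.0, lam=0.1, mixing=0.5)
        expr = pd.DataFrame([[2.0], [1.0]], index=["g1", "g2"], columns=["s"])
        assert clf.score(expr)["s"] == pytest.approx(1.0)

    def test_zero_weights_score_is_intercept(self):
        clf = u.TrainedClassifier(genes=[], weights=[], intercept=-0.3,
                                  lam=0.1, mixing=0.5)
        expr = pd.DataFrame(np.zeros((2, 3)), index=["g1", "g2"])
        assert np.allclose(clf.score(expr), -0.3)

    def test_affine_equivariance(self):
        expr = pd.DataFrame([[2.0, 5.0], [1.0, -1.0]], index=["g1", "g2"])
        a = u.TrainedClassifier(["g1", "g2"], [1.0, 2.0], 0.0, 0.1, 0.5)
        b = u.TrainedClassifier(["g1", "g2"], [2.0, 4.0], 0.0, 0.1, 0.5)
        np.testing.assert_allclose(2 * a.score(expr), b.score(expr))

    def test_missing_gene_error_names_gene(self):
        clf = u.TrainedClassifier(["gX"], [1.0], 0.0, 0.1, 0.5)
        expr = pd.DataFrame([[1.0]], index=["g1"])
        with pytest.raises(ClassifierError, match="gX"):
            clf.score(expr)

    def test_json_roundtrip_keeps_boundary(self, tmp_path):
        clf = u.TrainedClassifier(["g1"], [0.5], 0.1, 0.05, 0.7)
        clf.lock_boundary(0.87)
        path = str(tmp_path / "clf.json")
        clf.to_json(path)
        back = u.TrainedClassifier.from_json(path)
        assert back.boundary == 0.87
        assert back.content_hash() == clf.content_hash()


class TestOneSERule:
    def test_hand_example_picks_middle_candidate(self):
        table = pd.DataFrame(
            {
                "lam": [0.3, 0.2, 0.1],  # regularization decreasing down
                "mixing": [0.5, 0.5, 0.5],
                "mean_deviance": [0.30, 0.21, 0.20],
                "se_deviance": [0.02, 0.02, 0.02],
            }
        )
        chosen = u.one_se_select(table)
        assert chosen["mean_deviance"] == pytest.approx(0.21)
        assert chosen["lam"] == pytest.approx(0.2)

    def test_single_candidate_returned_unchanged(self):
        table = pd.DataFrame(
            {"lam": [0.1], "mixing": [0.9], "mean_deviance": [0.5], "se_deviance": [0.1]}
        )
        assert u.one_se_select(table)["lam"] == 0.1

    def test_tuning_is_seeded(self, small_pipeline):
        p = small_pipeline
        search = u.SearchSpec(n_draws=3, inner_k=2, seed=21)
        a = u.tune_hyperparameters(p["expr"], p["labels"], p["patient_map"], search, seed=4)
        b = u.tune_hyperparameters(p["expr"], p["labels"], p["patient_map"], search, seed=4)
        assert a[0] == b[0] and a[1] == b[1]

    def test_deviance_of_zero_scores(self):
        assert binomial_deviance(np.zeros(4), np.array([0, 1, 0, 1])) == pytest.approx(
            2 * np.log(2)
        )


class TestEnsembleScore:
    def test_weighted_average(self):
        s1 = pd.Series([1.0], index=["a"])
        s2 = pd.Series([3.0], index=["a"])
        out = u.ensemble_score([s1, s2], [0.5, 0.5])
        assert out["a"] == pytest.approx(2.0)

    def test_single_component_identity(self):
        s = pd.Series([1.0, -2.0], index=["a", "b"])
        pd.testing.assert_series_equal(u.ensemble_score([s], [1.0]), s.rename("score"))

    def test_permutation_symmetry(self, rng):
        s1 = pd.Series(rng.normal(size=4), index=list("abcd"))
        s2 = pd.Series(rng.normal(size=4), index=list("abcd"))
        a = u.ensemble_score([s1, s2], [0.3, 0.7])
        b = u.ensemble_score([s2, s1], [0.7, 0.3])
        pd.testing.assert_series_equal(a, b)

    def test_weights_must_sum_to_one(self):
        s = pd.Series([1.0], index=["a"])
        with pytest.raises(ClassifierError, match="sum to 1"):
            u.ensemble_score([s, s], [0.5, 0.6])


class TestRunLopo:
    def test_every_score_excludes_its_patient(self, small_cv):
        assert small_cv.audit_no_leakage()

    def test_fold_count_and_replicates(self, small_cv, small_pipeline):
        n_pat = small_pipeline["labels"].groupby(
            small_pipeline["patient_map"]
        ).first().shape[0]
        assert len(small_cv.fold_info) == n_pat
        reps = small_cv.replicate_scores.groupby("patient").size()
        assert (reps == small_pipeline["noise"].n_replicates).all()

    def test_patient_level_auc_at_least_sample_level(self, small_cv):
        assert small_cv.pooled_auc("patient") >= small_cv.pooled_auc("sample") - 0.02

    def test_requires_exactly_one_of_search_or_hyper(self, small_pipeline):
        p = small_pipeline
        with pytest.raises(ClassifierError):
            u.run_lopo(p["expr"], p["bio"], p["labels"], p["patient_map"],
                       p["frozen"], p["noise"])

    def test_seeded_determinism(self, small_pipeline, small_cv):
        p = small_pipeline
        again = u.run_lopo(p["expr"], p["bio"], p["labels"], p["patient_map"],
                           p["frozen"], p["noise"], hyper=(0.02, 0.5), seed=17)
        pd.testing.assert_frame_equal(again.sample_scores, small_cv.sample_scores)
        pd.testing.assert_frame_equal(again.replicate_scores, small_cv.replicate_scores)
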