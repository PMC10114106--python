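import numpy as np
import pandas as pd
import pytest

from polyexposure.cohort import CohortError
from polyexposure.fitting import fit_linear, fit_logistic
from polyexposure.penalized import (build_design, cv_elastic_net,
                                    cv_hier_interaction_lasso,
                                    enet_path_gaussian, enet_path_logistic,
                                    enet_path_cox, lambda_max_enet,
                                    make_folds, soft_threshold,
                                    _fista_group_lasso, _latent_layout,
                                    lambda_max_group)
from polyexposure.simulate import TruthSpec, generate_cohort
from conftest import make_cohort


def lm_instance(rng, n=80, p=6):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.r_[1.0, -0.5, np.zeros(p - 2)]
    y = X @ beta + rng.standard_normal(n)
    return X, y


class TestBuildDesign:
    def test_interaction_group_counting(self):
        spec = TruthSpec(n=50, n_continuous=2, n_categorical=0, effects={},
                         covariate_effects={}, missing_rate=0, unwanted_rate=0,
                         seed=0)
        d = build_design(generate_cohort(spec).cohort, ["exp01", "exp02"],
                         interactions=True)
        mains = [g for g in d.groups if g.kind == "main"]
        inters = [g for g in d.groups if g.kind == "interaction"]
        assert len(mains) == 2 and len(inters) == 1
        assert len(inters[0].cols) == 3          # two mains + one product

    def test_categorical_dummy_reference(self):
        frame = pd.DataFrame({"ID": list("abcdef"), "PHENO": np.arange(6.0),
                              "c": ["lo", "mid", "hi", "lo", "mid", "hi"]})
        c = make_cohort(frame, levels={"c": ["lo", "mid", "hi"]})
        d = build_design(c, ["c"])
        assert d.terms[:2] == ["c=mid", "c=hi"]  # reference level dropped

    def test_constant_exposure_dropped_with_warning(self, caplog):
        frame = pd.DataFrame({"ID": list("abcd"), "PHENO": np.arange(4.0),
                              "flat": [1.0] * 4, "ok": [1.0, 2, 3, 4]})
        with caplog.at_level("WARNING"):
            d = build_design(make_cohort(frame), ["flat", "ok"])
        assert d.terms == ["ok"]
        with pytest.raises(CohortError):
            build_design(make_cohort(frame[["ID", "PHENO", "flat"]].assign(flat=1.0)),
                         ["flat"])

    def test_standardization_recorded(self, lm_synthetic):
        from polyexposure.cohort import complete_cases
        cc = complete_cases(lm_synthetic.cohort, ["exp01", "age"])
        d = build_design(cc, ["exp01"], ["age"])
        col = d.X[:, d.col("exp01")]
        assert abs(col.mean()) < 1e-12 and abs(col.std() - 1) < 1e-12
        assert d.penalty_factor[d.col("age")] == 0


class TestElasticNet:
    def test_all_zero_at_analytic_lambda_max(self, rng):
        X, y = lm_instance(rng)
        n, p = X.shape
        Xi = np.column_stack([X, np.ones(n)])
        pf = np.r_[np.ones(p), 0.0]
        lam_max = lambda_max_enet(Xi, pf, 1.0, "lm", y=y)
        expected = np.max(np.abs(X.T @ (y - y.mean()))) / n
        assert lam_max == pytest.approx(expected, rel=1e-10)
        beta = enet_path_gaussian(Xi, y, np.array([lam_max, lam_max * 1.5]), 1.0, pf)
        assert np.all(beta[:, :p] == 0.0)
        just_below = enet_path_gaussian(Xi, y, np.array([lam_max * 0.99]), 1.0, pf)
        assert np.any(just_below[0, :p] != 0.0)

    def test_orthonormal_soft_threshold_closed_form(self, rng):
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)                 # X'X = n I
        y = rng.standard_normal(n)
        ols = X.T @ y / n
        for lam in (0.02, 0.1, 0.3):
            beta = enet_path_gaussian(X, y, np.array([lam]), 1.0)[0]
            expected = [soft_threshold(o, lam) for o in ols]
            assert np.allclose(beta, expected, atol=1e-6)

    def test_unpenalized_limit_matches_glm_engines(self, rng):
        X, y = lm_instance(rng, n=100, p=4)
        Xi = np.column_stack([np.ones(100), X])
        beta = enet_path_gaussian(Xi, y, np.array([0.0]), 1.0,
                                  np.r_[0.0, np.ones(4)])[0]
        ols = fit_linear(pd.DataFrame(Xi), y)
        assert np.allclose(beta, ols.beta, atol=1e-4)
        yb = (y > 0).astype(float)
        blog = enet_path_logistic(Xi, yb, np.array([0.0]), 1.0,
                                  np.r_[0.0, np.ones(4)])[0]
        glm = fit_logistic(pd.DataFrame(Xi), yb)
        assert np.allclose(blog, glm.beta, atol=1e-4)

    def test_matches_sklearn_lasso(self, rng):
        # independent implementation of the same Gaussian lasso objective
        from sklearn.linear_model import Lasso
        X, y = lm_instance(rng, n=120, p=10)
        for lam in (0.05, 0.2):
            ours = enet_path_gaussian(X, y, np.array([lam]), 1.0)[0]
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                        max_iter=100000).fit(X, y).coef_
            assert np.allclose(ours, ref, atol=1e-6)

    def test_kkt_subgradient_conditions(self, rng):
        X, y = lm_instance(rng, n=90, p=8)
        n = X.shape[0]
        lam = 0.08
        beta = enet_path_gaussian(X, y, np.array([lam]), 1.0, tol=1e-14)[0]
        g = X.T @ (X @ beta - y) / n
        for j in range(X.shape[1]):
            if beta[j] != 0:
                assert abs(g[j] + lam * np.sign(beta[j])) < 1e-6
            else:
                assert abs(g[j]) <= lam + 1e-6

    def test_warm_equals_cold_start(self, rng):
        X, y = lm_instance(rng)
        lams = np.geomspace(0.5, 0.005, 25)
        warm = enet_path_gaussian(X, y, lams, 1.0, tol=1e-14)
        for i in (0, 8, 24):
            cold = enet_path_gaussian(X, y, np.array([lams[i]]), 1.0, tol=1e-14)[0]
            assert np.allclose(warm[i], cold, atol=1e-6)

    def test_cox_path_recovers_signal_support(self, rng):
        spec = TruthSpec(n=600, n_continuous=5, n_categorical=0, family="cox",
                         effects={"exp01": 0.8}, covariate_effects={},
                         missing_rate=0, unwanted_rate=0, seed=5)
        syn = generate_cohort(spec)
        d = build_design(syn.cohort, syn.cohort.exposures)
        t = syn.cohort.time.to_numpy(float)
        e = syn.cohort.event.to_numpy(float)
        lam_max = lambda_max_enet(d.X, d.penalty_factor, 1.0, "cox",
                                  time=t, event=e)
        betas = enet_path_cox(d.X, t, e, np.array([lam_max, lam_max * 0.1]),
                              1.0, d.penalty_factor)
        assert np.all(betas[0] == 0)
        assert betas[1][d.col("exp01")] > 0.2

    def test_fold_assignment_deterministic_and_stratified(self):
        strat = np.r_[np.zeros(70), np.ones(30)]
        f1 = make_folds(100, 5, seed=3, strat=strat)
        f2 = make_folds(100, 5, seed=3, strat=strat)
        assert np.array_equal(f1, f2)
        for f in range(5):
            assert strat[f1 == f].sum() == 6      # 30 positives dealt evenly
        with pytest.raises(ValueError):
            make_folds(4, 10, seed=0)

    def test_cv_selects_true_support_lm(self, lm_synthetic):
        c = lm_synthetic.cohort
        from polyexposure.cohort import complete_cases
        cc = complete_cases(c, c.exposures + ["age", "sex"])
        d = build_design(cc, c.exposures, ["age", "sex"])
        fit = cv_elastic_net(d, y=cc.pheno.to_numpy(float), family="lm",
                             k=5, seed=0, n_lambda=60)
        assert set(fit.selected_exposures) >= {"exp01", "exp02", "exp03", "exp04"}
        assert fit.lambda_min in fit.lambda_path
        nz = {t for t, v in fit.beta.items() if v != 0}
        for e in fit.selected_exposures:
            assert any(t in nz for t in d.coding.terms_of(e))

    def test_alpha_validation(self, lm_synthetic):
        d = build_design(lm_synthetic.cohort.subset_ids(
            lm_synthetic.cohort.ids[:100]), ["exp01", "exp02"])
        with pytest.raises(ValueError):
            cv_elastic_net(d, y=np.zeros(100), family="lm", alpha=1.5)


def small_interaction_design(rng, n=120, p=4):
    spec = TruthSpec(n=n, n_continuous=p, n_categorical=0,
                     effects={"exp01": 0.5, "exp02": 0.5},
                     interaction_effects={("exp01", "exp02"): 0.5},
                     covariate_effects={}, missing_rate=0, unwanted_rate=0,
                     seed=int(rng.integers(1 << 30)))
    syn = generate_cohort(spec)
    d = build_design(syn.cohort, syn.cohort.exposures, interactions=True)
    return d, syn.cohort.pheno.to_numpy(float)


class TestHierarchicalGroupLasso:
    def test_hierarchy_on_random_fits(self, rng):
        for _ in range(10):
            d, y = small_interaction_design(rng)
            fit = cv_hier_interaction_lasso(d, y, "lm", k=3, seed=1, n_lambda=20)
            for a, b in fit.selected_interactions:
                assert a in fit.selected_exposures
                assert b in fit.selected_exposures

    def test_full_shrinkage_above_lambda_max(self, rng):
        d, y = small_interaction_design(rng)
        idx, blocks, free_start, n_int = _latent_layout(d, True)
        Xt = np.column_stack([d.X[:, idx], np.ones(d.n)])
        lam_max = lambda_max_group(Xt, y, "lm", blocks, free_start)
        thetas = _fista_group_lasso(Xt, y, "lm", np.array([lam_max * 1.01]),
                                    blocks, free_start, n_int)
        assert np.all(thetas[0][:free_start] == 0.0)

    def test_fista_reaches_convex_optimum(self, rng):
        # tiny instance: compare to a derivative-free optimizer and check
        # the group-lasso subgradient optimality conditions
        from scipy.optimize import minimize
        n, q = 40, 5
        X = rng.standard_normal((n, q))
        y = rng.standard_normal(n)

        class G:
            pass
        blocks = []
        for a, b in [(0, 2), (2, 4)]:
            g = G()
            g.weight = np.sqrt(b - a)
            blocks.append((a, b, g))
        lam = 0.15

        def objective(th):
            r = X @ th - y
            return 0.5 * r @ r / n + lam * sum(
                g.weight * np.linalg.norm(th[a:b]) for a, b, g in blocks)

        theta = _fista_group_lasso(X, y, "lm", np.array([lam]), blocks, 4, 1,
                                   tol=1e-14, max_iter=20000)[0]
        ref = minimize(objective, np.zeros(q), method="Powell",
                       options={"xtol": 1e-12, "ftol": 1e-12, "maxiter": 100000})
        assert objective(theta) <= ref.fun + 1e-8
        grad = X.T @ (X @ theta - y) / n
        for a, b, g in blocks:
            blk = theta[a:b]
            if np.linalg.norm(blk) > 0:
                assert np.allclose(grad[a:b] + lam * g.weight * blk / np.linalg.norm(blk),
                                   0.0, atol=1e-6)
            else:
                assert np.linalg.norm(grad[a:b]) <= lam * g.weight + 1e-6

    def test_true_interaction_selected(self):
        hits = 0
        for seed in range(6):
            spec = TruthSpec(n=900, n_continuous=6, n_categorical=0,
                             effects={"exp01": 0.5, "exp02": 0.5},
                             interaction_effects={("exp01", "exp02"): 0.5},
                             covariate_effects={}, missing_rate=0,
                             unwanted_rate=0, seed=100 + seed)
            syn = generate_cohort(spec)
            d = build_design(syn.cohort, syn.cohort.exposures, interactions=True)
            fit = cv_hier_interaction_lasso(
                d, syn.cohort.pheno.to_numpy(float), "lm", k=3, seed=seed,
                n_lambda=30)
            if ("exp01", "exp02") in fit.selected_interactions:
                hits += 1
        assert hits >= 5

    def test_requires_interaction_groups(self, lm_synthetic):
        d = build_design(lm_synthetic.cohort, ["exp01", "exp02"])
        with pytest.raises(ValueError, match="interaction"):
            cv_hier_interaction_lasso(d, np.zeros(d.n), "lm")
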