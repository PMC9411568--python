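"""Risk-score models: covariate preparation, penalized fits, double CV,
scoring and weight projection."""

import numpy as np
import pandas as pd
import pytest

from methrisk.models import (
    PenaltySpec, compute_score, cv_baseline, double_cv, fit_baseline,
    fit_penalized, prepare_covariates, project_external_score,
    restrict_to_array, select_best_model,
)
from methrisk._solver import auto_lambda_path

SEED = 12345


class TestPrepareCovariates:
    def test_dummy_coding(self, toy_covariates):
        X = prepare_covariates(toy_covariates)
        smoking_cols = [c for c in X.columns if c.startswith("smoking_")]
        assert len(smoking_cols) == 2  # 3 levels -> 2 indicators

    def test_simplex_collinearity_detected(self, toy_covariates, rng):
        props = pd.DataFrame(rng.dirichlet(np.ones(3), size=len(toy_covariates)),
                             columns=["cell_a", "cell_b", "cell_c"],
                             index=toy_covariates.index)
        # full simplex + intercept is rank-deficient
        with pytest.raises(ValueError, match="rank-deficient"):
            bad = pd.concat([toy_covariates, props], axis=1)
            prepare_covariates(bad)
        # the prepared path drops one column and passes
        X = prepare_covariates(toy_covariates, cell_props=props)
        assert "cell_a" not in X.columns and "cell_b" in X.columns

    def test_constant_column_rejected(self, toy_covariates):
        bad = toy_covariates.assign(const=1.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            prepare_covariates(bad)


class TestBaseline:
    def test_exact_linear_recovery(self, toy_covariates):
        X = prepare_covariates(toy_covariates)
        y = 2.0 * X["age"].to_numpy()
        model = fit_baseline(y, X, "linear")
        assert model.covariate_effects["age"] == pytest.approx(2.0, abs=1e-8)
        resid = y - model.predict(covariates=X).to_numpy()
        assert np.abs(resid).max() < 1e-8

    def test_row_permutation_invariance(self, toy_covariates, rng):
        X = prepare_covariates(toy_covariates)
        y = rng.normal(size=len(X))
        m1 = fit_baseline(y, X, "linear")
        perm = rng.permutation(len(X))
        m2 = fit_baseline(y[perm], X.iloc[perm], "linear")
        pd.testing.assert_series_equal(m1.covariate_effects, m2.covariate_effects,
                                       atol=1e-10)

    def test_null_baseline_cv_metric_near_zero(self, toy_covariates, rng):
        X = prepare_covariates(toy_covariates)
        n = len(X)
        y = rng.normal(size=n)
        pred = cv_baseline(y, X, seed=SEED, outcome="null")
        assert pred.metric < 0.1  # no signal to find

    def test_separation_falls_back(self):
        n = 40
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]},
                         index=[f"s{i}" for i in range(n)])
        y = X["x"].to_numpy()  # perfectly separable
        model = fit_baseline(y, X, "logistic")
        assert np.isfinite(model.covariate_effects["x"])


def _toy_problem(n=60, p=8, seed=SEED, binary=False):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    G = pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                     columns=[f"cg{j}" for j in range(p)])
    C = pd.DataFrame({"age": rng.uniform(18, 90, n), "sex": rng.integers(0, 2, n)},
                     index=idx, dtype=float)
    lp = G.iloc[:, 0] * 1.0 - G.iloc[:, 1] * 0.5 + 0.01 * C["age"]
    if binary:
        y = (rng.random(n) < 1 / (1 + np.exp(-(lp - lp.mean())))).astype(float).to_numpy()
    else:
        y = (lp + rng.normal(0, 0.5, n)).to_numpy()
    return y, G, C


class TestPenalized:
    def test_large_lambda_reduces_to_baseline(self):
        for binary in (False, True):
            y, G, C = _toy_problem(binary=binary)
            link = "logistic" if binary else "linear"
            spec = PenaltySpec("lasso", link=link)
            m = fit_penalized(y, G, C, spec, lam=1e6)
            assert m.n_selected == 0
            base = fit_baseline(y, C, link)
            np.testing.assert_allclose(m.predict(G, C), base.predict(covariates=C),
                                       atol=1e-6)

    def test_zero_genomic_matrix_reproduces_baseline(self):
        y, G, C = _toy_problem()
        Z = G * 0.0
        m = fit_penalized(y, Z, C, PenaltySpec("ridge"), lam=0.5)
        base = fit_baseline(y, C, "linear")
        np.testing.assert_allclose(m.predict(Z, C), base.predict(covariates=C),
                                   atol=1e-6)

    def test_small_ridge_approaches_ols(self):
        # 50 x 5, n > p: ridge at tiny lambda ~ closed-form joint least squares
        rng = np.random.default_rng(SEED)
        n, p = 50, 5
        idx = [f"s{i}" for i in range(n)]
        G = pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                         columns=[f"g{j}" for j in range(p)])
        C = pd.DataFrame({"age": rng.normal(size=n)}, index=idx)
        y = rng.normal(size=n)
        m = fit_penalized(y, G, C, PenaltySpec("ridge"), lam=1e-8, tol=1e-12)
        X = np.column_stack([np.ones(n), C.to_numpy(), G.to_numpy()])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(m.intercept, coef[0], atol=1e-4)
        np.testing.assert_allclose(m.covariate_effects.to_numpy(), coef[1:2], atol=1e-4)
        full_w = pd.Series(0.0, index=G.columns)
        full_w[m.weights.index] = m.weights
        np.testing.assert_allclose(full_w.to_numpy(), coef[2:], atol=1e-4)

    def test_lasso_kkt_stationarity(self):
        y, G, C = _toy_problem(n=80, p=20)
        Gn = G.to_numpy()
        Gs = (Gn - Gn.mean(0)) / Gn.std(0)
        Cn = C.to_numpy()
        Cs = (Cn - Cn.mean(0)) / Cn.std(0)
        X = np.column_stack([Cs, Gs])
        pf = np.r_[np.zeros(2), np.ones(20)]
        lams = auto_lambda_path(X, y, pf, 1.0)
        lam = lams[40]
        m = fit_penalized(y, G, C, PenaltySpec("lasso"), lam=lam, tol=1e-9)
        # reconstruct the standardized-scale solution and check KKT
        beta_std = np.zeros(20)
        w = m.weights.reindex(G.columns).fillna(0.0).to_numpy()
        beta_std = w * Gn.std(0)
        cov_std = m.covariate_effects.to_numpy() * Cn.std(0)
        eta = m.predict(G, C).to_numpy()
        r = y - eta
        grad = np.abs(r @ Gs) / len(y)
        zero = beta_std == 0
        assert (grad[zero] <= lam + 1e-4).all()
        # active features sit at the boundary
        active = ~zero
        if active.any():
            np.testing.assert_allclose(grad[active], lam, atol=1e-4)

    def test_sparsity_monotone_in_lambda(self):
        y, G, C = _toy_problem(n=100, p=30)
        spec = PenaltySpec("lasso")
        counts = []
        for lam in (0.5, 0.2, 0.05, 0.01):
            counts.append(fit_penalized(y, G, C, spec, lam=lam).n_selected)
        assert counts == sorted(counts)

    def test_bad_lambda(self):
        y, G, C = _toy_problem()
        with pytest.raises(ValueError):
            fit_penalized(y, G, C, PenaltySpec("lasso"), lam=0.0)


class TestGlmnetOracle:
    def test_logistic_lasso_with_unpenalized_covariates_matches_glmnet(self, tmp_path):
        """Independent cross-check of the coordinate-descent solver against
        R glmnet on the exact objective (glmnet rescales penalty factors to
        sum to nvars, so its lambda is adjusted by sum(pf)/p)."""
        import subprocess
        from methrisk._solver import fit_single

        rng = np.random.default_rng(SEED)
        n, p = 120, 20
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        lp = X[:, :3] @ np.array([1.0, -0.5, 0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        pf = np.ones(p)
        pf[:3] = 0.0
        lam = 0.03
        alpha, beta = fit_single(X, y, pf, 1.0, lam, link="logistic", tol=1e-10)
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y)
        script = f"""
        suppressMessages(library(glmnet))
        X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
        y <- scan("{tmp_path}/y.csv", quiet=TRUE)
        pf <- rep(1, {p}); pf[1:3] <- 0
        f <- glmnet(X, y, family="binomial", alpha=1,
                    lambda={lam} * sum(pf) / {p}, standardize=FALSE,
                    penalty.factor=pf, thresh=1e-14, maxit=1e6)
        write.csv(as.numeric(coef(f)), "{tmp_path}/ref.csv", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = np.loadtxt(tmp_path / "ref.csv", skiprows=1)
        assert abs(alpha - ref[0]) < 1e-6
        np.testing.assert_allclose(beta, ref[1:], atol=1e-6)


class TestDoubleCV:
    def test_seed_determinism(self):
        y, G, C = _toy_problem(n=80, p=15)
        a = double_cv(y, G, C, families=("lasso",), outer_k=5, inner_k=4,
                      seed=SEED, outcome="t")
        b = double_cv(y, G, C, families=("lasso",), outer_k=5, inner_k=4,
                      seed=SEED, outcome="t")
        pd.testing.assert_series_equal(a["lasso"].yhat, b["lasso"].yhat)
        pd.testing.assert_series_equal(a["lasso"].fold_assignment,
                                       b["lasso"].fold_assignment)

    def test_each_sample_predicted_once_and_fold_balance(self):
        y, G, C = _toy_problem(n=83, p=10)
        res = double_cv(y, G, C, families=("lasso",), outer_k=10, inner_k=4,
                        seed=SEED)["lasso"]
        sizes = res.fold_assignment.value_counts()
        assert len(res.yhat) == 83
        assert sizes.max() - sizes.min() <= 1

    def test_signal_recovered(self):
        y, G, C = _toy_problem(n=150, p=25)
        res = double_cv(y, G, C, families=("lasso",), outer_k=5, inner_k=5,
                        seed=SEED)["lasso"]
        assert res.metric > 0.3

    def test_single_class_fold_rejected(self):
        y, G, C = _toy_problem(n=40, p=5, binary=True)
        y[:] = 0.0
        y[0] = 1.0  # cannot stratify one case into 5 folds
        with pytest.raises(ValueError):
            double_cv(y, G, C, families=("lasso",), outer_k=5, inner_k=3,
                      seed=SEED, link="logistic")


class TestSelectBest:
    @staticmethod
    def _pred(family, metric):
        from methrisk.models import CrossValidatedPrediction
        return CrossValidatedPrediction(
            outcome="o", family=family, link="linear",
            yhat=pd.Series(dtype=float), fold_assignment=pd.Series(dtype=int),
            metric=metric, metric_name="r2")

    def test_highest_metric_wins(self):
        preds = {f: self._pred(f, m) for f, m in
                 [("lasso", 0.5), ("elastic_net", 0.7), ("ridge", 0.6)]}
        assert select_best_model(preds).family == "elastic_net"

    def test_tie_prefers_sparser(self):
        preds = {f: self._pred(f, 0.5) for f in ("ridge", "lasso")}
        assert select_best_model(preds).family == "lasso"

    def test_single_family_passthrough(self):
        preds = {"ridge": self._pred("ridge", 0.4)}
        assert select_best_model(preds).family == "ridge"


class TestComputeScore:
    def test_hand_arithmetic(self):
        w = pd.Series({"a": 0.5, "b": -1.0})
        X = pd.DataFrame({"a": [0.2], "b": [0.1]})
        assert compute_score(w, X).iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_zero_weights(self):
        w = pd.Series({"a": 0.0, "b": 0.0})
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert (compute_score(w, X) == 0).all()

    def test_matches_loop_oracle(self, rng):
        cols = [f"f{j}" for j in range(100)]
        w = pd.Series(rng.normal(size=100), index=cols)
        X = pd.DataFrame(rng.uniform(size=(7, 100)), columns=cols)
        ours = compute_score(w, X)
        for i in range(7):
            ref = sum(w[c] * X.iloc[i][c] for c in cols)
            assert ours.iloc[i] == pytest.approx(ref, abs=1e-12)

    def test_missing_feature_policies(self, rng):
        cols = [f"f{j}" for j in range(10)]
        w = pd.Series(rng.normal(size=10), index=cols)
        X = pd.DataFrame(rng.uniform(size=(3, 6)), columns=cols[:6])
        with pytest.raises(KeyError):
            compute_score(w, X)
        s = compute_score(w, X, missing_policy="drop")
        assert s.attrs["n_missing_features"] == 4
        with pytest.raises(ValueError, match="harmonization"):
            compute_score(w, X[cols[:4]], missing_policy="drop")


class TestExternalScore:
    @staticmethod
    def _setup():
        dosages = pd.DataFrame({"rs1": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        alleles = pd.DataFrame({"effect_allele": ["A"], "other_allele": ["G"]},
                               index=["rs1"])
        return dosages, alleles

    def test_matched_alleles(self):
        dosages, alleles = self._setup()
        wt = pd.DataFrame({"rsid": ["rs1"], "effect_allele": ["A"],
                           "other_allele": ["G"], "effect_weight": [1.0]})
        s, rep = project_external_score(dosages, wt, alleles)
        np.testing.assert_allclose(s.to_numpy(), [0, 1, 2])

    def test_swapped_alleles_flip(self):
        dosages, alleles = self._setup()
        wt = pd.DataFrame({"rsid": ["rs1"], "effect_allele": ["G"],
                           "other_allele": ["A"], "effect_weight": [1.0]})
        s, rep = project_external_score(dosages, wt, alleles)
        np.testing.assert_allclose(s.to_numpy(), [2, 1, 0])
        assert rep["n_flipped"] == 1

    def test_matches_brute_force_on_random_table(self, rng):
        m = 20
        vids = [f"rs{j}" for j in range(m)]
        dos = pd.DataFrame(rng.integers(0, 3, size=(15, m)).astype(float),
                           columns=vids)
        dos.iloc[0, 0] = np.nan
        pairs = [("A", "G"), ("C", "T")]
        mat_alleles = pd.DataFrame(
            [pairs[int(b)] for b in rng.integers(0, 2, m)],
            columns=["effect_allele", "other_allele"], index=vids)
        flip = rng.integers(0, 2, m).astype(bool)
        wt = pd.DataFrame({
            "rsid": vids,
            "effect_allele": [mat_alleles.loc[v, "other_allele"] if f
                              else mat_alleles.loc[v, "effect_allele"]
                              for v, f in zip(vids, flip)],
            "other_allele": [mat_alleles.loc[v, "effect_allele"] if f
                             else mat_alleles.loc[v, "other_allele"]
                             for v, f in zip(vids, flip)],
            "effect_weight": rng.normal(size=m),
        })
        ours, rep = project_external_score(dos, wt, mat_alleles)
        ref = np.zeros(15)
        for j, v in enumerate(vids):
            x = dos[v].fillna(dos[v].mean()).to_numpy()
            if flip[j]:
                x = 2 - x
            ref += wt["effect_weight"][j] * x
        np.testing.assert_allclose(ours.to_numpy(), ref, atol=1e-12)

    def test_no_overlap_errors(self):
        dosages, alleles = self._setup()
        wt = pd.DataFrame({"rsid": ["rs999"], "effect_allele": ["A"],
                           "other_allele": ["G"], "effect_weight": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            project_external_score(dosages, wt, alleles)


class TestRestrictToArray:
    def test_full_list_identity(self):
        y, G, C = _toy_problem()
        out = restrict_to_array(G, list(G.columns))
        pd.testing.assert_frame_equal(out, G)

    def test_excluding_selected_sites_zeroes_score(self):
        y, G, C = _toy_problem()
        m = fit_penalized(y, G, C, PenaltySpec("lasso"), lam=0.05)
        assert m.n_selected > 0
        restricted = restrict_to_array(m, ["not_a_site"] )
        assert restricted.n_selected == 0
        s = compute_score(restricted.weights, G)
        assert (s == 0).all()

    def test_empty_list_errors(self):
        y, G, C = _toy_problem()
        with pytest.raises(ValueError):
            restrict_to_array(G, [])

    def test_retrained_on_signal_free_subset_does_worse(self):
        # plant the signal in excluded columns: the restricted training
        # matrix cannot beat the full one beyond sampling noise
        y, G, C = _toy_problem(n=150, p=25)
        signal_free = [c for c in G.columns if c not in ("cg0", "cg1")]
        G_restricted = restrict_to_array(G, signal_free)
        full = double_cv(y, G, C, families=("lasso",), outer_k=5, inner_k=4,
                         seed=SEED)["lasso"].metric
        sub = double_cv(y, G_restricted, C, families=("lasso",), outer_k=5,
                        inner_k=4, seed=SEED)["lasso"].metric
        assert sub <= full + 0.1
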