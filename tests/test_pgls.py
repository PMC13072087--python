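import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichebreadth.phylo import parse_newick, vcv, lambda_transform, write_newick
from nichebreadth.pgls import (
    fit_pgls_lambda,
    gls_profile,
    profile_loglik,
    r_squared,
    slope_test,
)
from nichebreadth.synthetic import (
    simulate_regression_dataset,
    simulate_yule_tree,
)


def _random_problem(seed, n=8):
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n, seed=seed)
    V = vcv(tree).matrix
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    return y, X, V


class TestGLSProfile:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 2.0 + 0.5 * X[:, 1] + rng.normal(size=n)
        beta, sigma2, _ = gls_profile(y, X, np.eye(n))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_explicit_inverse_formula(self, seed):
        """Cholesky route equals the textbook dense-inverse GLS algebra."""
        y, X, V = _random_problem(seed)
        beta, sigma2, ll = gls_profile(y, X, V)
        Vi = np.linalg.inv(V)
        beta_o = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta_o
        sigma2_o = float(r @ Vi @ r) / len(y)
        ll_o = (
            -0.5 * len(y) * np.log(2 * np.pi * sigma2_o)
            - 0.5 * np.linalg.slogdet(V)[1]
            - 0.5 * len(y)
        )
        np.testing.assert_allclose(beta, beta_o, atol=1e-10)
        assert sigma2 == pytest.approx(sigma2_o, abs=1e-10)
        assert ll == pytest.approx(ll_o, abs=1e-8)

    def test_matches_statsmodels_gls(self):
        sm = pytest.importorskip("statsmodels.api")
        y, X, V = _random_problem(3, n=20)
        beta, _, _ = gls_profile(y, X, V)
        fit = sm.GLS(y, X, sigma=V).fit()
        np.testing.assert_allclose(beta, fit.params, atol=1e-8)

    def test_perfect_fit_hits_sigma_floor(self):
        y, X, V = _random_problem(4)
        y = X @ np.array([1.0, 2.0])
        _, sigma2, ll = gls_profile(y, X, V)
        assert sigma2 == pytest.approx(1e-12)
        assert np.isfinite(ll)

    def test_collinear_design_rejected(self):
        y, X, V = _random_problem(5)
        X = np.column_stack([X[:, 0], X[:, 0]])
        with pytest.raises(np.linalg.LinAlgError, match="condition number"):
            gls_profile(y, X, V)

    def test_singular_covariance_rejected(self):
        y, X, V = _random_problem(6)
        V = np.ones_like(V)  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="singular|condition"):
            gls_profile(y, X, V)


class TestRsquared:
    def test_identity_matches_ols_r2(self):
        rng = np.random.default_rng(7)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.0 - 0.8 * X[:, 1] + rng.normal(size=n)
        beta, _, _ = gls_profile(y, X, np.eye(n))
        r2 = r_squared(y, X, beta, np.eye(n))
        ss_res = np.sum((y - X @ beta) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_constant_response_zero(self):
        y, X, V = _random_problem(8)
        y = np.full_like(y, 3.0)
        beta, _, _ = gls_profile(y, X, V)
        with pytest.warns(UserWarning, match="constant"):
            assert r_squared(y, X, beta, V) == 0.0

    def test_perfect_fit_one(self):
        y, X, V = _random_problem(9)
        y = X @ np.array([1.0, -2.0])
        beta, _, _ = gls_profile(y, X, V)
        assert r_squared(y, X, beta, V) == pytest.approx(1.0)


class TestSlopeTest:
    def test_identity_matches_classical_t_test(self):
        rng = np.random.default_rng(10)
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 0.5 + 0.3 * X[:, 1] + rng.normal(size=n)
        beta, _, _ = gls_profile(y, X, np.eye(n))
        p, se, t = slope_test(y, X, beta, np.eye(n))
        # classical OLS oracle
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        se_o = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t_o = beta[1] / se_o
        p_o = 2 * stats.t.sf(abs(t_o), n - 2)
        assert se == pytest.approx(se_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_sign_of_t_matches_slope(self):
        for seed in range(5):
            y, X, V = _random_problem(seed, n=12)
            beta, _, _ = gls_profile(y, X, V)
            _, _, t = slope_test(y, X, beta, V)
            assert np.sign(t) == np.sign(beta[1])


class TestFitPGLSLambda:
    def test_star_phylogeny_equals_ols(self):
        """On a star tree V is diagonal, lambda has no effect and the fit
        must reproduce OLS exactly."""
        n = 30
        text = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        star = parse_newick(text)
        rng = np.random.default_rng(11)
        x = pd.Series(rng.normal(size=n), index=star.tip_labels)
        y = 1.0 + 0.7 * x + rng.normal(size=n)
        fit = fit_pgls_lambda(y, x, star)
        X = np.column_stack([np.ones(n), x.to_numpy()])
        ols = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_optimizer_beats_lambda_grid(self, seed):
        """Brute-force grid oracle: optimizer loglik >= grid max - 1e-4."""
        tree = simulate_yule_tree(40, seed=30 + seed)
        x, y, _ = simulate_regression_dataset(tree, 0.5, 0.0, 0.6, 1.0, seed=seed)
        fit = fit_pgls_lambda(y, x, tree)
        cov = vcv(tree).reorder(list(y.index))
        X = np.column_stack([np.ones(len(y)), x.loc[y.index].to_numpy()])
        grid = np.linspace(0, 1, 101)
        grid_best = max(profile_loglik(l, y.to_numpy(), X, cov) for l in grid)
        assert fit.loglik >= grid_best - 1e-4

    def test_endpoint_dominance(self):
        tree = simulate_yule_tree(60, seed=40)
        x, y, _ = simulate_regression_dataset(tree, -0.3, 0.0, 0.9, 2.0, seed=41)
        fit = fit_pgls_lambda(y, x, tree)
        cov = vcv(tree).reorder(list(y.index))
        X = np.column_stack([np.ones(len(y)), x.loc[y.index].to_numpy()])
        for lam in (0.0, 1.0):
            assert fit.loglik >= profile_loglik(lam, y.to_numpy(), X, cov) - 1e-6

    def test_branch_length_rescaling_invariance(self):
        """Multiplying all branch lengths by c scales sigma2 by 1/c and
        leaves lambda, beta, r2 and p unchanged."""
        tree = simulate_yule_tree(50, seed=50)
        x, y, _ = simulate_regression_dataset(tree, 0.4, 1.0, 0.7, 1.5, seed=51)
        fit1 = fit_pgls_lambda(y, x, tree)
        c = 37.5
        scaled = parse_newick(write_newick(tree))
        for nd in scaled.tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= c
        fit2 = fit_pgls_lambda(y, x, scaled)
        assert fit2.lambda_hat == pytest.approx(fit1.lambda_hat, abs=1e-5)
        np.testing.assert_allclose(fit2.beta, fit1.beta, rtol=1e-6)
        assert fit2.r2 == pytest.approx(fit1.r2, abs=1e-6)
        assert fit2.p_slope == pytest.approx(fit1.p_slope, abs=1e-6)
        assert fit2.sigma2_hat == pytest.approx(fit1.sigma2_hat / c, rel=1e-4)

    def test_missing_species_dropped_pairwise(self, yule50):
        x, y, _ = simulate_regression_dataset(yule50, 0.2, 0.0, 0.5, 1.0, seed=60)
        x = x.copy()
        x.iloc[:5] = np.nan
        fit = fit_pgls_lambda(y, x, yule50)
        assert fit.n == 45

    def test_non_overlapping_taxa_listed(self, yule50):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=["nope1", "nope2", "nope3", "nope4"])
        with pytest.raises(ValueError, match="nope1"):
            fit_pgls_lambda(x, x, yule50)

    def test_too_few_cases(self, yule50):
        labels = yule50.tip_labels[:3]
        x = pd.Series([1.0, 2.0, 3.0], index=labels)
        with pytest.raises(ValueError, match="at least 4"):
            fit_pgls_lambda(x, x, yule50)

    def test_lambda_zero_recovery_iid_noise(self):
        """Data generated without phylogenetic signal: lambda_hat stays
        near 0 in most replicates (n=100 tips, 20 reps)."""
        tree = simulate_yule_tree(100, seed=70)
        cov = vcv(tree)
        low = 0
        for rep in range(20):
            x, y, _ = simulate_regression_dataset(tree, 0.5, 0.0, 0.0, 1.0,
                                                  seed=700 + rep)
            fit = fit_pgls_lambda(y, x, cov)
            low += fit.lambda_hat < 0.2
        assert low >= 18


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstRImplementation:
    def test_matches_ape_corpagel(self, tmp_path):
        """Independent oracle: nlme::gls with ape's corPagel (ML) must agree
        on lambda, coefficients, log-likelihood and the slope p-value."""
        tree = simulate_yule_tree(30, seed=90)
        x, y, _ = simulate_regression_dataset(tree, 0.7, 1.0, 0.6, 0.5, seed=91)
        fit = fit_pgls_lambda(y, x, tree)

        (tmp_path / "tree.nwk").write_text(write_newick(tree) + "\n")
        pd.DataFrame({"species": x.index, "x": x.values, "y": y.values}).to_csv(
            tmp_path / "dat.csv", index=False
        )
        script = """
        suppressMessages({library(ape); library(nlme)})
        args <- commandArgs(trailingOnly=TRUE)
        tree <- read.tree(args[1]); dat <- read.csv(args[2])
        rownames(dat) <- dat$species; dat <- dat[tree$tip.label,]
        f <- gls(y ~ x, data=dat, correlation=corPagel(0.5, phy=tree, form=~species),
                 method="ML")
        cat(f$modelStruct$corStruct[1], coef(f), logLik(f),
            summary(f)$tTable[2,4], sep="\\n")
        """
        (tmp_path / "fit.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "fit.R"), str(tmp_path / "tree.nwk"),
             str(tmp_path / "dat.csv")],
            capture_output=True, text=True, check=True,
        )
        lam_r, int_r, slope_r, ll_r, p_r = map(float, out.stdout.split())
        assert fit.lambda_hat == pytest.approx(lam_r, abs=1e-4)
        assert fit.intercept == pytest.approx(int_r, rel=1e-5)
        assert fit.slope == pytest.approx(slope_r, rel=1e-5)
        assert fit.loglik == pytest.approx(ll_r, abs=1e-4)
        assert fit.p_slope == pytest.approx(p_r, rel=1e-3)
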