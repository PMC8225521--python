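"""Least-squares ANCOVA fit and Wald test, checked against brute-force
dummy-coded regression oracles."""

import numpy as np
import pytest

from ancova_power import (
    AncovaDataset,
    fit_ancova,
    omnibus_contrast,
    wald_test,
)


def random_dataset(rng, G=3, n=5, P=2, mu=None, beta=None, sigma=1.0):
    mu = np.arange(G, dtype=float) if mu is None else np.asarray(mu, float)
    beta = rng.normal(size=P) if beta is None else np.asarray(beta, float)
    group = np.repeat(np.arange(1, G + 1), n)
    X = rng.normal(size=(G * n, P))
    y = mu[group - 1] + X @ beta + rng.normal(0, sigma, size=G * n)
    return AncovaDataset(group=group, y=y, X=X)


def dummy_design_matrix(data):
    """Full dummy-coded design matrix: one indicator per group plus covariates."""
    labels = list(dict.fromkeys(data.group.tolist()))
    Z = np.zeros((len(data.y), len(labels) + data.X.shape[1]))
    for i, lab in enumerate(labels):
        Z[data.group == lab, i] = 1.0
    Z[:, len(labels):] = data.X
    return Z


class TestFitAgainstBruteForce:
    def test_coefficients_and_sse_match_normal_equations(self):
        rng = np.random.default_rng(42)
        data = random_dataset(rng, G=3, n=5, P=2)
        fit = fit_ancova(data)
        Z = dummy_design_matrix(data)
        coef, *_ = np.linalg.lstsq(Z, data.y, rcond=None)
        resid = data.y - Z @ coef
        np.testing.assert_allclose(fit.mu_hat, coef[:3], atol=1e-8)
        np.testing.assert_allclose(fit.beta_hat, coef[3:], atol=1e-8)
        assert fit.sse == pytest.approx(float(resid @ resid), abs=1e-8)
        assert fit.nu == 15 - 3 - 2
        assert fit.sigma2_hat == pytest.approx(fit.sse / fit.nu)

    def test_uncorrelated_covariate_leaves_raw_means(self):
        """When S_XY = 0 by construction, the slopes vanish and the fitted
        intercepts are the raw group means."""
        rng = np.random.default_rng(3)
        group = np.repeat([1, 2, 3], 8)
        X = rng.normal(size=(24, 1))
        # project noise orthogonally to the within-group-centred covariate
        e = rng.normal(size=24)
        for g in (1, 2, 3):
            m = group == g
            xc = X[m, 0] - X[m, 0].mean()
            e[m] -= xc * (e[m] @ xc) / (xc @ xc)
        y = np.repeat([10.0, 12.0, 15.0], 8) + e
        fit = fit_ancova(AncovaDataset(group=group, y=y, X=X))
        assert fit.beta_hat[0] == pytest.approx(0.0, abs=1e-10)
        for g, expect in zip((1, 2, 3), (10.0, 12.0, 15.0)):
            assert fit.mu_hat[g - 1] == pytest.approx(y[group == g].mean())

    def test_adjusted_mean_identity(self):
        rng = np.random.default_rng(11)
        data = random_dataset(rng, G=4, n=6, P=3)
        fit = fit_ancova(data)
        for i in range(4):
            m = data.group == i + 1
            ybar = data.y[m].mean()
            shift = (fit.groupwise_covariate_means[i]
                     - fit.grand_covariate_mean) @ fit.beta_hat
            assert fit.adjusted_means[i] == pytest.approx(ybar - shift, abs=1e-10)

    def test_adjusted_means_approach_raw_means_with_independent_covariate(self):
        rng = np.random.default_rng(5)
        data = random_dataset(rng, G=3, n=4000, P=1, mu=[0, 5, 10],
                              beta=[0.0], sigma=1.0)
        fit = fit_ancova(data)
        raw = [data.y[data.group == g].mean() for g in (1, 2, 3)]
        np.testing.assert_allclose(fit.adjusted_means, raw, atol=0.05)

    def test_sigma2_invariant_to_relabeling_and_affine_covariates(self):
        rng = np.random.default_rng(9)
        data = random_dataset(rng, G=3, n=6, P=2)
        fit = fit_ancova(data)
        perm = rng.permutation(len(data.y))
        shuffled = AncovaDataset(group=data.group[perm], y=data.y[perm],
                                 X=data.X[perm])
        assert fit_ancova(shuffled).sigma2_hat == pytest.approx(fit.sigma2_hat)
        affine = AncovaDataset(group=data.group, y=data.y,
                               X=3.0 * data.X + np.array([5.0, -2.0]))
        assert fit_ancova(affine).sigma2_hat == pytest.approx(fit.sigma2_hat)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(2)
        group = np.repeat([1, 2, 3], 5)
        x = rng.normal(size=15)
        X = np.column_stack([x, 2 * x])
        y = rng.normal(size=15)
        with pytest.warns(UserWarning, match="collinear"):
            with pytest.raises(np.linalg.LinAlgError):
                fit_ancova(AncovaDataset(group=group, y=y, X=X))

    def test_too_small_design_rejected(self):
        with pytest.raises(ValueError, match="nu"):
            fit_ancova(AncovaDataset(group=[1, 1, 2, 2], y=[1.0, 2, 3, 4],
                                     X=np.ones((4, 2)) * [[1], [2], [3], [4]]))


class TestWaldStatistic:
    def test_two_forms_agree(self):
        """The raw-intercept and adjusted-mean quadratic forms give the
        identical statistic for any zero-row-sum contrast."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            data = random_dataset(rng, G=4, n=6, P=2)
            fit = fit_ancova(data)
            C = omnibus_contrast(4)
            w1 = wald_test(fit, C).W_star
            w2 = wald_test(fit, C, use_adjusted=True).W_star
            assert w1 == pytest.approx(w2, abs=1e-8, rel=1e-8)

    def test_null_contrast_value_is_zero(self):
        # subtracting the fitted intercepts groupwise forces C mu_hat = 0
        rng = np.random.default_rng(23)
        data = random_dataset(rng, G=3, n=6, P=1)
        fit = fit_ancova(data)
        y0 = data.y - fit.mu_hat[data.group - 1]
        fit0 = fit_ancova(AncovaDataset(group=data.group, y=y0, X=data.X))
        res = wald_test(fit0, omnibus_contrast(3))
        assert res.W_star == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_full_vs_reduced_model_f(self):
        """The omnibus Wald statistic equals the classical ANCOVA F from
        comparing the full model with the no-group-effect reduction."""
        rng = np.random.default_rng(31)
        data = random_dataset(rng, G=3, n=7, P=2, mu=[0, 2, 4])
        fit = fit_ancova(data)
        Zf = dummy_design_matrix(data)
        Zr = np.column_stack([np.ones(len(data.y)), data.X])  # drop group terms
        sse_f = float(np.sum((data.y - Zf @ np.linalg.lstsq(Zf, data.y, rcond=None)[0]) ** 2))
        sse_r = float(np.sum((data.y - Zr @ np.linalg.lstsq(Zr, data.y, rcond=None)[0]) ** 2))
        c, nu = 2, fit.nu
        f_classic = ((sse_r - sse_f) / c) / (sse_f / nu)
        res = wald_test(fit, omnibus_contrast(3))
        assert res.W_star == pytest.approx(f_classic, rel=1e-8)
        assert (res.df1, res.df2) == (c, nu)

    def test_single_row_contrast_uses_its_own_dof(self):
        rng = np.random.default_rng(41)
        data = random_dataset(rng, G=3, n=8, P=1)
        fit = fit_ancova(data)
        from ancova_power import ContrastMatrix

        res = wald_test(fit, ContrastMatrix(np.array([[1.0, -1.0, 0.0]])))
        assert res.df1 == 1

    def test_contrast_shape_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        fit = fit_ancova(random_dataset(rng, G=3, n=5, P=1))
        with pytest.raises(ValueError, match="columns"):
            wald_test(fit, omnibus_contrast(4))


class TestNullDistribution:
    def test_null_statistic_follows_central_f(self):
        """Under equal intercepts the Wald statistic is central F(c, nu):
        checked by a KS comparison on simulated replicates."""
        from scipy import stats

        from ancova_power import CovariateModel, DesignSpec, SimulationSpec, generate_dataset

        design = DesignSpec.balanced(G=3, P=1, n_per_group=7)
        spec = SimulationSpec(
            design=design, mu=np.zeros(3), sigma2=4.0, beta=np.array([1.0]),
            covariates=CovariateModel(P=1), n_reps=100, seed=314,
        )
        C = omnibus_contrast(3)
        ws = np.empty(3000)
        for rep in range(3000):
            ws[rep] = wald_test(fit_ancova(generate_dataset(spec, rep)), C).W_star
        _, p = stats.kstest(ws, stats.f(2, design.nu).cdf)
        assert p > 1e-3
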