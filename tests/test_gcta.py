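"""Variance-component estimation: covariance assembly, profile likelihood
against dense oracles, the five-model machinery, grid-search optimality,
and component summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from triofx import experiments as ex
from triofx import gcta
from triofx.grm import GRMSet
from triofx.params import VCParams


def _pedigree_grms(n):
    """Exact expectation GRM blocks: G_rr = I, parent-offspring = 0.5 I,
    mother-father = 0 under random mating."""
    eye = np.eye(n)
    blocks = {
        "oo": eye.copy(), "mm": eye.copy(), "pp": eye.copy(),
        "om": 0.5 * eye, "op": 0.5 * eye, "mp": np.zeros((n, n)),
    }
    return GRMSet(family_ids=np.array([f"F{i}" for i in range(n)]), blocks=blocks, n_snps_used=0)


@pytest.fixture(scope="module")
def small_dataset():
    return ex.make_gcta_dataset(ex.SCENARIOS["MO"], 300, 300, seed=11)


class TestAssembleCovariance:
    def test_residual_only_gives_identity(self):
        v = gcta.assemble_covariance(_pedigree_grms(5), VCParams(sigma2_e=1.0), "offspring")
        assert np.array_equal(v, np.eye(5))

    def test_cross_term_diagonal_contribution(self):
        # with only sigma_om = c, diag(V) - sigma2_e = 2 * 0.5 * c = c
        c = 0.04
        params = VCParams(sigma2_o=0.1, sigma2_m=0.1, sigma_om=c, sigma2_e=0.5)
        v = gcta.assemble_covariance(_pedigree_grms(4), params, "offspring")
        assert np.allclose(np.diag(v), 0.1 + 0.1 + c + 0.5)

    def test_pedigree_limit_reproduces_variance_identity(self):
        params = VCParams(
            sigma2_o=0.09, sigma2_m=0.10, sigma2_p=0.05,
            sigma_om=-0.012, sigma_op=0.02, sigma_mp=0.01, sigma2_e=0.78,
        )
        v = gcta.assemble_covariance(_pedigree_grms(3), params, "offspring")
        total = 0.09 + 0.10 + 0.05 + (-0.012) + 0.02 + 0.78
        assert np.allclose(np.diag(v), total)
        # sigma_mp enters V only off the phenotypic-variance diagonal path
        v0 = gcta.assemble_covariance(
            _pedigree_grms(3),
            VCParams(
                sigma2_o=0.09, sigma2_m=0.10, sigma2_p=0.05,
                sigma_om=-0.012, sigma_op=0.02, sigma_mp=0.0, sigma2_e=0.78,
            ),
            "offspring",
        )
        assert np.allclose(np.diag(v), np.diag(v0))


class TestProfileLoglik:
    def test_identity_covariance_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        x = np.ones((40, 1))
        ll, beta = gcta.profile_loglik(np.eye(40), y, x)
        expect = -20 * np.log(2 * np.pi) - 0.5 * ((y - y.mean()) ** 2).sum()
        assert ll == pytest.approx(expect, abs=1e-10)
        assert beta[0] == pytest.approx(y.mean())

    def test_matches_dense_multivariate_normal_oracle(self):
        rng = np.random.default_rng(1)
        n = 6
        a = rng.standard_normal((n, n))
        v = a @ a.T + n * np.eye(n)
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        ll, beta = gcta.profile_loglik(v, y, x)
        # independent GLS + dense density evaluation
        vi = np.linalg.inv(v)
        beta_o = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        ll_o = sps.multivariate_normal(mean=x @ beta_o, cov=v).logpdf(y)
        assert np.allclose(beta, beta_o, atol=1e-10)
        assert ll == pytest.approx(ll_o, abs=1e-8)

    def test_duplicated_columns_rejected_by_name(self):
        y = np.zeros(5)
        x = np.ones((5, 2))
        with pytest.raises(ValueError, match="collinear"):
            gcta.profile_loglik(np.eye(5), y, x, names=["intercept", "copy"])


class TestFitModel:
    def test_null_model_closed_form(self, small_dataset):
        grms, y, x, names = small_dataset
        fit = gcta.fit_model(gcta.ModelSpec("NULL"), grms, y, x, x_names=names)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = ((y - x @ beta) ** 2).sum()
        assert fit.estimates.sigma2_e == pytest.approx(rss / y.size, rel=1e-10)
        assert fit.estimates.sigma2_o == 0.0
        assert fit.converged

    def test_full_likelihood_dominates_nested(self, small_dataset):
        grms, y, x, names = small_dataset
        opts = gcta.FitOptions(restarts=2)
        fits = {
            name: gcta.fit_model(gcta.ModelSpec(name), grms, y, x, opts, x_names=names)
            for name in gcta.MODEL_NAMES
        }
        for name in ("MO", "FO", "DIRECT", "NULL"):
            assert fits["FULL"].loglik >= fits[name].loglik - 1e-6

    def test_grid_search_never_beats_optimizer(self):
        grms, y, x, names = ex.make_gcta_dataset(ex.SCENARIOS["DIRECT"], 50, 200, seed=21)
        fit = gcta.fit_model(
            gcta.ModelSpec("DIRECT"), grms, y, x, gcta.FitOptions(restarts=3), x_names=names
        )
        g_oo = grms.block("o", "o")
        best = -np.inf
        for s2o in np.arange(0.0, 0.4001, 0.02):
            for s2e in np.arange(0.1, 2.0001, 0.02):
                v = s2o * g_oo + s2e * np.eye(50)
                ll = _dense_profile_ll(v, y, x)
                best = max(best, ll)
        assert fit.loglik >= best - 1e-4

    def test_permutation_invariance_of_likelihood(self, small_dataset):
        grms, y, x, names = small_dataset
        params = VCParams(sigma2_o=0.1, sigma2_m=0.08, sigma_om=-0.01, sigma2_e=0.8)
        v = gcta.assemble_covariance(grms, params, "offspring")
        ll, _ = gcta.profile_loglik(v, y, x)
        perm = np.random.default_rng(3).permutation(len(y))
        grms_p = grms.subset(perm)
        v_p = gcta.assemble_covariance(grms_p, params, "offspring")
        ll_p, _ = gcta.profile_loglik(v_p, y[perm], x[perm])
        assert ll_p == pytest.approx(ll, abs=1e-8)

    def test_permuted_fit_recovers_same_estimates(self, small_dataset):
        grms, y, x, names = small_dataset
        opts = gcta.FitOptions(restarts=1)
        fit = gcta.fit_model(gcta.ModelSpec("MO"), grms, y, x, opts, x_names=names)
        perm = np.random.default_rng(4).permutation(len(y))
        fit_p = gcta.fit_model(
            gcta.ModelSpec("MO"), grms.subset(perm), y[perm], x[perm], opts, x_names=names
        )
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-5)
        for k, v in fit.estimates.as_dict().items():
            assert fit_p.estimates.as_dict()[k] == pytest.approx(v, abs=1e-4)


def _dense_profile_ll(v, y, x):
    """Independent evaluation: GLS beta then dense Gaussian density."""
    vi = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    return sps.multivariate_normal(mean=x @ beta, cov=v, allow_singular=False).logpdf(y)


class TestComparison:
    def _result(self, name, ll, n_obs=100):
        spec = gcta.ModelSpec(name)
        est = VCParams(sigma2_o=0.1 if name != "NULL" else 0.0, sigma2_e=0.9)
        return gcta._make_result(
            spec, est, ll, True, n_obs, np.zeros(1), ["intercept"], gcta.FitOptions()
        )

    def test_information_criteria_formulas(self):
        fit = self._result("DIRECT", -100.0)  # k = 2
        assert fit.aic == pytest.approx(204.0)
        assert fit.bic == pytest.approx(2 * np.log(100) + 200.0)

    def test_equal_loglik_gives_zero_lrt(self):
        fits = {"FULL": self._result("FULL", -50.0), "MO": self._result("MO", -50.0)}
        comp = gcta.compare_models(fits)
        stat, df, p = comp.lrt_vs_full["MO"]
        assert stat == 0.0 and df == 3 and p == pytest.approx(1.0)

    def test_selection_prefers_parsimony_on_ties(self):
        # same AIC for MO (k=4, ll=-50) and FULL (k=7, ll=-47)
        fits = {"FULL": self._result("FULL", -47.0), "MO": self._result("MO", -50.0)}
        assert gcta.compare_models(fits).selected == "MO"

    def test_mismatched_sample_sizes_rejected(self):
        fits = {"FULL": self._result("FULL", -50.0), "MO": self._result("MO", -50.0, n_obs=99)}
        with pytest.raises(ValueError, match="n_obs"):
            gcta.compare_models(fits)


class TestSummaries:
    def test_direct_share(self):
        fit = gcta._make_result(
            gcta.ModelSpec("DIRECT"), VCParams(sigma2_o=0.1, sigma2_e=0.9),
            -1.0, True, 10, np.zeros(1), ["intercept"], gcta.FitOptions(),
        )
        out = gcta.summarize_components(fit)
        assert out["shares"]["sigma2_o"] == pytest.approx(0.10)

    def test_reported_correlation_convention(self):
        # child-indirect on father vs father's direct: r = -0.49
        s2o, s2p = 0.101, 0.046
        est = VCParams(
            sigma2_o=s2o, sigma2_p=s2p, sigma_op=-0.49 * np.sqrt(s2o * s2p), sigma2_e=0.8
        )
        fit = gcta._make_result(
            gcta.ModelSpec("FO", focal_role="father"), est, -1.0, True, 10,
            np.zeros(1), ["intercept"], gcta.FitOptions(),
        )
        assert gcta.summarize_components(fit)["r_op"] == pytest.approx(-0.49, abs=1e-12)

    def test_signed_shares_sum_to_one(self):
        est = VCParams(
            sigma2_o=0.09, sigma2_m=0.10, sigma2_p=0.05,
            sigma_om=-0.012, sigma_op=0.02, sigma_mp=0.01, sigma2_e=0.78,
        )
        fit = gcta._make_result(
            gcta.ModelSpec("FULL"), est, -1.0, True, 10, np.zeros(1), ["intercept"],
            gcta.FitOptions(),
        )
        shares = gcta.summarize_components(fit)["shares"]
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        # sigma_mp is reported alongside but excluded from the total
        assert "sigma_mp" not in shares
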