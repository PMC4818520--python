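import numpy as np
import pytest
from scipy.stats import kstest

import multitrans as mt
from multitrans.errors import NumericalError, ValidationError
from multitrans.lmm_core import _profiled_negloglik, eigendecompose


@pytest.fixture(scope="module")
def fitted(small_study):
    vc = mt.fit_variance_components(small_study.phenotype, small_study.kinship)
    return small_study, vc


class TestFitVarianceComponents:
    def test_scale_equivariance(self, small_study):
        y = small_study.phenotype
        k = small_study.kinship
        vc1 = mt.fit_variance_components(y, k)
        vc2 = mt.fit_variance_components(
            mt.PhenotypeVector(2.0 * y.values, y.individual_ids), k
        )
        assert vc2.sigma_g2 == pytest.approx(4.0 * vc1.sigma_g2, rel=1e-4)
        assert vc2.sigma_e2 == pytest.approx(4.0 * vc1.sigma_e2, rel=1e-4)
        assert vc2.heritability == pytest.approx(vc1.heritability, abs=1e-6)

    def test_constant_phenotype_rejected(self, small_study):
        y = mt.PhenotypeVector(np.full(small_study.kinship.n, 3.14))
        with pytest.raises(ValidationError, match="zero variance"):
            mt.fit_variance_components(y, small_study.kinship)

    def test_single_draw_recovery(self):
        """Simulation oracle: at n=500 a single h2=0.5 draw lands within 0.15."""
        cfg = mt.SynthConfig(n_individuals=500, n_markers=800, fst=0.2,
                             ld_rho=0.7, seed=42)
        g = mt.standardize(mt.filter_markers(mt.simulate_genotypes(cfg)))
        k = mt.compute_kinship(g)
        y = mt.simulate_phenotype(k, 0.5, seed=1)
        vc = mt.fit_variance_components(y, k)
        assert abs(vc.heritability - 0.5) < 0.15

    def test_profiled_optimum_is_local_max(self, fitted):
        """The returned delta maximizes the profiled restricted likelihood."""
        study, vc = fitted
        n = study.kinship.n
        lam, U = eigendecompose(study.kinship)
        yr = U.T @ study.phenotype.values
        xr = U.T @ np.ones(n)
        log10d = np.log10(vc.sigma_e2 / vc.sigma_g2)
        at = _profiled_negloglik(log10d, yr, xr, lam, n, "REML")
        for bump in (np.log10(1.01), -np.log10(1.01)):
            assert _profiled_negloglik(log10d + bump, yr, xr, lam, n, "REML") >= at - 1e-9

    def test_ml_and_reml_close_at_moderate_n(self, small_study):
        reml = mt.fit_variance_components(small_study.phenotype, small_study.kinship, "REML")
        ml = mt.fit_variance_components(small_study.phenotype, small_study.kinship, "ML")
        assert ml.heritability == pytest.approx(reml.heritability, abs=0.15)

    def test_boundary_warns(self, small_study):
        rng = np.random.default_rng(0)
        y = mt.PhenotypeVector(rng.standard_normal(small_study.kinship.n))
        with pytest.warns(UserWarning, match="bracket edge"):
            # pure-noise phenotype drives the genetic component to zero
            vc = mt.fit_variance_components(y, mt.KinshipMatrix(
                np.eye(small_study.kinship.n)))
        assert vc.heritability < 0.05 or vc.heritability > 0.95


class TestCovarianceModel:
    def test_pure_noise_gives_identity(self, small_study):
        vc = mt.VarianceComponents(0.0, 1.0, 0.0, method="fixed")
        model = mt.build_covariance_model(small_study.kinship, vc)
        np.testing.assert_allclose(model.V_inv_sqrt, np.eye(model.n), atol=1e-8)

    def test_scalar_case(self, small_study):
        vc = mt.VarianceComponents(0.0, 4.0, 0.0, method="fixed")
        model = mt.build_covariance_model(small_study.kinship, vc)
        np.testing.assert_allclose(model.V_inv_sqrt, 0.5 * np.eye(model.n), atol=1e-8)

    def test_inverse_square_root_oracle(self, small_study):
        """Matrix-inverse oracle: V^{-1/2} V V^{-1/2} = I."""
        vc = mt.VarianceComponents(0.7, 0.3, 0.7, method="fixed")
        model = mt.build_covariance_model(small_study.kinship, vc)
        eye = model.V_inv_sqrt @ model.V @ model.V_inv_sqrt
        np.testing.assert_allclose(eye, np.eye(model.n), atol=1e-6)
        np.testing.assert_allclose(model.V_inv_sqrt, model.V_inv_sqrt.T, atol=1e-10)
        np.testing.assert_allclose(
            model.V_sqrt @ model.V_inv_sqrt, np.eye(model.n), atol=1e-6
        )

    def test_singular_covariance_rejected(self):
        # rank-one kinship with sigma_e2 = 0 makes V singular
        vc = mt.VarianceComponents(1.0, 0.0, 1.0, method="fixed")
        k = mt.KinshipMatrix(np.ones((4, 4)))
        with pytest.raises(NumericalError, match="singular"):
            mt.build_covariance_model(k, vc)


class TestAssociationScan:
    def test_identity_model_equals_linear_zscores(self, small_study):
        """With V = I the statistic is the plain linear-model z-score
        sqrt(n) * corr(x, y) on standardized data."""
        g = small_study.genotypes
        y = small_study.phenotype
        res = mt.association_scan(y, g)
        yc = (y.values - y.values.mean()) / y.values.std()
        expected = g.dosages.T @ yc / np.sqrt(g.n)
        np.testing.assert_allclose(res.stat, expected, atol=1e-8)

    def test_null_statistics_standard_normal(self, small_study):
        """Simulation oracle: scanning phenotypes drawn from the fitted V
        yields ~N(0,1) statistics."""
        vc = mt.VarianceComponents.from_heritability(0.5)
        model = mt.build_covariance_model(small_study.kinship, vc)
        rng = np.random.default_rng(11)
        stats = []
        for i in range(100):
            z = rng.standard_normal(model.n)
            y = mt.PhenotypeVector(model.V_sqrt @ z)
            stats.append(mt.association_scan(y, small_study.genotypes, model).stat)
        pooled = np.concatenate(stats)
        assert kstest(pooled, "norm").pvalue > 0.01

    def test_planted_signal_found(self, small_study):
        g = small_study.genotypes
        rng = np.random.default_rng(5)
        y = mt.PhenotypeVector(2.0 * g.dosages[:, 0] + 0.01 * rng.standard_normal(g.n))
        res = mt.association_scan(y, g)
        assert int(np.argmax(np.abs(res.stat))) == 0

    def test_pvalue_matches_normal_tail(self, small_study):
        res = mt.association_scan(small_study.phenotype, small_study.genotypes)
        from scipy.stats import norm
        np.testing.assert_allclose(
            res.pvalue, np.clip(2 * norm.sf(np.abs(res.stat)), 1e-300, 1), atol=1e-12
        )

    def test_calibrated_under_bootstrap_null(self, small_study):
        """Fraction of p < 0.05 over bootstrap-null scans stays within 3
        binomial SDs of 0.05."""
        vc = mt.fit_variance_components(small_study.phenotype, small_study.kinship)
        run = mt.parametric_bootstrap(
            small_study.genotypes, small_study.kinship, vc,
            n_reps=500, seed=13, collect_pvalues=True,
        )
        frac = (run.pooled_pvalues < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / run.pooled_pvalues.size)
        assert abs(frac - 0.05) < 3 * sd
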