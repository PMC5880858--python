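import itertools

import numpy as np
import pytest

from netpredict.data import VariableSpec
from netpredict.simulate import (
    SimulationSpec,
    chain_precision,
    gaussian_specs,
    ggm_analytic_r2,
    sample_ggm,
    sample_mgm,
    sample_var,
)


class TestSampleGGM:
    def test_identity_precision_gives_identity_covariance(self):
        spec = SimulationSpec(specs=gaussian_specs(3), n=10_000, seed=61,
                              precision=np.eye(3))
        d = sample_ggm(spec)
        assert np.allclose(np.cov(d.values.T), np.eye(3), atol=0.05)

    def test_partial_correlation_matches_precision(self):
        """Precision [[1,-0.5],[-0.5,1]] encodes partial (= simple, at p=2)
        correlation +0.5."""
        omega = np.array([[1.0, -0.5], [-0.5, 1.0]])
        d = sample_ggm(SimulationSpec(specs=gaussian_specs(2), n=10_000,
                                      seed=63, precision=omega))
        r = np.corrcoef(d.values.T)[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_single_row_draw(self):
        d = sample_ggm(SimulationSpec(specs=gaussian_specs(2), n=1, seed=1,
                                      precision=np.eye(2)))
        assert d.values.shape == (1, 2)

    def test_non_positive_definite_rejected(self):
        omega = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            sample_ggm(SimulationSpec(specs=gaussian_specs(2), n=10, seed=1,
                                      precision=omega))

    def test_deterministic_given_seed(self):
        spec = dict(specs=gaussian_specs(2), n=50, precision=np.eye(2))
        a = sample_ggm(SimulationSpec(seed=5, **spec))
        b = sample_ggm(SimulationSpec(seed=5, **spec))
        assert np.array_equal(a.values, b.values)

    def test_analytic_r2_of_chain(self):
        """For the unit-diagonal chain precision, an end node's population
        R^2 is 1 - 1/Sigma_00; cross-check against direct inversion."""
        omega = chain_precision(4, 0.35)
        r2 = ggm_analytic_r2(omega)
        sigma = np.linalg.inv(omega)
        assert r2[0] == pytest.approx(1 - 1 / sigma[0, 0])
        assert np.all((r2 > 0) & (r2 < 1))


class TestSampleMGM:
    def test_null_couplings_give_independence(self):
        specs = [VariableSpec("g", "gaussian"),
                 VariableSpec("c", "categorical", 2),
                 VariableSpec("h", "gaussian")]
        d = sample_mgm(SimulationSpec(specs=specs, n=5000, seed=65,
                                      burn_in=200, thinning=2))
        corr = np.corrcoef(d.values.T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_gaussian_binary_coupling_shifts_group_means(self):
        """Coupling rho = (-0.6, +0.6) between a unit-precision gaussian
        node and a binary node makes the gaussian conditional mean -0.6 in
        category 1 and +0.6 in category 2."""
        specs = [VariableSpec("g", "gaussian"),
                 VariableSpec("c", "categorical", 2)]
        d = sample_mgm(SimulationSpec(
            specs=specs, n=5000, seed=67, burn_in=500, thinning=3,
            interactions={(0, 1): np.array([-0.6, 0.6])}))
        g, c = d.values[:, 0], d.values[:, 1]
        assert abs(np.mean(g[c == 1]) - (-0.6)) < 0.1
        assert abs(np.mean(g[c == 2]) - 0.6) < 0.1

    def test_ising_pair_sign_matches_exact_distribution(self):
        """A positive diagonal coupling between two binary nodes yields a
        positive association; the oracle is the exact 2x2 distribution from
        brute-force enumeration of the joint potentials."""
        phi = np.array([[0.5, -0.5], [-0.5, 0.5]])
        # exact joint: P(k,l) propto exp(phi[k,l])
        weights = {}
        for k, l in itertools.product(range(2), repeat=2):
            weights[(k, l)] = np.exp(phi[k, l])
        Z = sum(weights.values())
        p_equal_exact = (weights[(0, 0)] + weights[(1, 1)]) / Z
        assert p_equal_exact > 0.5  # positive association in truth

        specs = [VariableSpec("a", "categorical", 2),
                 VariableSpec("b", "categorical", 2)]
        d = sample_mgm(SimulationSpec(specs=specs, n=4000, seed=69,
                                      burn_in=500, thinning=3,
                                      interactions={(0, 1): phi}))
        p_equal = np.mean(d.values[:, 0] == d.values[:, 1])
        assert abs(p_equal - p_equal_exact) < 0.05
        assert np.corrcoef(d.values.T)[0, 1] > 0

    def test_nonpositive_conditional_precision_rejected(self):
        specs = [VariableSpec("g", "gaussian"), VariableSpec("h", "gaussian")]
        spec = SimulationSpec(specs=specs, n=10, seed=1, burn_in=1,
                              gaussian_precision=np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="divergent"):
            sample_mgm(spec)

    def test_deterministic_given_seed(self):
        specs = [VariableSpec("g", "gaussian"),
                 VariableSpec("c", "categorical", 2)]
        kw = dict(specs=specs, n=50, burn_in=50, thinning=1,
                  interactions={(0, 1): np.array([-0.3, 0.3])})
        a = sample_mgm(SimulationSpec(seed=9, **kw))
        b = sample_mgm(SimulationSpec(seed=9, **kw))
        assert np.array_equal(a.values, b.values)


class TestSampleVAR:
    def test_white_noise_has_no_autocorrelation(self):
        d = sample_var(SimulationSpec(specs=gaussian_specs(2), n=5000,
                                      seed=71, var_coefs=np.zeros((2, 2))))
        for j in range(2):
            x = d.values[:, j]
            r = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert abs(r) < 0.05

    def test_ar1_autocorrelation_equals_coefficient(self):
        d = sample_var(SimulationSpec(specs=gaussian_specs(2), n=5000,
                                      seed=73,
                                      var_coefs=np.diag([0.5, 0.0])))
        x = d.values[:, 0]
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_explosive_system_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            sample_var(SimulationSpec(specs=gaussian_specs(2), n=10, seed=1,
                                      var_coefs=np.diag([1.2, 0.5])))

    def test_orientation_of_coefficient_matrix(self):
        """var_coefs[i, j] drives target j from lagged i: a strong 0 -> 1
        coefficient shows up in the cross-covariance of x0(t-1) with x1(t)."""
        B = np.array([[0.0, 0.7], [0.0, 0.0]])
        d = sample_var(SimulationSpec(specs=gaussian_specs(2), n=5000,
                                      seed=77, var_coefs=B))
        x = d.values
        c_forward = np.corrcoef(x[:-1, 0], x[1:, 1])[0, 1]
        c_backward = np.corrcoef(x[:-1, 1], x[1:, 0])[0, 1]
        assert c_forward > 0.4
        assert abs(c_backward) < 0.1
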