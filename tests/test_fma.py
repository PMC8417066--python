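"""Constrained mixture screening: specs, EM behaviour, classification."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import multivariate_normal

from helpers import symmetric_spec

from wordfx import (
    ClassAssignment,
    GeneratorSpec,
    arias_spec,
    classify,
    cohen_kappa,
    entropy_index,
    fit_fma,
    generate_responses,
    screen_sample,
    steinmann_spec,
)
from wordfx.fma import _pack, _unpack, kappa_band
from wordfx.synth import CONSISTENT, INCONSISTENT
from wordfx.types import default_polarity

POL = default_polarity(5, 5)


class TestSpecs:
    def test_steinmann_free_parameter_count(self):
        assert steinmann_spec(POL).n_free_parameters == 38

    def test_arias_free_parameter_count(self):
        assert arias_spec(POL).n_free_parameters == 23

    @pytest.mark.parametrize("builder", [steinmann_spec, arias_spec])
    def test_all_positive_polarity_rejected(self, builder):
        with pytest.raises(ValueError, match="not identifiable"):
            builder(["positive"] * 10)

    def test_arias_loading_pattern(self):
        spec = arias_spec(POL)
        params = _unpack(_pack_default(spec), spec)
        assert np.array_equal(params.loadings[0], [1] * 5 + [-1] * 5)
        assert np.array_equal(params.loadings[1], np.ones(10))

    def test_steinmann_sign_link_and_sharing(self):
        spec = steinmann_spec(POL)
        params = _unpack(_pack_default(spec), spec)
        # class 1 negative loadings are the exact mirror of class 2
        assert np.allclose(params.loadings[0, 5:], -params.loadings[1, 5:])
        assert np.allclose(params.loadings[0, :5], params.loadings[1, :5])
        assert params.factor_means[1] == 0.0
        assert params.factor_variances[1] == 1.0


def _pack_default(spec):
    from wordfx.fma import FMAParameters
    p = spec.p
    lam = np.ones((2, p))
    lam[0, spec.neg_idx] *= -1
    return _pack(
        FMAParameters(lam, np.full((2, p), 3.0), np.ones(p),
                      np.zeros(2), np.ones(2), 0.1),
        spec,
    )


class TestEntropyKappa:
    def test_entropy_perfect(self):
        post = np.tile([1.0, 0.0], (20, 1))
        assert entropy_index(post) == pytest.approx(1.0)

    def test_entropy_uninformative(self):
        post = np.tile([0.5, 0.5], (20, 1))
        assert entropy_index(post) == pytest.approx(0.0)

    def test_entropy_hand_value(self):
        post = np.vstack([np.tile([0.9, 0.1], (10, 1)),
                          np.tile([0.1, 0.9], (10, 1))])
        expected = 1.0 - (-0.9 * np.log(0.9) - 0.1 * np.log(0.1)) / np.log(2)
        assert entropy_index(post) == pytest.approx(expected)
        assert expected == pytest.approx(0.531, abs=5e-4)

    def test_entropy_invalid_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            entropy_index(np.array([[0.6, 0.6]]))

    def test_kappa_identical(self):
        a = ClassAssignment(np.array([INCONSISTENT] * 5 + [CONSISTENT] * 5),
                            np.ones(10))
        k, band = cohen_kappa(a, a)
        assert k == pytest.approx(1.0)
        assert band == "almost-perfect"

    def test_kappa_hand_computed_table(self):
        # cross-table [[40, 10], [10, 40]]: p_o = 0.8, p_e = 0.5, kappa = 0.6
        la = np.array([INCONSISTENT] * 50 + [CONSISTENT] * 50)
        lb = np.array([INCONSISTENT] * 40 + [CONSISTENT] * 10
                      + [INCONSISTENT] * 10 + [CONSISTENT] * 40)
        a = ClassAssignment(la, np.ones(100))
        b = ClassAssignment(lb, np.ones(100))
        k, band = cohen_kappa(a, b)
        assert k == pytest.approx(0.6)
        assert band == "moderate"

    def test_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(5)
        la = rng.choice([INCONSISTENT, CONSISTENT], 200, p=[0.2, 0.8])
        lb = rng.choice([INCONSISTENT, CONSISTENT], 200, p=[0.3, 0.7])
        k, _ = cohen_kappa(ClassAssignment(la, np.ones(200)),
                           ClassAssignment(lb, np.ones(200)))
        assert k == pytest.approx(cohen_kappa_score(la, lb), abs=1e-12)

    def test_kappa_length_mismatch(self):
        a = ClassAssignment(np.array([CONSISTENT] * 3), np.ones(3))
        b = ClassAssignment(np.array([CONSISTENT] * 4), np.ones(4))
        with pytest.raises(ValueError):
            cohen_kappa(a, b)

    def test_band_cut_points(self):
        assert kappa_band(-0.1) == "none"
        assert kappa_band(0.1) == "none-to-slight"
        assert kappa_band(0.33) == "fair"
        assert kappa_band(0.75) == "substantial"


class TestFitting:
    def test_em_monotone_and_constraints(self, contaminated_continuous):
        fit = fit_fma(contaminated_continuous.continuous, arias_spec(POL),
                      n_starts=8, n_final=2, seed=0)
        assert (np.diff(fit.loglik_history) >= -1e-6).all()
        lam = fit.parameters.loadings
        assert np.allclose(lam[0], [1] * 5 + [-1] * 5, atol=1e-12)
        assert (fit.parameters.uniquenesses > 0).all()
        assert (fit.parameters.factor_variances > 0).all()
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-10)
        assert 0.0 <= fit.entropy <= 1.0

    def test_arias_parameter_recovery(self, contaminated_continuous):
        # truth: mixing 0.10, phi = (0.5, 1.0), n = 2000
        fit = fit_fma(contaminated_continuous.continuous, arias_spec(POL),
                      n_starts=10, n_final=3, seed=1)
        n = 2000
        se_w = np.sqrt(0.1 * 0.9 / n)
        assert abs(fit.parameters.mixing_weight - 0.10) < 3 * se_w + 0.01
        assert abs(fit.parameters.factor_variances[0] - 0.5) < 0.15
        assert abs(fit.parameters.factor_variances[1] - 1.0) < 0.15

    def test_steinmann_constraint_fidelity(self):
        spec = GeneratorSpec(mixing_weight=0.12, seed=17)
        lab = generate_responses(spec, 1200, mechanism="steinmann",
                                 continuous=True)
        fit = fit_fma(lab.continuous, steinmann_spec(POL),
                      n_starts=10, n_final=2, seed=3)
        lam = fit.parameters.loadings
        assert np.allclose(lam[0, 5:], -lam[1, 5:], atol=1e-8)
        assert np.allclose(lam[0, :5], lam[1, :5], atol=1e-8)
        nu = fit.parameters.intercepts
        assert np.allclose(nu[0, :5], nu[1, :5], atol=1e-8)
        assert fit.parameters.factor_means[1] == 0.0
        assert fit.parameters.factor_variances[1] == 1.0

    def test_em_matches_direct_optimizer_on_toy(self):
        """On a small instance the EM optimum should match direct numerical
        maximization of the same constrained loglikelihood."""
        spec_g = symmetric_spec(mixing_weight=0.25, seed=23,
                                class_factor_variances=(0.4, 1.0))
        lab = generate_responses(spec_g, 80, mechanism="arias", continuous=True)
        Y = lab.continuous
        mspec = arias_spec(POL)
        fit = fit_fma(Y, mspec, n_starts=12, n_final=4, seed=4)

        def negll(z):
            theta, pi = z[:-1], expit(z[-1])
            params = _unpack(theta, mspec)
            mu = params.intercepts + params.factor_means[:, None] * params.loadings
            dens = np.empty((len(Y), 2))
            for k in range(2):
                cov = (params.factor_variances[k]
                       * np.outer(params.loadings[k], params.loadings[k])
                       + np.diag(params.uniquenesses))
                dens[:, k] = multivariate_normal(mu[k], cov).logpdf(Y)
            return -logsumexp(dens + np.log([pi, 1 - pi]), axis=1).sum()

        z0 = np.concatenate([_pack(fit.parameters, mspec),
                             [logit(fit.parameters.mixing_weight)]])
        res = minimize(negll, z0, method="Nelder-Mead",
                       options={"maxiter": 40000, "fatol": 1e-10,
                                "xatol": 1e-8, "adaptive": True})
        # the independent optimizer cannot improve on the EM solution
        assert -res.fun <= fit.loglikelihood + 1e-4

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="sample size"):
            fit_fma(np.zeros((20, 10)), arias_spec(POL), n_starts=1)


class TestClassification:
    def test_modal_assignment_and_tie_break(self):
        from wordfx.fma import FMAFit
        fit = FMAFit(spec=arias_spec(POL), parameters=None,
                     loglikelihood=0.0, n_free_parameters=23,
                     posteriors=np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]]),
                     entropy=0.5, n_starts_run=1, best_loglik_replications=1,
                     converged=True)
        a = classify(fit)
        assert a.labels.tolist() == [INCONSISTENT, CONSISTENT, CONSISTENT]
        assert (a.max_posterior >= 0.5).all()

    def test_well_separated_classification_accuracy(self):
        # high standardized loadings => sharp posteriors
        spec = symmetric_spec(mixing_weight=0.10, seed=29,
                              class_factor_variances=(1.0, 1.0))
        spec.uniquenesses = np.full(10, 0.15)
        lab = generate_responses(spec, 1500, mechanism="steinmann",
                                 continuous=True)
        fit = fit_fma(lab.continuous, steinmann_spec(POL),
                      n_starts=10, n_final=3, seed=5)
        agree = (classify(fit).labels == lab.true_class).mean()
        assert agree > 0.95

    def test_screen_sample_bookkeeping(self):
        lab = generate_responses(GeneratorSpec(mixing_weight=0.2, seed=3), 200)
        truth = ClassAssignment(lab.true_class, np.ones(200))
        screened = screen_sample(lab.responses, truth)
        assert screened.n == (lab.true_class == CONSISTENT).sum()
        kept = lab.responses.data.index[lab.true_class == CONSISTENT]
        assert list(screened.data.index) == list(kept)

    def test_screen_sample_no_inconsistent_identity(self):
        lab = generate_responses(GeneratorSpec(mixing_weight=0.0, seed=6), 100)
        all_cons = ClassAssignment(np.array([CONSISTENT] * 100), np.ones(100))
        screened = screen_sample(lab.responses, all_cons)
        assert (screened.data == lab.responses.data).all().all()
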