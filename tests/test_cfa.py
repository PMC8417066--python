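"""Confirmatory structures: dof bookkeeping, recovery, indices, MIs."""

import numpy as np
import pytest

from wordfx import (
    RSES_POLARITY,
    build_cfa_spec,
    fit_cfa,
    fit_indices,
    modification_indices,
    table1_matrix,
    table1_sample_size,
)
from wordfx.cfa import implied_correlation, independence_baseline
from wordfx.types import default_polarity

ITEMS = [f"p{i+1}" for i in range(5)] + [f"n{i+1}" for i in range(5)]


class TestSpecs:
    @pytest.mark.parametrize("kind,theta,df", [
        ("one_factor", None, 35),
        ("one_factor", True, 34),
        ("two_factor", None, 34),
        ("two_factor", True, 33),
        ("riifa", None, 34),
        ("riifa", True, 33),
    ])
    def test_degrees_of_freedom(self, kind, theta, df):
        spec = build_cfa_spec(kind, RSES_POLARITY, theta=theta, item_names=ITEMS)
        assert spec.df == df

    def test_riifa_requires_negatives(self):
        with pytest.raises(ValueError, match="negatively"):
            build_cfa_spec("riifa", ["positive"] * 10)

    def test_riifa_method_sign_pattern(self):
        spec = build_cfa_spec("riifa", RSES_POLARITY)
        assert spec.method_signs.tolist() == [1] * 5 + [-1] * 5

    def test_implied_unit_diagonal(self):
        spec = build_cfa_spec("riifa", RSES_POLARITY, theta=(3, 4))
        S = implied_correlation(spec, np.linspace(0.4, 0.8, 10), 0.3, 0.2)
        assert np.allclose(np.diag(S), 1.0, atol=1e-12)


class TestFitting:
    def test_one_factor_self_consistency(self):
        lam = np.linspace(0.5, 0.9, 10)
        spec = build_cfa_spec("one_factor", RSES_POLARITY)
        R = implied_correlation(spec, lam, None, 0.0)
        fit = fit_cfa(R, 500, spec)
        assert fit.discrepancy_value == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.abs(fit.standardized_loadings), lam, atol=1e-6)
        assert np.allclose(fit.communalities, lam**2, atol=1e-6)

    def test_two_factor_theta_recovers_parameters(self):
        lam = np.full(10, 0.7)
        spec = build_cfa_spec("two_factor", RSES_POLARITY, theta=(3, 4),
                              item_names=ITEMS)
        R = implied_correlation(spec, lam, 0.8, 0.15)
        fit = fit_cfa(R, 500, spec)
        assert fit.factor_correlation == pytest.approx(0.8, abs=1e-6)
        # theta is reported as a residual correlation
        assert fit.theta_standardized == pytest.approx(0.15 / (1 - 0.49), abs=1e-5)

    def test_riifa_method_loadings_equal_magnitude(self):
        R = table1_matrix("total")
        spec = build_cfa_spec("riifa", RSES_POLARITY, theta=True, item_names=ITEMS)
        fit = fit_cfa(R, 632, spec)
        # single method variance => one shared standardized magnitude
        assert fit.method_loading is not None
        assert fit.method_loading >= 0

    def test_nesting_of_discrepancies(self):
        R = table1_matrix("total")
        fits = {
            kind: fit_cfa(R, 632, build_cfa_spec(kind, RSES_POLARITY,
                                                 item_names=ITEMS))
            for kind in ("one_factor", "two_factor", "riifa")
        }
        assert fits["one_factor"].discrepancy_value >= \
            fits["two_factor"].discrepancy_value - 1e-10
        assert fits["one_factor"].discrepancy_value >= \
            fits["riifa"].discrepancy_value - 1e-10

    @pytest.mark.parametrize("sample,expected", [
        ("total", 0.77), ("steinmann", 0.87), ("arias", 0.98)])
    def test_two_factor_theta_factor_correlations(self, sample, expected):
        R = table1_matrix(sample)
        n = table1_sample_size(sample)
        spec = build_cfa_spec("two_factor", RSES_POLARITY, theta=True,
                              item_names=ITEMS)
        fit = fit_cfa(R, n, spec, estimator="dwls")
        assert fit.factor_correlation == pytest.approx(expected, abs=0.02)

    @pytest.mark.parametrize("sample,expected", [
        ("total", 0.25), ("steinmann", 0.20), ("arias", 0.07)])
    def test_riifa_theta_method_loadings(self, sample, expected):
        R = table1_matrix(sample)
        n = table1_sample_size(sample)
        spec = build_cfa_spec("riifa", RSES_POLARITY, theta=True, item_names=ITEMS)
        fit = fit_cfa(R, n, spec, estimator="dwls")
        assert fit.method_loading == pytest.approx(expected, abs=0.02)


class TestIndices:
    def test_perfect_fit(self):
        lam = np.full(10, 0.7)
        spec = build_cfa_spec("one_factor", RSES_POLARITY)
        R = implied_correlation(spec, lam, None, 0.0)
        fit = fit_cfa(R, 500, spec)
        idx = fit_indices(fit)
        assert idx["CFI"] == pytest.approx(1.0)
        assert idx["RMSEA"] == pytest.approx(0.0, abs=1e-6)
        assert idx["SRMR"] == pytest.approx(0.0, abs=1e-8)

    def test_hand_computed_formulas(self):
        # chi2_M=100, df_M=35, chi2_B=1000, df_B=45, n=632
        from wordfx.cfa import CFAFit
        spec = build_cfa_spec("one_factor", RSES_POLARITY)
        fit = CFAFit(spec=spec, standardized_loadings=np.zeros(10),
                     communalities=np.zeros(10), factor_correlation=None,
                     method_loading=None, theta_standardized=None,
                     discrepancy_value=0.0, chi_square=100.0, df=35,
                     sample_size=632, R=np.eye(10), implied=np.eye(10))
        idx = fit_indices(fit, baseline=(1000.0, 45))
        assert idx["CFI"] == pytest.approx(1 - 65 / 955, abs=1e-9)
        assert idx["RMSEA"] == pytest.approx(np.sqrt(65 / (35 * 631)), abs=1e-9)
        tli = ((1000 / 45) - (100 / 35)) / ((1000 / 45) - 1)
        assert idx["TLI"] == pytest.approx(tli, abs=1e-9)

    def test_rmsea_ci_brackets_point_estimate(self):
        R = table1_matrix("total")
        spec = build_cfa_spec("one_factor", RSES_POLARITY, item_names=ITEMS)
        fit = fit_cfa(R, 632, spec)
        idx = fit_indices(fit)
        lo, hi = idx["RMSEA_90ci"]
        assert lo <= idx["RMSEA"] <= hi

    def test_qualitative_bands(self):
        from wordfx.cfa import CFAFit
        spec = build_cfa_spec("one_factor", RSES_POLARITY)
        fit = CFAFit(spec=spec, standardized_loadings=np.zeros(10),
                     communalities=np.zeros(10), factor_correlation=None,
                     method_loading=None, theta_standardized=None,
                     discrepancy_value=0.0, chi_square=40.0, df=35,
                     sample_size=632, R=np.eye(10), implied=np.eye(10))
        idx = fit_indices(fit, baseline=(1000.0, 45))
        assert idx["CFI_band"] == "excellent"
        assert idx["RMSEA_band"] == "close"
        assert idx["SRMR_band"] == "good"

    def test_baseline_df(self):
        chi, df = independence_baseline(table1_matrix("total"), 632)
        assert df == 45
        assert chi > 0


class TestModificationIndices:
    def test_freed_parameter_excluded(self):
        R = table1_matrix("total")
        spec = build_cfa_spec("one_factor", RSES_POLARITY, theta=True,
                              item_names=ITEMS)
        fit = fit_cfa(R, 632, spec)
        mi = modification_indices(fit)
        assert "p4~~p5" not in set(mi["parameter"])

    def test_refit_oracle_on_toy(self):
        """The score-based MI should approximate the chi-square improvement
        obtained by actually freeing the parameter and refitting."""
        # six items: with only four, the freed covariance is exchangeable
        # across pairs (equivalent models), so the top pair is not unique
        items = ["p1", "p2", "p3", "n1", "n2", "n3"]
        pol = default_polarity(3, 3)
        lam = np.full(6, 0.7)
        spec_true = build_cfa_spec("one_factor", pol, theta=(0, 1),
                                   item_names=items)
        theta_corr = 0.4
        theta_cov = theta_corr * (1 - 0.49)   # residual corr -> covariance
        R = implied_correlation(spec_true, lam, None, theta_cov)
        n = 800
        spec_restricted = build_cfa_spec("one_factor", pol, item_names=items)
        fit0 = fit_cfa(R, n, spec_restricted)
        mi = modification_indices(fit0)
        top = mi.iloc[0]
        assert top["parameter"] == "p1~~p2"
        assert top["SEPC"] == pytest.approx(theta_corr, abs=0.08)
        fit1 = fit_cfa(R, n, spec_true)
        actual_drop = fit0.chi_square - fit1.chi_square
        assert top["MI"] == pytest.approx(actual_drop, rel=0.15)

    def test_p4_p5_tops_every_study_model(self):
        for sample in ("total", "arias"):
            R = table1_matrix(sample)
            n = table1_sample_size(sample)
            for kind in ("one_factor", "two_factor", "riifa"):
                spec = build_cfa_spec(kind, RSES_POLARITY, item_names=ITEMS)
                fit = fit_cfa(R, n, spec, estimator="dwls")
                mi = modification_indices(fit)
                err = mi[mi["kind"] == "error_cov"]
                assert err.iloc[0]["parameter"] == "p4~~p5"
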