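"""Bivariate pooling, sROC, proportion pooling, heterogeneity, Deeks, Fagan."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit, logit

from crcscreen import (
    BivariateFit,
    MetaParams,
    StudyRecord,
    deeks_test,
    fagan_posttest,
    fit_bivariate,
    heterogeneity,
    meta_regression,
    pool_proportion,
    proportion_ci,
    simulate_study_set,
    sroc_curve,
    summarize_bivariate,
)
from crcscreen.meta import _logit_data


def make_fit(mu_sens, mu_spec, tau2_sens=0.2, tau2_spec=0.2, rho=0.0, se=0.05):
    """Hand-built fitted model for summary/sROC tests."""
    return BivariateFit(
        mu_sens=mu_sens,
        mu_spec=mu_spec,
        tau2_sens=tau2_sens,
        tau2_spec=tau2_spec,
        rho=rho,
        loglik=0.0,
        n_studies=10,
        method="reml_normal",
        mu_cov=np.eye(2) * se**2,
    )


class TestFitBivariate:
    def test_homogeneous_studies(self, homogeneous_studies):
        fit = fit_bivariate(homogeneous_studies)
        assert fit.pooled_sensitivity == pytest.approx(0.76, abs=0.005)
        assert fit.pooled_specificity == pytest.approx(0.93, abs=0.005)
        assert fit.tau2_sens < 1e-4
        assert fit.tau2_spec < 1e-4

    def test_fixed_effect_closed_form(self):
        """With tau2 pinned at zero the pooled logits are the
        inverse-variance weighted means, computed here by hand."""
        studies = [
            StudyRecord("a", tp=40, fn=10, tn=180, fp=20),
            StudyRecord("b", tp=25, fn=25, tn=90, fp=10),
        ]
        fit = fit_bivariate(studies, tau2_fixed=(0.0, 0.0))
        y, s2 = _logit_data(studies, 0.5)
        w = 1.0 / s2
        expected = (w * y).sum(axis=0) / w.sum(axis=0)
        assert fit.mu_sens == pytest.approx(expected[0], abs=1e-6)
        assert fit.mu_spec == pytest.approx(expected[1], abs=1e-6)

    def test_moderate_recovery(self, heterogeneous_studies):
        fit = fit_bivariate(heterogeneous_studies)
        assert fit.pooled_sensitivity == pytest.approx(0.76, abs=0.06)
        assert fit.pooled_specificity == pytest.approx(0.92, abs=0.04)
        assert fit.rho < 0.5  # generating correlation is negative

    def test_binomial_ml_agrees_with_reml(self):
        params = MetaParams(n_studies=30, tau_sens=0.3, tau_spec=0.3, rho=0.0,
                            study_size_range=(1000, 3000), seed=21)
        studies = simulate_study_set(params)
        reml = fit_bivariate(studies)
        ml = fit_bivariate(studies, method="ml_binomial")
        assert ml.pooled_sensitivity == pytest.approx(
            reml.pooled_sensitivity, abs=0.02
        )
        assert ml.pooled_specificity == pytest.approx(
            reml.pooled_specificity, abs=0.02
        )

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            fit_bivariate([StudyRecord("only", tp=10, fn=5, tn=20, fp=5)])

    def test_zero_cells_handled_by_correction(self):
        studies = [
            StudyRecord("z", tp=10, fn=0, tn=50, fp=5),
            StudyRecord("y", tp=8, fn=2, tn=45, fp=10),
            StudyRecord("x", tp=9, fn=1, tn=48, fp=7),
        ]
        fit = fit_bivariate(studies)
        assert 0 < fit.pooled_sensitivity < 1


class TestSummarizeBivariate:
    def test_lr_neg_closed_form(self):
        fit = make_fit(logit(0.76), logit(0.59))
        pooled = summarize_bivariate(fit)
        assert pooled.lr_neg == pytest.approx((1 - 0.76) / 0.59, abs=1e-6)

    def test_uninformative(self):
        fit = make_fit(0.0, 0.0)
        pooled = summarize_bivariate(fit)
        assert pooled.lr_pos == pytest.approx(1.0)
        assert pooled.lr_neg == pytest.approx(1.0)

    def test_lr_identities_at_point_estimates(self, heterogeneous_studies):
        pooled = summarize_bivariate(fit_bivariate(heterogeneous_studies))
        assert pooled.lr_pos == pytest.approx(
            pooled.sensitivity / (1 - pooled.specificity)
        )
        assert pooled.lr_neg == pytest.approx(
            (1 - pooled.sensitivity) / pooled.specificity
        )

    def test_bootstrap_cross_check(self):
        fit = make_fit(logit(0.8), logit(0.9), se=0.1)
        delta = summarize_bivariate(fit)
        boot = summarize_bivariate(fit, bootstrap=4000, seed=0)
        assert boot.lr_pos_ci.lower == pytest.approx(delta.lr_pos_ci.lower, rel=0.1)
        assert boot.lr_pos_ci.upper == pytest.approx(delta.lr_pos_ci.upper, rel=0.1)
        assert delta.lr_pos in boot.lr_pos_ci

    def test_intervals_contain_points(self, heterogeneous_studies):
        pooled = summarize_bivariate(fit_bivariate(heterogeneous_studies))
        assert pooled.sensitivity in pooled.sensitivity_ci
        assert pooled.lr_neg in pooled.lr_neg_ci


class TestSROC:
    def test_auc_matches_quadrature_oracle(self):
        fit = make_fit(1.2, 1.2, tau2_sens=0.25, tau2_spec=0.25, rho=-0.2)
        sroc = sroc_curve(fit, grid_size=2000)
        beta = 0.0  # equal tau
        lam = fit.mu_sens + fit.mu_spec
        oracle, err = quad(
            lambda f: expit(lam * math.exp(-beta / 2) + math.exp(-beta) * logit(f)),
            0.0,
            1.0,
            limit=200,
        )
        assert sroc.auc == pytest.approx(oracle, abs=1e-4)

    def test_symmetric_fit_curve_symmetry(self):
        """Equal pooled sens/spec with equal tau gives a curve symmetric
        about the anti-diagonal: sens(f) = 1 - f_at(1 - sens)."""
        fit = make_fit(1.0, 1.0, tau2_sens=0.3, tau2_spec=0.3)
        sroc = sroc_curve(fit, grid_size=4001)
        fpr, sens = sroc.curve[:, 0], sroc.curve[:, 1]
        flipped = np.interp(1 - sens[::-1], fpr, sens)
        assert np.allclose(flipped, 1 - fpr[::-1], atol=1e-5)

    def test_perfect_test_limit(self):
        sroc = sroc_curve(make_fit(8.0, 8.0, tau2_sens=0.1, tau2_spec=0.1))
        assert sroc.auc > 0.99

    def test_uninformative_diagonal(self):
        sroc = sroc_curve(make_fit(logit(0.6), logit(0.4), tau2_sens=0.2,
                                   tau2_spec=0.2, rho=0.0))
        assert sroc.auc == pytest.approx(0.5, abs=1e-3)

    def test_grid_size_invariance(self):
        fit = make_fit(1.5, 1.0, tau2_sens=0.3, tau2_spec=0.5)
        a1 = sroc_curve(fit, grid_size=1000).auc
        a2 = sroc_curve(fit, grid_size=4000).auc
        assert abs(a1 - a2) < 1e-4

    def test_degenerate_fit_flagged(self):
        fit = make_fit(1.0, 1.0, tau2_sens=0.0, tau2_spec=0.0)
        with pytest.warns(UserWarning):
            sroc = sroc_curve(fit)
        assert sroc.degenerate
        assert sroc.auc is None


class TestPoolProportion:
    def test_identical_studies(self):
        pooled = pool_proportion([50, 50, 50], [1000, 1000, 1000])
        assert pooled.estimate == pytest.approx(0.05, abs=1e-9)
        assert pooled.tau2 == 0.0
        assert pooled.i2 == 0.0

    def test_single_study_reduces_to_proportion_ci(self):
        pooled = pool_proportion([30], [1000])
        ci = proportion_ci(30, 1000)
        assert pooled.estimate == pytest.approx(0.03)
        assert pooled.interval.lower == ci.lower
        assert pooled.interval.upper == ci.upper

    def test_heterogeneity_detected(self):
        rng = np.random.default_rng(0)
        n = np.full(60, 2000)
        true_logit = rng.normal(logit(0.05), 0.5, size=60)
        k = rng.binomial(n, expit(true_logit))
        pooled = pool_proportion(k.tolist(), n.tolist())
        assert pooled.tau2 == pytest.approx(0.25, abs=0.15)
        assert pooled.i2 > 0.5

    def test_all_zero_flagged(self):
        pooled = pool_proportion([0, 0], [100, 200])
        assert pooled.all_zero
        assert pooled.estimate == 0.0
        assert pooled.interval.lower == 0.0
        assert pooled.interval.upper > 0

    def test_per_1000_scale(self):
        prop = pool_proportion([20, 30], [10_000, 12_000])
        rate = pool_proportion([20, 30], [10_000, 12_000], scale="per_1000")
        assert rate.estimate == pytest.approx(1000 * prop.estimate)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pool_proportion([1, 2], [100])


class TestHeterogeneity:
    def test_identical_estimates(self):
        r = heterogeneity([1.0, 1.0, 1.0], [0.1, 0.2, 0.1])
        assert r.q == pytest.approx(0.0, abs=1e-12)
        assert r.i2 == 0.0

    def test_two_study_hand_computation(self):
        # w = (10, 5); weighted mean = (10*2 + 5*3)/15 = 7/3
        # Q = 10*(2-7/3)^2 + 5*(3-7/3)^2 = 10/9 + 20/9 = 10/3
        r = heterogeneity([2.0, 3.0], [0.1, 0.2])
        assert r.q == pytest.approx(10.0 / 3.0)
        assert r.df == 1
        assert r.i2 == pytest.approx((10 / 3 - 1) / (10 / 3))

    def test_floor_at_zero(self):
        # tiny spread relative to variances => Q < df => I2 floored
        r = heterogeneity([1.0, 1.001, 0.999], [1.0, 1.0, 1.0])
        assert r.i2 == 0.0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity([1.0, 2.0], [0.1, 0.0])


class TestMetaRegression:
    def test_planted_sensitivity_effect(self):
        params = MetaParams(
            n_studies=60, mu_sens=0.0, mu_spec=logit(0.9),
            tau_sens=0.3, tau_spec=0.4, rho=0.0,
            covariate_effects={"regime": {"A": (-1.0, 0.0), "B": (1.0, 0.0)}},
            seed=3,
        )
        result = meta_regression(simulate_study_set(params), "regime")
        assert result.het_explained["sensitivity"] > 0.8
        assert result.p_values["sensitivity"] < 1e-6
        assert result.p_values["specificity"] > 0.01
        # planted contrast between categories is 2 logits
        assert result.coefficients["B"][0] == pytest.approx(2.0, abs=0.5)

    def test_null_covariate_explains_little(self):
        params = MetaParams(
            n_studies=60, tau_sens=0.3, tau_spec=0.4, rho=0.0,
            covariate_effects={"noise": {"A": (0.0, 0.0), "B": (0.0, 0.0)}},
            seed=4,
        )
        result = meta_regression(simulate_study_set(params), "noise")
        assert result.het_explained["sensitivity"] < 0.3
        assert result.p_values["sensitivity"] > 0.01

    def test_single_category_rejected(self):
        studies = [
            StudyRecord(f"s{i}", tp=40, fn=10, tn=90, fp=10,
                        covariates={"kind": "only"})
            for i in range(6)
        ]
        with pytest.raises(ValueError):
            meta_regression(studies, "kind")

    def test_singleton_category_dropped(self):
        studies = [
            StudyRecord(f"s{i}", tp=40 + i, fn=10, tn=90, fp=10,
                        covariates={"kind": "A" if i < 3 else "B"})
            for i in range(6)
        ] + [
            StudyRecord("lone", tp=30, fn=20, tn=80, fp=20,
                        covariates={"kind": "C"})
        ]
        with pytest.warns(UserWarning, match="singleton"):
            result = meta_regression(studies, "kind")
        assert result.dropped_categories == ("C",)
        assert result.n_studies == 6

    def test_missing_covariate_rejected(self):
        studies = [
            StudyRecord("a", tp=40, fn=10, tn=90, fp=10, covariates={"x": "1"}),
            StudyRecord("b", tp=40, fn=10, tn=90, fp=10),
        ]
        with pytest.raises(ValueError):
            meta_regression(studies, "x")


class TestDeeks:
    def test_identical_studies_slope_zero(self):
        studies = [StudyRecord(f"s{i}", tp=40, fn=10, tn=90, fp=10) for i in range(5)]
        r = deeks_test(studies)
        assert r.slope == pytest.approx(0.0, abs=1e-9)

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            deeks_test([StudyRecord("a", tp=4, fn=1, tn=9, fp=1)] * 2)

    def test_planted_small_study_effect_recovered(self):
        """ln DOR inflated by gamma/sqrt(ESS): the regression slope should
        recover gamma.  Large cells keep the logit small-sample bias
        negligible; the check is on the replicate mean within 2 SE."""
        gamma = 10.0
        slopes = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            studies = []
            for i in range(30):
                n = int(np.exp(rng.uniform(np.log(20_000), np.log(50_000))))
                n1 = int(round(n * 0.2))
                n2 = n - n1
                ess = 4.0 * n1 * n2 / n
                s = expit(logit(0.8) + gamma / math.sqrt(ess))
                tp = int(rng.binomial(n1, s))
                tn = int(rng.binomial(n2, 0.9))
                studies.append(
                    StudyRecord(f"s{i}", tp=tp, fn=n1 - tp, tn=tn, fp=n2 - tn)
                )
            slopes.append(deeks_test(studies).slope)
        slopes = np.array(slopes)
        sem = slopes.std(ddof=1) / math.sqrt(len(slopes))
        assert abs(slopes.mean() - gamma) < 2 * sem + 0.1


class TestFagan:
    @pytest.mark.parametrize(
        "pretest, lr, expected",
        [
            (0.01, (1 - 0.76) / 0.59, 0.0041),
            (0.5, 1.0, 0.5),
            (0.01, 0.258, 0.0026),
        ],
    )
    def test_examples(self, pretest, lr, expected):
        assert round(fagan_posttest(pretest, lr).posttest, 4) == expected

    def test_monotone_in_lr_and_pretest(self):
        base = fagan_posttest(0.1, 2.0).posttest
        assert fagan_posttest(0.1, 3.0).posttest > base
        assert fagan_posttest(0.2, 2.0).posttest > base

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            fagan_posttest(0.0, 2.0)
        with pytest.raises(ValueError):
            fagan_posttest(0.5, 0.0)
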