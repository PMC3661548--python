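"""Facing-gamma components, mixture likelihood, fitting and classification.

Frozen expected values were computed from the regularized incomplete gamma
function (scipy.special.gammainc / scipy.stats.gamma at high precision)
applied to the published component parameters.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import morphmix as mm
from morphmix.facing_gamma import (ClassificationRule, FitConfig, _neg_loglik,
                                   classification_cutoffs, cutoffs_overlap)


class TestComponentDensity:
    def test_zero_below_lower_bound(self, homeo_component):
        assert homeo_component.pdf(0.40) == 0.0

    def test_exponential_special_case_at_origin(self):
        # shape 1 reduces to an exponential: density 1/θ at the bound
        c = mm.right_facing(1.0, 2.0, 0.0)
        assert c.pdf(0.0) == pytest.approx(0.5)

    def test_frozen_density_value(self, homeo_component):
        # oracle: gamma pdf at (1.02-0.48)/θ with shape 1.91, scale 0.163
        assert homeo_component.pdf(1.02) == pytest.approx(0.6883381867605508, rel=1e-12)

    def test_left_facing_mirror_density(self, hetero_component):
        assert hetero_component.pdf(1.02) == pytest.approx(0.1836540772884964, rel=1e-12)
        assert hetero_component.pdf(2.30) == 0.0   # above upper bound

    def test_moments(self, homeo_component, hetero_component):
        assert homeo_component.mean == pytest.approx(0.48 + 1.91 * 0.163)
        assert hetero_component.mean == pytest.approx(2.25 - 2.88 * 0.201)
        assert homeo_component.variance == pytest.approx(1.91 * 0.163 ** 2)


class TestComponentCdfQuantile:
    def test_cdf_limits(self, homeo_component, hetero_component):
        assert homeo_component.cdf(0.48) == 0.0
        assert hetero_component.cdf(2.25) == 1.0
        assert homeo_component.cdf(50.0) == pytest.approx(1.0)
        assert hetero_component.cdf(-50.0) == pytest.approx(0.0, abs=1e-300)

    def test_printed_upper_cutoff_is_95th_percentile(self, homeo_component):
        assert homeo_component.cdf(1.23) == pytest.approx(0.95, abs=2e-4)
        assert homeo_component.quantile(0.95) == pytest.approx(1.2293429261977926, abs=1e-9)

    def test_printed_lower_cutoff_is_5th_percentile(self, hetero_component):
        assert hetero_component.quantile(0.05) == pytest.approx(1.020768533152641, abs=1e-9)

    def test_exponential_median_closed_form(self):
        r = mm.right_facing(1.0, 0.3, 2.0)
        l = mm.left_facing(1.0, 0.3, 2.0)
        assert r.quantile(0.5) == pytest.approx(2.0 + 0.3 * math.log(2), abs=1e-12)
        assert l.quantile(0.5) == pytest.approx(2.0 - 0.3 * math.log(2), abs=1e-12)

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99, 0.999])
    def test_quantile_inverts_cdf(self, homeo_component, hetero_component, p):
        for c in (homeo_component, hetero_component):
            assert c.cdf(c.quantile(p)) == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize("p", [-0.1, 0.0, 1.0, 1.5])
    def test_quantile_domain(self, homeo_component, p):
        with pytest.raises(ValueError):
            homeo_component.quantile(p)


class TestMixtureDensity:
    def test_near_degenerate_weight_matches_component(self, homeo_component,
                                                      hetero_component):
        m = mm.MixtureModel(1 - 1e-12, homeo_component, hetero_component)
        xs = np.linspace(0.5, 1.5, 7)
        assert np.allclose(m.pdf(xs), homeo_component.pdf(xs), atol=1e-9)

    def test_normalization(self, reference_model):
        total, _ = integrate.quad(reference_model.pdf, -5.0, 10.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_frozen_mixture_value(self, reference_model):
        # 0.5·(0.688338 + 0.183654)
        assert reference_model.pdf(1.02) == pytest.approx(0.4359961320245236, rel=1e-10)

    def test_strictly_positive_between_bounds(self, reference_model):
        xs = np.linspace(0.48, 2.25, 101)
        assert np.all(reference_model.pdf(xs) > 0)


class TestLogLikelihood:
    def test_matches_brute_force_summation(self, reference_model):
        rng = np.random.default_rng(5)
        xs = reference_model.sample(200, rng)
        brute = sum(math.log(float(reference_model.pdf(float(x)))) for x in xs)
        assert reference_model.log_likelihood(xs) == pytest.approx(brute, abs=1e-10)

    def test_duplication_additivity(self, reference_model):
        xs = np.array([0.7, 1.1, 1.8])
        one = reference_model.log_likelihood(xs)
        assert reference_model.log_likelihood(np.tile(xs, 4)) == pytest.approx(4 * one)

    def test_empty_sample_rejected(self, reference_model):
        with pytest.raises(ValueError):
            reference_model.log_likelihood([])


class TestPosterior:
    def test_support_extremes(self, reference_model):
        assert reference_model.posterior_hetero(2.26) == 0.0   # above U
        assert reference_model.posterior_hetero(0.40) == 1.0   # below L

    def test_frozen_interior_value(self, reference_model):
        assert reference_model.posterior_hetero(1.02) == pytest.approx(
            0.21061434242, abs=1e-9)

    def test_bounded_and_monotone_through_the_gap(self, reference_model):
        # monotone between the component means; near the bounds the
        # vanishing within-component density makes the posterior spike
        xs = np.linspace(0.5, 2.2, 200)
        post = reference_model.posterior_hetero(xs)
        assert np.all((post >= 0) & (post <= 1))
        gap = np.linspace(0.80, 1.65, 100)
        assert np.all(np.diff(reference_model.posterior_hetero(gap)) >= -1e-12)


class TestCutoffs:
    def test_printed_cutoffs_reproduced(self, reference_model):
        lo, hi = classification_cutoffs(reference_model, 0.95)
        assert round(lo, 2) == 1.02
        assert round(hi, 2) == 1.23

    def test_monotone_in_level(self, reference_model):
        lows, highs = zip(*(classification_cutoffs(reference_model, lv)
                            for lv in (0.90, 0.95, 0.99)))
        assert lows[0] >= lows[1] >= lows[2]
        assert highs[0] <= highs[1] <= highs[2]

    def test_crossed_assertion_regions_flagged(self):
        # very tight components: the hetero 5th percentile sits above the
        # homeo 95th percentile, so the two assertion regions overlap
        m = mm.MixtureModel(0.5, mm.right_facing(2.0, 0.02, 0.5),
                            mm.left_facing(2.0, 0.02, 2.25))
        assert cutoffs_overlap(m, 0.95)
        res = mm.classify(m, [1.5])   # inside the doubly-claimed band
        assert res.overlapping and res.labels == ["unassigned"]

    def test_moderate_separation_not_flagged(self, reference_model):
        assert not cutoffs_overlap(reference_model, 0.95)

    @pytest.mark.parametrize("level", [0.4, 0.5, 1.0])
    def test_level_domain(self, reference_model, level):
        with pytest.raises(ValueError):
            classification_cutoffs(reference_model, level)


class TestClassify:
    def test_short_patella_homeomorphic_under_both_rules(self, reference_model):
        for rule in ClassificationRule:
            res = mm.classify(reference_model, [0.60], rule=rule)
            assert res.labels == ["homeomorphic"]

    def test_value_at_cutoff_unassigned(self, reference_model):
        lo, hi = classification_cutoffs(reference_model, 0.95)
        res = mm.classify(reference_model, [lo, hi])
        assert res.labels == ["unassigned", "unassigned"]

    def test_all_above_high_cutoff(self, reference_model):
        res = mm.classify(reference_model, [1.5, 1.9, 2.2])
        assert res.counts() == {"homeomorphic": 0, "heteromorphic": 3,
                                "unassigned": 0}

    def test_posterior_rule_depends_on_weight(self, homeo_component,
                                              hetero_component):
        # at x=1.15 the posterior flips with π while quantile labels do not
        skew = mm.MixtureModel(0.98, homeo_component, hetero_component)
        res = mm.classify(skew, [1.15], rule="posterior")
        assert res.labels == ["homeomorphic"]


class TestFit:
    def test_recovery_and_dominance(self, reference_model, bimodal_sample,
                                    fitted_model):
        truth = reference_model.parameters
        est = fitted_model.parameters
        for key in truth:
            assert est[key] == pytest.approx(truth[key], rel=0.10), key
        # the MLE can never do worse than the generating parameters
        assert fitted_model.loglik >= reference_model.log_likelihood(bimodal_sample)

    def test_loglik_field_consistent(self, bimodal_sample, fitted_model):
        assert fitted_model.loglik == pytest.approx(
            fitted_model.log_likelihood(bimodal_sample), abs=1e-6)

    def test_deterministic_given_config(self, bimodal_sample, fitted_model):
        again = mm.fit_mixture(bimodal_sample, FitConfig())
        assert again.parameters == fitted_model.parameters

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            mm.fit_mixture([0.6, 0.7, 1.8], FitConfig())

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mm.fit_mixture(np.r_[np.linspace(-0.1, 1, 20)], FitConfig())

    def test_reflection_symmetry(self, reference_model):
        # reflecting the data through a constant swaps the two components
        rng = np.random.default_rng(9)
        xs = reference_model.sample(600, rng)
        c = 3.0
        cfg = FitConfig(starts=6)
        fit = mm.fit_mixture(xs, cfg)
        mirror = mm.fit_mixture(c - xs, cfg)
        assert mirror.loglik == pytest.approx(fit.loglik, abs=0.5)
        assert mirror.homeo.shape == pytest.approx(fit.hetero.shape, rel=0.05)
        assert mirror.hetero.shape == pytest.approx(fit.homeo.shape, rel=0.05)
        assert mirror.homeo.bound == pytest.approx(c - fit.hetero.bound, abs=0.02)
        assert mirror.hetero.bound == pytest.approx(c - fit.homeo.bound, abs=0.02)

    def test_grid_search_never_beats_optimizer(self, reference_model):
        rng = np.random.default_rng(11)
        xs = reference_model.sample(200, rng)
        fit = mm.fit_mixture(xs, FitConfig())
        span = xs.max() - xs.min()
        L = xs.min() - 1e-6
        U = xs.max() + 1e-6
        best_grid = -np.inf
        for pi in (0.3, 0.5, 0.7):
            for lam1 in (1.0, 1.5, 2.0, 3.0):
                for th1 in (0.08, 0.15, 0.25):
                    for lam2 in (1.0, 1.5, 2.0, 3.0):
                        for th2 in (0.1, 0.2, 0.3):
                            t = math.log(pi / (1 - pi))
                            p = np.array([
                                t,
                                math.log(max(lam1 - 1, 1e-9)), math.log(th1), L,
                                math.log(max(lam2 - 1, 1e-9)), math.log(th2), U])
                            best_grid = max(best_grid, -_neg_loglik(p, xs, span))
        assert fit.loglik >= best_grid - 0.1

    def test_serialization_round_trip(self, fitted_model):
        back = mm.MixtureModel.from_json(fitted_model.to_json())
        assert back.parameters == fitted_model.parameters
        assert back.loglik == fitted_model.loglik


class TestModelCompare:
    def test_bimodal_prefers_mixture(self, reference_model):
        rng = np.random.default_rng(3)
        xs = reference_model.sample(500, rng)
        report = mm.model_compare(xs, FitConfig(starts=4))
        assert report.preferred == "facing_mixture"

    def test_unimodal_prefers_single_gamma(self):
        rng = np.random.default_rng(4)
        xs = 0.5 + rng.gamma(2.0, 0.2, size=500)
        report = mm.model_compare(xs, FitConfig(starts=4))
        assert report.preferred == "single_gamma"

    def test_single_fit_matches_component_recovery(self):
        rng = np.random.default_rng(6)
        xs = 0.5 + rng.gamma(2.0, 0.2, size=2000)
        comp = mm.fit_single_gamma(xs)
        assert comp.shape == pytest.approx(2.0, rel=0.2)
        assert comp.bound == pytest.approx(0.5, abs=0.05)


class TestInvariantProperties:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shape=st.floats(1.0, 8.0), scale=st.floats(0.05, 0.5),
           bound=st.floats(0.1, 3.0), p=st.floats(0.01, 0.99))
    def test_quantile_cdf_inversion_property(self, shape, scale, bound, p):
        for make in (mm.right_facing, mm.left_facing):
            c = make(shape, scale, bound)
            assert c.cdf(c.quantile(p)) == pytest.approx(p, abs=1e-9)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(pi=st.floats(0.05, 0.95), lam1=st.floats(1.0, 5.0),
           lam2=st.floats(1.0, 5.0))
    def test_normalization_property(self, pi, lam1, lam2):
        m = mm.MixtureModel(pi, mm.right_facing(lam1, 0.2, 0.4),
                            mm.left_facing(lam2, 0.2, 2.3))
        total, _ = integrate.quad(m.pdf, -5.0, 10.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)
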