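"""Spatial-domain observer: template, decision variables, d', empirical AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npwmf import (
    DecisionSet,
    InternalNoiseModel,
    NoiseSpec,
    Template,
    analytic_template,
    auc_empirical,
    auc_from_dprime,
    decision_variables,
    disk_image,
    dprime_spatial,
    estimate_template,
    extract_samples,
    internal_noise_sigma,
    simulate_ensemble,
)
from npwmf.roi import RoiSamples


def _decisions(l1, l2, slices=None):
    return DecisionSet(L_absent=np.asarray(l1, float),
                       L_present=np.asarray(l2, float), slice_index=slices)


class TestTemplate:
    def test_noiseless_template_equals_blurred_profile(self, small_scene, small_geometry):
        spec, _ = small_scene
        ens = simulate_ensemble(spec, NoiseSpec(model="white", target_std=0.0), 2, 2, 1)
        s = extract_samples(ens, small_geometry)
        t = estimate_template(s)
        profile = disk_image(spec)[small_geometry.roi_mask]
        np.testing.assert_allclose(t.values, profile, atol=1e-9)
        assert t.source == "empirical"

    def test_noisy_template_within_clt_bound(self, small_scene, small_geometry):
        spec, _ = small_scene
        ens = simulate_ensemble(spec, NoiseSpec(model="white", target_std=5.0), 100, 3, 5)
        t = estimate_template(extract_samples(ens, small_geometry))
        profile = disk_image(spec)[small_geometry.roi_mask]
        # template pixel noise ~ sqrt(2) * sigma / sqrt(nm); allow 4 sigma
        bound = 4 * np.sqrt(2) * 5.0 / np.sqrt(300)
        assert np.all(np.abs(t.values - profile) < bound)

    def test_identical_classes_flagged_degenerate(self, small_geometry):
        x = np.random.default_rng(0).normal(size=(6, small_geometry.n_pixels))
        s = RoiSamples(present=x.copy(), absent=x.copy(),
                       slice_index=np.zeros(6, int), geometry=small_geometry)
        with pytest.warns(UserWarning, match="degenerate"):
            estimate_template(s)

    def test_analytic_template_matches_rendered_disk(self, small_scene, small_geometry):
        spec, _ = small_scene
        t = analytic_template(spec, small_geometry)
        assert t.source == "analytic"
        profile = disk_image(spec)[small_geometry.roi_mask]
        np.testing.assert_allclose(t.values, profile, atol=1e-12)


class TestDecisionVariables:
    def test_hand_worked_inner_product(self, small_geometry):
        t = Template(values=np.array([1.0, 2.0, 0.0]), source="empirical")
        s = RoiSamples(
            present=np.array([[4.0, -1.0, 7.0]]), absent=np.array([[0.0, 0.0, 0.0]]),
            slice_index=np.zeros(1, int), geometry=small_geometry,
        )
        d = decision_variables(s, t)
        assert d.L_present[0] == 2.0 and d.L_absent[0] == 0.0

    def test_ones_template_sums_roi(self, small_ensemble, small_geometry):
        s = extract_samples(small_ensemble, small_geometry)
        t = Template(values=np.ones(small_geometry.n_pixels), source="empirical")
        d = decision_variables(s, t)
        np.testing.assert_allclose(d.L_present, s.present.sum(axis=1))

    def test_linearity_in_image_scale(self, small_ensemble, small_geometry):
        s = extract_samples(small_ensemble, small_geometry)
        t = estimate_template(s)
        d = decision_variables(s, t)
        s2 = RoiSamples(present=3 * s.present, absent=3 * s.absent,
                        slice_index=s.slice_index, geometry=s.geometry)
        d2 = decision_variables(s2, t)
        np.testing.assert_allclose(d2.L_present, 3 * d.L_present)

    def test_length_mismatch_rejected(self, small_ensemble, small_geometry):
        s = extract_samples(small_ensemble, small_geometry)
        with pytest.raises(ValueError, match="template length"):
            decision_variables(s, Template(values=np.ones(3), source="empirical"))


class TestDprime:
    def test_known_means_and_variances(self):
        # sample means 0 and 2, unbiased sample variances exactly 1
        h = np.sqrt(0.5)
        d = dprime_spatial(_decisions([-h, h], [2 - h, 2 + h]))
        assert d == pytest.approx(2.0)

    def test_identical_classes_give_zero(self):
        assert dprime_spatial(_decisions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dprime_spatial(_decisions([1.0, 1.0], [2.0, 2.0]))

    def test_shift_and_scale_invariance(self, rng):
        l1, l2 = rng.normal(0, 1, 50), rng.normal(1.5, 1, 50)
        d0 = dprime_spatial(_decisions(l1, l2))
        assert dprime_spatial(_decisions(l1 + 10, l2 + 10)) == pytest.approx(d0)
        assert dprime_spatial(_decisions(5 * l1, 5 * l2)) == pytest.approx(d0)

    def test_gaussian_recovery_at_designed_separation(self, rng):
        # designed d' = 2 with 550 observations per class: the estimator is
        # unbiased and its spread matches the analytic ~3% relative sd
        est = []
        for _ in range(60):
            l1 = rng.normal(0, 1, 550)
            l2 = rng.normal(2, 1, 550)
            est.append(dprime_spatial(_decisions(l1, l2)))
        est = np.asarray(est)
        sem = est.std(ddof=1) / np.sqrt(len(est))
        assert est.mean() == pytest.approx(2.0, abs=3.5 * sem)
        assert est.std(ddof=1) / est.mean() == pytest.approx(0.03, rel=0.35)


class TestDprimeRoiRoute:
    def test_agrees_with_pooled_estimator_on_centred_data(self, rng):
        from npwmf import dprime_roi_route

        n, m = 40, 4
        l1 = rng.normal(0, 1, n * m)
        l2 = rng.normal(2, 1, n * m)
        sl = np.tile(np.arange(m), n)
        d = _decisions(l1, l2, slices=sl)
        # same quantity, different variance pooling: close but not identical
        assert dprime_roi_route(d) == pytest.approx(dprime_spatial(d), rel=0.1)

    def test_requires_slice_labels_and_repeats(self, rng):
        from npwmf import dprime_roi_route

        with pytest.raises(ValueError, match="slice labels"):
            dprime_roi_route(_decisions([0, 1], [2, 3]))
        d = _decisions([0.0, 1.0], [2.0, 3.0], slices=np.array([0, 1]))
        with pytest.raises(ValueError, match="repeats per slice"):
            dprime_roi_route(d)

    def test_warns_when_absent_mean_far_from_zero(self, rng):
        from npwmf import dprime_roi_route

        n, m = 50, 2
        l1 = rng.normal(5, 1, n * m)  # background correction failed
        l2 = rng.normal(7, 1, n * m)
        d = _decisions(l1, l2, slices=np.tile(np.arange(m), n))
        with pytest.warns(UserWarning, match="background"):
            dprime_roi_route(d)


class TestAucEmpirical:
    def test_perfect_separation(self):
        assert auc_empirical(_decisions([0, 1], [2, 3])) == 1.0

    def test_interleaved_pairs(self):
        assert auc_empirical(_decisions([1, 3], [2, 4])) == 0.75

    def test_tie_convention_half(self):
        assert auc_empirical(_decisions([0.0], [0.0])) == 0.5

    def test_internal_noise_on_equal_singletons(self):
        a = auc_empirical(_decisions([0.0], [0.0]), InternalNoiseModel(sigma=1.5))
        assert a == 0.5

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            auc_empirical(_decisions([0], [1]), InternalNoiseModel(sigma=-1))

    @given(
        l1=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        l2=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_brute_force_pair_count(self, l1, l2):
        d = _decisions(l1, l2)
        brute = np.mean(
            [1.0 if b > a else 0.5 if b == a else 0.0 for a in l1 for b in l2]
        )
        assert auc_empirical(d) == pytest.approx(brute, abs=1e-12)

    def test_shift_scale_invariance(self, rng):
        l1, l2 = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
        a0 = auc_empirical(_decisions(l1, l2))
        assert auc_empirical(_decisions(l1 + 3, l2 + 3)) == a0
        assert auc_empirical(_decisions(2 * l1, 2 * l2)) == a0

    def test_sigma_continuity_to_heaviside(self, rng):
        l1, l2 = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        a0 = auc_empirical(_decisions(l1, l2))
        a_eps = auc_empirical(_decisions(l1, l2), InternalNoiseModel(sigma=1e-9))
        assert a_eps == pytest.approx(a0, abs=1e-6)

    @pytest.mark.parametrize("beta", [0.5, 3.0])
    def test_methods_2_and_3_agree_on_large_gaussian_sets(self, beta, rng):
        # pairwise AUC with beta-equivalent internal noise converges to the
        # Gaussian-response closed form Phi(d'/(sqrt(1+beta) sqrt 2))
        mu, n = 1.4, 6000
        l1 = rng.normal(0, 1, n)
        l2 = rng.normal(mu, 1, n)
        d = _decisions(l1, l2)
        a3 = auc_empirical(d, InternalNoiseModel(beta=beta))
        a2 = auc_from_dprime(dprime_spatial(d), beta)
        assert a3 == pytest.approx(a2, abs=0.01)


class TestInternalNoise:
    def test_beta_zero_gives_zero_sigma(self):
        assert internal_noise_sigma(_decisions([0, 1], [2, 3]), 0.0) == 0.0

    def test_unit_variances_give_sqrt_six(self):
        h = np.sqrt(0.5)
        d = _decisions([-h, h], [2 - h, 2 + h])  # sample variances exactly 1
        assert internal_noise_sigma(d, 3.0) == pytest.approx(np.sqrt(6.0))

    def test_sigma_scales_with_decision_scale(self, rng):
        l1, l2 = rng.normal(0, 1, 30), rng.normal(1, 2, 30)
        s0 = internal_noise_sigma(_decisions(l1, l2), 2.0)
        s5 = internal_noise_sigma(_decisions(5 * l1, 5 * l2), 2.0)
        assert s5 == pytest.approx(5 * s0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            internal_noise_sigma(_decisions([1, 1], [2, 2]), 3.0)
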