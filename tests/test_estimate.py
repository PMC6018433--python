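"""Unit-size estimators, binning, alpha fit, collapse, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sizechain as sc
from sizechain.errors import (
    DegenerateSampleError,
    DomainError,
    PeakNotFoundError,
)


class TestL0FromBirthSizes:
    def test_zero_variance_sample(self):
        est = sc.estimate_l0_birth([3.6] * 10)
        assert est.l0 == pytest.approx(3.6)
        assert est.spread == 0.0
        assert est.n_retained == 10

    def test_filter_removes_filamentous_tail(self):
        # 90% unit cells at 3.6 +/- 0.5, 10% two-unit cells: the Z-score
        # cut drops the tail and the retained mean lands on l0
        rng = np.random.default_rng(0)
        sample = np.concatenate(
            [rng.normal(3.6, 0.5, 900), rng.normal(7.2, 0.7, 100)]
        )
        est = sc.estimate_l0_birth(sample)
        assert abs(est.l0 - 3.6) < 0.1
        assert est.n_retained < 1000

    def test_recovery_from_generator(self, wildtype_population):
        births = wildtype_population.birth_lengths[:1000]
        est = sc.estimate_l0_birth(births)
        assert abs(est.l0 - 3.6) < 0.1

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSampleError):
            sc.estimate_l0_birth([3.6])
        with pytest.raises(DomainError):
            sc.estimate_l0_birth([3.6, -1.0])


class TestL0FromMotherDaughter:
    def test_identical_samples_give_zero(self):
        x = np.linspace(2, 5, 200)
        est = sc.estimate_l0_mother_daughter(x, x)
        assert est.l0_mode_diff == pytest.approx(0.0)
        assert est.l0_mean_diff == pytest.approx(0.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        mothers = rng.normal(7.2, 0.5, 500)
        daughters = rng.normal(3.6, 0.4, 500)
        base = sc.estimate_l0_mother_daughter(mothers, daughters)
        shifted = sc.estimate_l0_mother_daughter(mothers, daughters + 1.0)
        assert shifted.l0_mean_diff == pytest.approx(base.l0_mean_diff - 1.0)
        assert shifted.l0_mode_diff == pytest.approx(base.l0_mode_diff - 1.0, abs=0.2)

    def test_recovery_near_unit_size(self):
        rng = np.random.default_rng(2)
        mothers = rng.normal(2 * 3.6, 0.5, 2000)
        daughters = rng.normal(3.6, 0.5, 2000)
        est = sc.estimate_l0_mother_daughter(mothers, daughters)
        assert abs(est.l0_mode_diff - 3.6) < 0.3
        assert abs(est.l0_mean_diff - 3.6) < 0.1


class TestSpectralL0:
    def _profiles(self, lam, noise, n_cells, seed):
        cfg = sc.GeneratorConfig(lambda_profile=lam, profile_noise=noise, seed=seed)
        rng = np.random.default_rng(seed)
        lengths = rng.uniform(3 * lam, 7 * lam, n_cells)
        return sc.generate_profiles(cfg, lengths)

    def test_noiseless_recovery(self):
        spec = sc.estimate_l0_spectral(self._profiles(8.3, 0.0, 20, 4))
        grid = spec.q_grid[1]
        assert abs(spec.q_star - 1 / 8.3) < grid
        assert spec.l0 == pytest.approx(spec.lam / 2)
        assert abs(spec.l0 - 8.3 / 2) < grid * 8.3**2 / 2  # propagated one-grid-step error

    def test_noisy_cohort_recovery(self):
        spec = sc.estimate_l0_spectral(self._profiles(8.3, 0.5, 165, 5))
        assert abs(spec.q_star - 1 / 8.3) < spec.q_grid[1]

    def test_poor_medium_spacing(self):
        spec = sc.estimate_l0_spectral(self._profiles(7.8, 0.0, 20, 6))
        assert abs(spec.l0 - 3.9) < 0.2

    def test_constant_profile_has_no_peak(self):
        x = np.arange(0, 20, 0.065)
        with pytest.raises(PeakNotFoundError):
            sc.estimate_l0_spectral([(x, np.ones_like(x))])

    def test_too_short_profile(self):
        with pytest.raises(DomainError):
            sc.estimate_l0_spectral([(np.arange(5.0), np.arange(5.0))])


class TestBinning:
    def test_exact_multiples(self):
        h = sc.bin_lengths([3.6, 7.2, 10.8], 3.6)
        np.testing.assert_array_equal(h.counts, [1, 1, 1])

    def test_half_integer_edge_goes_up(self):
        h = sc.bin_lengths([5.4], 3.6)  # exactly 1.5 l0
        np.testing.assert_array_equal(h.counts, [0, 1])

    def test_short_lengths_map_to_state_one(self):
        h = sc.bin_lengths([0.3, 1.0], 3.6)
        np.testing.assert_array_equal(h.counts, [2])

    def test_wildtype_mass_in_first_three_states(self, wildtype_histograms):
        hp, _ = wildtype_histograms
        assert hp.probs[:3].sum() > 0.98

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        lengths=st.lists(
            st.floats(min_value=0.05, max_value=80, allow_nan=False), min_size=1, max_size=60
        ),
        l0=st.floats(min_value=0.5, max_value=10),
    )
    def test_mass_conservation_and_bin_rule(self, lengths, l0):
        h = sc.bin_lengths(lengths, l0)
        assert h.probs.sum() == pytest.approx(1.0)
        assert h.counts.sum() == len(lengths)
        for length in lengths:
            n = max(int(np.floor(length / l0 + 0.5)), 1)
            assert h.counts[n - 1] > 0

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(DomainError):
            sc.bin_lengths([3.6, 0.0], 3.6)


class TestBallparkAlpha:
    @pytest.mark.parametrize("l0,lb,expected", [(3.6, 4.0, 0.9), (3.6, 3.6, 1.0), (2.0, 4.0, 0.5)])
    def test_values(self, l0, lb, expected):
        assert sc.ballpark_alpha(l0, lb) == pytest.approx(expected)

    def test_model_violation_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert sc.ballpark_alpha(5.0, 4.0) == 1.0


class TestFitAlpha:
    def test_self_consistency_on_model_histograms(self):
        # histograms that ARE the theory at alpha = 0.87 must be fitted
        # by alpha = 0.87
        p_theo, pi_theo = sc.theory_histograms(0.87, "binomial", 20)
        hp = sc.BinnedHistogram(counts=p_theo * 1e6, probs=p_theo, l0=3.6)
        hpi = sc.BinnedHistogram(counts=pi_theo * 1e6, probs=pi_theo, l0=3.6)
        fit = sc.fit_alpha(hp, hpi, "binomial", 20)
        assert fit.alpha_hat == pytest.approx(0.87, abs=1e-3)

    def test_boundary_recovery_alpha_one(self):
        p_theo, pi_theo = sc.theory_histograms(1.0, "binomial", 20)
        hp = sc.BinnedHistogram(counts=p_theo, probs=p_theo, l0=3.6)
        hpi = sc.BinnedHistogram(counts=pi_theo, probs=pi_theo, l0=3.6)
        fit = sc.fit_alpha(hp, hpi, "binomial", 20)
        assert fit.alpha_hat > 0.995

    def test_recovery_from_synthetic_population(self, wildtype_population, wildtype_histograms):
        hp, hpi = wildtype_histograms
        fit = sc.fit_alpha(hp, hpi, "binomial", 20)
        boots = sc.bootstrap_alpha(
            wildtype_population.snapshot_lengths,
            wildtype_population.birth_lengths,
            3.6,
            "binomial",
            20,
            n_boot=200,
            seed=1,
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= 0.87 <= hi
        assert abs(fit.alpha_hat - 0.87) < 0.03

    def test_patterns_agree_when_long_cells_are_rare(self, wildtype_histograms):
        # with alpha near one, states > 3 are rare and the kernels are
        # nearly indistinguishable: fitted alphas differ by little
        hp, hpi = wildtype_histograms
        fits = {pat: sc.fit_alpha(hp, hpi, pat, 20).alpha_hat for pat in sc.PATTERNS}
        spread = max(fits.values()) - min(fits.values())
        assert spread < 0.02, fits

    def test_error_curve_is_diagnostic(self, wildtype_histograms):
        hp, hpi = wildtype_histograms
        fit = sc.fit_alpha(hp, hpi, "binomial", 20)
        i_best = int(np.argmin(fit.errors))
        assert abs(fit.alphas[i_best] - fit.alpha_hat) < 0.011
        assert fit.errors[0] > fit.error  # far-off alphas fit worse


class TestCollapse:
    def test_collapse_identity(self, wildtype_population):
        lengths = wildtype_population.snapshot_lengths
        ref = sc.bin_lengths(lengths, 3.6)
        res = sc.collapse_l0(ref, lengths)
        assert res.l0_other == pytest.approx(3.6)
        assert res.collapse_error == pytest.approx(0.0, abs=1e-15)

    def test_scale_equivariance(self, wildtype_population):
        lengths = wildtype_population.snapshot_lengths
        ref = sc.bin_lengths(lengths, 3.6)
        res = sc.collapse_l0(ref, lengths * (3.5 / 3.6))
        assert res.l0_other == pytest.approx(3.5, abs=0.05)
        assert res.collapse_error < 1e-3

    def test_different_alpha_is_a_negative_control(self, wildtype_population):
        ref = sc.bin_lengths(wildtype_population.snapshot_lengths, 3.6)
        other = sc.generate_population(
            sc.GeneratorConfig(alpha=0.5, n_cells=2000, seed=9)
        ).snapshot_lengths
        res_same = sc.collapse_l0(ref, wildtype_population.snapshot_lengths * (3.5 / 3.6))
        res_diff = sc.collapse_l0(ref, other)
        assert res_diff.collapse_error > 10 * res_same.collapse_error


class TestSensitivity:
    def test_zero_delta_gives_identical_fits(self, wildtype_population):
        res = sc.sensitivity_analysis(
            wildtype_population.snapshot_lengths[:2000],
            wildtype_population.birth_lengths[:1000],
            "binomial",
            20,
            3.6,
            0.0,
        )
        assert res.table["alpha_hat"].nunique() == 1

    def test_output_less_variable_than_input(self, wildtype_population):
        res = sc.sensitivity_analysis(
            wildtype_population.snapshot_lengths,
            wildtype_population.birth_lengths,
            "binomial",
            20,
            3.6,
            0.5,
        )
        assert res.robust
        assert res.cv_alpha < res.cv_l0

    def test_excessive_delta_rejected(self, wildtype_population):
        with pytest.raises(DomainError):
            sc.sensitivity_analysis(
                wildtype_population.snapshot_lengths,
                wildtype_population.birth_lengths,
                "binomial",
                20,
                3.6,
                3.6,
            )
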