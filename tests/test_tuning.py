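"""Single-unit tuning statistics, SP/MP classification, MI-Pr models."""

import numpy as np
import pytest
from scipy.special import i0, i1

import headcode as hc
from headcode.session import Session
from headcode.tuning import (
    TuningCurve,
    classify_sp_mp,
    fwhm,
    mean_vector_length,
    mutual_information_hd,
    partial_corr,
    piecewise_mi_pr_fit,
    pr_ahv,
    shuffle_significance,
    tuning_curve,
)

TWO_PI = 2 * np.pi


def _curve(rates, occupancy=None, edges=None):
    """Hand-built HD tuning curve."""
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    if edges is None:
        edges = np.linspace(0, TWO_PI, n + 1)
    if occupancy is None:
        occupancy = np.full(n, 1.0 / n)
    return TuningCurve(
        kind="hd", bin_edges=edges, mean_rate=rates,
        occupancy_p=np.asarray(occupancy, dtype=float),
    )


def _session_from(theta, rates, ahv=None, dt=0.025):
    rates = np.atleast_2d(rates)
    if ahv is None:
        ahv = np.zeros_like(theta)
    return Session(hd=theta, ahv=ahv, rates=rates, dt=dt)


class TestTuningCurve:
    def test_constant_rate_gives_flat_curve(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, TWO_PI, 5000)
        sess = _session_from(theta, np.full(5000, 3.0))
        tc = tuning_curve(sess, 0, "hd", n_permutations=0)
        np.testing.assert_allclose(tc.mean_rate[tc.occupied], 3.0)
        assert tc.n_bins == 50
        assert tc.occupancy_p.sum() == pytest.approx(1.0)

    def test_indicator_rate_gives_indicator_curve(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, TWO_PI, 20000)
        k = 13
        in_bin = (theta >= k * TWO_PI / 50) & (theta < (k + 1) * TWO_PI / 50)
        sess = _session_from(theta, in_bin.astype(float))
        tc = tuning_curve(sess, 0, "hd", n_permutations=0)
        assert tc.mean_rate[k] == pytest.approx(1.0)
        others = np.delete(tc.mean_rate, k)
        np.testing.assert_allclose(others[np.isfinite(others)], 0.0)

    def test_permutation_sd_shrinks_with_signal_to_noise(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, TWO_PI, 20000)
        clean = np.cos(theta) + 1.5
        noisy = clean + rng.normal(0, 2.0, theta.shape)
        sess = _session_from(theta, np.vstack([clean, noisy]))
        sd_clean = tuning_curve(sess, 0, "hd", seed=0).sd
        sd_noisy = tuning_curve(sess, 1, "hd", seed=0).sd
        assert np.nanmean(sd_noisy) > 3 * np.nanmean(sd_clean)

    def test_ahv_curve_uses_fifth_rad_bins(self):
        rng = np.random.default_rng(3)
        ahv = rng.normal(0, 2.0, 10000)
        sess = _session_from(
            np.zeros(10000), np.abs(ahv), ahv=ahv
        )
        tc = tuning_curve(sess, 0, "ahv", n_permutations=0)
        widths = np.diff(tc.bin_edges)
        np.testing.assert_allclose(widths, 0.2, atol=1e-9)


class TestMutualInformation:
    def test_flat_curve_carries_zero_information(self):
        assert mutual_information_hd(_curve(np.full(50, 2.0)))[0] == 0.0

    def test_two_bin_worked_example(self):
        # p = (1/2, 1/2), rates (2, 0): fr = 1, MI = 0.5*2*log2(2) = 1 bit/s
        bits_s, bits_spk = mutual_information_hd(_curve([2.0, 0.0]))
        assert bits_s == pytest.approx(1.0)
        assert bits_spk == pytest.approx(1.0)

    def test_rate_doubling_doubles_bits_per_second_only(self):
        rng = np.random.default_rng(4)
        rates = rng.uniform(0.5, 5.0, 50)
        mi1, spk1 = mutual_information_hd(_curve(rates))
        mi2, spk2 = mutual_information_hd(_curve(2 * rates))
        assert mi2 == pytest.approx(2 * mi1)
        assert spk2 == pytest.approx(spk1)

    def test_nonnegative_and_binlabel_invariant(self):
        rng = np.random.default_rng(5)
        rates = rng.uniform(0, 3.0, 50)
        occ = rng.dirichlet(np.ones(50))
        mi, _ = mutual_information_hd(_curve(rates, occ))
        assert mi >= 0
        perm = rng.permutation(50)
        mi_p, _ = mutual_information_hd(_curve(rates[perm], occ[perm]))
        assert mi_p == pytest.approx(mi)

    def test_silent_unit_defined_as_zero(self):
        assert mutual_information_hd(_curve(np.zeros(50))) == (0.0, 0.0)


class TestMeanVectorLength:
    def test_uniform_curve_is_zero(self):
        assert mean_vector_length(_curve(np.ones(50))) == pytest.approx(0.0)

    def test_single_bin_is_one(self):
        rates = np.zeros(50)
        rates[7] = 4.2
        assert mean_vector_length(_curve(rates)) == pytest.approx(1.0)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0, 8.0])
    def test_von_mises_matches_bessel_ratio(self, kappa):
        centers = (np.arange(50) + 0.5) * TWO_PI / 50
        rates = np.exp(kappa * np.cos(centers - 1.3))
        expected = i1(kappa) / i0(kappa)
        assert mean_vector_length(_curve(rates)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_invariant_to_rate_scaling(self):
        rng = np.random.default_rng(6)
        rates = rng.uniform(0, 2, 50)
        assert mean_vector_length(_curve(rates)) == pytest.approx(
            mean_vector_length(_curve(7.7 * rates))
        )

    def test_all_zero_curve_undefined(self):
        assert np.isnan(mean_vector_length(_curve(np.zeros(50))))


class TestPrAHV:
    def _trajectory(self, n=20000, seed=0):
        a = hc.simulate_ahv(n, sigma=1.2, momentum=0.8, dt=0.025, seed=seed)
        hd = hc.integrate_heading(a, theta0=0.3)
        return hd.theta, a.values

    def test_noise_unit_uncorrelated(self):
        theta, ahv = self._trajectory()
        rng = np.random.default_rng(7)
        sess = _session_from(theta, rng.normal(5, 1, len(theta)), ahv=ahv)
        assert pr_ahv(sess, 0) < 0.05

    def test_rate_equal_to_ahv_gives_unity(self):
        theta, ahv = self._trajectory(seed=1)
        sess = _session_from(theta, ahv.copy(), ahv=ahv)
        assert pr_ahv(sess, 0) == pytest.approx(1.0, abs=1e-6)

    def test_hd_mediated_component_partialled_out(self):
        # rate an exact linear function of hd, independent of ahv given hd
        theta, ahv = self._trajectory(seed=2)
        sess = _session_from(theta, 2.0 * theta + 1.0, ahv=ahv)
        assert pr_ahv(sess, 0) < 0.05

    def test_partial_corr_formula(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=5000)
        x = z + rng.normal(size=5000)
        y = -z + rng.normal(size=5000)
        # conditional on z, x and y are independent
        assert abs(partial_corr(x, y, z)) < 0.05
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.3

    def test_min_sample_guard(self):
        theta, ahv = self._trajectory(n=150)
        sess = _session_from(theta, np.abs(ahv), ahv=ahv)
        assert np.isnan(pr_ahv(sess, 0, min_samples=100))


class TestShuffleSignificance:
    def _session(self, tuned: bool, seed=0, n=24000):
        rng = np.random.default_rng(seed)
        a = hc.simulate_ahv(n, sigma=1.2, momentum=0.8, dt=0.025, seed=seed)
        hd = hc.integrate_heading(a, theta0=1.0)
        if tuned:
            rates = 5 * np.exp(4 * (np.cos(hd.theta - 2.0) - 1))
        else:
            rates = rng.normal(5, 1, n)
        return _session_from(hd.theta, rates, ahv=a.values)

    def test_strongly_tuned_unit_significant(self):
        res = shuffle_significance(
            self._session(True), 0, "mi", n_shuffles=200, seed=0
        )
        assert res.significant
        assert res.observed > 2 * res.threshold

    def test_untuned_unit_not_significant(self):
        res = shuffle_significance(
            self._session(False), 0, "mi", n_shuffles=200, seed=1
        )
        assert not res.significant

    def test_short_session_rejected(self):
        sess = _session_from(np.zeros(100), np.ones(100))
        with pytest.raises(ValueError, match="too short"):
            shuffle_significance(sess, 0, "mi")


class TestClassification:
    def _vm(self, kappa, mu=2.0):
        centers = (np.arange(50) + 0.5) * TWO_PI / 50
        return _curve(np.exp(kappa * (np.cos(centers - mu) - 1)))

    @pytest.mark.parametrize("alpha", [0.05, 0.10, 0.20])
    def test_clean_von_mises_is_sp_at_all_alphas(self, alpha):
        assert classify_sp_mp(self._vm(4.0), alpha=alpha) == "SP"

    def test_two_opposite_peaks_are_mp(self):
        centers = (np.arange(50) + 0.5) * TWO_PI / 50
        rates = np.exp(6 * (np.cos(centers - 1.0) - 1)) + np.exp(
            6 * (np.cos(centers - 1.0 - np.pi) - 1)
        )
        assert classify_sp_mp(_curve(rates)) == "MP"

    def test_flat_curve_untuned(self):
        assert classify_sp_mp(_curve(np.ones(50))) == "untuned"

    def test_monotone_in_alpha(self):
        # SP at a stricter alpha implies SP at a looser one
        rng = np.random.default_rng(9)
        centers = (np.arange(50) + 0.5) * TWO_PI / 50
        for trial in range(30):
            base = np.exp(3 * (np.cos(centers - rng.uniform(0, TWO_PI)) - 1))
            curve = _curve(base + rng.uniform(0, 0.25, 50))
            labels = [
                classify_sp_mp(curve, alpha=a) for a in (0.05, 0.10, 0.20)
            ]
            for strict, loose in zip(labels, labels[1:]):
                assert not (strict == "SP" and loose == "MP")


class TestFWHM:
    def test_rectangular_bump_width(self):
        rates = np.zeros(50)
        rates[10:20] = 1.0  # 10 bins wide
        w, n = fwhm(_curve(rates), mode="sp")
        assert n == 1
        assert w == pytest.approx(10 * TWO_PI / 50, abs=TWO_PI / 50)

    def test_triangular_peak_half_base(self):
        # symmetric triangle of half-base b: half-max crossings at b/2 each side
        rates = np.zeros(50)
        half_base = 8
        for k in range(-half_base, half_base + 1):
            rates[(25 + k) % 50] = 1.0 - abs(k) / half_base
        w, _ = fwhm(_curve(rates), mode="sp")
        assert w == pytest.approx(half_base * TWO_PI / 50, rel=0.02)

    def test_mp_mean_over_qualified_peaks(self):
        centers = (np.arange(50) + 0.5) * TWO_PI / 50
        k1, k2 = 40.0, 10.0  # two peaks of different widths
        rates = np.exp(k1 * (np.cos(centers - 1.0) - 1)) + np.exp(
            k2 * (np.cos(centers - 4.0) - 1)
        )
        w_mp, n = fwhm(_curve(rates), mode="mp", min_separation_bins=8)
        assert n == 2
        from headcode.synth import vonmises_kappa_to_fwhm

        expected = 0.5 * (
            vonmises_kappa_to_fwhm(k1) + vonmises_kappa_to_fwhm(k2)
        )
        assert w_mp == pytest.approx(expected, rel=0.15)

    def test_sp_fwhm_decreases_with_kappa(self):
        centers = (np.arange(50) + 0.5) * TWO_PI / 50
        widths = []
        for kappa in (1.0, 2.0, 4.0, 8.0):
            rates = np.exp(kappa * (np.cos(centers - 3.0) - 1))
            widths.append(fwhm(_curve(rates), mode="sp")[0])
        assert np.all(np.diff(widths) < 0)

    def test_peak_wrapping_across_zero(self):
        centers = (np.arange(50) + 0.5) * TWO_PI / 50
        rates = np.exp(4 * (np.cos(centers - 0.05) - 1))  # peak at wrap point
        w, _ = fwhm(_curve(rates), mode="sp")
        from headcode.synth import vonmises_kappa_to_fwhm

        assert w == pytest.approx(vonmises_kappa_to_fwhm(4.0), rel=0.1)


class TestPiecewiseFit:
    def test_recovers_two_line_oracle(self):
        rng = np.random.default_rng(10)
        x = np.sort(rng.uniform(0, 0.1, 120))
        brk = 0.025
        y = np.where(
            x < brk, 0.5 - 16.9 * (x - brk), 0.5 - 0.28 * (x - brk)
        )
        fit = piecewise_mi_pr_fit(x, y)
        assert fit["break"] == pytest.approx(brk, abs=0.005)
        assert fit["slope_lo"] == pytest.approx(-16.9, rel=0.02)
        assert fit["slope_hi"] == pytest.approx(-0.28, rel=0.05)
        assert fit["r2"] > 0.999

    def test_single_line_data_nested_model(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 80)
        y = 2.0 - 0.5 * x + rng.normal(0, 0.01, 80)
        fit = piecewise_mi_pr_fit(x, y)
        assert fit["r2"] >= fit["r2_linear"] - 1e-9
        assert fit["r2"] == pytest.approx(fit["r2_linear"], abs=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            piecewise_mi_pr_fit(np.arange(5), np.arange(5))
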