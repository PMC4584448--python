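"""Windowing, sample budget, VAR estimation, validation and dDTF measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latnets import spectral_causality as sc


def _random_stable_var(k, p, rng, radius=0.9):
    """Random VAR with companion spectral radius scaled below ``radius``."""
    coeffs = rng.standard_normal((p, k, k)) * 0.4
    m = sc.VARModel(coeffs=coeffs, sigma=np.eye(k), n_obs=1)
    rho = m.spectral_radius()
    if rho >= radius:
        coeffs *= (radius / rho) ** np.arange(1, p + 1)[:, None, None]
        m = sc.VARModel(coeffs=coeffs, sigma=np.eye(k), n_obs=1)
    return m


class TestSegment:
    def test_window_count_formula(self):
        g = sc.segment(2000, 250.0, 250.0, 50.0)
        # 250 ms -> 63 samples, 50 ms -> 13 (round half-up); floor((2000-63)/13)+1
        assert (g.window_samples, g.step_samples, g.n_windows) == (63, 13, 150)

    def test_window_equal_to_trial_is_single_window(self):
        g = sc.segment(500, 250.0, 2000.0, 50.0)
        assert g.n_windows == 1

    def test_step_larger_than_slack_is_single_window(self):
        g = sc.segment(70, 250.0, 250.0, 2000.0)
        assert g.n_windows == 1

    def test_window_longer_than_trial_rejected(self):
        with pytest.raises(ValueError):
            sc.segment(50, 250.0, 250.0, 50.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(80, 5000),
        w_ms=st.floats(20, 1000),
        s_ms=st.floats(4, 1000),
    )
    def test_count_invariant_holds_for_any_grid(self, n, w_ms, s_ms):
        try:
            g = sc.segment(n, 250.0, w_ms, s_ms)
        except ValueError:
            return  # window longer than trial: rejected by contract
        assert g.n_windows == (n - g.window_samples) // g.step_samples + 1
        assert g.n_windows >= 1
        # every window fits inside the trial
        assert g.starts()[-1] + g.window_samples <= n

    def test_centers_are_window_midpoints(self):
        g = sc.segment(2000, 250.0, 250.0, 50.0)
        np.testing.assert_allclose(g.centers_s()[0], 63 / 2 / 250.0)


class TestSampleBudget:
    def test_study_scale_numbers_pass_adopted_reading(self):
        r = sc.check_sample_budget(w=63, k=33, p=9, n=122)
        assert r["passes"]
        assert abs(r["adopted_min_w"] - 10 * 33 * 9 / 122) < 1e-9
        assert r["readings_disagree"]  # literal form would demand w >= 803

    def test_single_trial_fails(self):
        assert not sc.check_sample_budget(w=63, k=33, p=9, n=1)["passes"]

    def test_scalar_channel_readings_coincide(self):
        r = sc.check_sample_budget(w=63, k=1, p=9, n=10)
        assert r["adopted_min_w"] == r["literal_min_w"]
        assert not r["readings_disagree"]


class TestVARFit:
    def test_planted_var2_recovered(self, rng):
        m_true = _random_stable_var(3, 2, rng, radius=0.7)
        data = sc.simulate_var(m_true, n_trials=200, n_samples=80, seed=1)
        m = sc.fit_var_multitrial(data, 2)
        assert np.abs(m.coeffs - m_true.coeffs).max() < 0.05

    def test_uncoupled_var_off_diagonals_near_zero(self, rng):
        coeffs = np.zeros((1, 3, 3))
        coeffs[0] = np.diag([0.5, 0.4, 0.3])
        m_true = sc.VARModel(coeffs=coeffs, sigma=np.eye(3), n_obs=1)
        data = sc.simulate_var(m_true, 200, 80, seed=2)
        m = sc.fit_var_multitrial(data, 1)
        off = m.coeffs[0][~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_window_stats_match_direct_fit(self, rng):
        data = rng.standard_normal((30, 3, 100))
        grid = sc.segment(100, 100.0, 1000.0, 1000.0)  # one full-trial window
        stats = sc.WindowEnsembleStats(data, grid, p=2)
        a, sigma = stats.fit()
        m = sc.fit_var_multitrial(data, 2)
        np.testing.assert_allclose(
            a[0].reshape(2, 3, 3).transpose(0, 2, 1), m.coeffs, atol=1e-10
        )
        np.testing.assert_allclose(sigma[0], m.sigma, atol=1e-10)

    def test_aic_recovers_planted_order(self):
        coeffs = np.zeros((3, 2, 2))
        coeffs[0] = [[0.2, 0.1], [0.0, 0.2]]
        coeffs[1] = [[-0.3, 0.0], [0.1, -0.2]]
        coeffs[2] = [[0.3, 0.2], [-0.2, 0.35]]  # strong lag-3 term
        m_true = sc.VARModel(coeffs=coeffs, sigma=np.eye(2), n_obs=1)
        data = sc.simulate_var(m_true, 300, 100, seed=3)
        p, curve = sc.select_order_aic(data, p_max=6)
        assert p == 3
        assert np.all(np.isfinite(curve))

    def test_aic_white_noise_selects_minimum_order(self, rng):
        data = rng.standard_normal((200, 3, 80))
        p, _ = sc.select_order_aic(data, p_max=5)
        assert p == 1


class TestValidation:
    def test_self_simulation_passes_whiteness_and_consistency(self, rng):
        m_true = _random_stable_var(3, 2, rng, radius=0.7)
        data = sc.simulate_var(m_true, 100, 120, seed=4)
        m = sc.fit_var_multitrial(data, 2)
        v = sc.validate_var(m, data, seed=0)
        assert v["whiteness_pass"]
        assert v["consistency"] >= 95.0
        assert v["stationarity_pass"]

    def test_random_walk_fails_kpss(self, rng):
        steps = rng.standard_normal((4, 2, 400)).cumsum(axis=2)
        m = sc.fit_var_multitrial(steps, 1)
        v = sc.validate_var(m, steps, seed=0)
        assert not all(v["kpss_pass"])


class TestSpectralTransfer:
    def test_zero_coefficients_give_identity_transfer(self):
        m = sc.VARModel(coeffs=np.zeros((2, 3, 3)), sigma=np.eye(3), n_obs=1)
        h = sc.spectral_transfer(m, np.array([1.0, 10.0, 40.0]), 250.0)
        for hf in h:
            np.testing.assert_allclose(hf, np.eye(3), atol=1e-12)

    def test_ar2_resonator_peak_at_resonance(self):
        from latnets.synthetic_data import _resonator_ar2

        f0 = 20.0
        a1, a2 = _resonator_ar2(f0, 4.0, 250.0)
        coeffs = np.zeros((2, 1, 1))
        coeffs[0, 0, 0] = a1
        coeffs[1, 0, 0] = a2
        m = sc.VARModel(coeffs=coeffs, sigma=np.eye(1), n_obs=1)
        freqs = np.linspace(2, 120, 237)  # 0.5 Hz grid
        h = sc.spectral_transfer(m, freqs, 250.0)
        peak = freqs[np.argmax(np.abs(h[:, 0, 0]))]
        assert abs(peak - f0) <= 0.5

    def test_numeric_transfer_matches_symbolic_2x2_var1(self):
        # closed-form inverse of I - A e^{-iωΔ} for a hand-written 2x2 VAR(1)
        a = np.array([[0.5, 0.2], [-0.1, 0.3]])
        m = sc.VARModel(coeffs=a[None], sigma=np.eye(2), n_obs=1)
        freqs = np.array([3.0, 17.0, 41.0])
        h = sc.spectral_transfer(m, freqs, 250.0)
        for fi, f in enumerate(freqs):
            z = np.exp(-2j * np.pi * f / 250.0)
            af = np.eye(2) - a * z
            det = af[0, 0] * af[1, 1] - af[0, 1] * af[1, 0]
            href = np.array([[af[1, 1], -af[0, 1]], [-af[1, 0], af[0, 0]]]) / det
            np.testing.assert_allclose(h[fi], href, atol=1e-10)


class TestDdtf:
    def test_uncoupled_var_has_zero_cross_ddtf(self):
        coeffs = np.zeros((1, 3, 3))
        coeffs[0] = np.diag([0.5, 0.4, 0.3])
        m = sc.VARModel(coeffs=coeffs, sigma=np.eye(3), n_obs=1)
        d = sc.ddtf(m, sc.default_frequency_grid(), 250.0)
        off = ~np.eye(3, dtype=bool)
        assert np.abs(d["ddtf"][:, off]).max() < 1e-10

    def test_ffdtf_normalization_sums_to_one_per_sink(self, rng):
        for trial in range(5):
            m = _random_stable_var(4, 2, rng)
            h = sc._transfer_batch(m.coeffs[None], sc.default_frequency_grid(), 250.0)
            meas = sc._measures_from_transfer(h, m.sigma[None], zero_diag=False)
            sums = (meas["ffdtf"][0] ** 2).sum(axis=(0, 2))
            np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_values_bounded_and_ddtf_below_ffdtf(self, rng):
        m = _random_stable_var(4, 3, rng)
        d = sc.ddtf(m, sc.default_frequency_grid(), 250.0)
        for name in ("dtf", "ffdtf", "pcoh", "ddtf"):
            assert d[name].min() >= 0.0
            assert d[name].max() <= 1.0 + 1e-9
        assert np.all(d["ddtf"] <= d["ffdtf"] + 1e-12)

    def test_estimated_ddtf_close_to_true_coefficient_ddtf(self, rng):
        """Estimator agreement with the analytic map of the generating VAR."""
        m_true = _random_stable_var(3, 2, rng, radius=0.8)
        data = sc.simulate_var(m_true, 150, 100, seed=6)
        m_est = sc.fit_var_multitrial(data, 2)
        freqs = sc.default_frequency_grid(10, 4, 45)
        d_true = sc.ddtf(m_true, freqs, 100.0)["ddtf"]
        d_est = sc.ddtf(m_est, freqs, 100.0)["ddtf"]
        strong = d_true > 0.2
        if strong.any():
            rel = np.abs(d_est[strong] - d_true[strong]) / d_true[strong]
            assert np.median(rel) < 0.15
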