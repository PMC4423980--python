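"""Estimators: log-log slope fitting, exponential fits, release statistics."""

import numpy as np
import pytest

from calyxsim import fit_loglog_slope, fit_single_exponential, release_statistics
from calyxsim.engine import ReleaseBatch


class TestSlopeEstimator:
    def test_exact_cubic_power_law(self):
        q = np.geomspace(0.5, 5, 9)
        p = 1e-3 * q**3
        fit = fit_loglog_slope(q, p)
        assert fit.slope == pytest.approx(3.000, abs=1e-9)

    def test_linear_with_saturated_outlier_flagged(self):
        q = np.geomspace(0.1, 10, 8)
        p = 0.08 * q
        p[-1] = 0.35  # saturated: far below the linear extrapolation 0.8
        fit = fit_loglog_slope(q, p)
        assert fit.n_excluded_saturated >= 1
        assert not fit.included[-1]
        assert fit.slope == pytest.approx(1.000, abs=1e-9)

    def test_recovers_known_exponents_from_binomial_noise(self):
        """Noisy power laws with exponents 1.0 / 3.0 / 3.5 are recovered
        within 0.2 over replicate draws."""
        rng = np.random.default_rng(0)
        q = np.geomspace(0.6, 2.0, 9)
        for exponent in (1.0, 3.0, 3.5):
            slopes = []
            for _ in range(30):
                p_true = 0.1 * (q / q[-1]) ** exponent
                n = 4000
                p_obs = rng.binomial(n, p_true) / n
                fit = fit_loglog_slope(q, p_obs, n_trials=n)
                slopes.append(fit.slope)
            assert np.mean(slopes) == pytest.approx(exponent, abs=0.2)

    def test_scale_invariance(self):
        """Rescaling Q (units) or p (per-site vs per-AZ) shifts the line only."""
        q = np.geomspace(1, 10, 7)
        rng = np.random.default_rng(1)
        p = 1e-3 * q**2.5 * np.exp(rng.normal(0, 0.05, len(q)))
        s1 = fit_loglog_slope(q, p).slope
        s2 = fit_loglog_slope(q * 321.0, p * 6.0).slope
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_too_few_points_fails(self):
        with pytest.raises(ValueError):
            fit_loglog_slope([1.0, 2.0], [0.1, 0.2])


class TestExponentialFit:
    def test_exact_synthetic_trace(self):
        t = np.linspace(0, 10, 200)
        y = 1 - np.exp(-t / 2.0)
        fit = fit_single_exponential(t, y)
        assert fit.tau_ms == pytest.approx(2.000, abs=1e-6)
        assert not fit.double_exp_preferred

    def test_amplitude_invariance(self):
        t = np.linspace(0, 10, 200)
        fit = fit_single_exponential(t, 7.3 * (1 - np.exp(-t / 2.0)))
        assert fit.tau_ms == pytest.approx(2.000, abs=1e-6)
        assert fit.amplitude == pytest.approx(7.3, rel=1e-6)

    def test_two_component_trace_flags_double_exponential(self):
        t = np.linspace(0, 60, 600)
        y = 0.6 * (1 - np.exp(-t / 1.0)) + 0.4 * (1 - np.exp(-t / 20.0))
        fit = fit_single_exponential(t, y)
        assert fit.double_exp_preferred
        taus = sorted(fit.tau_double_ms)
        assert taus[0] == pytest.approx(1.0, rel=0.1)
        assert taus[1] == pytest.approx(20.0, rel=0.1)

    def test_non_monotone_trace_rejected(self):
        t = np.linspace(0, 5, 50)
        y = np.sin(t)
        with pytest.raises(ValueError, match="monotone"):
            fit_single_exponential(t, y)


def _batch_from_pves(p_ves, n_trials, seed=0):
    """Construct a synthetic trial batch with independent per-site fusion."""
    rng = np.random.default_rng(seed)
    nv = len(p_ves)
    fused = rng.random((n_trials, nv)) < np.asarray(p_ves)
    times = [np.sort(rng.uniform(0.5, 3.0, fused[:, v].sum())) for v in range(nv)]
    return ReleaseBatch(
        n_trials=n_trials,
        n_vesicles=nv,
        fusion_counts=fused.sum(0).astype(float),
        fusion_times=times,
        released_per_trial=fused.sum(1),
        injected_per_trial=np.full(n_trials, 1500),
        stop_times_ms=np.full(n_trials, 3.5),
    )


class TestReleaseStatistics:
    def test_all_trials_fuse_everything(self):
        batch = _batch_from_pves([1.0, 1.0, 1.0], 50)
        stats = release_statistics(batch)
        assert np.all(stats.p_ves == 1.0)
        assert stats.failure_fraction == 0.0

    def test_cv_matches_hand_calculation(self):
        p = np.array([0.1, 0.2, 0.4, 0.05])
        batch = _batch_from_pves(p, 100000, seed=3)
        stats = release_statistics(batch)
        hand_cv = np.std(stats.p_ves) / np.mean(stats.p_ves)
        assert stats.cv == pytest.approx(hand_cv)
        # and the realized p_ves estimates the generating probabilities
        np.testing.assert_allclose(stats.p_ves, p, atol=0.01)

    def test_histogram_masses_and_failures(self):
        batch = _batch_from_pves([0.3, 0.3], 5000, seed=4)
        stats = release_statistics(batch)
        assert stats.released_count_hist.sum() == pytest.approx(1.0)
        assert stats.failure_fraction == pytest.approx(0.49, abs=0.03)
        # rate histogram integrates to the mean number released per trial
        integral = stats.release_rate_per_ms.sum() * np.diff(
            stats.release_rate_t_ms[:2]
        )[0]
        assert integral == pytest.approx(batch.released_per_trial.mean(), rel=1e-6)
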