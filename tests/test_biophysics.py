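"""AP waveforms, two-state gating, GHK current, Poisson ion entry."""

import numpy as np
import pytest

from calyxsim import (
    APParams,
    ChannelCurrentParams,
    GatingParams,
    ap_waveform,
    calibrate_gating,
    open_probability,
    sample_gating,
    sample_ion_injections,
    single_channel_current,
    step_waveform,
)
from calyxsim.biophysics import IONS_PER_PA_MS, expected_charge_pC


class TestAPWaveform:
    def test_standard_half_width(self, standard_ap):
        assert standard_ap.measured_half_width_ms() == pytest.approx(0.49, abs=0.002)

    @pytest.mark.parametrize("scale", [0.6, 1.4, 2.0])
    def test_half_width_scales_linearly(self, scale):
        ap = ap_waveform(width_scale=scale)
        assert ap.measured_half_width_ms() == pytest.approx(0.49 * scale, abs=0.003)

    def test_peak_amplitude_invariant_across_scales(self):
        peaks = [ap_waveform(width_scale=s).v_mV.max() for s in (0.6, 1.0, 2.0)]
        np.testing.assert_allclose(peaks, peaks[0], atol=0.2)

    def test_starts_at_rest(self, standard_ap):
        assert standard_ap.v_mV[0] == standard_ap.params.resting_potential_mV

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ap_waveform(width_scale=0)
        with pytest.raises(ValueError):
            ap_waveform(dt_ms=-1)


class TestGating:
    def test_steady_state_closed_form(self):
        g = GatingParams()
        v = 10.0
        a, b = float(g.alpha(v)), float(g.beta(v))
        wave = step_waveform(v_step_mV=v, duration_ms=30.0, holding_mV=v)
        p = open_probability(wave, g)
        assert p[-1] == pytest.approx(a / (a + b), abs=1e-6)

    def test_far_below_threshold_stays_closed(self):
        g = GatingParams()
        wave = step_waveform(v_step_mV=-90, duration_ms=5.0, holding_mV=-90)
        assert open_probability(wave, g).max() < 1e-2

    def test_calibrated_defaults_reproduce_calibration(self, standard_ap):
        fresh = calibrate_gating()
        shipped = GatingParams()
        assert fresh.alpha0_per_ms == pytest.approx(shipped.alpha0_per_ms, rel=1e-4)
        assert open_probability(standard_ap, shipped).max() == pytest.approx(0.6, abs=0.005)

    def test_no_openings_when_alpha_is_negligible(self, standard_ap):
        g = GatingParams(alpha0_per_ms=1e-12)
        traces = sample_gating(standard_ap, g, 200, seed=1)
        assert all(len(t.open_times_ms) == 0 for t in traces)

    def test_ensemble_open_fraction_matches_ode(self, standard_ap):
        """Stochastic sampler vs deterministic ODE: sup-norm < 2% of peak."""
        g = GatingParams()
        n = 20_000
        traces = sample_gating(standard_ap, g, n, seed=3)
        frac = np.zeros(len(standard_ap.t_ms))
        for tr in traces:
            frac += tr.open_mask(standard_ap.t_ms)
        frac /= n
        p = open_probability(standard_ap, g)
        assert np.max(np.abs(frac - p)) < 0.02

    def test_openings_on_upstroke_closings_on_repolarisation(self, standard_ap):
        g = GatingParams()
        traces = sample_gating(standard_ap, g, 3000, seed=5)
        opens = np.concatenate([t.open_times_ms for t in traces])
        closes = np.concatenate(
            [t.close_times_ms[t.close_times_ms < standard_ap.t_ms[-1]] for t in traces]
        )
        t_peak = standard_ap.t_ms[np.argmax(standard_ap.v_mV)]
        assert np.median(opens) < t_peak + 0.15
        assert np.median(closes) > np.median(opens)


class TestCurrent:
    def test_anchor_at_zero_mV(self):
        assert single_channel_current(0.0) == pytest.approx(0.12)

    def test_zero_at_reversal(self):
        assert single_channel_current(45.0) == pytest.approx(0.0, abs=1e-12)

    def test_larger_magnitude_at_hyperpolarised_potentials(self):
        assert single_channel_current(-70.0) > 0.12

    def test_monotone_decreasing_toward_reversal(self):
        v = np.linspace(-100, 45, 200)
        i = single_channel_current(v)
        assert np.all(np.diff(i) <= 1e-12)

    def test_ohmic_mode_anchors_match(self):
        p = ChannelCurrentParams(mode="ohmic")
        assert single_channel_current(0.0, p) == pytest.approx(0.12)
        assert single_channel_current(45.0, p) == pytest.approx(0.0)


class TestIonInjection:
    def test_open_channel_at_0mV_mean_count(self):
        """0.12 pA for 1 ms -> ~375 divalent ions."""
        wave = step_waveform(v_step_mV=0.0, duration_ms=1.0, holding_mV=0.0, onset_ms=0.0)
        from calyxsim.biophysics import GatingTrace

        tr = GatingTrace(np.array([0.0]), np.array([1.0]))
        rng = np.random.default_rng(0)
        counts = [len(sample_ion_injections(tr, wave, seed=rng)) for _ in range(300)]
        assert np.mean(counts) == pytest.approx(0.12 * IONS_PER_PA_MS, rel=0.02)
        # Poisson dispersion: variance ~ mean
        assert np.var(counts) == pytest.approx(np.mean(counts), rel=0.25)

    def test_no_open_intervals_no_ions(self, standard_ap):
        from calyxsim.biophysics import GatingTrace

        tr = GatingTrace(np.array([]), np.array([]))
        assert len(sample_ion_injections(tr, standard_ap, seed=1)) == 0

    def test_charge_bookkeeping(self, standard_ap):
        """Summed ions x 2e matches the time integral of the open-channel
        current within Poisson error."""
        g = GatingParams()
        traces = sample_gating(standard_ap, g, 200, seed=11)
        rng = np.random.default_rng(2)
        total_ions = 0
        expected_ions = 0.0
        for tr in traces:
            total_ions += len(sample_ion_injections(tr, standard_ap, seed=rng))
            expected_ions += expected_charge_pC(tr, standard_ap) * 1e3 * IONS_PER_PA_MS
        assert total_ions == pytest.approx(expected_ions, rel=0.03)

    def test_flux_peaks_during_repolarisation(self, standard_ap):
        """Tail currents: ensemble single-channel flux peaks after the AP peak,
        when driving force recovers while channels are still open."""
        g = GatingParams()
        traces = sample_gating(standard_ap, g, 2000, seed=13)
        rng = np.random.default_rng(3)
        times = np.concatenate(
            [sample_ion_injections(tr, standard_ap, seed=rng) for tr in traces]
        )
        hist, edges = np.histogram(times, bins=np.arange(0, standard_ap.duration_ms, 0.05))
        t_flux_peak = edges[np.argmax(hist)]
        t_v_peak = standard_ap.t_ms[np.argmax(standard_ap.v_mV)]
        assert t_flux_peak > t_v_peak
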