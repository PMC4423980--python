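"""Particle engine: conservation, diffusion, point-source and ODE oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from calyxsim import (
    ChannelLayout,
    SimConfig,
    StabilityError,
    near_membrane_map,
    run_trial,
    run_trials,
    sensor_response,
    step_waveform,
    wellmixed_reference,
)
from calyxsim.azmap import ActiveZoneMap
from calyxsim.config import IONS_PER_NM3_PER_UM, SensorParams


def silent_stimulus():
    """A waveform that never opens channels (held far below threshold)."""
    return step_waveform(v_step_mV=-120, duration_ms=0.01, holding_mV=-120)


def free_box_config(**kw):
    cfg = SimConfig(**kw)
    cfg.buffers = []
    return cfg


@pytest.fixture(scope="module")
def dummy_layout():
    return ChannelLayout(np.array([[140.0, 140.0]]), "random")


class TestBasics:
    def test_no_open_channels_no_ions_no_fusion(self, az5_like, default_config):
        layout = ChannelLayout(np.array([[100.0, 100.0]]), "random")
        res = run_trial(az5_like, layout, default_config, silent_stimulus(), seed=0)
        assert res.n_injected == 0
        assert res.n_fused == 0

    def test_time_step_stability_guard(self, az5_like, standard_ap):
        cfg = SimConfig()
        cfg.dt_fine_ms = 5e-3  # rms step ~47 nm >> vesicle radius / 4
        layout = ChannelLayout(np.array([[100.0, 100.0]]), "random")
        with pytest.raises(StabilityError, match="obstacle radius"):
            run_trial(az5_like, layout, cfg, standard_ap, seed=0)

    def test_mass_conservation_through_full_trial(self, az5_like, standard_ap):
        from calyxsim import place_channels_exclusion_zone

        layout = place_channels_exclusion_zone(az5_like, 14, 30.0, seed=3)
        res = run_trial(az5_like, layout, SimConfig(), standard_ap, seed=5)
        assert res.n_injected > 200
        res.check_mass_conservation()  # free + bound + sensor == injected, all times

    def test_determinism_per_seed(self, az5_like, standard_ap):
        from calyxsim import place_channels_exclusion_zone

        layout = place_channels_exclusion_zone(az5_like, 14, 30.0, seed=3)
        a = run_trial(az5_like, layout, SimConfig(), standard_ap, seed=77)
        b = run_trial(az5_like, layout, SimConfig(), standard_ap, seed=77)
        assert a.n_injected == b.n_injected
        np.testing.assert_array_equal(a.fusion_times_ms, b.fusion_times_ms)


class TestDiffusion:
    def test_msd_matches_free_diffusion(self, dummy_layout):
        """Lateral MSD after time t equals 4 D t (walls untouched at short t)."""
        boundary = np.array([[-290, -290], [290, -290], [290, 290], [-290, 290]], float)
        az = ActiveZoneMap("empty", boundary, np.zeros((0, 2)))
        cfg = free_box_config()
        rng = np.random.default_rng(0)
        n = 4000
        start = np.column_stack(
            [np.zeros(n), np.zeros(n), np.full(n, 600.0)]
        )
        T = 0.02
        res = run_trial(
            az, dummy_layout, cfg, silent_stimulus(), seed=1, duration_ms=T,
            init_ion_positions=start, record_final_positions=True,
        )
        disp = res.final_positions[:, :2]
        msd = (disp**2).sum(1).mean()
        d_ca = cfg.d_ca_um2_s * 1000.0
        assert msd == pytest.approx(4 * d_ca * T, rel=0.05)

    def test_reflective_box_conserves_particles(self, dummy_layout):
        boundary = np.array([[-290, -290], [290, -290], [290, 290], [-290, 290]], float)
        az = ActiveZoneMap("empty", boundary, np.zeros((0, 2)))
        cfg = free_box_config()
        rng = np.random.default_rng(4)
        start = rng.uniform([-300, -300, 0], [300, 300, 1200], (500, 3))
        res = run_trial(az, dummy_layout, cfg, silent_stimulus(), seed=2,
                        duration_ms=0.5, init_ion_positions=start,
                        record_final_positions=True)
        assert (res.final_states == 0).sum() == 500
        p = res.final_positions
        assert np.all((p[:, 0] >= -300) & (p[:, 0] <= 300))
        assert np.all((p[:, 2] >= 0) & (p[:, 2] <= 1200))

    def test_point_source_concentration_profile(self):
        """Open channel on a reflective plane: steady state c(r) = Phi/(2 pi D r).

        Checked via the time-averaged near-membrane map in an annulus where
        boundary effects are negligible.
        """
        boundary = np.array([[-290, -290], [290, -290], [290, 290], [-290, 290]], float)
        az = ActiveZoneMap("empty", boundary, np.zeros((0, 2)))
        layout = ChannelLayout(np.array([[0.0, 0.0]]), "random")
        cfg = free_box_config()
        cfg.record.map_snapshot_times_ms = list(np.arange(0.4, 1.2, 0.004))
        cfg.record.map_bin_nm = 10.0
        cfg.max_flight_steps = 4  # sharp position sampling for the profile
        wave = step_waveform(v_step_mV=0.0, duration_ms=1.2, holding_mV=0.0, onset_ms=0.0)
        # force the channel permanently open via gating with huge alpha
        cfg.gating.alpha0_per_ms = 500.0
        cfg.gating.beta0_per_ms = 1e-9
        maps = None
        n_rep = 25
        for s in range(n_rep):
            res = run_trial(az, layout, cfg, wave, seed=s, duration_ms=1.2)
            m = res.map_snapshots.astype(float)
            maps = m if maps is None else maps + m
        mean_counts = maps.mean(0) / n_rep
        vol = cfg.record.map_bin_nm**2 * cfg.record.map_slab_nm
        conc = mean_counts / (vol * IONS_PER_NM3_PER_UM)
        xs = (np.arange(conc.shape[0]) + 0.5) * 10 - 300
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        r = np.hypot(gx, gy)
        from calyxsim.biophysics import IONS_PER_PA_MS, single_channel_current

        phi = float(single_channel_current(0.0)) * IONS_PER_PA_MS  # ions/ms
        d_ca = cfg.d_ca_um2_s * 1000.0

        def ring_mean(lo, hi):
            ring = (r >= lo) & (r < hi)
            return conc[ring].mean(), r[ring].mean()

        # the sealed box accumulates a quasi-uniform background; comparing
        # annulus differences cancels it, leaving the 1/(2 pi D r) law
        # (image source on the reflective membrane doubles free space)
        far, r_far = ring_mean(150, 220)
        for lo, hi in [(30, 50), (50, 80), (80, 120)]:
            measured, r_eff = ring_mean(lo, hi)
            expected = (
                phi / (2 * np.pi * d_ca) * (1 / r_eff - 1 / r_far)
            ) / IONS_PER_NM3_PER_UM
            assert measured - far == pytest.approx(expected, rel=0.15)


class TestSensorAndODE:
    def test_pure_birth_cascade_matrix_exponential(self):
        """k_off = 0, constant Ca, gamma -> fusion: the sensor is a pure-birth
        chain; occupancy matches the matrix exponential."""
        sp = SensorParams(k_off_per_ms=0.0, gamma_per_ms=0.0)
        c = 10.0
        t_end = 0.4
        t = np.linspace(0, t_end, 201)
        resp = sensor_response(sp, np.full_like(t, c), t)
        lam = [(5 - j) * sp.k_on_per_uM_ms * c for j in range(5)]
        Q = np.zeros((6, 6))
        for j, l in enumerate(lam):
            Q[j, j] -= l
            Q[j + 1, j] += l
        P = expm(Q * t_end)[:, 0]
        np.testing.assert_allclose(resp.sensor_states[-1], P, atol=1e-6)

    def test_zero_calcium_zero_fusion(self, default_config):
        ref = wellmixed_reference(default_config, ca0_uM=0.0, t_end_ms=2.0)
        assert ref.final_fusion_probability == 0.0

    def test_step_calcium_gives_order_point_one_fusion(self):
        """10-20 uM for ~0.5 ms drives fusion probabilities of order 0.1 —
        the regime reported at docked vesicles."""
        sp = SensorParams()
        t = np.linspace(0, 0.5, 201)
        p_lo = sensor_response(sp, np.full_like(t, 10.0), t).final_fusion_probability
        p_hi = sensor_response(sp, np.full_like(t, 20.0), t).final_fusion_probability
        assert 0.01 < p_lo < 0.5
        assert 0.03 < p_hi < 0.8

    def test_engine_matches_wellmixed_ode_fusion(self, square_az, dummy_layout):
        """Uniform ion bolus in a small box, sensor only: particle engine
        fusion probability within 5% (plus counting error) of the ODE."""
        cfg = free_box_config()
        cfg.box_x_nm = cfg.box_y_nm = cfg.box_z_nm = 300.0
        vol = 300**3 - 4 / 3 * np.pi * 22.5**3
        ipu = vol * IONS_PER_NM3_PER_UM
        n_ions = int(round(12.0 * ipu))
        ref = wellmixed_reference(cfg, ca0_uM=n_ions / ipu, t_end_ms=1.0)
        rng = np.random.default_rng(123)
        nf = 0
        n_trials = 600
        for s in range(n_trials):
            while True:
                p = rng.uniform([-150, -150, 0], [150, 150, 300], (2 * n_ions, 3))
                ok = (p[:, 0] ** 2 + p[:, 1] ** 2 + (p[:, 2] - 27.5) ** 2) > 22.5**2
                p = p[ok][:n_ions]
                if len(p) == n_ions:
                    break
            res = run_trial(square_az, dummy_layout, cfg, silent_stimulus(),
                            seed=5000 + s, duration_ms=1.0, init_ion_positions=p)
            nf += res.n_fused
        p_engine = nf / n_trials
        se = np.sqrt(p_engine * (1 - p_engine) / n_trials)
        assert abs(p_engine - ref.final_fusion_probability) <= (
            0.05 * ref.final_fusion_probability + 2 * se
        )


class TestNearMembraneMap:
    def test_zero_ions_all_zero_grid(self, az5_like, default_config):
        cfg = default_config
        cfg.record.map_snapshot_times_ms = [0.05]
        layout = ChannelLayout(np.array([[100.0, 100.0]]), "random")
        res = run_trial(az5_like, layout, cfg, silent_stimulus(), seed=0,
                        duration_ms=0.1)
        grid = near_membrane_map(res, 0.05)
        assert np.all(grid == 0)

    def test_single_ion_concentration_units(self, dummy_layout):
        boundary = np.array([[-290, -290], [290, -290], [290, 290], [-290, 290]], float)
        az = ActiveZoneMap("empty", boundary, np.zeros((0, 2)))
        cfg = free_box_config()
        cfg.d_ca_um2_s = 0.0  # freeze the ion in place
        cfg.record.map_snapshot_times_ms = [0.01]
        res = run_trial(az, dummy_layout, cfg, silent_stimulus(), seed=1,
                        duration_ms=0.02,
                        init_ion_positions=np.array([[5.0, 5.0, 2.0]]))
        grid = near_membrane_map(res, 0.01)
        assert (grid > 0).sum() == 1
        vol = cfg.record.map_bin_nm**2 * cfg.record.map_slab_nm
        assert grid.max() == pytest.approx(1 / (vol * IONS_PER_NM3_PER_UM))

    def test_map_disabled_raises(self, az5_like, default_config, standard_ap):
        layout = ChannelLayout(np.array([[100.0, 100.0]]), "random")
        res = run_trial(az5_like, layout, default_config, silent_stimulus(), seed=0)
        with pytest.raises(RuntimeError, match="recording"):
            near_membrane_map(res, 0.5)
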