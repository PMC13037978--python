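import dataclasses
import math

import numpy as np
import pytest

from helpers import estimate_frequency, fit_sinusoid
from vcgsim import (
    CardiacCycleParams,
    CircularTrajectory,
    LeadSeries,
    WaveParams,
    add_noise,
    altered_cycle_params,
    beat_average,
    gen_cardiac_cycle,
    gen_circular,
    loop_from_series,
    normal_cycle_params,
    peak_vector,
)


class TestGenCircularIdeal:
    def test_one_hz_sinusoids_with_expected_phases(self):
        c = CircularTrajectory(radius_mm=10.0, omega=2 * math.pi, fs=250.0, n_revolutions=3.0)
        s, pos = gen_circular(c, model="ideal")
        t = s.t
        for lead, phase_expected in (("DI", 0.0), ("DII", -60.0), ("DIII", -120.0)):
            amp, phase = fit_sinusoid(t, getattr(s, lead), c.omega)
            assert amp == pytest.approx(0.1, rel=1e-12)
            assert phase == pytest.approx(phase_expected, abs=1e-6)
        # ground-truth positions lie on the requested circle
        np.testing.assert_allclose(np.hypot(pos[:, 0], pos[:, 1]), 10.0, rtol=1e-12)

    def test_amplitude_proportional_to_radius(self):
        base = dict(omega=2 * math.pi, fs=250.0, n_revolutions=2.0)
        s1, _ = gen_circular(CircularTrajectory(radius_mm=10.0, **base))
        s2, _ = gen_circular(CircularTrajectory(radius_mm=20.0, **base))
        np.testing.assert_allclose(s2.DI, 2.0 * s1.DI, rtol=1e-12)
        np.testing.assert_allclose(s2.DIII, 2.0 * s1.DIII, rtol=1e-12)

    def test_frequency_proportional_to_omega(self):
        base = dict(radius_mm=10.0, fs=500.0, n_revolutions=4.0)
        s1, _ = gen_circular(CircularTrajectory(omega=math.pi, **base))
        s2, _ = gen_circular(CircularTrajectory(omega=2 * math.pi, **base))
        f1 = estimate_frequency(s1.DI, s1.fs)
        f2 = estimate_frequency(s2.DI, s2.fs)
        assert f2 / f1 == pytest.approx(2.0, rel=1e-9)

    def test_reversing_omega_reverses_orientation(self):
        base = dict(radius_mm=10.0, fs=250.0, n_revolutions=1.0)
        fwd, _ = gen_circular(CircularTrajectory(omega=2 * math.pi, **base))
        rev, _ = gen_circular(CircularTrajectory(omega=-2 * math.pi, **base))
        # reversed rotation conjugates the phase ordering: DIII leads DI
        _, ph_fwd = fit_sinusoid(fwd.t, fwd.DIII, 2 * math.pi)
        _, ph_rev = fit_sinusoid(rev.t, rev.DIII, 2 * math.pi)
        assert ph_fwd == pytest.approx(-120.0, abs=1e-6)
        assert ph_rev == pytest.approx(+120.0, abs=1e-6)
        # loop orientation flips (signed area changes sign)
        lf = loop_from_series(fwd)
        lr = loop_from_series(rev)
        area_f = np.sum(lf.vx * np.roll(lf.vy, -1) - lf.vy * np.roll(lf.vx, -1))
        area_r = np.sum(lr.vx * np.roll(lr.vy, -1) - lr.vy * np.roll(lr.vx, -1))
        assert area_f * area_r < 0

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            CircularTrajectory(radius_mm=10.0, omega=2 * math.pi * 100, fs=150.0)

    @pytest.mark.parametrize("bad", [dict(radius_mm=0.0), dict(omega=0.0),
                                     dict(n_revolutions=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(radius_mm=10.0, omega=2 * math.pi, fs=250.0, n_revolutions=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            CircularTrajectory(**kwargs)


class TestGenCircularTank:
    def test_near_field_sinusoid_and_radius_ratio(self, tank_cfg):
        # r <= 0.1 * side: the dipole limit makes leads near-sinusoidal
        base = dict(omega=2 * math.pi, fs=250.0, n_revolutions=2.0)
        s5, _ = gen_circular(CircularTrajectory(radius_mm=5.0, **base), "tank", tank_cfg)
        s10, _ = gen_circular(CircularTrajectory(radius_mm=10.0, **base), "tank", tank_cfg)
        a5, _ = fit_sinusoid(s5.t, s5.DI, 2 * math.pi)
        a10, _ = fit_sinusoid(s10.t, s10.DI, 2 * math.pi)
        assert a10 / a5 == pytest.approx(2.0, rel=0.02)
        # the waveform is near-sinusoidal; the residual is genuine near-field
        # harmonic distortion, shrinking with radius
        fit5 = a5 * np.cos(2 * math.pi * s5.t)
        fit10 = a10 * np.cos(2 * math.pi * s10.t)
        rms5 = np.std(s5.DI - fit5) / a5
        rms10 = np.std(s10.DI - fit10) / a10
        assert rms10 < 0.10
        assert rms5 < 0.6 * rms10  # distortion falls off with r

    def test_einthoven_exact_for_tank_series(self, tank_cfg):
        c = CircularTrajectory(radius_mm=8.0, omega=math.pi, fs=100.0, n_revolutions=1.0)
        s, _ = gen_circular(c, "tank", tank_cfg)
        scale = np.max(np.abs(np.c_[s.DI, s.DII, s.DIII]))
        assert np.max(np.abs(s.DII - s.DI - s.DIII)) <= 1e-12 * scale


class TestGenCardiacCycle:
    def test_leads_zero_outside_qrs_when_p_t_absent(self):
        p = dataclasses.replace(
            normal_cycle_params(),
            P=WaveParams(0.0, 50.0, 25.0, 0.090),
            T=WaveParams(0.0, 45.0, 20.0, 0.180),
        )
        s, truth = gen_cardiac_cycle(p, n_cycles=1, fs=800.0)
        t = s.t
        qrs_start = p.P.duration_s + p.pr_segment_s
        qrs_end = qrs_start + p.QRS.duration_s
        outside = (t < qrs_start) | (t >= qrs_end)
        assert np.all(s.DI[outside] == 0.0)
        assert np.all(s.DII[outside] == 0.0)
        assert np.all(truth.Vh[outside] == 0.0)

    def test_noiseless_round_trip_recovers_truth(self):
        s, truth = gen_cardiac_cycle(normal_cycle_params(), n_cycles=1, fs=800.0)
        loop = loop_from_series(s)
        off_origin = ~truth.degenerate
        assert np.max(np.abs(loop.alpha_deg[off_origin] - truth.alpha_deg[off_origin])) <= 1e-6
        np.testing.assert_allclose(loop.Vh, truth.Vh, atol=1e-12)

    def test_peak_is_inside_qrs_at_the_qrs_axis(self):
        p = normal_cycle_params()
        _, truth = gen_cardiac_cycle(p, n_cycles=1, fs=800.0)
        i = int(np.argmax(truth.Vh))
        t_peak = truth.t[i]
        qrs_start = p.P.duration_s + p.pr_segment_s
        assert qrs_start <= t_peak < qrs_start + p.QRS.duration_s
        assert truth.alpha_deg[i] == pytest.approx(p.QRS.axis_deg, abs=1e-9)
        assert truth.Vh[i] == pytest.approx(p.QRS.amplitude, rel=1e-12)

    def test_qrs_loop_is_closed_at_the_origin(self):
        p = normal_cycle_params()
        _, truth = gen_cardiac_cycle(p, n_cycles=1, fs=800.0)
        # first and last QRS samples sit at the origin boundary (sin(0)=sin(pi)=0)
        qrs_start = p.P.duration_s + p.pr_segment_s
        i0 = int(round(qrs_start * 800.0))
        assert truth.Vh[i0] <= 1e-9  # departs from the origin
        i1 = int(round((qrs_start + p.QRS.duration_s) * 800.0))
        assert truth.Vh[i1] <= 1e-9  # isoelectric again after the wave

    def test_hand_time_scale_dilates_cycle(self):
        real = normal_cycle_params("real")
        hand = normal_cycle_params("hand")
        assert hand.cycle_length_s == pytest.approx(12.5 * real.cycle_length_s, rel=1e-12)

    def test_altered_preset_drops_every_third_qrs(self):
        p = altered_cycle_params(dropped_every=3)
        s, truth = gen_cardiac_cycle(p, n_cycles=3, fs=800.0)
        cyc = p.cycle_length_s
        qrs_lo = p.P.duration_s + p.pr_segment_s
        qrs_hi = qrs_lo + p.QRS.duration_s
        t = truth.t
        for k, expect_beat in ((0, True), (1, True), (2, False)):
            m = (t >= k * cyc + qrs_lo) & (t < k * cyc + qrs_hi)
            peak = truth.Vh[m].max()
            if expect_beat:
                assert peak > 0.9
            else:
                assert peak == 0.0
        # P waves march on in the dropped cycle
        mp = (t >= 2 * cyc) & (t < 2 * cyc + p.P.duration_s)
        assert truth.Vh[mp].max() > 0.05

    def test_tank_model_renders_finite_leads(self, tank_cfg):
        s, _ = gen_cardiac_cycle(normal_cycle_params(), n_cycles=1, model="tank",
                                 cfg=tank_cfg, fs=200.0)
        assert np.all(np.isfinite(s.DI))
        scale = np.max(np.abs(s.DII))
        assert np.max(np.abs(s.DII - s.DI - s.DIII)) <= 1e-12 * scale

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            WaveParams(1.0, 60.0, 40.0, -0.1)
        with pytest.raises(ValueError):
            CardiacCycleParams(pr_segment_s=-0.01)


class TestAddNoise:
    def test_zero_sd_is_identity(self):
        s, _ = gen_cardiac_cycle(normal_cycle_params(), fs=200.0)
        assert add_noise(s, 0.0, seed=1) is s

    def test_same_seed_reproduces(self):
        s, _ = gen_cardiac_cycle(normal_cycle_params(), fs=200.0)
        a = add_noise(s, 0.01, seed=42)
        b = add_noise(s, 0.01, seed=42)
        np.testing.assert_array_equal(a.DI, b.DI)
        np.testing.assert_array_equal(a.DIII, b.DIII)

    def test_sample_sd_matches_request(self):
        n = 100_000
        s = LeadSeries(fs=1000.0, DI=np.zeros(n), DII=np.zeros(n), DIII=np.zeros(n))
        noisy = add_noise(s, 0.01, seed=7)
        assert np.std(noisy.DI) == pytest.approx(0.01, rel=0.01)

    def test_negative_sd_rejected(self):
        s, _ = gen_cardiac_cycle(normal_cycle_params(), fs=200.0)
        with pytest.raises(ValueError):
            add_noise(s, -0.01, seed=1)


class TestParameterRecovery:
    def test_noiseless_peak_recovery(self):
        p = normal_cycle_params()
        s, _ = gen_cardiac_cycle(p, n_cycles=1, fs=800.0)
        loop = loop_from_series(s)
        vh, alpha = peak_vector(loop, fs=s.fs)
        assert abs(alpha - p.QRS.axis_deg) <= 0.5
        assert abs(vh - p.QRS.amplitude) <= 1e-3 * p.QRS.amplitude

    def test_beat_average_reduces_noise(self):
        p = dataclasses.replace(normal_cycle_params(), noise_sd=0.05, seed=3)
        s, _ = gen_cardiac_cycle(p, n_cycles=8, fs=800.0)
        avg = beat_average(s, p.cycle_length_s)
        clean, _ = gen_cardiac_cycle(normal_cycle_params(), n_cycles=1, fs=800.0)
        resid_avg = np.std(avg.DI - clean.DI[: len(avg)])
        assert resid_avg < 0.05 / math.sqrt(8) * 1.3
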