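"""Angle-trace decomposition, beat envelopes, and the asymmetry index."""

import numpy as np
import pytest

from casakit import flagbeat as fb
from casakit import synthgen as sg


class TestUnwrapAngle:
    def test_wrap_at_360_removed(self):
        trace = fb.unwrap_angle([359.0, 1.0, 3.0], frame_rate=10.0)
        assert np.allclose(trace.theta, [0.0, 2.0, 4.0])

    def test_monotone_ramp_only_shifted(self):
        raw = np.linspace(20.0, 120.0, 11)
        trace = fb.unwrap_angle(raw, frame_rate=10.0)
        assert np.allclose(trace.theta, raw - 20.0)

    def test_generator_net_rotation_preserved(self):
        spec = sg.BeatSpec(rotation_velocity=95.0, noise_sd=0.0, duration=15.0)
        truth = sg.gen_angle_trace(spec, seed=0)
        wrapped = np.mod(truth.theta, 360.0)
        trace = fb.unwrap_angle(wrapped, frame_rate=spec.frame_rate)
        assert trace.theta[-1] == pytest.approx(truth.theta[-1] - truth.theta[0], abs=1e-9)
        assert trace.theta[-1] == pytest.approx(1425.0, abs=2 * spec.osc_amp)


class TestFitOscillation:
    def test_noiseless_identity(self):
        spec = sg.BeatSpec(
            osc_freq=15.0, osc_amp=10.0, rotation_velocity=50.0, phase=0.7,
            noise_sd=0.0,
        )
        fit = fb.fit_oscillation(sg.gen_angle_trace(spec, seed=0))
        assert fit.converged
        assert fit.omega == pytest.approx(50.0, abs=1e-6)
        assert fit.amp == pytest.approx(10.0, abs=1e-6)
        assert fit.freq == pytest.approx(15.0, abs=1e-6)

    def test_pure_ramp_degenerate_policy(self):
        spec = sg.BeatSpec(osc_freq=15.0, osc_amp=0.0, rotation_velocity=50.0, noise_sd=0.0)
        fit = fb.fit_oscillation(sg.gen_angle_trace(spec, seed=0))
        assert not fit.converged
        assert fit.amp == pytest.approx(0.0, abs=1e-9)
        assert fit.omega == pytest.approx(50.0, abs=1e-9)

    def test_noisy_recovery_tolerances(self):
        for seed in range(9):
            spec = sg.BeatSpec(
                osc_freq=15.0, osc_amp=10.0, rotation_velocity=50.0, noise_sd=2.0
            )
            fit = fb.fit_oscillation(sg.gen_angle_trace(spec, seed=seed))
            assert fit.freq == pytest.approx(15.0, abs=0.2)
            assert fit.omega == pytest.approx(50.0, abs=5.0)

    def test_equivariance_under_added_ramp(self):
        spec = sg.BeatSpec(
            osc_freq=12.0, osc_amp=8.0, rotation_velocity=30.0, phase=1.1, noise_sd=0.0
        )
        trace = sg.gen_angle_trace(spec, seed=0)
        fit = fb.fit_oscillation(trace)
        shifted = fb.AngleTrace(
            times=trace.times, theta=trace.theta + 25.0 * trace.times,
            frame_rate=trace.frame_rate,
        )
        fit2 = fb.fit_oscillation(shifted)
        assert fit2.omega - fit.omega == pytest.approx(25.0, abs=1e-6)
        assert fit2.freq == pytest.approx(fit.freq, abs=1e-6)
        assert fit2.amp == pytest.approx(fit.amp, abs=1e-6)

    def test_recovery_error_shrinks_with_duration(self):
        """Mean frequency error over 10 seeds decreases from 2 to 5 to 15 s."""
        mean_err = []
        for dur in (2.0, 5.0, 15.0):
            errs = []
            for seed in range(10):
                spec = sg.BeatSpec(
                    osc_freq=15.0, osc_amp=10.0, rotation_velocity=50.0,
                    noise_sd=2.0, duration=dur,
                )
                errs.append(abs(fb.fit_oscillation(sg.gen_angle_trace(spec, seed=seed)).freq - 15.0))
            mean_err.append(np.mean(errs))
        assert mean_err[0] > mean_err[1] > mean_err[2]


class TestPrePostCompare:
    def test_identical_fits_give_zero_deltas(self):
        spec = sg.BeatSpec(noise_sd=0.0, phase=0.3)
        fit = fb.fit_oscillation(sg.gen_angle_trace(spec, seed=0))
        d = fb.pre_post_compare(fit, fit)
        assert (d.dfreq, d.damp, d.domega) == (0.0, 0.0, 0.0)

    def test_injected_shift_recovered_noiseless(self):
        pre_spec = sg.BeatSpec(
            osc_freq=15.0, osc_amp=10.0, rotation_velocity=50.0, phase=0.2, noise_sd=0.0
        )
        post_spec = sg.BeatSpec(
            osc_freq=11.9, osc_amp=14.9, rotation_velocity=145.0, phase=0.9, noise_sd=0.0
        )
        d = fb.pre_post_compare(
            fb.fit_oscillation(sg.gen_angle_trace(pre_spec, seed=0)),
            fb.fit_oscillation(sg.gen_angle_trace(post_spec, seed=0, epoch="post")),
        )
        assert d.dfreq == pytest.approx(-3.1, abs=1e-6)
        assert d.damp == pytest.approx(4.9, abs=1e-6)
        assert d.domega == pytest.approx(95.0, abs=1e-6)

    def test_mean_frequency_shift_over_seeded_pairs(self):
        deltas = []
        for seed in range(9):
            pre = sg.BeatSpec(osc_freq=15.0, osc_amp=10.0, rotation_velocity=50.0, noise_sd=2.0)
            post = sg.BeatSpec(osc_freq=11.9, osc_amp=14.9, rotation_velocity=145.0, noise_sd=2.0)
            d = fb.pre_post_compare(
                fb.fit_oscillation(sg.gen_angle_trace(pre, seed=seed)),
                fb.fit_oscillation(sg.gen_angle_trace(post, seed=1000 + seed, epoch="post")),
            )
            deltas.append(d.dfreq)
        assert float(np.mean(deltas)) == pytest.approx(-3.1, abs=0.2)

    def test_unconverged_input_rejected(self):
        good = fb.fit_oscillation(
            sg.gen_angle_trace(sg.BeatSpec(noise_sd=0.0, phase=0.1), seed=0)
        )
        bad = fb.OscillationFit(0.0, 0.0, 0.0, 0.0, 0.0, converged=False)
        with pytest.raises(ValueError, match="converged"):
            fb.pre_post_compare(good, bad)


def sinusoidal_beat_centerlines(n_frames=50, n_arc=64, amp=12.0, length=50.0):
    """Planar beat y(s, t) = a(s) * sin(w t) with a(s) = amp * sin(pi s / L)."""
    s = np.linspace(0.0, length, n_arc)
    a = amp * np.sin(np.pi * s / length)
    phases = np.linspace(0, 2 * np.pi, n_frames, endpoint=False)
    cl = np.empty((n_frames, n_arc, 2))
    cl[:, :, 0] = s[None, :]
    cl[:, :, 1] = a[None, :] * np.sin(phases)[:, None]
    return s, a, cl


class TestBeatEnvelope:
    def test_mirror_symmetric_beat_gives_equal_envelopes(self):
        s, a, cl = sinusoidal_beat_centerlines()
        env = fb.beat_envelope(s, cl, ((0.0, 0.0), (1.0, 0.0)))
        assert np.allclose(env.amp_above, env.amp_below, atol=1e-9)

    def test_one_sided_beat_zeroes_opposite_envelope(self):
        s, a, cl = sinusoidal_beat_centerlines()
        cl[:, :, 1] = np.abs(cl[:, :, 1])
        env = fb.beat_envelope(s, cl, ((0.0, 0.0), (1.0, 0.0)))
        assert np.all(env.amp_below == 0.0)
        assert env.amp_above.max() > 0

    def test_analytic_amplitude_profile_recovered(self):
        s, a, cl = sinusoidal_beat_centerlines(n_frames=80)
        env = fb.beat_envelope(s, cl, ((0.0, 0.0), (1.0, 0.0)))
        # phase grid resolves the extremes to within (1 - cos(pi/n))
        tol = a.max() * (1 - np.cos(np.pi / 80)) + 1e-9
        assert np.max(np.abs(env.amp_above - a)) <= tol

    def test_time_reversal_invariance(self):
        s, a, cl = sinusoidal_beat_centerlines()
        axis = ((0.0, 0.0), (1.0, 0.0))
        env_f = fb.beat_envelope(s, cl, axis)
        env_r = fb.beat_envelope(s, cl[::-1], axis)
        assert np.array_equal(env_f.amp_above, env_r.amp_above)
        assert np.array_equal(env_f.amp_below, env_r.amp_below)

    def test_too_few_centerlines_rejected(self):
        s, a, cl = sinusoidal_beat_centerlines(n_frames=2)
        with pytest.raises(ValueError, match="3 centerlines"):
            fb.beat_envelope(s, cl, ((0.0, 0.0), (1.0, 0.0)))


class TestAsymmetryIndex:
    def test_symmetric_envelope_is_zero(self):
        env = sg.gen_envelope(sg.EnvelopeSpec(area_above=4.0, area_below=4.0))
        assert fb.asymmetry_index(env) == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_envelope_is_one(self):
        env = sg.gen_envelope(sg.EnvelopeSpec(area_above=4.0, area_below=0.0))
        assert fb.asymmetry_index(env) == pytest.approx(1.0, abs=1e-12)

    def test_five_to_three_ratio_gives_quarter(self):
        env = sg.gen_envelope(sg.EnvelopeSpec(area_above=5.0, area_below=3.0))
        assert fb.asymmetry_index(env) == pytest.approx(0.25, abs=1e-9)

    def test_swap_and_scale_invariance(self):
        env = sg.gen_envelope(sg.EnvelopeSpec(area_above=5.0, area_below=3.0))
        swapped = fb.BeatEnvelope(env.arc_positions, env.amp_below, env.amp_above)
        scaled = fb.BeatEnvelope(
            env.arc_positions, 3.7 * env.amp_above, 3.7 * env.amp_below
        )
        ai = fb.asymmetry_index(env)
        assert fb.asymmetry_index(swapped) == pytest.approx(ai, abs=1e-12)
        assert fb.asymmetry_index(scaled) == pytest.approx(ai, abs=1e-12)
        assert 0.0 <= ai <= 1.0


class TestMaxAmplitude:
    def test_flat_envelope(self):
        env = fb.BeatEnvelope(np.arange(5.0), np.zeros(5), np.zeros(5))
        assert fb.max_amplitude(env) == 0.0

    def test_triangular_peak(self):
        # 65 arc points put the apex exactly on the grid; triangle area =
        # L * peak / 2 over L = 50 um -> peak = 20 um
        env = sg.gen_envelope(
            sg.EnvelopeSpec(
                area_above=500.0, area_below=100.0,
                profile_shape="triangular", n_arc_points=65,
            )
        )
        assert fb.max_amplitude(env) == pytest.approx(20.0, rel=1e-9)

    def test_analytic_half_sine_beat(self):
        s, a, cl = sinusoidal_beat_centerlines(n_frames=80, amp=9.0)
        env = fb.beat_envelope(s, cl, ((0.0, 0.0), (1.0, 0.0)))
        assert fb.max_amplitude(env) == pytest.approx(9.0, rel=1e-3)
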