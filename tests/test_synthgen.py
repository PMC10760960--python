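"""Generator determinism, closed-form agreement, and class fidelity."""

import math

import numpy as np
import pytest

from casakit import synthgen as sg
from casakit import trackkin as tk


class TestGenTrack:
    def test_straight_noiseless_track_is_identity_kinematics(self):
        spec = sg.TrackSpec(
            kind="progressive", speed=100.0, beat_freq=0.0, lateral_amp=0.0,
            curvature_bias=0.0, noise_sd=0.0,
        )
        ks = tk.kinematics(sg.gen_track(spec, seed=0))
        assert ks.vcl == pytest.approx(100.0, abs=1e-9)
        assert ks.vsl == pytest.approx(100.0, abs=1e-9)
        assert ks.vap == pytest.approx(100.0, abs=1e-9)
        assert ks.lin == pytest.approx(1.0, abs=1e-12)
        assert ks.alh == pytest.approx(0.0, abs=1e-9)

    def test_immotile_noiseless_has_zero_vcl(self):
        spec = sg.TrackSpec(
            kind="immotile", speed=0.0, beat_freq=0.0, lateral_amp=0.0,
            curvature_bias=0.0, noise_sd=0.0,
        )
        assert tk.kinematics(sg.gen_track(spec, seed=3)).vcl == 0.0

    def test_default_classes_respect_hyperactivation_gate(self):
        """Hyperactive defaults pass the gate and progressive defaults fail it
        on at least 95 of 100 seeds (verified by the kinematics oracle)."""
        hyper = sum(
            tk.kinematics(sg.gen_track(sg.HYPERACTIVE_SPEC, s)).hyperactive
            for s in range(100)
        )
        prog = sum(
            tk.kinematics(sg.gen_track(sg.PROGRESSIVE_SPEC, s)).hyperactive
            for s in range(100)
        )
        assert hyper >= 95
        assert prog <= 5

    def test_deterministic_for_fixed_spec_and_seed(self):
        a = sg.gen_track(sg.HYPERACTIVE_SPEC, seed=42)
        b = sg.gen_track(sg.HYPERACTIVE_SPEC, seed=42)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_invalid_spec_names_the_field(self):
        with pytest.raises(ValueError, match="speed"):
            sg.TrackSpec(
                kind="progressive", speed=-1.0, beat_freq=0, lateral_amp=0,
                curvature_bias=0,
            )
        with pytest.raises(ValueError, match="duration"):
            sg.TrackSpec(
                kind="progressive", speed=1.0, beat_freq=0, lateral_amp=0,
                curvature_bias=0, duration=0,
            )


class TestGenPopulation:
    def test_donor_mixture_yields_exact_hyperactive_count(self):
        tracks, counts = sg.gen_population(
            1000, {"hyperactive": 0.122, "progressive": 0.878}, seed=0
        )
        assert counts == {"hyperactive": 122, "progressive": 878}
        assert len(tracks) == 1000

    def test_single_class(self):
        tracks, counts = sg.gen_population(10, {"progressive": 1.0}, seed=0)
        assert counts == {"progressive": 10} and len(tracks) == 10

    def test_largest_remainder_tie_break_by_mixture_order(self):
        _, counts = sg.gen_population(
            3, {"progressive": 0.5, "hyperactive": 0.5}, seed=0
        )
        assert counts == {"progressive": 2, "hyperactive": 1}

    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            sg.gen_population(10, {"progressive": 0.7}, seed=0)


class TestGenDecaySeries:
    def test_noiseless_closed_form(self):
        spec = sg.DecaySpec(tau=27.0, sample_times=(0, 27), n_cells_per_timepoint=None)
        series = sg.gen_decay_series(spec)
        assert series.motile_fraction[1] == pytest.approx(100 * math.exp(-1), abs=1e-9)

    def test_infinite_tau_is_constant(self):
        spec = sg.DecaySpec(tau=math.inf, n_cells_per_timepoint=None)
        series = sg.gen_decay_series(spec)
        assert np.all(series.motile_fraction == 100.0)

    def test_progesterone_accelerated_tau_at_readout(self):
        spec = sg.DecaySpec(
            tau=27.0 / 4, sample_times=(0, 15), n_cells_per_timepoint=None
        )
        series = sg.gen_decay_series(spec)
        assert series.motile_fraction[1] == pytest.approx(10.84, abs=0.005)

    def test_binomial_sampling_converges_to_closed_form(self):
        spec = sg.DecaySpec(tau=27.0, n_cells_per_timepoint=100_000)
        series = sg.gen_decay_series(spec, seed=0)
        exact = 100 * np.exp(-np.asarray(spec.sample_times) / 27.0)
        assert np.max(np.abs(series.motile_fraction - exact)) < 1.0


class TestGenAngleTrace:
    def test_pure_ramp(self):
        spec = sg.BeatSpec(osc_freq=1.0, osc_amp=0.0, rotation_velocity=50.0, noise_sd=0.0)
        trace = sg.gen_angle_trace(spec, seed=0)
        slope = np.polyfit(trace.times, trace.theta, 1)[0]
        assert slope == pytest.approx(50.0, abs=1e-9)

    def test_aliasing_rejected_at_spec_level(self):
        with pytest.raises(ValueError, match="frame_rate"):
            sg.BeatSpec(osc_freq=70.0, frame_rate=135.0)

    def test_trace_is_unwrapped_and_zero_based(self):
        spec = sg.BeatSpec(rotation_velocity=95.0, noise_sd=0.0, duration=15.0)
        trace = sg.gen_angle_trace(spec, seed=0)
        assert trace.theta[0] == 0.0
        assert trace.theta[-1] == pytest.approx(95.0 * 15.0, abs=2 * spec.osc_amp)
        assert np.all(np.abs(np.diff(trace.theta)) < 180)


class TestGenEnvelope:
    def test_areas_integrate_back_exactly(self):
        for shape in ("sinusoidal", "triangular"):
            spec = sg.EnvelopeSpec(area_above=5.0, area_below=3.0, profile_shape=shape)
            env = sg.gen_envelope(spec)
            assert np.trapezoid(env.amp_above, env.arc_positions) == pytest.approx(
                5.0, rel=1e-9
            )
            assert np.trapezoid(env.amp_below, env.arc_positions) == pytest.approx(
                3.0, rel=1e-9
            )

    def test_both_areas_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sg.EnvelopeSpec(area_above=0.0, area_below=0.0)


class TestRenderDarkfield:
    def test_static_head_detected_within_half_pixel(self):
        spec = sg.TrackSpec(
            kind="immotile", speed=0, beat_freq=0, lateral_amp=0,
            curvature_bias=0, noise_sd=0.0, duration=0.05,
        )
        base = sg.gen_track(spec, seed=0)
        track = tk.Track("still", base.t, base.x + 60.3, base.y + 70.7, base.frame_rate)
        stack = sg.render_darkfield([track], image_shape=(128, 128), noise_sd=0.0)
        (cx, cy), *rest = tk.detect_heads(stack.frames[0], min_area=3)
        assert not rest
        assert abs(cx - 60.3) < 0.5 and abs(cy - 70.7) < 0.5

    def test_zero_tracks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sg.render_darkfield([])

    def test_two_separated_heads_link_without_swaps(self):
        spec = sg.TrackSpec(
            kind="progressive", speed=50.0, beat_freq=0, lateral_amp=0,
            curvature_bias=0, noise_sd=0.0, duration=0.5,
        )
        a = sg.gen_track(spec, seed=1)
        b = sg.gen_track(spec, seed=2)
        ta = tk.Track("a", a.t, 30 + (a.x - a.x[0]), 30 + (a.y - a.y[0]), a.frame_rate)
        tb = tk.Track("b", b.t, 80 + (b.x - b.x[0]), 80 + (b.y - b.y[0]), b.frame_rate)
        stack = sg.render_darkfield([ta, tb], image_shape=(160, 160), noise_sd=0.0)
        recovered = tk.analyze_stack(stack, max_disp=5.0, min_area=3)
        assert len(recovered) == 2
        for truth in (ta, tb):
            start = truth.xy()[0]
            match = min(
                recovered, key=lambda r: np.linalg.norm(r.xy()[0] - start)
            )
            assert np.max(np.linalg.norm(match.xy() - truth.xy(), axis=1)) < 1.0


class TestGenCohort:
    def test_defective_count_screens_exactly(self):
        from casakit.catsper import screen_cohort

        cohort = sg.gen_cohort(sg.CohortSpec(n_subjects=2286, n_defective=16, seed=0))
        report = screen_cohort(list(cohort.records))
        assert report.n_flagged == 16

    def test_all_donor_and_all_defective_cohorts(self):
        from casakit.catsper import screen_cohort

        clean = sg.gen_cohort(sg.CohortSpec(n_subjects=10, n_defective=0, seed=1))
        assert screen_cohort(list(clean.records)).n_flagged == 0
        bad = sg.gen_cohort(sg.CohortSpec(n_subjects=5, n_defective=5, seed=2))
        assert screen_cohort(list(bad.records)).n_flagged == 5

    def test_straddling_range_recorded_in_metadata(self):
        cohort = sg.gen_cohort(
            sg.CohortSpec(
                n_subjects=10, n_defective=5,
                defective_cai_range=(0.0, 60.0), seed=0,
            )
        )
        assert any("threshold" in w for w in cohort.metadata["warnings"])


class TestGenCalciumTrace:
    def test_zero_response_is_flat_until_ionomycin(self):
        from casakit.signals import dff0

        spec = sg.CalciumSpec(response_amp=0.0, noise_sd=0.0)
        trace = sg.gen_calcium_trace(spec)
        d = dff0(trace)
        before_iono = trace.times < spec.iono_time
        assert np.max(np.abs(d[before_iono])) < 1e-9

    def test_noiseless_normalization_recovers_response_amp(self):
        from casakit.signals import response_amplitudes

        spec = sg.CalciumSpec(response_amp=0.5, noise_sd=0.0)
        resp = response_amplitudes(sg.gen_calcium_trace(spec))
        assert resp.rel_amp == pytest.approx(0.5, abs=0.005)

    def test_monophasic_trace_has_single_peak(self):
        spec = sg.CalciumSpec(response_amp=0.3, waveform="monophasic", noise_sd=0.0)
        trace = sg.gen_calcium_trace(spec)
        mask = (trace.times >= spec.stim_time) & (trace.times < spec.iono_time)
        seg = trace.F[mask]
        interior_maxima = np.nonzero(
            (seg[1:-1] > seg[:-2] + 1e-12) & (seg[1:-1] > seg[2:] + 1e-12)
        )[0]
        assert interior_maxima.size == 1


class TestGenKineticEnsemble:
    def test_exact_composition_per_window(self):
        tracks = sg.gen_kinetic_ensemble([10.0] * 7, n_per_window=100, seed=0)
        assert len(tracks) == 700
        n_hyper = sum("hyperactive" in tr.track_id for tr in tracks)
        assert n_hyper == 70
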