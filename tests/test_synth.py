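"""Generator-level checks: determinism, exponential run statistics,
Brownian increments, rendering fidelity, oscillation traces."""

import numpy as np
import pytest
from scipy import stats

import minitrack as mt
from minitrack.synth import TUMBLE_JITTER_FRACTION


class TestParamValidation:
    @pytest.mark.parametrize("kwargs, field", [
        (dict(speed=0), "speed"),
        (dict(speed=-1), "speed"),
        (dict(mean_run_duration=0), "mean_run_duration"),
        (dict(mean_tumble_duration=-0.1), "mean_tumble_duration"),
        (dict(dt=0.5), "dt"),                 # violates dt < mean_run/5
        (dict(arena=(0, 100)), "arena"),
        (dict(boundary="wrap"), "boundary"),
    ])
    def test_swimmer_errors_name_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            mt.SwimmerParams(**kwargs)

    def test_bead_negative_d(self):
        with pytest.raises(ValueError, match="diffusion_coefficient"):
            mt.BeadParams(diffusion_coefficient=-0.1)

    @pytest.mark.parametrize("kwargs, field", [
        (dict(frequency=28.0), "frequency"),   # at Nyquist for 56 fps
        (dict(frequency=30.0), "frequency"),
        (dict(n_frames=100), "n_frames"),      # not a power of two
    ])
    def test_oscillation_errors(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            mt.OscillationParams(**kwargs)


class TestRunTumbleSimulation:
    def test_seed_determinism(self):
        p = mt.SwimmerParams(n_swimmers=5, duration=5.0, seed=42)
        a = mt.simulate_run_tumble(p)
        b = mt.simulate_run_tumble(p)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)
            np.testing.assert_array_equal(ta.states, tb.states)

    def test_degenerate_single_straight_run(self):
        """No tumble pauses, no rotational diffusion, no reorientation kick:
        one straight run at constant speed."""
        p = mt.SwimmerParams(speed=12.0, mean_tumble_duration=0.0,
                             rotational_diffusion=0.0, tumble_angle_spread=0.0,
                             chemotactic_modulation=0.0, n_swimmers=1,
                             duration=5.0, arena=(5000.0, 5000.0), seed=3)
        (tr,) = mt.simulate_run_tumble(p)
        assert tr.states.all()
        steps = np.diff(tr.positions, axis=0)
        speeds = np.hypot(steps[:, 0], steps[:, 1]) / p.dt
        np.testing.assert_allclose(speeds, 12.0, rtol=1e-9)
        # straight: displacement magnitude equals path length
        d = tr.positions[-1] - tr.positions[0]
        assert np.hypot(*d) == pytest.approx(12.0 * tr.duration, rel=1e-9)

    def test_null_drift_consistent_with_zero(self, null_ensemble):
        g = (0.0, 1.0)
        per_track = np.array([(t.positions[-1] - t.positions[0])[1] / t.duration
                              for t in null_ensemble])
        se = per_track.std(ddof=1) / np.sqrt(len(per_track))
        assert abs(mt.ground_truth_drift(null_ensemble, g)) < 3 * se

    def test_biased_drift_positive_and_equals_brute_force(self, biased_ensemble):
        disp = sum(float(t.positions[-1, 1] - t.positions[0, 1])
                   for t in biased_ensemble)
        total_t = sum(t.duration for t in biased_ensemble)
        brute = disp / total_t
        assert brute > 0
        assert mt.ground_truth_drift(biased_ensemble, (0.0, 1.0)) == pytest.approx(
            brute, rel=1e-12)

    def test_run_durations_exponential(self):
        """Ground-truth run durations (kappa=0) pass a KS test against
        Exp(mean_run_duration) at the 1% level."""
        p = mt.SwimmerParams(n_swimmers=120, duration=60.0, mean_run_duration=1.0,
                             mean_tumble_duration=0.3, seed=21)
        tracks = mt.simulate_run_tumble(p)
        durations = []
        for tr in tracks:
            mask = tr.states
            n = len(mask)
            i = 0
            while i < n:
                j = i
                while j + 1 < n and mask[j + 1] == mask[i]:
                    j += 1
                if mask[i] and i > 0 and j < n - 1:  # uncensored runs only
                    durations.append((j - i + 1) * p.dt)
                i = j + 1
        durations = np.array(durations)
        assert len(durations) >= 5000
        ks = stats.kstest(durations, "expon", args=(0, 1.0)).statistic
        crit_1pct = 1.628 / np.sqrt(len(durations))
        assert ks < crit_1pct

    def test_speed_conserved_within_runs(self):
        p = mt.SwimmerParams(speed=15.0, n_swimmers=20, duration=20.0,
                             arena=(10000.0, 10000.0), seed=7)
        tracks = mt.simulate_run_tumble(p)
        for tr in tracks:
            run_step = tr.states[:-1] & tr.states[1:]
            # wall reflections fold a step; exclude the near-wall points
            margin = 2 * 15.0 * p.dt
            interior = ((tr.positions > margin) &
                        (tr.positions < 10000.0 - margin)).all(axis=1)
            run_step &= interior[:-1] & interior[1:]
            steps = np.diff(tr.positions, axis=0)[run_step]
            speeds = np.hypot(steps[:, 0], steps[:, 1]) / p.dt
            np.testing.assert_allclose(speeds, 15.0, rtol=0.01)

    def test_tumble_jitter_speed(self):
        p = mt.SwimmerParams(speed=15.0, mean_tumble_duration=0.5,
                             n_swimmers=20, duration=20.0, seed=8)
        tracks = mt.simulate_run_tumble(p)
        steps = np.concatenate([
            np.diff(tr.positions, axis=0)[~(tr.states[:-1] | tr.states[1:])]
            for tr in tracks])
        speeds = np.hypot(steps[:, 0], steps[:, 1]) / p.dt
        np.testing.assert_allclose(speeds, TUMBLE_JITTER_FRACTION * 15.0, rtol=0.01)

    def test_reflecting_walls_keep_swimmers_inside(self):
        p = mt.SwimmerParams(n_swimmers=50, duration=20.0, arena=(50.0, 50.0), seed=9)
        for tr in mt.simulate_run_tumble(p):
            assert tr.positions.min() >= 0
            assert tr.positions[:, 0].max() <= 50.0
            assert tr.positions[:, 1].max() <= 50.0


class TestBeads:
    def test_zero_d_stationary(self):
        tracks = mt.simulate_beads(mt.BeadParams(diffusion_coefficient=0.0,
                                                 n_beads=3, duration=1.0, seed=1))
        for tr in tracks:
            assert (tr.positions == tr.positions[0]).all()

    def test_increment_variance(self):
        p = mt.BeadParams(diffusion_coefficient=0.35, n_beads=50,
                          dt=0.02, duration=20.0, seed=2)
        incr = np.concatenate([np.diff(tr.positions, axis=0)
                               for tr in mt.simulate_beads(p)])
        assert incr.mean() == pytest.approx(0.0, abs=3 * incr.std() / np.sqrt(incr.size))
        assert incr.var() == pytest.approx(2 * 0.35 * 0.02, rel=0.10)

    def test_determinism(self):
        p = mt.BeadParams(n_beads=4, duration=1.0, seed=5)
        a, b = mt.simulate_beads(p), mt.simulate_beads(p)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_ensemble_msd_linear(self, bead_ensemble):
        """Ensemble MSD over the first 10 lags fits 4*D*tau with <5% slope error."""
        msd = np.zeros(10)
        for tr in bead_ensemble:
            for lag in range(1, 11):
                d = tr.positions[lag:] - tr.positions[:-lag]
                msd[lag - 1] += np.mean(np.sum(d * d, axis=1))
        msd /= len(bead_ensemble)
        tau = np.arange(1, 11) * 0.02
        slope = np.polyfit(tau, msd, 1)[0]
        assert slope == pytest.approx(4 * 0.35, rel=0.05)


class TestRenderMovie:
    def test_stationary_spot_argmax(self):
        from conftest import make_track
        rp = mt.RenderParams(noise_sd=0.0, seed=0)
        pos = np.array([40.3, 30.7]) * rp.pixel_size
        stack, truth = mt.render_movie([make_track([pos, pos])], rp, n_frames=2)
        for frame in stack.frames:
            r, c = np.unravel_index(np.argmax(frame), frame.shape)
            assert (c, r) == (40, 31)
        assert len(truth) == 2
        assert stack.pixel_size == rp.pixel_size
        assert stack.frame_rate == rp.frame_rate

    def test_empty_scene_is_background_noise(self):
        rp = mt.RenderParams(background=100.0, noise_sd=4.0, seed=1,
                             image_shape=(64, 64))
        stack, truth = mt.render_movie([], rp, n_frames=4)
        assert truth.empty
        assert stack.frames.mean() == pytest.approx(100.0, abs=1.0)
        assert stack.frames.std() == pytest.approx(4.0, abs=0.5)

    def test_out_of_view_error(self):
        from conftest import make_track
        rp = mt.RenderParams(out_of_view="error", image_shape=(32, 32), seed=0)
        far = np.array([1000.0, 1000.0])
        with pytest.raises(ValueError, match="outside"):
            mt.render_movie([make_track([far, far])], rp, n_frames=2)


class TestRotationTrace:
    def test_constant_without_signal_or_background(self):
        op = mt.OscillationParams(amplitude=0.0, brownian_background_D=0.0, seed=0)
        trace = mt.synth_rotation_trace(op)
        np.testing.assert_allclose(trace, op.offset)

    def test_determinism(self):
        op = mt.OscillationParams(seed=17)
        np.testing.assert_array_equal(mt.synth_rotation_trace(op),
                                      mt.synth_rotation_trace(op))

    def test_trace_length_and_offset(self):
        op = mt.OscillationParams(n_frames=256, seed=2)
        trace = mt.synth_rotation_trace(op)
        assert len(trace) == 256
        assert trace.mean() == pytest.approx(op.offset, abs=2.0)
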