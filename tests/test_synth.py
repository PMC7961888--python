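"""Generator: activation scripts, front-end model, force coupling, sessions."""

import numpy as np
import pytest
from scipy import signal

import myofeedback as mf
from myofeedback.errors import InvalidScriptError, ProtocolError, RateMismatchError


class TestBuildEnvelope:
    def test_empty_script_is_silence(self):
        env = mf.build_envelope(mf.ActivationScript(duration_s=1.0))
        assert env.values.shape == (2, 2000)
        assert not env.values.any()

    def test_square_segment_with_zero_rise(self):
        script = mf.ActivationScript(
            duration_s=1.0, segments=(mf.Segment("extensor", 0.0, 1.0, 1.0),),
            rise_s=0.0,
        )
        env = mf.build_envelope(script)
        assert np.all(env.channel("extensor") == 1.0)
        assert not env.channel("flexor").any()

    def test_linear_ramp_matches_closed_form(self):
        fs, level, rise, start, end = 1000.0, 0.5, 0.1, 0.5, 1.5
        script = mf.ActivationScript(
            duration_s=2.0, segments=(mf.Segment("extensor", start, end, level),),
            rise_s=rise,
        )
        tr = mf.build_envelope(script, fs_hz=fs).channel("extensor")
        t = np.arange(tr.size) / fs
        # closed-form trapezoid evaluated independently
        expected = level * np.clip(
            np.minimum((t - start) / rise, 1.0 - (t - end) / rise), 0.0, 1.0
        )
        np.testing.assert_allclose(tr, expected, atol=1e-12)
        i = int(round((start + rise) * fs))
        assert tr[i] == pytest.approx(level)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(InvalidScriptError):
            mf.ActivationScript(
                duration_s=2.0,
                segments=(mf.Segment("extensor", 0.0, 1.0, 0.5),
                          mf.Segment("extensor", 0.5, 1.5, 0.5)),
            )

    def test_out_of_range_level_rejected(self):
        with pytest.raises(InvalidScriptError):
            mf.ActivationScript(
                duration_s=1.0, segments=(mf.Segment("extensor", 0.0, 0.5, 1.5),)
            )


class TestSynthesizeEmg:
    def test_silence_with_zero_noise_floor_is_midpoint_code(self):
        model = mf.SensorModel(baseline_sd_v=0.0)
        env = mf.build_envelope(mf.ActivationScript(duration_s=0.5))
        rec = mf.synthesize_emg(env, model, seed=0)
        assert np.all(rec.samples == 2048)

    def test_counts_stay_in_quantizer_range(self, model):
        script = mf.ActivationScript(
            duration_s=2.0, segments=(mf.Segment("extensor", 0.0, 2.0, 1.0),
                                      mf.Segment("flexor", 0.0, 2.0, 1.0)),
        )
        rec = mf.synthesize_emg(mf.build_envelope(script), model, seed=3)
        assert rec.samples.min() >= 0
        assert rec.samples.max() <= model.full_scale
        assert np.issubdtype(rec.samples.dtype, np.integer)

    def test_rest_mean_sits_at_half_supply(self, rest_rec, model):
        volts = mf.counts_to_volts(rest_rec, model)
        assert volts.samples.mean() == pytest.approx(model.supply_v / 2, abs=0.01)

    def test_seed_determinism_is_bit_exact(self, model):
        env = mf.build_envelope(mf.ActivationScript(duration_s=0.5))
        a = mf.synthesize_emg(env, model, seed=42)
        b = mf.synthesize_emg(env, model, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = mf.synthesize_emg(env, model, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_rate_mismatch_rejected(self, model):
        env = mf.build_envelope(mf.ActivationScript(duration_s=0.5), fs_hz=1000.0)
        with pytest.raises(RateMismatchError):
            mf.synthesize_emg(env, model, seed=0)

    def test_spectrum_confined_to_shaping_band(self, model):
        script = mf.ActivationScript(
            duration_s=10.0, segments=(mf.Segment("extensor", 2.0, 8.0, 0.8),),
        )
        rec = mf.synthesize_emg(mf.build_envelope(script), model, seed=11)
        x = rec.channel("extensor").astype(float)
        x -= x.mean()
        f, pxx = signal.periodogram(x, fs=model.fs_hz)
        lo, hi = model.shaping_band
        in_band = pxx[(f >= lo) & (f <= hi)].sum()
        assert in_band / pxx.sum() >= 0.95

    def test_amplitude_monotone_in_activation(self, model):
        means = []
        for level in (0.0, 0.25, 0.5, 1.0):
            segs = (mf.Segment("extensor", 0.0, 2.0, level),) if level else ()
            env = mf.build_envelope(mf.ActivationScript(duration_s=2.0, segments=segs, rise_s=0.0))
            rec = mf.synthesize_emg(env, model, seed=5)
            filt = mf.bandpass(rec)
            means.append(np.abs(filt[0]).mean())
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_crosstalk_leaks_into_silent_channel(self):
        script = mf.ActivationScript(
            duration_s=2.0, segments=(mf.Segment("extensor", 0.0, 2.0, 1.0),),
        )
        env = mf.build_envelope(script)
        quiet = mf.synthesize_emg(env, mf.SensorModel(crosstalk=0.0), seed=9)
        leaky = mf.synthesize_emg(env, mf.SensorModel(crosstalk=0.3), seed=9)
        flex_rms = lambda r: np.abs(mf.bandpass(r)[1]).mean()
        assert flex_rms(leaky) > 5 * flex_rms(quiet)


class TestSynthesizeForce:
    def test_silence_gives_zero_force(self):
        env = mf.build_envelope(mf.ActivationScript(duration_s=1.0))
        force = mf.synthesize_force(env, mf.ForceModel(noise_sd=0.0), seed=0)
        assert not force.values.any()

    def test_step_response_matches_first_order_closed_form(self):
        fs, tau, level = 2000.0, 0.2, 0.8
        script = mf.ActivationScript(
            duration_s=2.0, segments=(mf.Segment("extensor", 0.0, 2.0, level),),
            rise_s=0.0,
        )
        env = mf.build_envelope(script, fs_hz=fs)
        fmodel = mf.ForceModel(weights={"extensor": 1.0}, tau_s=tau, noise_sd=0.0)
        force = mf.synthesize_force(env, fmodel, seed=0)
        k = int(round(tau * fs))
        assert force.values[k] == pytest.approx((1 - np.exp(-1)) * level, rel=0.01)

    def test_steady_state_gain_is_unity(self):
        script = mf.ActivationScript(
            duration_s=3.0, segments=(mf.Segment("extensor", 0.0, 3.0, 0.25),),
            rise_s=0.0,
        )
        env = mf.build_envelope(script)
        fmodel = mf.ForceModel(weights={"extensor": 1.0}, tau_s=0.1, noise_sd=0.0)
        force = mf.synthesize_force(env, fmodel, seed=0)
        assert force.values[-1] == pytest.approx(0.25, rel=1e-3)


class TestSimulatedRecordings:
    def test_grip_calibration_matches_brute_force_windowed_mean(self, model, grip_rec):
        profile = mf.calibrate_grip(grip_rec)
        # independent oracle: direct trailing 250-ms mean of the rectified
        # band-passed signal, maximum over time, via plain convolution
        filt = mf.bandpass(grip_rec)
        m = int(0.25 * model.fs_hz)
        w = np.ones(m) / m
        for i, ch in enumerate(grip_rec.channels):
            brute = np.convolve(np.abs(filt[i]), w, mode="valid").max()
            assert profile.amplitudes[ch] == pytest.approx(brute, rel=0.10)

    def test_zero_grip_amplitude_is_noise_floor(self, model):
        rec = mf.simulate_grip_recording(model, grip_level=0.0, seed=2)
        filt = mf.bandpass(rec)
        # rectified mean of pure baseline noise, referred to post-gain volts
        per_lsb = model.supply_v / model.full_scale
        assert np.abs(filt[0]).mean() * per_lsb < 5 * model.baseline_sd_v * model.gain

    def test_seeds_change_samples_not_summary_amplitude(self, model):
        a = mf.simulate_grip_recording(model, seed=21)
        b = mf.simulate_grip_recording(model, seed=22)
        assert not np.array_equal(a.samples, b.samples)
        amp_a = mf.calibrate_grip(a).amplitudes["extensor"]
        amp_b = mf.calibrate_grip(b).amplitudes["extensor"]
        assert amp_a == pytest.approx(amp_b, rel=0.15)

    def test_training_session_has_one_onset_per_trial(self, model, small_protocol):
        sim = mf.simulate_training_session(small_protocol, None, model, seed=1)
        assert len(sim.onsets) == small_protocol.n_trials
        assert sim.recording.duration_s > sim.onsets[-1] + small_protocol.trial_window_s

    def test_default_protocol_yields_100_trials(self):
        assert mf.TrainingProtocol().n_trials == 100

    def test_individuation_length_mismatch_rejected(self, model, small_protocol):
        with pytest.raises(ProtocolError):
            mf.simulate_training_session(small_protocol, [(0.5, 0.5)], model, seed=0)
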