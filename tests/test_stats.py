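"""Hold-phase ER extraction, paired tests, regressions, trends, exclusions."""

import numpy as np
import pytest
from scipy import stats as sps

import myofeedback as mf
from myofeedback.errors import CalibrationError, DegenerateDataError, ProtocolError


def _const_env(ext, flex, n=20000, fs=2000.0):
    return mf.Envelope(fs_hz=fs, channels=("extensor", "flexor"),
                       values=np.vstack([np.full(n, ext), np.full(n, flex)]))


def _trial(i, er=0.6, ext=0.6, flex=0.4, pts=20, degenerate=False):
    return mf.TrialResult(index=i, onset_s=float(i), er=er, ext_mean=ext,
                          flex_mean=flex, points=pts, bin=2, degenerate=degenerate)


class TestHoldEr:
    def test_equal_constant_envelopes_give_half(self):
        series, means = mf.hold_er_series(_const_env(0.3, 0.3), [(0.0, 2.0), (4.0, 6.0)])
        assert all(np.all(s == 0.5) for s in series)
        np.testing.assert_allclose(means, 0.5)

    def test_extensor_only_gives_one(self):
        _, means = mf.hold_er_series(_const_env(0.7, 0.0), [(1.0, 3.0)])
        np.testing.assert_allclose(means, 1.0)

    def test_one_mean_per_interval(self):
        p = mf.RampHoldProtocol()
        env = _const_env(0.4, 0.4, n=int(p.duration_s * 2000))
        _, means = mf.hold_er_series(env, mf.hold_intervals(p))
        assert means.shape == (12,)

    def test_empty_interval_rejected(self):
        with pytest.raises(ProtocolError):
            mf.hold_er_series(_const_env(0.5, 0.5), [(2.0, 2.0)])


class TestPairedT:
    def test_textbook_three_pair_example(self):
        # differences 1, 2, 3: mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 3.464, df = 2
        b = np.array([5.0, 5.0, 5.0])
        a = b + np.array([1.0, 2.0, 3.0])
        t, p = mf.paired_t(a, b)
        assert t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-3)
        assert p == pytest.approx(2 * sps.t.sf(3.4641, df=2), rel=1e-3)

    def test_identical_samples_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateDataError):
            mf.paired_t(x, x)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.5, 0.05, size=12)
        b = a + 0.2 + rng.normal(0, 0.01, size=12)
        t, p = mf.paired_t(b, a)
        assert t > 10 and p < 1e-6


class TestRampRegression:
    def test_exact_linear_coupling_recovered(self):
        n = 4000
        act = np.linspace(0, 1, n)
        env = mf.Envelope(fs_hz=2000.0, channels=("extensor", "flexor"),
                          values=np.vstack([act, act * 0.5]))
        force = 1.5 * act
        out = mf.ramp_regression(env, force, [(0.0, 2.0)])
        assert out["extensor"].slope == pytest.approx(1.5)
        assert out["extensor"].r2 == pytest.approx(1.0)
        assert out["flexor"].slope == pytest.approx(3.0)

    def test_matches_normal_equations_on_noisy_data(self):
        rng = np.random.default_rng(5)
        act = rng.uniform(0, 1, 3000)
        force = 0.8 * act + rng.normal(0, 0.1, 3000)
        env = mf.Envelope(fs_hz=1000.0, channels=("extensor", "flexor"),
                          values=np.vstack([act, act + rng.uniform(0.01, 0.02, 3000)]))
        out = mf.ramp_regression(env, force, [(0.0, 3.0)])
        X = np.c_[act, np.ones_like(act)]
        beta = np.linalg.solve(X.T @ X, X.T @ force)  # brute-force normal equations
        assert out["extensor"].slope == pytest.approx(beta[0], rel=1e-9)
        assert out["extensor"].intercept == pytest.approx(beta[1], rel=1e-6, abs=1e-9)

    def test_constant_predictor_rejected(self):
        env = _const_env(0.5, 0.5, n=1000)
        with pytest.raises(DegenerateDataError):
            mf.ramp_regression(env, np.linspace(0, 1, 1000), [(0.0, 0.5)])

    def test_r2_degrades_with_force_noise(self, model):
        p = mf.RampHoldProtocol(n_trials=3)
        r2 = []
        for noise in (0.005, 0.05, 0.2):
            sim = mf.simulate_validation_session(
                p, model, mf.ForceModel(noise_sd=noise), seed=9
            )
            prof = mf.calibrate_grip(mf.simulate_grip_recording(model, seed=9))
            env = mf.process(sim.recording, prof, mf.VALIDATION_CONFIG)
            out = mf.ramp_regression(env, sim.force.values, mf.ramp_intervals(p))
            r2.append(out["extensor"].r2)
        assert r2[0] > 0.8
        assert r2[0] > r2[1] > r2[2]


class TestSummaries:
    def test_identical_trials_average_to_their_value(self):
        s = mf.summarize_session([_trial(i) for i in range(100)], index=3)
        assert s.er_mean == pytest.approx(0.6)
        assert s.n_trials == 100 and not s.excluded
        assert s.score == pytest.approx(2000)

    def test_mean_matches_brute_force_sum(self):
        rng = np.random.default_rng(8)
        trials = [_trial(i, er=float(rng.uniform()), ext=float(rng.uniform()),
                         flex=float(rng.uniform()), pts=int(rng.integers(0, 30)))
                  for i in range(37)]
        s = mf.summarize_session(trials, index=0)
        assert s.er_mean == pytest.approx(sum(t.er for t in trials) / 37)
        assert s.ext_mean == pytest.approx(sum(t.ext_mean for t in trials) / 37)

    def test_empty_session_rejected_unless_excluded(self):
        with pytest.raises(ProtocolError):
            mf.summarize_session([], index=0)
        s = mf.summarize_session([], index=0, excluded=True, reason="missing data")
        assert s.excluded and s.reason == "missing data"

    def test_all_degenerate_session_is_flagged(self):
        trials = [_trial(i, degenerate=True) for i in range(5)]
        s = mf.summarize_session(trials, index=1)
        assert s.excluded and "degenerate" in s.reason


class TestTrend:
    @staticmethod
    def _summaries(values, excluded=None):
        excluded = excluded or set()
        return [
            mf.SessionSummary(session_index=i, er_mean=float(v), ext_mean=float(v),
                              flex_mean=float(v), n_trials=10,
                              score=float(v), excluded=i in excluded,
                              reason="x" if i in excluded else None)
            for i, v in enumerate(values)
        ]

    def test_strictly_increasing_field_has_unit_correlation(self):
        tr = mf.longitudinal_trend(self._summaries(np.linspace(0.4, 0.7, 10)))
        assert tr.rho == pytest.approx(1.0)
        assert tr.n == 10

    def test_constant_field_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            mf.longitudinal_trend(self._summaries([0.5] * 10))

    def test_too_few_sessions_rejected(self):
        with pytest.raises(DegenerateDataError):
            mf.longitudinal_trend(self._summaries([0.1, 0.2]))

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.3, 0.7, 20)
        t1 = mf.longitudinal_trend(self._summaries(vals))
        t2 = mf.longitudinal_trend(self._summaries(0.25 * vals + 0.1))
        assert t1.rho == pytest.approx(t2.rho, abs=1e-12)
        assert t1.p == pytest.approx(t2.p, rel=1e-9)

    def test_excluded_sessions_never_contribute(self):
        vals = list(np.linspace(0.4, 0.7, 12))
        clean = mf.longitudinal_trend(self._summaries(vals + [0.0],
                                                      excluded={12}))
        base = mf.longitudinal_trend(self._summaries(vals))
        assert clean.n == 12
        assert clean.rho == pytest.approx(base.rho)

    def test_zero_drift_null_rejection_rate_is_nominal(self):
        # under no real change across sessions, ~5% of trends reject at alpha=0.05
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            vals = 0.5 + rng.normal(0, 0.05, 40)
            tr = mf.longitudinal_trend(self._summaries(vals))
            rejections += tr.p < 0.05
        assert 0.035 <= rejections / 1000 <= 0.065


class TestExclusions:
    def test_clean_session_not_excluded(self, grip_rec, profile):
        flags = mf.flag_exclusions([(grip_rec, profile)])
        assert not flags[0].excluded

    def test_missing_data_and_channels_flagged(self, grip_rec, profile):
        one_ch = mf.EmgRecording(grip_rec.fs_hz, ("extensor",),
                                 grip_rec.samples[:1], units="counts")
        flags = mf.flag_exclusions([
            (None, profile),
            (one_ch, profile),
            (grip_rec, CalibrationError("channel 'flexor' appears silent")),
        ])
        assert [f.excluded for f in flags] == [True, True, True]
        assert "missing data" in flags[0].reason
        assert "flexor" in flags[1].reason
        assert "calibration failure" in flags[2].reason

    def test_noisy_session_excluded_by_ceiling(self, model):
        noisy_model = mf.SensorModel(baseline_sd_v=10 * model.baseline_sd_v)
        rec = mf.simulate_grip_recording(noisy_model, seed=17)
        prof = mf.calibrate_grip(rec)
        clean = mf.simulate_grip_recording(model, seed=17)
        clean_prof = mf.calibrate_grip(clean)
        flags = mf.flag_exclusions([(rec, prof), (clean, clean_prof)])
        assert flags[0].excluded and "noise" in flags[0].reason
        assert not flags[1].excluded
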