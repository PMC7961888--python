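"""End-to-end simulated studies: signal synthesis through session statistics.

These orchestration helpers wire the generator, the conditioning chain,
the scoring engine and the statistics together, so a whole training study
or a sensor-validation experiment can be run from a single seed.  They are
what the command-line ``play``, ``validate`` and ``trend`` commands, the
examples, and the parameter-recovery tests call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .games import DEFAULT_SCORE_TABLE, ScoreTable, SessionLog, play_session
from .pipeline import (
    VALIDATION_CONFIG,
    CalibrationProfile,
    PipelineConfig,
    calibrate_grip,
    process,
)
from .protocols import RampHoldProtocol, TrainingProtocol, hold_intervals, ramp_intervals
from .sensor import SensorModel
from .stats import (
    RegressionResult,
    SessionSummary,
    hold_er_series,
    paired_t,
    ramp_regression,
    summarize_session,
)
from .synth import (
    ForceModel,
    simulate_grip_recording,
    simulate_training_session,
    simulate_validation_session,
)


def _seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


@dataclass
class SimulatedSession:
    """One simulated, processed and scored training session."""

    log: SessionLog
    summary: SessionSummary
    profile: CalibrationProfile


def run_training_session(
    session_index: int = 0,
    individuation: list[tuple[float, float]] | None = None,
    protocol: TrainingProtocol | None = None,
    model: SensorModel | None = None,
    table: ScoreTable = DEFAULT_SCORE_TABLE,
    cfg: PipelineConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> SimulatedSession:
    """Simulate one training session and run it through the full chain.

    A reference grip is simulated first (same sensor, its own noise
    realization) and used to calibrate; the session recording is then
    processed and every trial scored.
    """
    protocol = protocol or TrainingProtocol()
    model = model or SensorModel()
    cfg = cfg or PipelineConfig()
    ss = _seedseq(seed)
    grip_ss, sess_ss, game_ss = ss.spawn(3)
    grip = simulate_grip_recording(model, grip_level=1.0, seed=grip_ss)
    profile = calibrate_grip(grip, cfg)
    sim = simulate_training_session(protocol, individuation, model, seed=sess_ss)
    env = process(sim.recording, profile, cfg)
    rng = np.random.default_rng(game_ss)
    log = play_session(env, sim.onsets, table, rng, window_s=protocol.trial_window_s)
    summary = summarize_session(log.trials, session_index)
    return SimulatedSession(log=log, summary=summary, profile=profile)


def run_longitudinal_study(
    n_sessions: int = 40,
    er_start: float = 0.5,
    er_end: float = 0.7,
    protocol: TrainingProtocol | None = None,
    model: SensorModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[SessionSummary]:
    """Simulate a multi-session study with linearly drifting individuation.

    The participant's target extensor ratio drifts linearly from
    ``er_start`` to ``er_end`` across sessions (activation pairs are
    ``(r, 1 - r)`` scaled to a 0.8 summed drive), emulating gradually
    improving individuation while total effort stays constant.
    """
    protocol = protocol or TrainingProtocol()
    ss = _seedseq(seed)
    children = ss.spawn(n_sessions)
    ratios = np.linspace(er_start, er_end, n_sessions)
    summaries = []
    for k, (r, child) in enumerate(zip(ratios, children)):
        pairs = [(0.8 * r, 0.8 * (1 - r))] * protocol.n_trials
        sess = run_training_session(
            session_index=k, individuation=pairs, protocol=protocol, model=model,
            seed=child,
        )
        summaries.append(sess.summary)
    return summaries


@dataclass
class ValidationReport:
    """Paired comparison of two sensors on the isometric ramp–hold task."""

    er_means_a: np.ndarray
    er_means_b: np.ndarray
    t: float
    p: float
    regressions_a: dict[str, RegressionResult]
    regressions_b: dict[str, RegressionResult]


def run_validation_study(
    protocol: RampHoldProtocol | None = None,
    model_a: SensorModel | None = None,
    model_b: SensorModel | None = None,
    fmodel: ForceModel | None = None,
    cfg: PipelineConfig = VALIDATION_CONFIG,
    seed: int | np.random.SeedSequence = 0,
) -> ValidationReport:
    """Simulate the same ramp–hold task with two sensor models and compare.

    Per device: simulate the 12-trial session, calibrate on a simulated
    grip, extract hold-phase ER (one mean per trial), then a paired t-test
    across the per-trial means and per-muscle EMG–force regressions over
    the ramps.
    """
    protocol = protocol or RampHoldProtocol()
    model_a = model_a or SensorModel()
    model_b = model_b or model_a
    ss = _seedseq(seed)
    holds = hold_intervals(protocol)
    ramps = ramp_intervals(protocol)
    results = []
    for model, child in zip((model_a, model_b), ss.spawn(2)):
        grip_ss, sess_ss = child.spawn(2)
        grip = simulate_grip_recording(model, grip_level=1.0, seed=grip_ss)
        profile = calibrate_grip(grip, cfg)
        sim = simulate_validation_session(protocol, model, fmodel, seed=sess_ss)
        env = process(sim.recording, profile, cfg)
        _, means = hold_er_series(env, holds)
        regs = ramp_regression(env, sim.force.values, ramps)
        results.append((means, regs))
    (means_a, regs_a), (means_b, regs_b) = results
    t, p = paired_t(means_a, means_b)
    return ValidationReport(
        er_means_a=means_a, er_means_b=means_b, t=t, p=p,
        regressions_a=regs_a, regressions_b=regs_b,
    )
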