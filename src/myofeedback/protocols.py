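"""Timed experimental protocols.

Two protocols are encoded:

* the isometric *ramp–hold* validation task — 5 s linear build-up to 25 %
  of maximum grip force, 5 s hold, 7 s rest, repeated 12 times (17 s per
  trial);
* the *training session* structure — 5 blocks of 20 movement-attempt
  repetitions (100 trials), with short rests between trials and 1–2 min
  between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np


class TrialEpochs(NamedTuple):
    """Half-open intervals ``[start, end)`` in seconds for one trial."""

    ramp: tuple[float, float]
    hold: tuple[float, float]
    rest: tuple[float, float]


@dataclass(frozen=True)
class RampHoldProtocol:
    """Isometric force-tracking task: ramp to a target, hold it, rest."""

    ramp_s: float = 5.0
    hold_s: float = 5.0
    rest_s: float = 7.0
    target_frac: float = 0.25
    n_trials: int = 12
    #: analysis-time trim at the start of each hold, to skip ramp overshoot
    hold_trim_s: float = 0.5

    def __post_init__(self) -> None:
        if min(self.ramp_s, self.hold_s, self.rest_s) <= 0:
            raise ValueError("all phase durations must be positive")
        if not (0 < self.target_frac <= 1):
            raise ValueError("target_frac must lie in (0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.hold_trim_s < 0 or self.hold_trim_s >= self.hold_s:
            raise ValueError("hold_trim_s must lie in [0, hold_s)")

    @property
    def trial_s(self) -> float:
        """Duration of one trial (the cursor's screen sweep)."""
        return self.ramp_s + self.hold_s + self.rest_s

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.trial_s


def target_trace(p: RampHoldProtocol, fs_hz: float) -> np.ndarray:
    """Force target (fraction of MVC) for the whole session.

    Linear 0 → ``target_frac`` over the ramp, constant over the hold, zero
    over the rest, repeated ``n_trials`` times.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    n_trial = int(round(p.trial_s * fs_hz))
    t = np.arange(n_trial) / fs_hz
    one = np.zeros(n_trial)
    ramp = t < p.ramp_s
    one[ramp] = p.target_frac * t[ramp] / p.ramp_s
    hold = (t >= p.ramp_s) & (t < p.ramp_s + p.hold_s)
    one[hold] = p.target_frac
    return np.tile(one, p.n_trials)


def epoch_boundaries(p: RampHoldProtocol) -> list[TrialEpochs]:
    """Labeled (ramp, hold, rest) intervals for every trial, in seconds."""
    out = []
    for k in range(p.n_trials):
        t0 = k * p.trial_s
        out.append(
            TrialEpochs(
                ramp=(t0, t0 + p.ramp_s),
                hold=(t0 + p.ramp_s, t0 + p.ramp_s + p.hold_s),
                rest=(t0 + p.ramp_s + p.hold_s, t0 + p.trial_s),
            )
        )
    return out


def hold_intervals(p: RampHoldProtocol, trimmed: bool = True) -> list[tuple[float, float]]:
    """Hold-phase intervals for analysis, with the leading trim applied."""
    trim = p.hold_trim_s if trimmed else 0.0
    return [(h[0] + trim, h[1]) for h in (e.hold for e in epoch_boundaries(p))]


def ramp_intervals(p: RampHoldProtocol) -> list[tuple[float, float]]:
    return [e.ramp for e in epoch_boundaries(p)]


@dataclass(frozen=True)
class TrainingProtocol:
    """Blocked movement-attempt training session."""

    blocks: int = 5
    reps_per_block: int = 20
    trial_window_s: float = 2.0
    inter_trial_rest_s: float = 3.0
    inter_block_rest_s: float = 90.0

    def __post_init__(self) -> None:
        if self.blocks < 1 or self.reps_per_block < 1:
            raise ValueError("blocks and reps_per_block must be >= 1")
        if self.trial_window_s <= 0:
            raise ValueError("trial_window_s must be positive")
        if self.inter_trial_rest_s < 0 or self.inter_block_rest_s < 0:
            raise ValueError("rest durations must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.blocks * self.reps_per_block

    @property
    def trial_period_s(self) -> float:
        return self.trial_window_s + self.inter_trial_rest_s


def training_onsets(p: TrainingProtocol) -> tuple[list[float], list[float]]:
    """Trial onset times and block start times, in seconds from session start."""
    onsets: list[float] = []
    block_starts: list[float] = []
    t = 0.0
    for _ in range(p.blocks):
        block_starts.append(t)
        for _ in range(p.reps_per_block):
            onsets.append(t)
            t += p.trial_period_s
        t += p.inter_block_rest_s
    return onsets, block_starts
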