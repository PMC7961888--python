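"""Statistical analyses of validation and training sessions.

Covers the two study designs the library supports:

* *sensor validation* — extensor-ratio distributions during isometric grip
  holds compared between two recordings with a paired t-test, and
  EMG–force linear regressions over the ramp phases;
* *longitudinal training* — per-session means of normalized extensor
  activity, flexor activity and ER across trials, with Pearson
  correlations against session number to test for changes over time.

All p-values are two-sided and uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import CalibrationError, DegenerateDataError, ProtocolError
from .games import DENOM_FLOOR, TrialResult
from .pipeline import Envelope, PipelineConfig, process
from .recording import DEFAULT_CHANNELS, EmgRecording


@dataclass
class SessionSummary:
    """Per-session averages across trials."""

    session_index: int
    ext_mean: float = float("nan")
    flex_mean: float = float("nan")
    er_mean: float = float("nan")
    n_trials: int = 0
    score: float | None = None
    excluded: bool = False
    reason: str | None = None


@dataclass
class TrendResult:
    """Pearson correlation of a session-level field against session number."""

    rho: float
    p: float
    n: int


@dataclass
class RegressionResult:
    """Ordinary least-squares line of force on normalized activity."""

    slope: float
    intercept: float
    r2: float


def _interval_slice(interval: tuple[float, float], fs_hz: float, n: int) -> slice:
    i0 = int(round(interval[0] * fs_hz))
    i1 = int(round(interval[1] * fs_hz))
    if i0 < 0 or i1 > n or i1 <= i0:
        raise ProtocolError(f"interval {interval} s outside the recording")
    return slice(i0, i1)


def hold_er_series(
    env: Envelope,
    intervals: list[tuple[float, float]],
    ext_channel: str = "extensor",
    flex_channel: str = "flexor",
) -> tuple[list[np.ndarray], np.ndarray]:
    """Pointwise ER inside every hold interval, plus one mean per trial.

    Pointwise ER is ``ext(t) / (ext(t) + flex(t))``; samples with a
    near-zero denominator are reported as 0.5.
    """
    ext = env.channel(ext_channel)
    flex = env.channel(flex_channel)
    per_trial: list[np.ndarray] = []
    for iv in intervals:
        s = _interval_slice(iv, env.fs_hz, env.n_samples)
        e, f = ext[s], flex[s]
        total = e + f
        er = np.where(total < DENOM_FLOOR, 0.5, e / np.where(total < DENOM_FLOOR, 1.0, total))
        per_trial.append(er)
    means = np.array([er.mean() for er in per_trial])
    return per_trial, means


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classical paired Student t-test on ``a - b``; two-sided p, n−1 df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise DegenerateDataError("paired_t needs two equal-length 1-d arrays, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateDataError(
            "paired differences have zero variance; the t statistic is undefined"
        )
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def ramp_regression(
    env: Envelope,
    force: np.ndarray,
    intervals: list[tuple[float, float]],
) -> dict[str, RegressionResult]:
    """OLS of force on normalized activity, pooled over ramp epochs, per muscle."""
    force = np.asarray(force, dtype=float)
    if force.shape[-1] != env.n_samples:
        raise ProtocolError("force trace and envelope must be aligned sample-for-sample")
    slices = [_interval_slice(iv, env.fs_hz, env.n_samples) for iv in intervals]
    f = np.concatenate([force[s] for s in slices])
    out: dict[str, RegressionResult] = {}
    for ch in env.channels:
        x = np.concatenate([env.channel(ch)[s] for s in slices])
        if np.ptp(x) == 0:
            raise DegenerateDataError(f"activity on channel {ch!r} is constant")
        fit = sps.linregress(x, f)
        out[ch] = RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r2=float(fit.rvalue**2),
        )
    return out


def summarize_session(
    trials: list[TrialResult],
    index: int,
    excluded: bool = False,
    reason: str | None = None,
) -> SessionSummary:
    """Arithmetic means of per-trial activity and ER for one session.

    A session whose trials are all degenerate (no measurable activity) is
    flagged as excluded rather than averaged.
    """
    if excluded:
        return SessionSummary(session_index=index, excluded=True, reason=reason)
    if not trials:
        raise ProtocolError(f"session {index} has no trials and is not excluded")
    if all(t.degenerate for t in trials):
        return SessionSummary(
            session_index=index, n_trials=len(trials),
            excluded=True, reason="all trials degenerate",
        )
    return SessionSummary(
        session_index=index,
        ext_mean=float(np.mean([t.ext_mean for t in trials])),
        flex_mean=float(np.mean([t.flex_mean for t in trials])),
        er_mean=float(np.mean([t.er for t in trials])),
        n_trials=len(trials),
        score=float(sum(t.points for t in trials)),
    )


def longitudinal_trend(
    summaries: list[SessionSummary],
    field: str = "er_mean",
) -> TrendResult:
    """Pearson correlation of ``field`` against session index, excluded sessions dropped."""
    if field not in ("er_mean", "ext_mean", "flex_mean", "score"):
        raise ValueError(f"unknown trend field {field!r}")
    usable = [s for s in summaries if not s.excluded]
    if len(usable) < 3:
        raise DegenerateDataError(
            f"need at least 3 non-excluded sessions, have {len(usable)}"
        )
    x = np.array([s.session_index for s in usable], dtype=float)
    y = np.array([getattr(s, field) for s in usable], dtype=float)
    if np.any(np.isnan(y)):
        raise DegenerateDataError(f"field {field!r} contains NaN in a usable session")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise DegenerateDataError(f"field {field!r} is constant; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TrendResult(rho=float(r), p=float(p), n=len(usable))


@dataclass
class ExclusionFlag:
    excluded: bool
    reason: str | None = None


def flag_exclusions(
    sessions,
    cfg: PipelineConfig | None = None,
    noise_ceiling: float = 0.02,
    rest_interval: tuple[float, float] = (0.0, 0.5),
    required_channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> list[ExclusionFlag]:
    """Operational exclusion rules for recorded sessions.

    ``sessions`` is an iterable of ``(recording, profile)`` pairs where
    either element may be ``None`` (missing data) and the profile may be a
    :class:`CalibrationError` captured while calibrating.  A session is
    excluded when data or channels are missing, calibration failed, or the
    normalized envelope over the leading rest epoch exceeds
    ``noise_ceiling`` (excessive noise).
    """
    cfg = cfg or PipelineConfig()
    flags: list[ExclusionFlag] = []
    for rec, profile in sessions:
        if rec is None or profile is None:
            flags.append(ExclusionFlag(True, "missing data"))
            continue
        if isinstance(profile, CalibrationError):
            flags.append(ExclusionFlag(True, f"calibration failure: {profile}"))
            continue
        missing = [ch for ch in required_channels if ch not in rec.channels]
        if missing:
            flags.append(ExclusionFlag(True, f"missing data: channels {missing}"))
            continue
        env = process(rec, profile, cfg)
        s = _interval_slice(rest_interval, env.fs_hz, env.n_samples)
        rest_level = float(env.values[:, s].mean(axis=1).max())
        if rest_level > noise_ceiling:
            flags.append(ExclusionFlag(
                True, f"excessive noise: rest envelope {rest_level:.3g} > {noise_ceiling}"
            ))
            continue
        flags.append(ExclusionFlag(False, None))
    return flags
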