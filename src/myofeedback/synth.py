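"""Synthetic surface-EMG generation.

The generative model is the standard phenomenological one for surface EMG:
band-limited Gaussian noise whose instantaneous amplitude is modulated by
the muscle's activation level.  Per channel, the electrode-referred signal
is

    x(t) = n(t) * (baseline_sd_v + a(t) * max_emg_sd_v)

where ``n`` is unit-variance white noise shaped to the sensor model's
``shaping_band`` (default 20–450 Hz) and ``a(t)`` in [0, 1] is the
activation envelope.  Optional linear crosstalk mixes a fraction of each
channel's pre-gain signal into the other.  The front-end then amplifies,
offsets to mid-supply, saturates at the rails, and quantizes — see
:class:`~myofeedback.sensor.SensorModel`.

Grip force is coupled to activation by a first-order linear model: a
weighted sum of channel activations passed through a low-pass with time
constant ``tau_s`` plus additive Gaussian noise, clipped at zero.  This is
deliberately the simplest coupling that reproduces linear EMG–force
behavior during slow isometric ramps; it makes no claim about contraction
dynamics.

All randomness flows from a single caller-supplied seed through
``numpy.random.SeedSequence``; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InvalidScriptError, ProtocolError, RateMismatchError
from .protocols import RampHoldProtocol, TrainingProtocol, target_trace, training_onsets
from .recording import COUNTS, DEFAULT_CHANNELS, EmgRecording
from .sensor import SensorModel


@dataclass(frozen=True)
class Segment:
    """One constant-level activation epoch on one channel."""

    channel: str
    start_s: float
    end_s: float
    level: float


@dataclass(frozen=True)
class ActivationScript:
    """Piecewise-constant activation plan with linear transitions.

    Stands in for the participant's volitional activation: each segment
    holds ``level`` on ``channel`` over ``[start_s, end_s)``, with linear
    rise/fall ramps of width ``rise_s`` attached outside the plateau.
    """

    duration_s: float
    segments: tuple[Segment, ...] = ()
    rise_s: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        ))
        if self.duration_s <= 0:
            raise InvalidScriptError("duration_s must be positive")
        if self.rise_s < 0:
            raise InvalidScriptError("rise_s must be nonnegative")
        per_channel: dict[str, list[Segment]] = {}
        for s in self.segments:
            if not (0 <= s.start_s < s.end_s <= self.duration_s):
                raise InvalidScriptError(
                    f"segment {s} outside [0, {self.duration_s}] or empty"
                )
            if not (0 <= s.level <= 1):
                raise InvalidScriptError(f"segment level {s.level} outside [0, 1]")
            per_channel.setdefault(s.channel, []).append(s)
        for ch, segs in per_channel.items():
            segs = sorted(segs, key=lambda s: s.start_s)
            for a, b in zip(segs, segs[1:]):
                if b.start_s < a.end_s:
                    raise InvalidScriptError(
                        f"overlapping segments on channel {ch!r}: {a} and {b}"
                    )


@dataclass
class ActivationTraces:
    """Per-channel activation in [0, 1], uniformly sampled."""

    fs_hz: float
    channels: tuple[str, ...]
    values: np.ndarray  # (n_channels, n_samples)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channels.index(label)]


@dataclass(frozen=True)
class ForceModel:
    """First-order linear activation→grip-force coupling.

    ``weights`` maps channel label to its contribution to force (fraction
    of MVC per unit activation); ``tau_s`` is the low-pass time constant;
    ``noise_sd`` the additive force noise, as a fraction of MVC.
    """

    weights: dict = field(default_factory=lambda: {"extensor": 0.5, "flexor": 0.5})
    tau_s: float = 0.1
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class ForceTrace:
    """Exerted grip force as a fraction of MVC."""

    fs_hz: float
    values: np.ndarray


def build_envelope(
    script: ActivationScript,
    fs_hz: float = 2000.0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> ActivationTraces:
    """Render an activation script to per-channel traces in [0, 1].

    Inside each segment's plateau the trace equals the segment level
    exactly; edges are linear: the trace rises from zero at ``start_s`` to
    the level at ``start_s + rise_s`` and falls back to zero over
    ``rise_s`` after ``end_s``.  Overlapping ramp tails from adjacent
    segments combine by pointwise maximum.
    """
    ordered = list(channels)
    for s in script.segments:
        if s.channel not in ordered:
            ordered.append(s.channel)
    n = int(round(script.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    values = np.zeros((len(ordered), n))
    for s in script.segments:
        i = ordered.index(s.channel)
        tr = np.zeros(n)
        if script.rise_s > 0:
            # rising edge: 0 at start_s, level at start_s + rise_s
            rise = np.clip((t - s.start_s) / script.rise_s, 0.0, 1.0)
            fall = np.clip(1.0 - (t - s.end_s) / script.rise_s, 0.0, 1.0)
            tr = s.level * np.minimum(rise, fall)
        else:
            tr[(t >= s.start_s) & (t < s.end_s)] = s.level
        np.maximum(values[i], tr, out=values[i])
    return ActivationTraces(fs_hz=fs_hz, channels=tuple(ordered), values=values)


def _shaped_noise(n: int, fs_hz: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``.

    An 8th-order Butterworth keeps >95% of the power inside the shaping
    band; a gentler filter would leak appreciable skirt power outside it.
    """
    sos = signal.butter(8, band, btype="bandpass", fs=fs_hz, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def synthesize_emg(
    envelope: ActivationTraces,
    model: SensorModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> EmgRecording:
    """Pass activation traces through the generative model and the front-end.

    Returns an integer-count recording; reproducible bit-for-bit given the
    same inputs and seed.
    """
    model = model or SensorModel()
    if abs(envelope.fs_hz - model.fs_hz) > 1e-9:
        raise RateMismatchError(
            f"envelope rate {envelope.fs_hz} Hz != sensor rate {model.fs_hz} Hz"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_ch, n = envelope.values.shape
    pre_gain = np.empty((n_ch, n))
    for i, child in enumerate(ss.spawn(n_ch)):
        rng = np.random.default_rng(child)
        carrier = _shaped_noise(n, model.fs_hz, model.shaping_band, rng)
        amp = model.baseline_sd_v + envelope.values[i] * model.max_emg_sd_v
        pre_gain[i] = carrier * amp
    if model.crosstalk > 0 and n_ch > 1:
        mixed = pre_gain.copy()
        total = pre_gain.sum(axis=0)
        for i in range(n_ch):
            mixed[i] = pre_gain[i] + model.crosstalk * (total - pre_gain[i])
        pre_gain = mixed
    v = model.gain * pre_gain + model.midpoint_v
    np.clip(v, 0.0, model.supply_v, out=v)
    counts = np.round(v / model.supply_v * model.full_scale).astype(np.int32)
    entropy = ss.entropy
    return EmgRecording(
        fs_hz=model.fs_hz,
        channels=envelope.channels,
        samples=counts,
        units=COUNTS,
        meta={"sensor": model.to_dict(), "seed_entropy": int(entropy) if isinstance(entropy, int) else list(entropy)},
    )


def synthesize_force(
    envelope: ActivationTraces,
    fmodel: ForceModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ForceTrace:
    """Grip force from activation: low-passed weighted sum plus noise, clipped at 0."""
    fmodel = fmodel or ForceModel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    drive = np.zeros(envelope.n_samples)
    for i, ch in enumerate(envelope.channels):
        drive += fmodel.weights.get(ch, 0.0) * envelope.values[i]
    dt = 1.0 / envelope.fs_hz
    # exact zero-order-hold discretization of dy/dt = (x - y)/tau
    a = 1.0 - np.exp(-dt / fmodel.tau_s)
    force = signal.lfilter([a], [1.0, a - 1.0], drive)
    if fmodel.noise_sd > 0:
        force = force + rng.normal(0.0, fmodel.noise_sd, size=force.shape)
    return ForceTrace(fs_hz=envelope.fs_hz, values=np.clip(force, 0.0, None))


def simulate_grip_recording(
    model: SensorModel | None = None,
    grip_level: float = 1.0,
    duration_s: float = 3.0,
    rest_pad_s: float = 1.0,
    rise_s: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
) -> EmgRecording:
    """A calibration-style recording: both channels co-activated at ``grip_level``.

    The grip (default 3 s) is flanked by rest padding so downstream
    calibration can measure the noise floor from the leading rest epoch.
    """
    model = model or SensorModel()
    if not (0 <= grip_level <= 1):
        raise ValueError("grip_level must lie in [0, 1]")
    total = duration_s + 2 * rest_pad_s
    segs = []
    if grip_level > 0:
        segs = [
            Segment(ch, rest_pad_s, rest_pad_s + duration_s, grip_level)
            for ch in DEFAULT_CHANNELS
        ]
    script = ActivationScript(duration_s=total, segments=tuple(segs), rise_s=rise_s)
    env = build_envelope(script, fs_hz=model.fs_hz)
    rec = synthesize_emg(env, model, seed)
    rec.meta.update({"kind": "grip", "grip_level": grip_level, "grip_s": duration_s, "rest_pad_s": rest_pad_s})
    return rec


@dataclass
class TrainingSim:
    """One simulated training session."""

    recording: EmgRecording
    onsets: list[float]
    force: ForceTrace | None = None


def simulate_training_session(
    protocol: TrainingProtocol | None = None,
    individuation: list[tuple[float, float]] | None = None,
    model: SensorModel | None = None,
    fmodel: ForceModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    rise_s: float = 0.1,
) -> TrainingSim:
    """Simulate a blocked training session of movement attempts.

    ``individuation`` gives one (extensor level, flexor level) pair per
    trial; each pair drives both channels for the protocol's trial window
    at its onset.  Returns the raw recording plus the ground-truth onsets
    for downstream trial extraction.
    """
    protocol = protocol or TrainingProtocol()
    if individuation is None:
        individuation = [(0.5, 0.5)] * protocol.n_trials
    if len(individuation) != protocol.n_trials:
        raise ProtocolError(
            f"{len(individuation)} individuation pairs for {protocol.n_trials} trials"
        )
    model = model or SensorModel()
    onsets, _ = training_onsets(protocol)
    segs = []
    for onset, (ext, flex) in zip(onsets, individuation):
        end = onset + protocol.trial_window_s
        if ext > 0:
            segs.append(Segment("extensor", onset, end, ext))
        if flex > 0:
            segs.append(Segment("flexor", onset, end, flex))
    duration = onsets[-1] + protocol.trial_window_s + max(protocol.inter_trial_rest_s, rise_s + 0.5)
    script = ActivationScript(duration_s=duration, segments=tuple(segs), rise_s=rise_s)
    env = build_envelope(script, fs_hz=model.fs_hz)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    emg_ss, force_ss = ss.spawn(2)
    rec = synthesize_emg(env, model, emg_ss)
    rec.meta.update({"kind": "training", "n_trials": protocol.n_trials})
    force = synthesize_force(env, fmodel, force_ss) if fmodel is not None else None
    return TrainingSim(recording=rec, onsets=list(onsets), force=force)


@dataclass
class ValidationSim:
    """One simulated ramp–hold validation session."""

    recording: EmgRecording
    force: ForceTrace
    target: np.ndarray
    protocol: RampHoldProtocol


def simulate_validation_session(
    protocol: RampHoldProtocol | None = None,
    model: SensorModel | None = None,
    fmodel: ForceModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    trial_gain_sd: float = 0.15,
) -> ValidationSim:
    """Simulate the isometric force-tracking task with coupled EMG and force.

    Both antagonists co-activate following the force target (a power grip
    engages extensors and flexors alike), so the expected extensor ratio
    during holds is 0.5.  Motor output is not metronomic: each trial draws
    an independent per-channel activation gain ``~ N(1, trial_gain_sd)``
    (clipped at 0), emulating the trial-to-trial variability of voluntary
    force tracking; the force trace is driven by the jittered activation.
    """
    protocol = protocol or RampHoldProtocol()
    model = model or SensorModel()
    fmodel = fmodel or ForceModel()
    tgt = target_trace(protocol, model.fs_hz)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    emg_ss, force_ss, gain_ss = ss.spawn(3)
    act = np.vstack([tgt, tgt]).copy()
    if trial_gain_sd > 0:
        grng = np.random.default_rng(gain_ss)
        n_trial = int(round(protocol.trial_s * model.fs_hz))
        gains = np.clip(
            grng.normal(1.0, trial_gain_sd, size=(2, protocol.n_trials)), 0.0, None
        )
        for k in range(protocol.n_trials):
            sl = slice(k * n_trial, (k + 1) * n_trial)
            act[:, sl] *= gains[:, k:k + 1]
        np.clip(act, 0.0, 1.0, out=act)
    env = ActivationTraces(fs_hz=model.fs_hz, channels=DEFAULT_CHANNELS, values=act)
    rec = synthesize_emg(env, model, emg_ss)
    rec.meta.update({"kind": "validation", "n_trials": protocol.n_trials})
    force = synthesize_force(env, fmodel, force_ss)
    return ValidationSim(recording=rec, force=force, target=tgt, protocol=protocol)
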