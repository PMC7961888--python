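"""EMG conditioning chain: filter, rectify, smooth, calibrate, normalize.

The chain mirrors standard surface-EMG envelope practice: a 4th-order
Butterworth band-pass (default 150–450 Hz, which also removes the
front-end's DC offset), full-wave rectification, normalization to a
reference grip, and smoothing with a unity-DC-gain window (250-ms Hann for
display, 1-s boxcar for slow isometric analysis).

Calibration follows the reference-grip rule: the per-muscle normalization
amplitude is the *highest* 250-ms moving-window average of the rectified,
filtered activity anywhere in the grip recording, so a normalized value
near 1 means "as active as during the calibration grip".

Two execution modes are provided.  ``offline`` uses zero-phase filtering
and centered windows; ``streaming`` uses causal filters and trailing
windows and can be driven chunk-by-chunk through
:class:`StreamingProcessor` with results identical sample-for-sample to a
one-shot causal run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import (
    BandError,
    CalibrationError,
    UnitsError,
    UnknownChannelError,
    WindowError,
)
from .recording import COUNTS, VOLTS, EmgRecording
from .sensor import SensorModel

OFFLINE = "offline"
STREAMING = "streaming"


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the conditioning chain."""

    band_low_hz: float = 150.0
    band_high_hz: float = 450.0
    smooth_kind: str = "hann"  # "hann" | "boxcar" | "none"
    smooth_window_s: float = 0.25
    mode: str = OFFLINE

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise BandError(
                f"need 0 < band_low ({self.band_low_hz}) < band_high ({self.band_high_hz})"
            )
        if self.smooth_kind not in ("hann", "boxcar", "none"):
            raise ValueError(f"unknown smooth_kind {self.smooth_kind!r}")
        if self.smooth_window_s <= 0:
            raise WindowError("smooth_window_s must be positive")
        if self.mode not in (OFFLINE, STREAMING):
            raise ValueError(f"unknown mode {self.mode!r}")


#: Configuration used for slow isometric (ramp–hold) analysis: same band,
#: 1-s rectangular moving average.
VALIDATION_CONFIG = PipelineConfig(smooth_kind="boxcar", smooth_window_s=1.0)


@dataclass
class CalibrationProfile:
    """Per-channel normalization amplitudes from a reference grip."""

    amplitudes: dict
    window_s: float = 0.25
    stat: str = "windowed_max"
    units: str = COUNTS
    source: str = ""
    created: str | None = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.amplitudes.values()):
            raise CalibrationError("calibration amplitudes must be positive")
        if self.window_s <= 0:
            raise WindowError("window_s must be positive")

    def amplitude(self, channel: str) -> float:
        try:
            return self.amplitudes[channel]
        except KeyError:
            raise UnknownChannelError(
                f"channel {channel!r} not in calibration profile "
                f"(has {sorted(self.amplitudes)})"
            ) from None


@dataclass
class Envelope:
    """Nonnegative normalized activation traces aligned to a recording."""

    fs_hz: float
    channels: tuple[str, ...]
    values: np.ndarray  # (n_channels, n_samples)
    calibration: str = ""
    config: PipelineConfig | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.values[self.channels.index(label)]
        except ValueError:
            raise UnknownChannelError(
                f"channel {label!r} not in envelope channels {self.channels}"
            ) from None


def counts_to_volts(rec: EmgRecording, model: SensorModel) -> EmgRecording:
    """Convert an integer-count recording to volts.

    ``volts = counts * supply_v / (2**adc_bits - 1)``.
    """
    if rec.units != COUNTS:
        raise UnitsError(f"recording units are {rec.units!r}, expected 'counts'")
    return EmgRecording(
        fs_hz=rec.fs_hz,
        channels=rec.channels,
        samples=model.counts_to_volts(rec.samples.astype(float)),
        units=VOLTS,
        meta=dict(rec.meta),
    )


def design_bandpass(cfg: PipelineConfig, fs_hz: float) -> np.ndarray:
    """Second-order sections of the 4th-order Butterworth band-pass."""
    if cfg.band_high_hz >= fs_hz / 2:
        raise BandError(
            f"band_high {cfg.band_high_hz} Hz >= Nyquist {fs_hz / 2} Hz"
        )
    return signal.butter(
        4, (cfg.band_low_hz, cfg.band_high_hz), btype="bandpass", fs=fs_hz, output="sos"
    )


def bandpass(rec: EmgRecording, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Band-pass filter every channel; removes any DC offset.

    Zero-phase (forward–backward) in offline mode, causal in streaming
    mode.  Returns a float array of shape ``(n_channels, n_samples)`` in
    the recording's amplitude units.
    """
    cfg = cfg or PipelineConfig()
    sos = design_bandpass(cfg, rec.fs_hz)
    x = rec.samples.astype(float)
    if cfg.mode == OFFLINE:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(x)


def _window_taps(kind: str, m: int) -> np.ndarray:
    if kind == "boxcar":
        w = np.ones(m)
    elif kind == "hann":
        w = signal.windows.hann(m) if m > 1 else np.ones(1)
    else:
        raise ValueError(f"unknown window kind {kind!r}")
    return w / w.sum()


def smooth(x: np.ndarray, cfg: PipelineConfig | None = None, fs_hz: float = 2000.0) -> np.ndarray:
    """Smooth with a unity-DC-gain window; output length equals input length.

    Offline: centered window with reflect padding.  Streaming: trailing
    (causal) window, zero-initialized, so the first ``smooth_window_s`` is
    a start-up transient.
    """
    cfg = cfg or PipelineConfig()
    if cfg.smooth_kind == "none":
        return np.asarray(x, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    squeeze = x.shape[0] == 1
    m = int(round(cfg.smooth_window_s * fs_hz))
    if m < 1 or m > x.shape[-1]:
        raise WindowError(
            f"window of {m} samples invalid for series of {x.shape[-1]} samples"
        )
    w = _window_taps(cfg.smooth_kind, m)
    if cfg.mode == OFFLINE:
        left = (m - 1) // 2
        right = m - 1 - left
        xp = np.pad(x, ((0, 0), (left, right)), mode="reflect")
        out = np.stack([np.convolve(row, w, mode="valid") for row in xp])
    else:
        out = signal.lfilter(w, [1.0], x, axis=-1)
    return out[0] if squeeze else out


def moving_average(x: np.ndarray, window_s: float, fs_hz: float, mode: str = OFFLINE) -> np.ndarray:
    """Rectangular moving average (helper used by calibration)."""
    cfg = PipelineConfig(smooth_kind="boxcar", smooth_window_s=window_s, mode=mode)
    return smooth(x, cfg, fs_hz)


def calibrate_grip(
    rec: EmgRecording,
    cfg: PipelineConfig | None = None,
    *,
    window_s: float = 0.25,
    stat: str = "windowed_max",
    silent_factor: float | None = 3.0,
    rest_interval: tuple[float, float] = (0.0, 0.5),
) -> CalibrationProfile:
    """Derive per-channel normalization amplitudes from a reference grip.

    Per channel: band-pass, rectify, ``window_s`` moving average, then the
    maximum over time (``stat="windowed_max"``, the default) or the mean of
    the rectified signal over the whole recording (``stat="mean"``, for
    recordings that consist mostly of grip).

    A channel whose peak amplitude is below ``silent_factor`` times its
    amplitude over ``rest_interval`` (seconds; default the first 0.5 s,
    which reference grips record as rest) is considered silent and raises
    :class:`CalibrationError`.  Pass ``silent_factor=None`` to disable for
    recordings with no leading rest.
    """
    cfg = cfg or PipelineConfig()
    if stat not in ("windowed_max", "mean"):
        raise ValueError(f"unknown calibration stat {stat!r}")
    if rec.duration_s < window_s:
        raise CalibrationError(
            f"recording of {rec.duration_s:.3f} s shorter than the "
            f"{window_s:.3f} s calibration window"
        )
    rect = rectify(bandpass(rec, replace(cfg, mode=OFFLINE)))
    windowed = moving_average(rect, window_s, rec.fs_hz, mode=OFFLINE)
    amplitudes: dict[str, float] = {}
    for i, ch in enumerate(rec.channels):
        amp = float(windowed[i].max()) if stat == "windowed_max" else float(rect[i].mean())
        if silent_factor is not None:
            i0 = int(rest_interval[0] * rec.fs_hz)
            i1 = max(i0 + 1, int(rest_interval[1] * rec.fs_hz))
            rest_amp = float(windowed[i, i0:i1].mean())
            if amp < silent_factor * rest_amp:
                raise CalibrationError(
                    f"channel {ch!r} appears silent: peak amplitude {amp:.4g} "
                    f"< {silent_factor} x rest amplitude {rest_amp:.4g}"
                )
        amplitudes[ch] = amp
    return CalibrationProfile(
        amplitudes=amplitudes,
        window_s=window_s,
        stat=stat,
        units=rec.units,
        source=str(rec.meta.get("id", rec.meta.get("kind", ""))),
    )


def normalize(x: np.ndarray, profile: CalibrationProfile, channel: str) -> np.ndarray:
    """Divide by the channel's calibration amplitude; values above 1 are kept."""
    return np.asarray(x, dtype=float) / profile.amplitude(channel)


def process(
    rec: EmgRecording,
    profile: CalibrationProfile,
    cfg: PipelineConfig | None = None,
) -> Envelope:
    """Full chain: band-pass → rectify → normalize → smooth."""
    cfg = cfg or PipelineConfig()
    if profile.units != rec.units:
        raise UnitsError(
            f"recording units {rec.units!r} do not match calibration units "
            f"{profile.units!r}"
        )
    rect = rectify(bandpass(rec, cfg))
    norm = np.stack([
        normalize(rect[i], profile, ch) for i, ch in enumerate(rec.channels)
    ])
    out = smooth(norm, cfg, rec.fs_hz) if cfg.smooth_kind != "none" else norm
    out = np.atleast_2d(out)
    return Envelope(
        fs_hz=rec.fs_hz,
        channels=rec.channels,
        values=out,
        calibration=profile.source,
        config=cfg,
    )


class StreamingProcessor:
    """Chunk-by-chunk causal envelope extraction with carried filter state.

    Feeding chunks of any size through :meth:`push` produces exactly the
    same samples as one causal :func:`process` call on the concatenated
    recording (mode ``"streaming"``).
    """

    def __init__(
        self,
        profile: CalibrationProfile,
        cfg: PipelineConfig,
        fs_hz: float,
        channels: tuple[str, ...],
    ) -> None:
        self.profile = profile
        self.cfg = cfg
        self.fs_hz = fs_hz
        self.channels = tuple(channels)
        self._sos = design_bandpass(cfg, fs_hz)
        n_ch = len(self.channels)
        self._zi = np.zeros((n_ch, self._sos.shape[0], 2))
        if cfg.smooth_kind != "none":
            m = int(round(cfg.smooth_window_s * fs_hz))
            self._taps = _window_taps(cfg.smooth_kind, m)
            self._fir_zi = np.zeros((n_ch, m - 1)) if m > 1 else None
        else:
            self._taps = None
            self._fir_zi = None
        self._amps = np.array([profile.amplitude(ch) for ch in self.channels])

    def push(self, chunk: np.ndarray) -> np.ndarray:
        """Process one ``(n_channels, k)`` chunk of raw samples."""
        chunk = np.atleast_2d(np.asarray(chunk, dtype=float))
        out = np.empty_like(chunk)
        for i in range(chunk.shape[0]):
            y, self._zi[i] = signal.sosfilt(self._sos, chunk[i], zi=self._zi[i])
            y = np.abs(y) / self._amps[i]
            if self._taps is not None:
                if self._fir_zi is None:
                    y = self._taps[0] * y
                else:
                    y, self._fir_zi[i] = signal.lfilter(
                        self._taps, [1.0], y, zi=self._fir_zi[i]
                    )
            out[i] = y
        return out


@dataclass
class DisplaySeries:
    """Envelope resampled to the screen refresh rate, with a color index.

    ``color_index`` maps each value linearly onto [0, 1] between the
    dynamic range ``(lo, hi)`` (blue→red heat map in the on-screen game).
    """

    fps: float
    channels: tuple[str, ...]
    values: np.ndarray
    color_index: np.ndarray


def downsample_for_display(
    env: Envelope, fps: float, lo: float = 0.0, hi: float = 1.0
) -> DisplaySeries:
    """One envelope value per frame: the last sample at or before each frame time."""
    if fps >= env.fs_hz:
        raise ValueError("fps must be below the envelope sampling rate")
    if hi <= lo:
        raise ValueError("display range requires hi > lo")
    n_frames = int(np.floor(env.n_samples / env.fs_hz * fps))
    idx = np.floor(np.arange(n_frames) / fps * env.fs_hz).astype(int)
    vals = env.values[:, idx]
    color = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    return DisplaySeries(fps=fps, channels=env.channels, values=vals, color_index=color)
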