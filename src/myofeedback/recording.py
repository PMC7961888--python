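"""In-memory container for uniformly sampled multichannel EMG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnknownChannelError

#: Canonical antagonist pair used throughout: wrist extensor and wrist flexor.
DEFAULT_CHANNELS: tuple[str, str] = ("extensor", "flexor")

COUNTS = "counts"
VOLTS = "volts"


@dataclass
class EmgRecording:
    """Uniformly sampled multichannel raw EMG.

    ``samples`` has shape ``(n_channels, n_samples)`` in the order of
    ``channels``.  ``units`` is either ``"counts"`` (integer ADC codes) or
    ``"volts"``.  ``meta`` carries free-form provenance (sensor model
    parameters, seed, session id).
    """

    fs_hz: float
    channels: tuple[str, ...]
    samples: np.ndarray
    units: str = COUNTS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.channels = tuple(self.channels)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"samples must have shape (n_channels={len(self.channels)}, n); "
                f"got {self.samples.shape}"
            )
        if self.units not in (COUNTS, VOLTS):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == COUNTS and not np.issubdtype(self.samples.dtype, np.integer):
            raise ValueError("units='counts' requires integer samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise UnknownChannelError(
                f"channel {label!r} not in recording channels {self.channels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]
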