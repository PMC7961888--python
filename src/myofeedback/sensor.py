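"""Model of a low-cost single-supply sEMG acquisition front-end.

The front-end emulated here is the common hobby-grade surface-EMG sensor
wired to a microcontroller ADC: the electrode signal is differentially
amplified (default 500 V/V), re-centered at half the supply rail so it fits
a unipolar ADC (1.65 V on a 3.3 V supply), and digitized at 2000 Hz with
12-bit resolution.  The sensor performs no in-board filtering; the spectral
shaping band below describes the physiological signal itself, not the
hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SensorModel:
    """Electrical model of the acquisition chain, electrode to ADC code.

    Parameters
    ----------
    gain
        In-board amplification, V/V.
    supply_v
        Supply voltage; the amplified signal is centered at ``supply_v / 2``.
    adc_bits
        ADC resolution; codes span ``[0, 2**adc_bits - 1]``.
    fs_hz
        Sampling rate in Hz.
    shaping_band
        (low, high) band in Hz occupied by the physiological signal.
    baseline_sd_v
        Electrode-referred (pre-gain) RMS of the noise floor, volts.
    max_emg_sd_v
        Electrode-referred RMS of the EMG at full activation, volts.
    crosstalk
        Fraction in [0, 0.5) of each channel's pre-gain signal mixed into
        the other channel.
    """

    gain: float = 500.0
    supply_v: float = 3.3
    adc_bits: int = 12
    fs_hz: float = 2000.0
    shaping_band: tuple[float, float] = (20.0, 450.0)
    baseline_sd_v: float = 5e-6
    max_emg_sd_v: float = 1e-3
    crosstalk: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.supply_v <= 0:
            raise ValueError("supply_v must be positive")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")
        lo, hi = self.shaping_band
        if not (0 < lo < hi):
            raise ValueError("shaping_band must satisfy 0 < low < high")
        if self.fs_hz <= 2 * hi:
            raise ValueError("fs_hz must exceed twice the shaping band's upper edge")
        if not (0 <= self.crosstalk < 0.5):
            raise ValueError("crosstalk must lie in [0, 0.5)")
        if self.baseline_sd_v < 0 or self.max_emg_sd_v < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    @property
    def full_scale(self) -> int:
        """Largest ADC code, ``2**adc_bits - 1``."""
        return (1 << self.adc_bits) - 1

    @property
    def midpoint_v(self) -> float:
        """DC offset applied by the board, half the supply."""
        return self.supply_v / 2.0

    def counts_to_volts(self, counts) -> "object":
        """Convert ADC codes to volts: ``volts = counts * supply_v / full_scale``."""
        return counts * (self.supply_v / self.full_scale)

    def to_dict(self) -> dict:
        return {
            "gain": self.gain,
            "supply_v": self.supply_v,
            "adc_bits": self.adc_bits,
            "fs_hz": self.fs_hz,
            "shaping_band": list(self.shaping_band),
            "baseline_sd_v": self.baseline_sd_v,
            "max_emg_sd_v": self.max_emg_sd_v,
            "crosstalk": self.crosstalk,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorModel":
        d = dict(d)
        if "shaping_band" in d:
            d["shaping_band"] = tuple(d["shaping_band"])
        return cls(**d)
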