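"""Sensor geometry and channel layout.

The instrument modelled here transmits two collinear near-infrared laser
wavelengths through a polarizer and records the backscattered light on four
detector channels: co- and de-polarized light for each wavelength.  All
channels are sampled synchronously.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_CHANNELS = ("co_l1", "de_l1", "co_l2", "de_l2")


@dataclass(frozen=True)
class SensorConfig:
    """Acquisition parameters of the four-channel optical sensor.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz.  Default 20 kHz.
    bandwidth : float
        Analog detection bandwidth in Hz.  Must satisfy the Nyquist
        condition ``sample_rate > 2 * bandwidth``.  Default 5 kHz.
    channel_names : tuple of str
        The four channels in fixed order: co-polarized wavelength 1,
        de-polarized wavelength 1, co-polarized wavelength 2,
        de-polarized wavelength 2.
    wavelengths : tuple of float
        The two laser wavelengths in nm.
    """

    sample_rate: float = 20_000.0
    bandwidth: float = 5_000.0
    channel_names: tuple = field(default=DEFAULT_CHANNELS)
    wavelengths: tuple = (808.0, 980.0)

    def __post_init__(self) -> None:
        if self.sample_rate <= 2 * self.bandwidth:
            raise ValueError(
                f"sample_rate ({self.sample_rate}) must exceed twice the "
                f"bandwidth ({self.bandwidth})"
            )
        if len(self.channel_names) != 4:
            raise ValueError("exactly 4 channels are required")
        if len(self.wavelengths) != 2:
            raise ValueError("exactly 2 wavelengths are required")

    @property
    def n_channels(self) -> int:
        return 4
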