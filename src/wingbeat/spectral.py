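"""Frequency-domain processing of segmented events.

Each channel of an event is mean-subtracted, zero-padded to 20,000
samples (1 s at a 20 kHz sampling rate, giving exactly 1 Hz bin
spacing) and Fourier transformed.  The magnitudes below 1 kHz feed both
the scalar feature extraction and, resampled to 512 points per channel
and concatenated into a 2048-vector, the neural-network classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import Event

__all__ = [
    "PADDED_LENGTH",
    "BAND_BINS",
    "POINTS_PER_CHANNEL",
    "PowerSpectrum",
    "SpectralVector",
    "power_spectrum",
    "spectral_vector",
    "average_spectrum",
]

PADDED_LENGTH = 20_000
BAND_BINS = 1_000  # bins below 1 kHz at 1 Hz spacing
POINTS_PER_CHANNEL = 512


@dataclass
class PowerSpectrum:
    """Full padded magnitude spectrum of one event.

    ``magnitudes`` is ``(4, 20000)``; ``bin_spacing`` equals
    ``sample_rate / 20000`` (1 Hz at 20 kHz).  ``native_resolution`` is
    the event's intrinsic resolution 1/duration, used to size harmonic
    search windows.
    """

    magnitudes: np.ndarray
    bin_spacing: float
    native_resolution: float

    @property
    def band(self) -> np.ndarray:
        """Channel magnitudes on the 0-999 Hz analysis band."""
        return self.magnitudes[:, :BAND_BINS]

    @property
    def channel_mean_band(self) -> np.ndarray:
        return self.band.mean(axis=0)


@dataclass
class SpectralVector:
    """2048-point classifier input: 4 channels x 512 resampled bins."""

    values: np.ndarray
    normalization: str = "l2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (4 * POINTS_PER_CHANNEL,):
            raise ValueError("spectral vector must have length 2048")


def power_spectrum(event: Event) -> PowerSpectrum:
    """Padded magnitude spectrum of an event.

    Per channel: subtract the channel mean, zero-pad (or
    centre-truncate, for events longer than 1 s) to 20,000 samples and
    take the DFT magnitude.
    """
    seg = event.segment
    if seg.shape[1] == 0:
        raise ValueError("empty segment")
    if seg.shape[1] > PADDED_LENGTH:
        # centre truncation preserves the transit peak
        off = (seg.shape[1] - PADDED_LENGTH) // 2
        seg = seg[:, off : off + PADDED_LENGTH]
    x = seg - seg.mean(axis=1, keepdims=True)
    mag = np.abs(np.fft.fft(x, n=PADDED_LENGTH, axis=1))
    return PowerSpectrum(
        magnitudes=mag,
        bin_spacing=event.sample_rate / PADDED_LENGTH,
        native_resolution=1.0 / event.duration,
    )


def spectral_vector(
    spectrum: PowerSpectrum, method: str = "interp", normalize: bool = True
) -> SpectralVector:
    """Resample the sub-kHz band of each channel to 512 points and
    concatenate the four channels in fixed order.

    ``method`` is ``"interp"`` (linear interpolation onto a uniform
    512-point grid, the default) or ``"bin_mean"`` (block averaging).
    The concatenated vector is L2-normalized unless ``normalize`` is
    False; an all-zero vector is returned unchanged.
    """
    band = spectrum.band
    if method == "interp":
        grid = np.linspace(0.0, BAND_BINS - 1, POINTS_PER_CHANNEL)
        base = np.arange(BAND_BINS)
        down = np.stack([np.interp(grid, base, ch) for ch in band])
    elif method == "bin_mean":
        edges = np.linspace(0, BAND_BINS, POINTS_PER_CHANNEL + 1).astype(int)
        down = np.stack(
            [
                np.array([ch[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
                for ch in band
            ]
        )
    else:
        raise ValueError(f"unknown resampling method: {method!r}")
    values = down.reshape(-1)
    norm_tag = "none"
    if normalize:
        norm = np.linalg.norm(values)
        if norm > 0:
            values = values / norm
            norm_tag = "l2"
    return SpectralVector(values=values, normalization=norm_tag)


def average_spectrum(events: Sequence[Event]):
    """Group-average spectrum with interquartile band.

    For each event, the magnitudes are averaged over the four channels
    on the 0-999 Hz grid; the pointwise mean and 25th/75th percentiles
    are then taken across events.  Returns
    ``(freqs, mean, (q25, q75))``.
    """
    if len(events) == 0:
        raise ValueError("average_spectrum requires at least one event")
    curves = np.stack(
        [power_spectrum(ev).channel_mean_band for ev in events]
    )
    freqs = np.arange(BAND_BINS, dtype=float)
    mean = curves.mean(axis=0)
    q25, q75 = np.percentile(curves, [25, 75], axis=0)
    return freqs, mean, (q25, q75)
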