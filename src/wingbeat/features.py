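"""Scalar feature extraction for the WBF and Features classifiers.

The wingbeat frequency (WBF) is taken as the dominant peak of the
channel-averaged spectrum in the 30-1000 Hz band — deliberately without
harmonic correction, so an event whose second harmonic is strongest
yields twice the true WBF (a known failure mode the downstream
classifiers can learn around).  The canonical 12-feature set adds
harmonic amplitudes and ratios, a spectral centroid, duration, total
energy and the polarization / dual-wavelength band ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Tuple

import numpy as np

from .detect import Event
from .spectral import BAND_BINS, PowerSpectrum, power_spectrum

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_BAND",
    "FeatureSet",
    "dominant_frequency",
    "harmonic_features",
    "full_feature_set",
]

DEFAULT_BAND = (30.0, 1000.0)

FEATURE_NAMES = (
    "wbf",
    "amp_1h",
    "amp_2h",
    "amp_3h",
    "ratio_2h_1h",
    "ratio_3h_1h",
    "spectral_centroid",
    "duration",
    "total_energy",
    "depol_ratio_l1",
    "depol_ratio_l2",
    "wavelength_ratio",
)


@dataclass(frozen=True)
class FeatureSet:
    """The canonical, ordered 12-feature description of one event.

    Frequencies in Hz, duration in seconds, energy in detector
    units squared times seconds; all ratios dimensionless.  Degenerate
    features (e.g. a harmonic beyond the 1 kHz band) are encoded as 0
    and flagged in ``degenerate``.
    """

    wbf: float
    amp_1h: float
    amp_2h: float
    amp_3h: float
    ratio_2h_1h: float
    ratio_3h_1h: float
    spectral_centroid: float
    duration: float
    total_energy: float
    depol_ratio_l1: float
    depol_ratio_l2: float
    wavelength_ratio: float
    degenerate: Tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    @staticmethod
    def names() -> Tuple[str, ...]:
        return FEATURE_NAMES


def dominant_frequency(
    spectrum: PowerSpectrum, band: Tuple[float, float] = DEFAULT_BAND
) -> float:
    """Frequency (Hz) of the strongest channel-averaged peak in ``band``.

    Always returns the argmax — on a noise-only event this is an
    arbitrary in-band value, by contract.
    """
    lo = int(np.ceil(band[0] / spectrum.bin_spacing))
    hi = int(np.floor(band[1] / spectrum.bin_spacing))
    hi = min(hi, BAND_BINS - 1)
    if hi < lo:
        raise ValueError("empty frequency band")
    mean = spectrum.channel_mean_band
    return float((lo + int(np.argmax(mean[lo : hi + 1]))) * spectrum.bin_spacing)


def _peak_near(mean: np.ndarray, spectrum: PowerSpectrum, f: float) -> Optional[float]:
    """Max magnitude within +/- one native resolution width of ``f``,
    or None if the window lies outside the sub-kHz band."""
    half = max(spectrum.native_resolution, spectrum.bin_spacing)
    lo = int(np.floor((f - half) / spectrum.bin_spacing))
    hi = int(np.ceil((f + half) / spectrum.bin_spacing))
    if lo >= BAND_BINS:
        return None
    lo = max(lo, 0)
    hi = min(hi, BAND_BINS - 1)
    return float(mean[lo : hi + 1].max())


def harmonic_features(spectrum: PowerSpectrum, f0: float) -> dict:
    """Amplitudes at f0, 2 f0, 3 f0 and their ratios to the fundamental.

    Each amplitude is the maximum channel-averaged magnitude within one
    native resolution width (1/duration) of the nominal harmonic
    frequency.  Harmonics falling beyond the 1 kHz band are encoded as
    0 and listed under ``"degenerate"``.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    mean = spectrum.channel_mean_band
    amps = {}
    degenerate = []
    for k in (1, 2, 3):
        peak = _peak_near(mean, spectrum, k * f0)
        if peak is None:
            peak = 0.0
            degenerate.append(f"amp_{k}h")
        amps[f"amp_{k}h"] = peak
    a1 = amps["amp_1h"]
    return {
        **amps,
        "ratio_2h_1h": amps["amp_2h"] / a1 if a1 > 0 else 0.0,
        "ratio_3h_1h": amps["amp_3h"] / a1 if a1 > 0 else 0.0,
        "degenerate": tuple(degenerate),
    }


def full_feature_set(
    event: Event,
    spectrum: Optional[PowerSpectrum] = None,
    band: Tuple[float, float] = DEFAULT_BAND,
) -> FeatureSet:
    """Compute the canonical 12-feature vector for one event.

    Deterministic and total: every detected event yields a FeatureSet,
    with degenerate entries set to 0 and flagged.
    """
    if spectrum is None:
        spectrum = power_spectrum(event)
    wbf = dominant_frequency(spectrum, band)
    harm = harmonic_features(spectrum, wbf)

    lo = int(np.ceil(band[0] / spectrum.bin_spacing))
    hi = min(int(np.floor(band[1] / spectrum.bin_spacing)), BAND_BINS - 1)
    mean_band = spectrum.channel_mean_band[lo : hi + 1]
    freqs = np.arange(lo, hi + 1) * spectrum.bin_spacing
    total = mean_band.sum()
    centroid = float((freqs * mean_band).sum() / total) if total > 0 else 0.0

    # band-integrated per-channel magnitudes, excluding DC/body leakage
    ch = spectrum.band[:, lo : hi + 1].sum(axis=1)
    degenerate = list(harm["degenerate"])

    def _ratio(num: float, den: float, name: str) -> float:
        if den > 0:
            return float(num / den)
        degenerate.append(name)
        return 0.0

    depol_l1 = _ratio(ch[1], ch[0], "depol_ratio_l1")
    depol_l2 = _ratio(ch[3], ch[2], "depol_ratio_l2")
    wl_ratio = _ratio(ch[0] + ch[1], ch[2] + ch[3], "wavelength_ratio")

    energy = float((event.segment**2).sum() / event.sample_rate)
    return FeatureSet(
        wbf=wbf,
        amp_1h=harm["amp_1h"],
        amp_2h=harm["amp_2h"],
        amp_3h=harm["amp_3h"],
        ratio_2h_1h=harm["ratio_2h_1h"],
        ratio_3h_1h=harm["ratio_3h_1h"],
        spectral_centroid=centroid,
        duration=event.duration,
        total_energy=energy,
        depol_ratio_l1=depol_l1,
        depol_ratio_l2=depol_l2,
        wavelength_ratio=wl_ratio,
        degenerate=tuple(degenerate),
    )
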