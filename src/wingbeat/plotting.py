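"""Plots: group-average spectra with interquartile bands."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .spectral import average_spectrum

__all__ = ["plot_average_spectra"]


def plot_average_spectra(dataset, outdir, max_freq: float = 1000.0) -> list:
    """One PNG per species: channel-averaged mean spectrum and IQR band.

    Returns the list of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for sp in dataset.species():
        events = [dataset.events[i] for i in dataset.indices_of(sp)]
        freqs, mean, (q25, q75) = average_spectrum(events)
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.fill_between(freqs, q25, q75, color="0.8", label="interquartile range")
        ax.plot(freqs, mean, color="C0", lw=1.0, label="mean")
        ax.set_xlim(0, max_freq)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("magnitude (a.u.)")
        ax.set_title(sp)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = outdir / f"spectrum_{sp}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
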