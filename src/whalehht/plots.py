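"""Minimal matplotlib renderings of marginal spectra and Hilbert-spectrum grids."""

from __future__ import annotations

import numpy as np

from .hilbert import HilbertSpectrumGrid, MarginalSpectrum

__all__ = ["plot_marginal", "plot_grid"]


def plot_marginal(mf: MarginalSpectrum, ax=None, max_freq: float | None = None):
    """Bar plot of a marginal spectrum (percent of segment energy per Hz bin)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hi = mf.bin_freqs.size
    if max_freq is not None:
        hi = min(hi, int(np.ceil(max_freq / mf.freq_res)) + 1)
    else:
        support = np.flatnonzero(mf.values)
        if support.size:
            hi = min(hi, support[-1] + 2)
    ax.bar(mf.bin_freqs[:hi], mf.values[:hi], width=0.9 * mf.freq_res)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("energy (% of segment)")
    ax.set_title(f"MF of IMF{mf.imf_index + 1}" if mf.imf_index >= 0 else "MF of residue")
    return ax


def plot_grid(grid: HilbertSpectrumGrid, ax=None, max_freq: float | None = None):
    """Heat map of a Hilbert-spectrum grid (time bins by frequency bins)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hi = grid.bin_freqs.size
    if max_freq is not None:
        hi = min(hi, int(np.ceil(max_freq / grid.freq_res)) + 1)
    im = ax.imshow(
        grid.values[:, :hi],
        aspect="auto",
        origin="upper",
        extent=(grid.bin_freqs[0], grid.bin_freqs[hi - 1], grid.n_time_bins * grid.time_bin_s * 1e3, 0),
    )
    ax.figure.colorbar(im, ax=ax, label="energy (% of segment)")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("time (ms)")
    return ax
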