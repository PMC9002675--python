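"""Analytic-signal tracks, marginal frequency spectra, and Hilbert spectra.

For each IMF the Hilbert transform gives the analytic signal
``z(t) = IMF(t) + j*HT{IMF(t)} = a(t) * exp(j*theta(t))``; the instantaneous
frequency is the derivative of the unwrapped phase over 2*pi.  Accumulating
squared analytic amplitude into frequency bins by each sample's instantaneous
frequency yields the marginal frequency spectrum (MF), expressed here as
percent of the whole segment's energy so that spectra, energy ratios and EDI
thresholds share one scale.  Slicing the same tracks into equal time bins
before binning gives the Hilbert spectrum (HS), a time-frequency-energy grid
whose sum over time reproduces the MF.

Normalisation: the squared analytic amplitude of a sinusoid integrates to
twice the signal energy, so the raw binned mass is rescaled so each
component's spectrum totals exactly that component's energy ratio (percent of
segment energy).  Samples whose instantaneous frequency falls outside
[0, Nyquist] — a known Hilbert-transform edge artefact — are excluded from
binning and their fraction recorded; the rescaling restores mass conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "AnalyticTrack",
    "MarginalSpectrum",
    "HilbertSpectrumGrid",
    "GridExtremes",
    "analytic_track",
    "marginal_spectrum",
    "hilbert_spectrum",
    "find_grid_extremes",
]

log = logging.getLogger(__name__)

RESIDUE_INDEX = -1  # sentinel imf_index for residue-derived spectra


@dataclass(frozen=True)
class AnalyticTrack:
    """Instantaneous amplitude, unwrapped phase and frequency of one component."""

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq: np.ndarray
    rate: float
    degenerate: bool = False
    invalid_fraction: float = 0.0  # fraction of samples with IF outside [0, Nyquist]


@dataclass(frozen=True)
class MarginalSpectrum:
    """Per-component frequency-energy distribution in percent of segment energy.

    ``values[k]`` is the percent of total segment energy the component carries
    in the frequency bin centred on ``bin_freqs[k]``; a bin at x Hz covers
    [x - res/2, x + res/2).  The vector sums to the component's energy ratio.
    """

    imf_index: int
    bin_freqs: np.ndarray
    values: np.ndarray
    freq_res: float = 1.0
    excluded_fraction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_freqs", np.asarray(self.bin_freqs, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.bin_freqs.size != self.values.size:
            raise ValueError("bin_freqs and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("marginal-spectrum values must be non-negative")

    @property
    def energy_ratio(self) -> float:
        """Total mass: the component's energy as percent of segment energy."""
        return float(self.values.sum())

    @property
    def argmax_freq(self) -> float:
        """Frequency bin of the global maximum (ties -> lowest frequency)."""
        return float(self.bin_freqs[int(np.argmax(self.values))])


@dataclass(frozen=True)
class HilbertSpectrumGrid:
    """Time-binned frequency-energy grid for one component.

    ``values`` has shape (n_time_bins, n_freq_bins); summing over the time
    axis reproduces the component's marginal spectrum.
    """

    imf_index: int
    values: np.ndarray
    bin_freqs: np.ndarray
    time_bin_s: float
    freq_res: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "bin_freqs", np.asarray(self.bin_freqs, dtype=float))
        if self.values.ndim != 2 or self.values.shape[1] != self.bin_freqs.size:
            raise ValueError("grid shape must be (n_time_bins, n_freq_bins)")

    @property
    def n_time_bins(self) -> int:
        return self.values.shape[0]

    @property
    def time_labels_ms(self) -> np.ndarray:
        """End-of-bin times in ms (30, 60, ... for 30 ms bins)."""
        return np.round((np.arange(self.n_time_bins) + 1) * self.time_bin_s * 1e3)

    def marginal(self) -> MarginalSpectrum:
        """Sum over time bins as a MarginalSpectrum."""
        return MarginalSpectrum(
            imf_index=self.imf_index,
            bin_freqs=self.bin_freqs,
            values=self.values.sum(axis=0),
            freq_res=self.freq_res,
        )

    def to_frame(self) -> pd.DataFrame:
        """Rows = time bins (ms), columns = frequency bins (Hz)."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.time_labels_ms.astype(int), name="time_ms"),
            columns=pd.Index(self.bin_freqs, name="freq_hz"),
        )


@dataclass(frozen=True)
class GridExtremes:
    """Largest and second-largest cells of a time-frequency grid."""

    max_value: float
    max_time: float
    max_freq: float
    second_value: float | None
    second_time: float | None
    second_freq: float | None


def analytic_track(imf: np.ndarray, rate: float) -> AnalyticTrack:
    """Hilbert-transform a component into amplitude/phase/frequency tracks.

    Instantaneous frequency is the central difference of the unwrapped phase
    divided by 2*pi (one-sided differences at the ends).  An all-zero input is
    flagged degenerate with zero amplitude and frequency rather than raising.
    """
    x = np.asarray(imf, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("analytic_track needs a 1-D signal of at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not np.any(x):
        z = np.zeros(x.size)
        return AnalyticTrack(z, z.copy(), z.copy(), rate, degenerate=True)
    z = scipy.signal.hilbert(x)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    inst_freq = np.gradient(phase) * rate / (2.0 * np.pi)
    nyq = rate / 2.0
    invalid = float(np.mean((inst_freq < 0) | (inst_freq > nyq)))
    return AnalyticTrack(amplitude, phase, inst_freq, rate, invalid_fraction=invalid)


def _binned_energy(
    track: AnalyticTrack, freq_res: float, sl: slice = slice(None)
) -> np.ndarray:
    """Raw squared-amplitude histogram over integer-spaced frequency bins."""
    nyq = track.rate / 2.0
    n_bins = int(np.floor(nyq / freq_res)) + 1
    f = track.inst_freq[sl]
    w = track.amplitude[sl] ** 2
    valid = (f >= 0) & (f <= nyq)
    b = np.clip(np.rint(f[valid] / freq_res).astype(int), 0, n_bins - 1)
    return np.bincount(b, weights=w[valid], minlength=n_bins)


def marginal_spectrum(
    component: np.ndarray,
    track: AnalyticTrack,
    e_total: float,
    freq_res: float = 1.0,
    imf_index: int = 0,
) -> MarginalSpectrum:
    """Marginal frequency spectrum of one component, percent of segment energy.

    Each sample contributes its squared analytic amplitude to the bin nearest
    its instantaneous frequency; out-of-band samples are excluded and counted;
    the result is rescaled so its total equals the component's energy ratio
    ``sum(component**2) / e_total * 100``.
    """
    if e_total <= 0:
        raise ValueError("e_total must be positive")
    if freq_res <= 0:
        raise ValueError("freq_res must be positive")
    component = np.asarray(component, dtype=float)
    ratio_pct = float(np.sum(component**2)) / e_total * 100.0
    raw = _binned_energy(track, freq_res)
    total = raw.sum()
    if ratio_pct > 0 and total > 0:
        values = raw * (ratio_pct / total)
    else:
        values = np.zeros_like(raw)
    bin_freqs = np.arange(raw.size) * freq_res
    return MarginalSpectrum(
        imf_index=imf_index,
        bin_freqs=bin_freqs,
        values=values,
        freq_res=freq_res,
        excluded_fraction=track.invalid_fraction,
    )


def hilbert_spectrum(
    component: np.ndarray,
    track: AnalyticTrack,
    e_total: float,
    n_time_bins: int = 6,
    freq_res: float = 1.0,
    imf_index: int = 0,
) -> HilbertSpectrumGrid:
    """Time-binned Hilbert spectrum of one component.

    The analytic tracks of the full segment are sliced into ``n_time_bins``
    equal parts (any remainder of at most ``n_time_bins - 1`` samples is
    appended to the last bin and logged) and the marginal-spectrum binning is
    applied within each part.  The whole grid shares one rescaling factor with
    the marginal spectrum, so summing over time bins reproduces it exactly.
    """
    if n_time_bins < 1:
        raise ValueError("n_time_bins must be >= 1")
    if e_total <= 0:
        raise ValueError("e_total must be positive")
    component = np.asarray(component, dtype=float)
    n = component.size
    base = n // n_time_bins
    if base < 1:
        raise ValueError("segment too short for that many time bins")
    remainder = n - base * n_time_bins
    if remainder:
        log.info("appending %d remainder samples to the last time bin", remainder)
    ratio_pct = float(np.sum(component**2)) / e_total * 100.0
    rows = []
    for k in range(n_time_bins):
        a = k * base
        b = (k + 1) * base if k < n_time_bins - 1 else n
        rows.append(_binned_energy(track, freq_res, slice(a, b)))
    grid = np.vstack(rows)
    total = grid.sum()
    if ratio_pct > 0 and total > 0:
        grid = grid * (ratio_pct / total)
    else:
        grid = np.zeros_like(grid)
    return HilbertSpectrumGrid(
        imf_index=imf_index,
        values=grid,
        bin_freqs=np.arange(grid.shape[1]) * freq_res,
        time_bin_s=base / track.rate,
        freq_res=freq_res,
    )


def find_grid_extremes(
    grid,
    time_labels: np.ndarray | None = None,
    freq_labels: np.ndarray | None = None,
) -> GridExtremes:
    """Largest and second-largest cells of a Hilbert-spectrum grid.

    ``grid`` may be a :class:`HilbertSpectrumGrid` or a plain 2-D array of
    time rows by frequency columns (e.g. a grid transcribed from a printed
    table), with optional axis labels.  Ties break toward the earlier time
    bin, then the lower frequency.
    """
    if isinstance(grid, HilbertSpectrumGrid):
        values = grid.values
        time_labels = grid.time_labels_ms
        freq_labels = grid.bin_freqs
    else:
        values = np.asarray(grid, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("grid must be a non-empty 2-D array")
    nt, nf = values.shape
    if time_labels is None:
        time_labels = np.arange(nt)
    if freq_labels is None:
        freq_labels = np.arange(nf)
    t_idx, f_idx = np.unravel_index(np.arange(values.size), values.shape)
    flat = values.ravel()
    order = np.lexsort((f_idx, t_idx, -flat))  # primary: value desc, then tie-break
    i0 = order[0]
    result = {
        "max_value": float(flat[i0]),
        "max_time": float(time_labels[t_idx[i0]]),
        "max_freq": float(freq_labels[f_idx[i0]]),
        "second_value": None,
        "second_time": None,
        "second_freq": None,
    }
    if values.size > 1:
        i1 = order[1]
        result.update(
            second_value=float(flat[i1]),
            second_time=float(time_labels[t_idx[i1]]),
            second_freq=float(freq_labels[f_idx[i1]]),
        )
    return GridExtremes(**result)
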