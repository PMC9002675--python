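"""Energy density intensity (EDI): thresholded marginal-spectrum features.

Given a component's marginal spectrum R_i[x] (percent of segment energy per
1 Hz bin) and a threshold Delta (percent), bins with R_i[x] >= Delta are
retained and the rest zeroed; the EDI is the cumulative retained mass

    EDI_i = sum_x { R_i[x] : R_i[x] >= Delta }.

The main frequency band is the maximal contiguous run of retained bins that
contains the spectrum's global maximum (suprathreshold bins can be
non-contiguous; the full mask is kept alongside so no information is lost).
EDI is non-increasing in Delta, and at Delta = 0 it equals the component's
energy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hilbert import MarginalSpectrum

__all__ = ["EDIFeature", "threshold_mask", "edi", "edi_sweep", "sweep_frame"]


@dataclass(frozen=True)
class EDIFeature:
    """EDI summary of one marginal spectrum at one threshold.

    ``main_band`` is an inclusive (low, high) Hz pair, or ``None`` when no bin
    reaches the threshold.  ``mask`` holds the frequencies of every retained
    bin (a superset of the main band when the suprathreshold set is split).
    ``max_freq``/``max_bin_value`` describe the unmasked spectrum's global
    maximum (ties resolve to the lowest frequency).
    """

    imf_index: int
    threshold: float
    edi: float
    main_band: tuple[float, float] | None
    max_freq: float
    max_bin_value: float
    mask: np.ndarray


def threshold_mask(mf: MarginalSpectrum, delta: float) -> MarginalSpectrum:
    """Copy of ``mf`` with every bin below ``delta`` percent zeroed."""
    if delta < 0:
        raise ValueError("threshold must be >= 0")
    values = np.where(mf.values >= delta, mf.values, 0.0)
    return MarginalSpectrum(
        imf_index=mf.imf_index,
        bin_freqs=mf.bin_freqs,
        values=values,
        freq_res=mf.freq_res,
        excluded_fraction=mf.excluded_fraction,
    )


def edi(mf: MarginalSpectrum, delta: float) -> EDIFeature:
    """EDI, main frequency band and maximum-frequency feature at one threshold."""
    if delta < 0:
        raise ValueError("threshold must be >= 0")
    v = mf.values
    keep = v >= delta
    k_max = int(np.argmax(v))  # first occurrence -> lowest frequency on ties
    max_freq = float(mf.bin_freqs[k_max])
    max_val = float(v[k_max])
    if not keep.any() or max_val < delta:
        return EDIFeature(
            imf_index=mf.imf_index,
            threshold=delta,
            edi=0.0,
            main_band=None,
            max_freq=max_freq,
            max_bin_value=max_val,
            mask=np.array([]),
        )
    lo = k_max
    while lo > 0 and keep[lo - 1]:
        lo -= 1
    hi = k_max
    while hi < v.size - 1 and keep[hi + 1]:
        hi += 1
    return EDIFeature(
        imf_index=mf.imf_index,
        threshold=delta,
        edi=float(v[keep].sum()),
        main_band=(float(mf.bin_freqs[lo]), float(mf.bin_freqs[hi])),
        max_freq=max_freq,
        max_bin_value=max_val,
        mask=mf.bin_freqs[keep],
    )


def edi_sweep(mf: MarginalSpectrum, deltas: list[float]) -> list[EDIFeature]:
    """EDI features over a set of thresholds, returned in ascending order."""
    if not len(deltas):
        raise ValueError("deltas must be non-empty")
    deltas = sorted(float(d) for d in deltas)
    if deltas[0] < 0:
        raise ValueError("thresholds must be >= 0")
    return [edi(mf, d) for d in deltas]


def sweep_frame(features: list[EDIFeature]) -> pd.DataFrame:
    """Tabulate an EDI sweep: one row per (imf, threshold)."""
    rows = []
    for f in features:
        lo, hi = f.main_band if f.main_band is not None else (np.nan, np.nan)
        rows.append(
            {
                "imf": f.imf_index,
                "delta_pct": f.threshold,
                "edi_pct": f.edi,
                "band_low_hz": lo,
                "band_high_hz": hi,
                "max_freq_hz": f.max_freq,
                "max_bin_pct": f.max_bin_value,
            }
        )
    return pd.DataFrame(rows)
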