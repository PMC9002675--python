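"""Per-component energy ratios and averaging across analysis samples.

The total energy of a decomposed segment is the sum of the energies of its
components, E_total = sum_i sum_t IMF_i(t)^2 + sum_t rf(t)^2 — deliberately
a sum of component energies, not the energy of the summed signal, so that the
per-component ratios ENG_IMFi = E_i / E_total * 100 always total exactly
100% (cross terms between components are ignored by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emd import Decomposition
from .hilbert import MarginalSpectrum

__all__ = ["EnergyProfile", "energy_profile", "average_profiles", "average_spectra"]


@dataclass(frozen=True)
class EnergyProfile:
    """Total energy plus per-IMF and residue percentage ratios."""

    e_total: float
    ratios: np.ndarray  # percent per IMF, extraction order
    rf_ratio: float

    def __post_init__(self) -> None:
        ratios = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "ratios", ratios)
        if self.e_total < 0 or np.any(ratios < 0) or self.rf_ratio < 0:
            raise ValueError("energies and ratios must be non-negative")

    @property
    def n_imfs(self) -> int:
        return self.ratios.size


def energy_profile(d: Decomposition) -> EnergyProfile:
    """Energy ratios of a decomposition's IMFs and residue (percent of total)."""
    energies = np.array([float(np.sum(m**2)) for m in d.imfs])
    rf_energy = float(np.sum(d.residue**2))
    e_total = float(energies.sum() + rf_energy)
    if e_total <= 0:
        raise ValueError("all-zero decomposition: energy ratios are undefined")
    return EnergyProfile(
        e_total=e_total,
        ratios=energies / e_total * 100.0,
        rf_ratio=rf_energy / e_total * 100.0,
    )


def average_profiles(profiles: list[EnergyProfile]) -> EnergyProfile:
    """Unweighted arithmetic mean of energy-ratio profiles.

    All inputs must have the same number of IMFs — filter by IMF count first;
    averaging across unequal decomposition depths is not meaningful.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    n = profiles[0].n_imfs
    if any(p.n_imfs != n for p in profiles):
        raise ValueError("profiles have mixed IMF counts; filter before averaging")
    return EnergyProfile(
        e_total=float(np.mean([p.e_total for p in profiles])),
        ratios=np.mean([p.ratios for p in profiles], axis=0),
        rf_ratio=float(np.mean([p.rf_ratio for p in profiles])),
    )


def average_spectra(spectra: list[MarginalSpectrum]) -> MarginalSpectrum:
    """Bin-wise arithmetic mean of marginal spectra for one component.

    Inputs must share ``imf_index`` and ``freq_res``; bin ranges are unioned
    with zero fill so recordings at different rates can still be pooled.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    idx = spectra[0].imf_index
    res = spectra[0].freq_res
    if any(s.imf_index != idx for s in spectra):
        raise ValueError("spectra have mismatched imf_index")
    if any(s.freq_res != res for s in spectra):
        raise ValueError("spectra have mismatched freq_res")
    n_bins = max(s.values.size for s in spectra)
    acc = np.zeros(n_bins)
    for s in spectra:
        acc[: s.values.size] += s.values
    return MarginalSpectrum(
        imf_index=idx,
        bin_freqs=np.arange(n_bins) * res,
        values=acc / len(spectra),
        freq_res=res,
        excluded_fraction=float(np.mean([s.excluded_fraction for s in spectra])),
    )


def profiles_frame(profiles: list[EnergyProfile]) -> pd.DataFrame:
    """Tabulate profiles with columns IMF1..IMFn, RF (percent) and e_total."""
    if not profiles:
        return pd.DataFrame()
    n = profiles[0].n_imfs
    data = {f"IMF{i + 1}": [p.ratios[i] for p in profiles] for i in range(n)}
    data["RF"] = [p.rf_ratio for p in profiles]
    data["e_total"] = [p.e_total for p in profiles]
    return pd.DataFrame(data)
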