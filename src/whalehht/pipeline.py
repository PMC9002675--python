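"""End-to-end analysis pipeline: EMD -> energy -> MF -> EDI -> classify -> HS.

:func:`run_pipeline` chains the library stages over a recording (WAV file or
in-memory :class:`~whalehht.signal_io.Recording`), keeping only windows whose
decomposition depth matches ``n_imfs_filter``, and emits the tabular report
bundle: per-segment energy profiles, per-group averaged marginal spectra,
EDI threshold sweeps, classification results, averaged Hilbert-spectrum grids
restricted to each component's main frequency band, and a JSON manifest that
is sufficient to reproduce the run byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassCriteria, ClassifiedBatch, classify_batch
from .edi import edi, edi_sweep, sweep_frame
from .emd import Decomposition, sift
from .energy import EnergyProfile, average_profiles, average_spectra, energy_profile, profiles_frame
from .hilbert import (
    HilbertSpectrumGrid,
    MarginalSpectrum,
    analytic_track,
    hilbert_spectrum,
    marginal_spectrum,
)
from .signal_io import Recording, read_wav, segment_manifest, window_segments

__all__ = ["RunConfig", "SegmentAnalysis", "GroupSummary", "PipelineResult",
           "analyze_segment", "dominant_components", "dominant_profile", "run_pipeline"]

log = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.10g"  # fixed formatting keeps reruns byte-identical


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults mirror the B-call analysis protocol."""

    window_ms: float = 180.0
    subwindows: int = 6
    freq_res_hz: float = 1.0
    thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)
    n_imfs_filter: int = 4
    start: float = 0.0
    stop: float | None = None
    criteria: ClassCriteria = field(default_factory=ClassCriteria)
    seed: int | None = None
    stop_sd: float = 0.2
    max_sifts: int = 100
    max_imfs: int = 10
    hs_band_delta: float = 1.0  # threshold picking the HS export band

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.subwindows < 1:
            raise ValueError("window_ms must be > 0 and subwindows >= 1")
        if abs(self.window_ms / self.subwindows - round(self.window_ms / self.subwindows)) > 1e-9:
            raise ValueError("window_ms must divide evenly into subwindows")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        if self.n_imfs_filter < 1:
            raise ValueError("n_imfs_filter must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"] = dataclasses.asdict(self.criteria)
        d["thresholds"] = list(self.thresholds)
        return d


@dataclass
class SegmentAnalysis:
    """Everything computed for one retained analysis window."""

    segment: object
    decomp: Decomposition
    profile: EnergyProfile
    spectra: list[MarginalSpectrum]  # per IMF, extraction order (residue excluded)
    grids: list[HilbertSpectrumGrid]
    mf1_max_freq: float
    mf2_max_freq: float


@dataclass
class GroupSummary:
    """Class-level (or pooled) averages: profile, spectra, EDI sweeps, HS grids."""

    name: str
    indices: list
    avg_profile: EnergyProfile
    avg_spectra: list[MarginalSpectrum]
    sweeps: dict  # imf ordinal (1-based) -> list[EDIFeature]
    avg_grids: list[HilbertSpectrumGrid]


@dataclass
class PipelineResult:
    config: RunConfig
    source_id: str
    n_segments: int
    imf_count_histogram: dict
    analyses: list
    batch: ClassifiedBatch | None
    groups: dict
    empty: bool = False


def analyze_segment(segment, config: RunConfig = RunConfig()) -> SegmentAnalysis:
    """Decompose one window and compute its profile, spectra and HS grids."""
    d = sift(segment, stop_sd=config.stop_sd, max_sifts=config.max_sifts,
             max_imfs=config.max_imfs)
    return _analyses_for([segment], [d], config)[0]


def dominant_components(d: Decomposition, k: int = 2) -> list[int]:
    """Indices of the ``k`` highest-energy IMFs, in extraction order.

    Useful on synthetic data, where low-energy broadband-noise IMFs precede
    the tonal components in extraction order: the dominant pair ordered by
    extraction (fastest first) corresponds to the harmonic/fundamental pair.
    """
    energies = np.array([np.sum(m**2) for m in d.imfs])
    if energies.size < k:
        raise ValueError(f"decomposition has {energies.size} IMFs, need {k}")
    top = np.sort(np.argsort(energies)[::-1][:k])
    return [int(i) for i in top]


def dominant_profile(d: Decomposition, k: int = 2) -> EnergyProfile:
    """Energy profile reindexed to the ``k`` dominant IMFs.

    ``ratios[j]`` is the energy percentage (of the full decomposition total)
    of the j-th dominant component in extraction order; everything else —
    minor IMFs plus residue — is pooled into ``rf_ratio``.  This restores the
    "IMF1 = harmonic, IMF2 = fundamental" indexing that classification
    criteria assume when broadband noise prepends low-energy modes.
    """
    full = energy_profile(d)
    idx = dominant_components(d, k)
    ratios = full.ratios[idx]
    return EnergyProfile(
        e_total=full.e_total,
        ratios=ratios,
        rf_ratio=float(max(0.0, 100.0 - ratios.sum())),
    )


def _analyses_for(segments, decomps, config: RunConfig) -> list[SegmentAnalysis]:
    out = []
    for seg, d in zip(segments, decomps):
        prof = energy_profile(d)
        spectra, grids = [], []
        for i, imf in enumerate(d.imfs):
            track = analytic_track(imf, seg.rate)
            spectra.append(
                marginal_spectrum(imf, track, prof.e_total, config.freq_res_hz, imf_index=i)
            )
            grids.append(
                hilbert_spectrum(imf, track, prof.e_total, config.subwindows,
                                 config.freq_res_hz, imf_index=i)
            )
        out.append(
            SegmentAnalysis(
                segment=seg,
                decomp=d,
                profile=prof,
                spectra=spectra,
                grids=grids,
                mf1_max_freq=spectra[0].argmax_freq if spectra else float("nan"),
                mf2_max_freq=spectra[1].argmax_freq if len(spectra) > 1 else float("nan"),
            )
        )
    return out


def _average_grids(grids: list[HilbertSpectrumGrid]) -> HilbertSpectrumGrid:
    g0 = grids[0]
    values = np.mean([g.values for g in grids], axis=0)
    return HilbertSpectrumGrid(
        imf_index=g0.imf_index,
        values=values,
        bin_freqs=g0.bin_freqs,
        time_bin_s=g0.time_bin_s,
        freq_res=g0.freq_res,
    )


def _summarise(name: str, indices: list, analyses: list, config: RunConfig) -> GroupSummary:
    members = [analyses[i] for i in indices]
    n_imfs = members[0].profile.n_imfs
    avg_profile = average_profiles([m.profile for m in members])
    avg_spectra = [
        average_spectra([m.spectra[i] for m in members]) for i in range(n_imfs)
    ]
    sweeps = {
        i + 1: edi_sweep(avg_spectra[i], list(config.thresholds))
        for i in range(min(2, n_imfs))
    }
    avg_grids = [
        _average_grids([m.grids[i] for m in members]) for i in range(min(2, n_imfs))
    ]
    return GroupSummary(name=name, indices=list(indices), avg_profile=avg_profile,
                        avg_spectra=avg_spectra, sweeps=sweeps, avg_grids=avg_grids)


def run_pipeline(
    source,
    config: RunConfig = RunConfig(),
    outdir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run the six analysis stages over a WAV path or Recording.

    When ``outdir`` is given, the report bundle (CSV tables plus
    ``manifest.json``) is written there.  If no window survives the IMF-count
    filter the result is flagged ``empty`` and only the manifest plus an
    explicit empty-result report are written — an empty recording is an
    outcome, not a crash.
    """
    rec = source if isinstance(source, Recording) else read_wav(source)
    segments = window_segments(rec, start=config.start, stop=config.stop,
                               duration=config.window_ms / 1e3)
    decomps = [
        sift(s, stop_sd=config.stop_sd, max_sifts=config.max_sifts,
             max_imfs=config.max_imfs)
        for s in segments
    ]
    hist: dict[int, int] = {}
    for d in decomps:
        hist[d.n_imfs] = hist.get(d.n_imfs, 0) + 1
    kept_pairs = [
        (s, d) for s, d in zip(segments, decomps) if d.n_imfs == config.n_imfs_filter
    ]
    log.info("kept %d/%d windows with %d IMFs (histogram %s)",
             len(kept_pairs), len(segments), config.n_imfs_filter, hist)

    if not kept_pairs:
        result = PipelineResult(
            config=config, source_id=rec.source_id, n_segments=len(segments),
            imf_count_histogram=hist, analyses=[], batch=None, groups={}, empty=True,
        )
        if outdir is not None:
            _write_bundle(result, segments, outdir)
        return result

    analyses = _analyses_for([s for s, _ in kept_pairs], [d for _, d in kept_pairs], config)

    batch = None
    groups: dict[str, GroupSummary] = {}
    groups["all"] = _summarise("all", list(range(len(analyses))), analyses, config)
    if config.n_imfs_filter >= 2:
        batch = classify_batch(
            [(a.profile, a.mf1_max_freq, a.mf2_max_freq) for a in analyses],
            config.criteria,
        )
        if batch.class1_indices:
            groups["class_I"] = _summarise("class_I", batch.class1_indices, analyses, config)
        if batch.class2_indices:
            groups["class_II"] = _summarise("class_II", batch.class2_indices, analyses, config)

    result = PipelineResult(
        config=config, source_id=rec.source_id, n_segments=len(segments),
        imf_count_histogram=hist, analyses=analyses, batch=batch, groups=groups,
    )
    if outdir is not None:
        _write_bundle(result, segments, outdir)
    return result


def _band_slice(summary: GroupSummary, imf_ordinal: int, delta: float):
    """Column slice for HS export: the main band of the averaged MF at ``delta``."""
    feature = edi(summary.avg_spectra[imf_ordinal - 1], delta)
    if feature.main_band is None:
        return slice(None)
    spec = summary.avg_spectra[imf_ordinal - 1]
    lo = int(round(feature.main_band[0] / spec.freq_res))
    hi = int(round(feature.main_band[1] / spec.freq_res))
    return slice(lo, hi + 1)


def _write_bundle(result: PipelineResult, segments, outdir) -> None:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    kw = dict(float_format=CSV_FLOAT_FORMAT, index=False)

    segment_manifest(segments).to_csv(os.path.join(outdir, "segments.csv"), **kw)

    manifest = {
        "package_version": __version__,
        "source_id": result.source_id,
        "config": result.config.to_dict(),
        "n_segments": result.n_segments,
        "n_kept": len(result.analyses),
        "imf_count_histogram": {str(k): v for k, v in sorted(result.imf_count_histogram.items())},
        "empty": result.empty,
    }
    if result.analyses:
        manifest["kept_segment_indices"] = [a.segment.index for a in result.analyses]
        manifest["excluded_if_fraction_mean"] = float(
            np.mean([s.excluded_fraction for a in result.analyses for s in a.spectra])
        )
        manifest["sift_counts"] = [list(a.decomp.sift_counts) for a in result.analyses]
    if result.batch is not None:
        manifest["class_counts"] = {k.value: v for k, v in result.batch.counts.items()}
        manifest["n_ambiguous"] = result.batch.n_ambiguous
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if result.empty:
        with open(os.path.join(outdir, "empty_result.json"), "w") as fh:
            json.dump(
                {"reason": f"no window yielded {result.config.n_imfs_filter} IMFs",
                 "imf_count_histogram": manifest["imf_count_histogram"]},
                fh, indent=2,
            )
        return

    prof_df = profiles_frame([a.profile for a in result.analyses])
    prof_df.insert(0, "segment_index", [a.segment.index for a in result.analyses])
    prof_df.to_csv(os.path.join(outdir, "energy_profiles.csv"), **kw)

    if result.batch is not None:
        df = result.batch.to_frame()
        df["segment_index"] = [a.segment.index for a in result.analyses]
        df["mf1_max_freq_hz"] = [a.mf1_max_freq for a in result.analyses]
        df["mf2_max_freq_hz"] = [a.mf2_max_freq for a in result.analyses]
        df.to_csv(os.path.join(outdir, "classification.csv"), **kw)

    mf_rows, edi_frames, avg_prof_rows = [], [], []
    for name, g in result.groups.items():
        row = {"group": name, "n_samples": len(g.indices)}
        row.update({f"IMF{i + 1}": g.avg_profile.ratios[i]
                    for i in range(g.avg_profile.n_imfs)})
        row["RF"] = g.avg_profile.rf_ratio
        avg_prof_rows.append(row)
        for i, spec in enumerate(g.avg_spectra):
            support = np.flatnonzero(spec.values)
            hi = support[-1] + 1 if support.size else 1
            for k in range(hi):
                mf_rows.append({"group": name, "imf": i + 1,
                                "freq_hz": spec.bin_freqs[k],
                                "energy_pct": spec.values[k]})
        for ordinal, sweep in g.sweeps.items():
            df = sweep_frame(sweep)
            df.insert(0, "group", name)
            df["imf"] = ordinal
            edi_frames.append(df)
        for ordinal, grid in zip((1, 2), g.avg_grids):
            sl = _band_slice(g, ordinal, result.config.hs_band_delta)
            frame = grid.to_frame().iloc[:, sl]
            frame.to_csv(os.path.join(outdir, f"hs_{name}_imf{ordinal}.csv"),
                         float_format=CSV_FLOAT_FORMAT)
    pd.DataFrame(avg_prof_rows).to_csv(os.path.join(outdir, "energy_averages.csv"), **kw)
    pd.DataFrame(mf_rows).to_csv(os.path.join(outdir, "mf_averages.csv"), **kw)
    pd.concat(edi_frames, ignore_index=True).to_csv(os.path.join(outdir, "edi_sweep.csv"), **kw)
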