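"""Empirical mode decomposition by sifting, and exact reconstruction.

EMD splits a signal x(t) into a small ordered set of intrinsic mode functions
(IMFs) plus a residue,

    x(t) = sum_i IMF_i(t) + rf(t),

where each IMF is a locally zero-mean oscillation (its extrema and
zero-crossing counts differ by at most one) and the residue is the monotonic
or near-monotonic trend left over.  IMFs come out ordered from the fastest
oscillation to the slowest, which is what makes them useful as frequency
channels for tonal-call analysis.

Sifting: interpolate cubic-spline envelopes through the local maxima and
minima, subtract the envelope mean, and repeat until the candidate's change
between iterations is small (a Cauchy-type standard-deviation criterion).
Each accepted candidate is subtracted from the running residue and extraction
continues until the residue has fewer than two extrema of either kind or a
cap on the number of IMFs is reached.

Boundary handling mirrors the two extrema nearest each end of the signal
across that end before fitting the splines, the standard defence against
envelope swings at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = ["Decomposition", "sift", "reconstruct", "local_extrema", "imf_quality"]

DEFAULT_STOP_SD = 0.2
DEFAULT_MAX_SIFTS = 100
DEFAULT_MAX_IMFS = 10


@dataclass(frozen=True)
class Decomposition:
    """Ordered IMFs plus residue for one segment.

    ``sift_counts[i]`` is the number of sifting iterations that produced
    ``imfs[i]``.  Summing all IMFs and the residue reproduces the source
    signal exactly (to floating-point round-off), by construction.
    """

    imfs: tuple[np.ndarray, ...]
    residue: np.ndarray
    sift_counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        imfs = tuple(np.asarray(m, dtype=float) for m in self.imfs)
        residue = np.asarray(self.residue, dtype=float)
        object.__setattr__(self, "imfs", imfs)
        object.__setattr__(self, "residue", residue)
        n = residue.size
        for m in imfs:
            if m.size != n:
                raise ValueError("IMF/residue length mismatch")
        if self.sift_counts and len(self.sift_counts) != len(imfs):
            raise ValueError("sift_counts length must match number of IMFs")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def components(self) -> tuple[np.ndarray, ...]:
        """All components in extraction order, residue last."""
        return self.imfs + (self.residue,)

    def to_frame(self) -> pd.DataFrame:
        """One column per IMF plus a ``residue`` column."""
        cols = {f"imf{i + 1}": m for i, m in enumerate(self.imfs)}
        cols["residue"] = self.residue
        return pd.DataFrame(cols)

    def to_wav(self, path, rate: float) -> None:
        """Write the components as one multi-channel float WAV for audition.

        Channel order matches extraction order, residue last.
        """
        from scipy.io import wavfile

        data = np.stack(self.components, axis=1).astype(np.float32)
        wavfile.write(path, int(round(rate)), data)


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima of ``x``.

    Extrema are strict sign changes of the first difference; a plateau between
    opposite-signed slopes counts once, at its midpoint sample.  Endpoints are
    never extrema.
    """
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    nz = np.flatnonzero(dx != 0)
    empty = np.array([], dtype=int)
    if nz.size < 2:
        return empty, empty
    s = np.sign(dx[nz])
    chg = np.flatnonzero(s[:-1] != s[1:])
    if chg.size == 0:
        return empty, empty
    left = nz[chg] + 1          # first sample of the (possibly plateau) extremum
    right = nz[chg + 1]         # last sample of it
    mids = (left + right) // 2
    return mids[s[chg] > 0], mids[s[chg] < 0]


def _envelope(x: np.ndarray, idx: np.ndarray, kind: int) -> np.ndarray:
    """Cubic-spline envelope of ``x`` through the extrema at ``idx``.

    ``kind`` is +1 for the upper (maxima) envelope, -1 for the lower.  The two
    extrema nearest each end are mirrored across the end sample so the spline
    has support beyond the boundaries; when an end sample itself pokes beyond
    the nearest extremum it is adopted as an extra knot first, so the envelope
    always encloses the boundary (otherwise envelope-mean errors at the edges
    inject large spurious swings into the extracted modes).  With fewer than
    four knots the envelope degrades to linear interpolation.
    """
    n = x.size
    idx = np.asarray(idx)
    if kind * x[0] > kind * x[idx[0]]:
        idx = np.concatenate(([0], idx))
    if kind * x[-1] > kind * x[idx[-1]]:
        idx = np.concatenate((idx, [n - 1]))
    left = [(-i, x[i]) for i in idx[:2] if i > 0][::-1]
    right = [(2 * (n - 1) - i, x[i]) for i in idx[-2:][::-1] if i < n - 1]
    knots_i = np.array([p for p, _ in left] + list(idx) + [p for p, _ in right], float)
    knots_v = np.array([v for _, v in left] + list(x[idx]) + [v for _, v in right], float)
    t = np.arange(n, dtype=float)
    if knots_i.size >= 4:
        return CubicSpline(knots_i, knots_v)(t)
    return np.interp(t, knots_i, knots_v)


def sift(
    segment,
    stop_sd: float = DEFAULT_STOP_SD,
    max_sifts: int = DEFAULT_MAX_SIFTS,
    max_imfs: int = DEFAULT_MAX_IMFS,
) -> Decomposition:
    """Decompose a segment (or plain array) into IMFs plus a residue.

    Parameters
    ----------
    segment
        A :class:`~whalehht.signal_io.Segment` or a 1-D float array of at
        least 8 samples.
    stop_sd
        Cauchy stopping tolerance for one sift: iteration ends when
        ``sum((h_prev - h)**2) / sum(h_prev**2) < stop_sd``.
    max_sifts
        Hard cap on sifting iterations per IMF.
    max_imfs
        Hard cap on the number of IMFs extracted.

    A signal with fewer than two maxima or two minima (e.g. a constant) is its
    own residue and yields zero IMFs.  Sifting is deterministic: the same
    samples and parameters always give bit-identical output.
    """
    x = np.asarray(getattr(segment, "samples", segment), dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("sift needs a 1-D signal of at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if stop_sd <= 0 or max_sifts < 1 or max_imfs < 1:
        raise ValueError("stop_sd must be > 0 and iteration caps >= 1")

    imfs: list[np.ndarray] = []
    counts: list[int] = []
    residue = x.copy()
    for _ in range(max_imfs):
        mx, mn = local_extrema(residue)
        if mx.size < 2 or mn.size < 2:
            break  # monotonic / too few extrema: extraction is finished
        h = residue.copy()
        n_sift = 0
        for _ in range(max_sifts):
            hm, hn = local_extrema(h)
            if hm.size < 2 or hn.size < 2:
                break
            mean_env = 0.5 * (_envelope(h, hm, +1) + _envelope(h, hn, -1))
            h_new = h - mean_env
            n_sift += 1
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < stop_sd:
                break
        if n_sift == 0:
            break
        imfs.append(h)
        counts.append(n_sift)
        residue = residue - h
    return Decomposition(imfs=tuple(imfs), residue=residue, sift_counts=tuple(counts))


def reconstruct(d: Decomposition) -> np.ndarray:
    """Elementwise sum of all IMFs plus the residue (exact inverse of sift)."""
    out = d.residue.copy()
    for m in d.imfs:
        if m.size != out.size:
            raise ValueError("component length mismatch")
        out += m
    return out


def imf_quality(imf: np.ndarray, edge_fraction: float = 0.05) -> dict:
    """Diagnostic counts for the IMF admissibility condition.

    Counts extrema and zero crossings over the central portion of the signal
    (the first and last ``edge_fraction`` of samples are excluded, where the
    mirrored-envelope boundary treatment leaves artefacts).  For a clean IMF
    the two counts differ by at most one.
    """
    x = np.asarray(imf, dtype=float)
    k = int(round(edge_fraction * x.size))
    core = x[k : x.size - k] if k else x
    mx, mn = local_extrema(core)
    zc = int(np.sum(np.signbit(core[:-1]) != np.signbit(core[1:])))
    n_ext = int(mx.size + mn.size)
    return {"n_extrema": n_ext, "n_zero_crossings": zc, "difference": abs(n_ext - zc)}
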