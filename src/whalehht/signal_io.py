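"""WAV input, segmentation into fixed-length analysis windows, and IMF-count filtering.

Passive acoustic monitoring (PAM) recordings of tonal whale calls arrive as
mono PCM WAV files.  Analysis proceeds on short fixed-duration windows
(180 ms by default elsewhere in the package) carved out of a caller-supplied
"valid signal" interval; windows are non-overlapping and contiguous, and a
trailing remainder shorter than one window is discarded.  After empirical mode
decomposition, only windows that yielded a chosen number of intrinsic mode
functions are retained for class-level statistics, because energy-ratio
features are only comparable between decompositions of equal depth.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Segment",
    "read_wav",
    "write_wav",
    "window_segments",
    "filter_by_imf_count",
    "segment_manifest",
]

log = logging.getLogger(__name__)

# peak absolute value per integer PCM dtype, used to scale into [-1, 1]
_PCM_PEAK = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
    np.dtype(np.uint8): 2.0**7,
}


@dataclass(frozen=True)
class Recording:
    """A mono recording: amplitude samples (dimensionless) at a fixed rate in Hz."""

    samples: np.ndarray
    rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("recording must hold a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        """Total length in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class Segment:
    """One fixed-duration analysis window cut from a recording.

    ``start_time`` is the offset of the window's first sample within the parent
    recording, in seconds; ``index`` is the window's ordinal within the cut.
    """

    samples: np.ndarray
    rate: float
    start_time: float
    index: int
    duration: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.duration > 0:
            raise ValueError("segment duration must be positive")
        if self.start_time < 0:
            raise ValueError("segment start_time must be >= 0")
        expected = int(round(self.rate * self.duration))
        if samples.size != expected:
            raise ValueError(
                f"segment length {samples.size} != round(rate*duration) = {expected}"
            )

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path: str | os.PathLike) -> Recording:
    """Read a PCM or float WAV file into a :class:`Recording`.

    Integer PCM samples are rescaled to [-1, 1]; float data is passed through.
    Multi-channel audio is collapsed to channel 0 (hydrophone data is mono in
    practice, and silently downmixing would alter energies) with a warning.
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on corrupt headers
        raise OSError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path!r} contains no audio")
    if data.ndim > 1:
        log.warning(
            "multi-channel WAV %r (%d channels): keeping channel 0", path, data.shape[1]
        )
        data = data[:, 0]
    peak = _PCM_PEAK.get(data.dtype)
    if peak is not None:
        if data.dtype == np.uint8:  # 8-bit WAV is unsigned, centred on 128
            samples = (data.astype(float) - 128.0) / peak
        else:
            samples = data.astype(float) / peak
    else:
        samples = data.astype(float)
    return Recording(samples=samples, rate=float(rate), source_id=os.fspath(path))


def write_wav(path: str | os.PathLike, rec: Recording, dtype: str = "int16") -> None:
    """Write a recording as WAV; ``dtype`` one of ``int16`` (PCM) or ``float32``."""
    x = np.clip(rec.samples, -1.0, 1.0)
    if dtype == "int16":
        data = np.round(x * (2.0**15 - 1)).astype(np.int16)
    elif dtype == "float32":
        data = x.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(os.fspath(path), int(round(rec.rate)), data)


def window_segments(
    rec: Recording,
    start: float = 0.0,
    stop: float | None = None,
    duration: float = 0.180,
) -> list[Segment]:
    """Cut ``rec[start:stop]`` into non-overlapping, contiguous windows.

    Returns ``floor((stop - start) / duration)`` segments (computed on the
    sample grid, so e.g. a 16.92 s interval at 180 ms yields exactly 94).
    A trailing remainder shorter than one window is discarded and its length
    logged.  ``stop`` defaults to the end of the recording.
    """
    if stop is None:
        stop = rec.duration
    if duration <= 0:
        raise ValueError("window duration must be positive")
    if not (0 <= start < stop):
        raise ValueError(f"need 0 <= start < stop, got start={start}, stop={stop}")
    if stop > rec.duration + 0.5 / rec.rate:
        raise ValueError(
            f"stop={stop} s exceeds recording length {rec.duration:.6f} s"
        )

    win = int(round(rec.rate * duration))
    if win < 1:
        raise ValueError("window duration shorter than one sample")
    i0 = int(round(start * rec.rate))
    i1 = min(int(round(stop * rec.rate)), rec.samples.size)
    n_seg = (i1 - i0) // win
    remainder = (i1 - i0) - n_seg * win
    if remainder:
        log.info(
            "discarding %.4f s trailing remainder (%d samples < one %d-sample window)",
            remainder / rec.rate,
            remainder,
            win,
        )
    segments = []
    for k in range(n_seg):
        a = i0 + k * win
        segments.append(
            Segment(
                samples=rec.samples[a : a + win],
                rate=rec.rate,
                start_time=a / rec.rate,
                index=k,
                duration=duration,
            )
        )
    return segments


def filter_by_imf_count(decomps: list, n_imfs: int) -> list:
    """Return the decompositions with exactly ``n_imfs`` IMFs, preserving order.

    An empty result is returned (not raised) when none match: attrition is a
    normal outcome of the stopping criterion on real recordings.
    """
    if n_imfs < 1:
        raise ValueError("n_imfs must be >= 1")
    if not decomps:
        raise ValueError("decomposition list is empty")
    return [d for d in decomps if d.n_imfs == n_imfs]


def segment_manifest(segments: list[Segment]) -> pd.DataFrame:
    """Tabulate segments as (index, start_time_s, duration_s, n_samples)."""
    return pd.DataFrame(
        {
            "index": [s.index for s in segments],
            "start_time_s": [s.start_time for s in segments],
            "duration_s": [s.duration for s in segments],
            "n_samples": [len(s) for s in segments],
        }
    )
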