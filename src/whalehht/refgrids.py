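"""Reference Hilbert-spectrum grids for a Scripps Whale Acoustics Lab B call.

These four small time-frequency-energy grids are the published worked-example
output of this analysis method on a 46.65 s B-call recording (180 ms analysis
windows, six 30 ms time bins, 1 Hz frequency bins, values in percent of
segment energy).  They serve as desk-scale fixtures: feeding them to
:func:`whalehht.hilbert.find_grid_extremes` must reproduce their known
largest and second-largest cells.

Rows are time bins ending at 30..180 ms; columns are the main-band frequency
bins (41-50 Hz for the first-IMF grids, 10-15 Hz for the second-IMF grids).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hilbert import GridExtremes, find_grid_extremes

__all__ = ["ReferenceGrid", "HS1_CLASS_I", "HS1_CLASS_II", "HS2_CLASS_I",
           "HS2_CLASS_II", "ALL_GRIDS"]

TIME_MS = np.array([30, 60, 90, 120, 150, 180], dtype=float)


@dataclass(frozen=True)
class ReferenceGrid:
    name: str
    values: np.ndarray  # (time, freq), percent of segment energy
    time_ms: np.ndarray
    freq_hz: np.ndarray

    def extremes(self) -> GridExtremes:
        return find_grid_extremes(self.values, self.time_ms, self.freq_hz)


HS1_CLASS_I = ReferenceGrid(
    name="hs1_class_I",
    time_ms=TIME_MS,
    freq_hz=np.arange(41, 51, dtype=float),
    values=np.array([
        [5.3772, 2.7042, 2.0189, 1.6313, 2.2850, 1.3131, 1.4670, 1.8087, 1.1427, 0.9644],
        [1.8089, 2.3290, 2.5002, 2.2260, 1.5188, 2.5957, 2.2484, 2.9589, 1.5979, 0.6230],
        [4.2118, 5.3723, 3.9669, 4.3410, 1.6975, 1.3459, 1.7999, 1.7419, 2.1899, 1.6947],
        [3.2341, 2.5195, 3.1334, 2.8402, 2.9004, 2.8112, 2.8166, 1.5609, 2.4858, 1.8153],
        [1.3895, 1.4866, 1.5857, 3.0558, 2.3109, 1.6275, 3.2360, 2.4181, 2.5619, 1.9033],
        [4.0709, 3.6968, 3.3743, 2.7741, 3.5424, 3.6585, 4.0669, 2.6698, 2.2187, 3.2907],
    ]),
)

HS1_CLASS_II = ReferenceGrid(
    name="hs1_class_II",
    time_ms=TIME_MS,
    freq_hz=np.arange(41, 51, dtype=float),
    values=np.array([
        [1.8098, 1.6628, 1.6385, 1.8475, 1.3740, 1.1829, 1.4319, 0.8178, 0.5399, 0.1937],
        [0.6000, 0.7085, 0.5411, 1.1298, 1.3377, 1.2971, 1.0400, 1.0035, 1.0035, 0.8401],
        [1.2738, 1.4977, 1.5970, 1.9975, 2.1943, 1.4831, 1.3497, 1.1374, 1.1374, 1.1350],
        [1.2376, 0.7775, 0.7527, 1.0351, 0.7279, 0.7795, 0.4897, 0.8161, 0.8161, 0.8087],
        [0.5638, 0.6451, 0.6744, 0.7585, 2.0259, 2.2794, 1.7586, 1.2902, 1.2902, 1.7578],
        [1.2230, 0.8972, 1.0387, 1.7696, 0.9117, 1.3053, 1.2976, 1.0124, 1.0124, 0.7057],
    ]),
)

HS2_CLASS_I = ReferenceGrid(
    name="hs2_class_I",
    time_ms=TIME_MS,
    freq_hz=np.arange(10, 16, dtype=float),
    values=np.array([
        [0.1397, 0.1436, 0.1450, 0.1035, 0.0915, 0.1032],
        [0.2132, 0.1826, 0.1443, 0.1220, 0.1377, 0.0893],
        [0.1161, 0.1367, 0.1169, 0.1595, 0.1507, 0.1042],
        [0.0924, 0.0873, 0.0853, 0.0839, 0.0665, 0.0642],
        [0.0994, 0.0929, 0.0608, 0.0772, 0.0666, 0.1291],
        [0.2417, 0.2281, 0.1939, 0.2113, 0.2132, 0.1520],
    ]),
)

HS2_CLASS_II = ReferenceGrid(
    name="hs2_class_II",
    time_ms=TIME_MS,
    freq_hz=np.arange(10, 16, dtype=float),
    values=np.array([
        [0.6355, 1.9432, 2.0005, 1.3782, 1.7531, 1.7134],
        [0.8390, 0.7247, 0.6159, 0.5713, 0.3830, 0.3698],
        [0.8440, 4.1130, 6.9196, 2.2401, 1.3338, 0.9931],
        [1.9624, 2.2184, 1.5042, 3.6569, 1.5626, 1.8535],
        [0.3579, 0.3781, 0.3199, 0.3984, 0.3454, 0.3895],
        [0.8606, 0.6916, 0.6527, 1.6893, 1.6208, 1.6371],
    ]),
)

ALL_GRIDS = (HS1_CLASS_I, HS1_CLASS_II, HS2_CLASS_I, HS2_CLASS_II)
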