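"""Two-class B-call assignment from energy ratios and maximum frequencies.

A decomposed segment is Class I when its first IMF dominates the energy
budget (ENG_IMF1 strictly above a threshold, default 70%) and the maximum
frequency of that IMF's marginal spectrum falls in the harmonic band (default
41-45 Hz inclusive).  It is Class II when the second IMF carries a large
share (ENG_IMF2 strictly above 30% by default) and its maximum frequency sits
in the fundamental band (default 10-14 Hz).  Segments meeting neither pair of
criteria stay unclassified; a segment meeting both is labelled Class I and
flagged ambiguous.  The band edges are configuration, not constants: B-call
harmonic bands shift between recording sites, so criteria load from a
key-value config file as easily as from defaults.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .energy import EnergyProfile

__all__ = ["Label", "ClassCriteria", "ClassLabel", "ClassifiedBatch",
           "classify_segment", "classify_batch"]


class Label(str, enum.Enum):
    CLASS_I = "CLASS_I"
    CLASS_II = "CLASS_II"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassCriteria:
    """Thresholds and frequency ranges for the two classes (Hz ranges inclusive)."""

    class1_imf1_min: float = 70.0
    class1_freq_range: tuple[float, float] = (41.0, 45.0)
    class2_imf2_min: float = 30.0
    class2_freq_range: tuple[float, float] = (10.0, 14.0)

    def __post_init__(self) -> None:
        for thr in (self.class1_imf1_min, self.class2_imf2_min):
            if not (0.0 < thr < 100.0):
                raise ValueError(f"energy threshold {thr} must be in (0, 100)")
        for lo, hi in (self.class1_freq_range, self.class2_freq_range):
            if lo > hi:
                raise ValueError(f"empty frequency range ({lo}, {hi})")

    @classmethod
    def from_mapping(cls, d: dict) -> "ClassCriteria":
        kwargs = {}
        for key in ("class1_imf1_min", "class2_imf2_min"):
            if key in d:
                kwargs[key] = float(d[key])
        for key in ("class1_freq_range", "class2_freq_range"):
            if key in d:
                lo, hi = d[key]
                kwargs[key] = (float(lo), float(hi))
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ClassCriteria":
        """Load criteria from a YAML/JSON key-value file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"criteria file {path!r} must hold a key-value mapping")
        return cls.from_mapping(data)


@dataclass(frozen=True)
class ClassLabel:
    label: Label
    trace: dict = field(default_factory=dict)  # per-criterion booleans
    ambiguous: bool = False


@dataclass(frozen=True)
class ClassifiedBatch:
    labels: list
    class1_indices: list
    class2_indices: list
    unclassified_indices: list
    n_ambiguous: int

    @property
    def counts(self) -> dict:
        return {
            Label.CLASS_I: len(self.class1_indices),
            Label.CLASS_II: len(self.class2_indices),
            Label.UNCLASSIFIED: len(self.unclassified_indices),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.labels):
            row = {"segment_id": i, "label": lab.label.value, "ambiguous": lab.ambiguous}
            row.update(lab.trace)
            rows.append(row)
        return pd.DataFrame(rows)


def classify_segment(
    profile: EnergyProfile,
    mf1_max_freq: float,
    mf2_max_freq: float,
    criteria: ClassCriteria = ClassCriteria(),
) -> ClassLabel:
    """Label one segment from its energy profile and per-IMF maximum frequencies.

    ``mf1_max_freq`` / ``mf2_max_freq`` are the argmax bins of the segment's
    first and second IMF marginal spectra (unmasked, so no threshold choice is
    involved).  Energy thresholds are strict inequalities; frequency range
    endpoints are inclusive.
    """
    if profile.n_imfs < 2:
        raise ValueError("classification needs at least two IMFs")
    c = criteria
    trace = {
        "class1_energy": bool(profile.ratios[0] > c.class1_imf1_min),
        "class1_freq": bool(c.class1_freq_range[0] <= mf1_max_freq <= c.class1_freq_range[1]),
        "class2_energy": bool(profile.ratios[1] > c.class2_imf2_min),
        "class2_freq": bool(c.class2_freq_range[0] <= mf2_max_freq <= c.class2_freq_range[1]),
    }
    is1 = trace["class1_energy"] and trace["class1_freq"]
    is2 = trace["class2_energy"] and trace["class2_freq"]
    if is1:
        return ClassLabel(Label.CLASS_I, trace, ambiguous=is2)
    if is2:
        return ClassLabel(Label.CLASS_II, trace)
    return ClassLabel(Label.UNCLASSIFIED, trace)


def classify_batch(
    items: list[tuple[EnergyProfile, float, float]],
    criteria: ClassCriteria = ClassCriteria(),
) -> ClassifiedBatch:
    """Classify (profile, mf1_max_freq, mf2_max_freq) triples, preserving order."""
    if not items:
        raise ValueError("batch is empty")
    labels = [classify_segment(p, f1, f2, criteria) for p, f1, f2 in items]
    by = {Label.CLASS_I: [], Label.CLASS_II: [], Label.UNCLASSIFIED: []}
    for i, lab in enumerate(labels):
        by[lab.label].append(i)
    return ClassifiedBatch(
        labels=labels,
        class1_indices=by[Label.CLASS_I],
        class2_indices=by[Label.CLASS_II],
        unclassified_indices=by[Label.UNCLASSIFIED],
        n_ambiguous=sum(lab.ambiguous for lab in labels),
    )
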