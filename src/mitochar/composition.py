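"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on the
strand stated for each region.  Both statistics flip sign under reverse
complement, so the strand convention matters: whole-genome values are given
on the J-strand (on which lepidopteran mitogenomes show slightly negative AT
skew), while per-gene-class values use each gene's coding strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core import AnnotationSet, MitogenomeRecord, extract_sequence


@dataclass
class CompositionSummary:
    """Base counts and derived statistics for one named region.

    Skews are ``None`` when their denominator is zero; ``other`` counts
    non-ACGT symbols, which are excluded from fractions and skews.
    """

    region: str
    a: int
    c: int
    g: int
    t: int
    other: int = 0

    @property
    def total_acgt(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_fraction(self) -> Optional[float]:
        n = self.total_acgt
        return (self.a + self.t) / n if n else None

    @property
    def at_skew(self) -> Optional[float]:
        d = self.a + self.t
        return (self.a - self.t) / d if d else None

    @property
    def gc_skew(self) -> Optional[float]:
        d = self.g + self.c
        return (self.g - self.c) / d if d else None


def base_counts(seq: str, region: str = "sequence") -> CompositionSummary:
    """Count A/C/G/T; anything else (IUPAC ambiguity, gaps) tallies as other."""
    c = Counter(seq.upper())
    acgt = {b: c.pop(b, 0) for b in "ACGT"}
    return CompositionSummary(region=region, a=acgt["A"], c=acgt["C"],
                              g=acgt["G"], t=acgt["T"],
                              other=sum(c.values()))


def at_content(seq: str) -> Optional[float]:
    return base_counts(seq).at_fraction


def at_skew(seq: str) -> Optional[float]:
    return base_counts(seq).at_skew


def gc_skew(seq: str) -> Optional[float]:
    return base_counts(seq).gc_skew


#: Region classes reported by :func:`region_composition_report`, in order.
REGION_CLASSES = ("whole", "PCGs", "tRNAs", "rRNAs", "control_region")

_CLASS_OF = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs",
             "control_region": "control_region"}


def region_composition_report(rec: MitogenomeRecord,
                              ann: AnnotationSet) -> list[CompositionSummary]:
    """Composition summaries for the whole genome and each gene class.

    Class sequences are the concatenation, in annotation order, of each
    member gene's coding-strand sequence (N-strand genes are
    reverse-complemented).  The whole-genome summary is computed on the
    J-strand as written.  Classes with no features are omitted.
    """
    out = [base_counts(rec.sequence, "whole")]
    parts: dict[str, list[str]] = {c: [] for c in REGION_CLASSES[1:]}
    for f in ann.features:
        parts[_CLASS_OF[f.category]].append(extract_sequence(rec, f))
    for cls in REGION_CLASSES[1:]:
        if parts[cls]:
            out.append(base_counts("".join(parts[cls]), cls))
    return out


def composition_frame(summaries: list[CompositionSummary]) -> pd.DataFrame:
    """Tabular report: counts, AT% (one decimal, as conventionally printed),
    and full-precision skews."""
    rows = []
    for s in summaries:
        rows.append({
            "region": s.region, "A": s.a, "C": s.c, "G": s.g, "T": s.t,
            "other": s.other,
            "AT_percent": None if s.at_fraction is None else round(100 * s.at_fraction, 1),
            "AT_skew": s.at_skew, "GC_skew": s.gc_skew,
        })
    return pd.DataFrame(rows)
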