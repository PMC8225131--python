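"""Locate the A+T-rich (control) region and scan its conserved elements.

In lepidopteran mitogenomes the control region is the largest non-coding
stretch, lying between rrnS and trnM on the circle.  Its conserved anatomy
comprises the motif ATAG followed by a long poly-T stretch, the motif ATTTA
followed by (AT)n microsatellites, and a poly-A stretch near the 3' end.
All reported positions are 1-based within the scanned sequence; runs are
maximal (non-extendable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .core import AnnotationSet, GeneFeature


@dataclass(frozen=True)
class MotifParams:
    """Scan thresholds; the defaults encode 'large' runs conservatively."""

    min_poly_t: int = 7
    min_poly_a: int = 5
    min_at_repeats: int = 3          # (AT)n with n >= 3
    atag_poly_t_window: int = 20     # max gap between ATAG and its poly-T


DEFAULT_MOTIF_PARAMS = MotifParams()


@dataclass
class AtagHit:
    position: int                    # 1-based start of ATAG
    poly_t_start: Optional[int]      # nearest downstream run within window
    poly_t_length: Optional[int]


@dataclass
class RunHit:
    position: int                    # 1-based start of the maximal run
    length: int                      # bp ((AT)n runs: 2n)


@dataclass
class MotifReport:
    atag: list[AtagHit] = field(default_factory=list)
    attta: list[RunHit] = field(default_factory=list)      # length always 5
    at_repeats: list[RunHit] = field(default_factory=list)
    poly_t: list[RunHit] = field(default_factory=list)
    poly_a: list[RunHit] = field(default_factory=list)


def locate_control_region(ann: AnnotationSet,
                          genome_length: Optional[int] = None) -> GeneFeature:
    """Derive the control region as the interval between rrnS and trnM.

    The region runs from the base after the end of rrnS to the base before
    the start of trnM on the circle; when trnM starts at position 1 (the
    conventional rotation) it is (end(rrnS)+1 .. genome_length).
    """
    L = genome_length or ann.genome_length
    rrns = ann.get("rrnS")
    trnm = ann.get("trnM")
    start = rrns.end + 1
    if trnm.start == 1:
        end, wraps = L, False
    elif trnm.start > start:
        end, wraps = trnm.start - 1, False
    else:
        end, wraps = trnm.start - 1, True
    return GeneFeature(name="CR", category="control_region", strand="J",
                       start=start, end=end, wraps=wraps)


def _maximal_runs(seq: str, base: str, min_len: int) -> list[RunHit]:
    hits = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                hits.append(RunHit(position=i + 1, length=j - i))
            i = j
        else:
            i += 1
    return hits


def _maximal_at_repeats(seq: str, min_repeats: int) -> list[RunHit]:
    """Maximal substrings of the form (AT)^n, n >= min_repeats; a run is
    maximal when it cannot be extended by another full AT unit on either
    side."""
    hits = []
    n = len(seq)
    i = 0
    while i + 1 < n:
        if seq[i] == "A" and seq[i + 1] == "T":
            j = i
            while j + 1 < n and seq[j] == "A" and seq[j + 1] == "T":
                j += 2
            reps = (j - i) // 2
            if reps >= min_repeats:
                hits.append(RunHit(position=i + 1, length=2 * reps))
            i = j
        else:
            i += 1
    return hits


def _find_all(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) 1-based occurrence starts."""
    out = []
    start = seq.find(motif)
    while start != -1:
        out.append(start + 1)
        start = seq.find(motif, start + 1)
    return out


def scan_motifs(seq: str,
                params: MotifParams = DEFAULT_MOTIF_PARAMS) -> MotifReport:
    """Left-to-right scan of a control-region sequence (5'->3', J-strand).

    Every ATAG occurrence is paired with the nearest downstream maximal
    poly-T run starting within ``atag_poly_t_window`` bp of the motif's
    end; poly-T/poly-A/(AT)n runs are reported once each, as maximal runs.
    """
    seq = seq.upper().replace("U", "T")
    report = MotifReport(
        attta=[RunHit(position=p, length=5) for p in _find_all(seq, "ATTTA")],
        at_repeats=_maximal_at_repeats(seq, params.min_at_repeats),
        poly_t=_maximal_runs(seq, "T", params.min_poly_t),
        poly_a=_maximal_runs(seq, "A", params.min_poly_a),
    )
    for pos in _find_all(seq, "ATAG"):
        after = pos + 4  # 1-based position just past the motif
        cand = [r for r in report.poly_t
                if after <= r.position <= after + params.atag_poly_t_window]
        if cand:
            nearest = min(cand, key=lambda r: r.position)
            report.atag.append(AtagHit(pos, nearest.position, nearest.length))
        else:
            report.atag.append(AtagHit(pos, None, None))
    return report


def motif_frame(report: MotifReport) -> pd.DataFrame:
    rows = []
    for h in report.atag:
        rows.append({"element": "ATAG", "position": h.position,
                     "length": 4, "poly_t_start": h.poly_t_start,
                     "poly_t_length": h.poly_t_length})
    for name, hits in (("ATTTA", report.attta), ("AT_repeat", report.at_repeats),
                       ("poly_T", report.poly_t), ("poly_A", report.poly_a)):
        for h in hits:
            rows.append({"element": name, "position": h.position,
                         "length": h.length, "poly_t_start": None,
                         "poly_t_length": None})
    return pd.DataFrame(rows, columns=["element", "position", "length",
                                       "poly_t_start", "poly_t_length"])
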