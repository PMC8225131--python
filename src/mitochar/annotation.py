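"""Genome-organization statistics: intergenic spacers and overlaps, strand
census, circular gene order and rearrangement detection, start/stop codon
extraction.

The spacer convention follows mitogenome organization tables: the spacer on
the pair (upstream, downstream) is ``start(downstream) - end(upstream) - 1``,
so abutting genes score 0 and an 8-bp overlap scores -8.  The circular
closure pair (last feature back to the first) is included.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .codons import GeneticCode, INVERTEBRATE_MITO
from .core import AnnotationSet, GeneFeature, MitogenomeRecord, extract_sequence


@dataclass
class SpacerEntry:
    upstream: str
    downstream: str
    spacer: int  # bp; negative = overlap


@dataclass
class StrandCensus:
    """Feature counts keyed by (strand, category); control region excluded."""

    counts: dict[tuple[str, str], int]

    def strand_total(self, strand: str) -> int:
        return sum(n for (s, _), n in self.counts.items() if s == strand)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CodonReport:
    gene: str
    start_codon: str
    stop_codon: str          # TAA/TAG complete, or truncated T/TA
    stop_class: str          # "complete" | "truncated"


def intergenic_table(ann: AnnotationSet, auto_sort: bool = False) -> list[SpacerEntry]:
    """One spacer entry per adjacent feature pair, closure pair included.

    Features must be in ascending start order along the J-strand reading of
    the circle (``auto_sort=True`` sorts a copy instead of rejecting).
    """
    feats = list(ann.features)
    starts = [f.start for f in feats]
    if starts != sorted(starts):
        if not auto_sort:
            raise ValueError(
                f"{ann.record_id}: features are not sorted by start; pass "
                "auto_sort=True to sort")
        feats = sorted(feats, key=lambda f: f.start)
    entries = []
    for a, b in zip(feats, feats[1:]):
        entries.append(SpacerEntry(a.name, b.name, b.start - a.end - 1))
    if len(feats) > 1:
        a, b = feats[-1], feats[0]
        entries.append(SpacerEntry(
            a.name, b.name, b.start + ann.genome_length - a.end - 1))
    return entries


def spacer_frame(entries: list[SpacerEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def strand_census(ann: AnnotationSet) -> StrandCensus:
    c = Counter((f.strand, f.category) for f in ann.features
                if f.category != "control_region")
    return StrandCensus(counts=dict(c))


def gene_order(ann: AnnotationSet, first_gene: str = "trnM") -> list[tuple[str, str]]:
    """(name, strand) pairs in circular order starting at ``first_gene``;
    the control region is not part of the gene order."""
    feats = sorted((f for f in ann.features if f.category != "control_region"),
                   key=lambda f: f.start)
    names = [f.name for f in feats]
    if first_gene not in names:
        raise ValueError(f"{ann.record_id}: first gene {first_gene!r} absent")
    i = names.index(first_gene)
    rotated = feats[i:] + feats[:i]
    return [(f.name, f.strand) for f in rotated]


# ---------------------------------------------------------------------------
# circular gene-order comparison
# ---------------------------------------------------------------------------

@dataclass
class RearrangementReport:
    """Genes outside a longest common circular subsequence of two orders."""

    moved: frozenset[str]
    conserved: tuple[str, ...]   # one maximal common circular subsequence


def _lcs_traceback(a: list[str], b: list[str]) -> list[str]:
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            row[j] = nxt[j + 1] + 1 if a[i] == b[j] else max(nxt[j], row[j + 1])
    out: list[str] = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            out.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def compare_gene_order(observed, reference) -> RearrangementReport:
    """Minimal moved-gene set between two circular gene orders.

    Both arguments are sequences of gene names or (name, strand) pairs over
    the same name set, each name occurring once.  The longest common
    *circular* subsequence is found exactly: any cyclic common subsequence
    can be cut immediately before one of its genes, and since names are
    unique that gene fixes the rotation of both orders — so taking the best
    linear LCS over all same-gene cuts is exhaustive.
    """
    obs = [g[0] if isinstance(g, tuple) else g for g in observed]
    ref = [g[0] if isinstance(g, tuple) else g for g in reference]
    if len(set(obs)) != len(obs) or len(set(ref)) != len(ref):
        raise ValueError("gene orders must not repeat names")
    if set(obs) != set(ref):
        only_obs = sorted(set(obs) - set(ref))
        only_ref = sorted(set(ref) - set(obs))
        raise ValueError(
            f"gene name sets differ: only in observed {only_obs}, only in "
            f"reference {only_ref}")
    if not obs:
        return RearrangementReport(moved=frozenset(), conserved=())
    ref_pos = {g: i for i, g in enumerate(ref)}
    best: list[str] = []
    for g in obs:
        i = obs.index(g)
        j = ref_pos[g]
        cand = _lcs_traceback(obs[i:] + obs[:i], ref[j:] + ref[:j])
        if len(cand) > len(best):
            best = cand
    return RearrangementReport(moved=frozenset(set(obs) - set(best)),
                               conserved=tuple(best))


# ---------------------------------------------------------------------------
# start / stop codons
# ---------------------------------------------------------------------------

def extract_codons(rec: MitogenomeRecord, ann: AnnotationSet,
                   code: GeneticCode = INVERTEBRATE_MITO) -> list[CodonReport]:
    """Start and stop codons of every protein-coding gene.

    The start is the first 3 nt of the coding sequence.  When the CDS length
    is not a multiple of 3 the trailing 1-2 nt are the stop, classified
    truncated (completed to TAA by polyadenylation); a truncated stop that is
    not a prefix of TAA is reported with a warning.  Otherwise the final
    codon is the stop, classified complete.
    """
    reports = []
    for f in ann.by_category("PCG"):
        seq = extract_sequence(rec, f)
        if len(seq) < 6:
            raise ValueError(f"{f.name}: PCG shorter than 6 nt")
        start = seq[:3]
        r = len(seq) % 3
        if r:
            stop, cls = seq[-r:], "truncated"
            if not "TAA".startswith(stop):
                warnings.warn(
                    f"{f.name}: truncated stop {stop!r} is not a prefix of "
                    "TAA", stacklevel=2)
        else:
            stop, cls = seq[-3:], "complete"
            if stop not in code.stop_codons:
                warnings.warn(
                    f"{f.name}: final codon {stop} is not a stop codon",
                    stacklevel=2)
        reports.append(CodonReport(gene=f.name, start_codon=start,
                                   stop_codon=stop, stop_class=cls))
    return reports


def codon_frame(reports: list[CodonReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
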