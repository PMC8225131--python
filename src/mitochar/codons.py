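"""Codon counting, relative synonymous codon usage (RSCU), and translation
under the invertebrate mitochondrial genetic code (NCBI translation table 5).

Table 5 differs from the standard code in that AGA/AGG encode serine, ATA
methionine and TGA tryptophan, leaving TAA and TAG as the only stop codons
(62 sense codons).  For RSCU, leucine and serine are split into their two
codon families — Leu1 (CTN), Leu2 (TTA/TTG), Ser1 (AGN), Ser2 (TCN) — and
every other amino acid forms a single family:

    RSCU(c) = count(c) * |F| / sum of counts over c's family F,

the observed count relative to its expectation under uniform usage within
the family, so family means are 1 whenever the family is used at all.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

ALL_CODONS = tuple("".join(p) for p in itertools.product("TCAG", repeat=3))

_AA3 = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
        "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
        "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
        "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val"}


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid table plus the synonymous-family partition."""

    table_id: int
    forward: dict[str, str]          # sense codon -> one-letter amino acid
    stop_codons: frozenset[str]
    family_of: dict[str, str]        # sense codon -> family id

    @classmethod
    def invertebrate_mito(cls) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[5]
        forward = dict(t.forward_table)
        family = {}
        for codon, aa in forward.items():
            if aa == "L":
                family[codon] = "Leu2" if codon in ("TTA", "TTG") else "Leu1"
            elif aa == "S":
                family[codon] = "Ser1" if codon.startswith("AG") else "Ser2"
            else:
                family[codon] = _AA3[aa]
        return cls(table_id=5, forward=forward,
                   stop_codons=frozenset(t.stop_codons), family_of=family)

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        fams: dict[str, list[str]] = {}
        for codon, fam in self.family_of.items():
            fams.setdefault(fam, []).append(codon)
        return {k: tuple(sorted(v)) for k, v in fams.items()}


INVERTEBRATE_MITO = GeneticCode.invertebrate_mito()


@dataclass
class CodonCounts:
    """Complete-codon counts with stop codons tallied separately."""

    sense: dict[str, int] = field(default_factory=dict)
    stops: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.sense.values()) + sum(self.stops.values())


def codon_counts(cds_list, code: GeneticCode = INVERTEBRATE_MITO) -> CodonCounts:
    """Count complete codons over a collection of coding sequences.

    ``cds_list`` is a sequence of 5'->3' coding-strand CDS strings, or a
    mapping gene name -> CDS.  A trailing incomplete codon (truncated stop)
    is dropped.  Internal stop codons are counted but raise a warning naming
    the gene and codon position.
    """
    if isinstance(cds_list, dict):
        items = list(cds_list.items())
    else:
        items = [(f"cds{i}", s) for i, s in enumerate(cds_list, 1)]
    counts = CodonCounts()
    for name, cds in items:
        cds = cds.upper().replace("U", "T")
        ncod = len(cds) // 3
        for i in range(ncod):
            codon = cds[3 * i:3 * i + 3]
            if codon in code.stop_codons:
                counts.stops[codon] = counts.stops.get(codon, 0) + 1
                if i < ncod - 1:
                    warnings.warn(
                        f"internal stop codon {codon} in {name} at codon "
                        f"{i + 1}", stacklevel=2)
            else:
                counts.sense[codon] = counts.sense.get(codon, 0) + 1
    return counts


def rscu(counts: CodonCounts | dict[str, int],
         code: GeneticCode = INVERTEBRATE_MITO) -> pd.DataFrame:
    """RSCU table over all sense codons.

    Returns a DataFrame with columns codon, amino_acid, family, count, rscu.
    Codons of an entirely unused family get rscu 0 and used=False; stop
    codons never appear.
    """
    sense = counts.sense if isinstance(counts, CodonCounts) else {
        c: n for c, n in counts.items() if c not in code.stop_codons}
    fam_totals: dict[str, int] = {}
    for codon, fam in code.family_of.items():
        fam_totals[fam] = fam_totals.get(fam, 0) + sense.get(codon, 0)
    fam_sizes = {fam: len(cods) for fam, cods in code.families.items()}
    rows = []
    for codon in ALL_CODONS:
        if codon in code.stop_codons:
            continue
        fam = code.family_of[codon]
        n = sense.get(codon, 0)
        total = fam_totals[fam]
        rows.append({
            "codon": codon,
            "amino_acid": code.forward[codon],
            "family": fam,
            "count": n,
            "rscu": n * fam_sizes[fam] / total if total else 0.0,
            "used": total > 0,
        })
    return pd.DataFrame(rows)


def translate(cds: str, code: GeneticCode = INVERTEBRATE_MITO,
              start_as_met: bool = True) -> str:
    """Translate a coding sequence under the given code.

    A trailing incomplete codon (truncated stop, completed in vivo by
    polyadenylation) is dropped, as is a terminal complete stop.  The first
    codon is rendered M when ``start_as_met`` (mitochondrial initiator
    convention for non-ATG starts).  Internal stops raise ``ValueError``.
    """
    cds = cds.upper().replace("U", "T")
    ncod = len(cds) // 3
    if ncod < 1:
        raise ValueError("coding sequence shorter than one codon")
    codons = [cds[3 * i:3 * i + 3] for i in range(ncod)]
    if codons[-1] in code.stop_codons:
        codons.pop()
    aa = []
    for i, codon in enumerate(codons):
        if codon in code.stop_codons:
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        if i == 0 and start_as_met:
            aa.append("M")
        else:
            aa.append(code.forward.get(codon, "X"))
    return "".join(aa)
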