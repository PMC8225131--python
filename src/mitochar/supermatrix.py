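"""Concatenated phylogenetic datasets from per-gene alignments of the 13
mitochondrial protein-coding genes.

Three datasets are built from the same per-gene aligned coding sequences:

* ``PCG123`` - all nucleotide positions;
* ``PCG12``  - third codon positions removed (columns 3, 6, 9, ... of each
  gene, counting gap columns), mitigating saturation at silent sites;
* ``AA``     - per-gene translation under the invertebrate mitochondrial
  code, codons containing any gap rendered as the gap character.

Genes are concatenated in the canonical mitochondrial positional order and
the per-gene column intervals are recorded as a partition map, exportable as
a RAxML-style partition file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .codons import GeneticCode, INVERTEBRATE_MITO
from .core import PCG_NAMES

GAP = "-"


@dataclass
class GeneAlignmentSet:
    """Per-gene aligned coding-strand sequences: gene -> taxon -> row.

    Within a gene all rows must be equal length and divisible by 3, with
    stop codons already removed; alignment itself is an input contract.
    """

    alignments: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for gene, rows in self.alignments.items():
            lengths = {len(s) for s in rows.values()}
            if len(lengths) > 1:
                raise ValueError(f"{gene}: unequal aligned lengths {sorted(lengths)}")
            if lengths and next(iter(lengths)) % 3:
                raise ValueError(f"{gene}: aligned length not divisible by 3")

    @property
    def genes(self) -> list[str]:
        return list(self.alignments)

    @property
    def taxa(self) -> list[str]:
        taxa: list[str] = []
        for rows in self.alignments.values():
            for t in rows:
                if t not in taxa:
                    taxa.append(t)
        return taxa


@dataclass
class Supermatrix:
    rows: dict[str, str]                      # taxon -> characters
    partitions: dict[str, tuple[int, int]]    # gene -> 1-based column interval
    datatype: str                             # "nt" | "aa"

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def partition_lines(self) -> list[str]:
        dtype = "DNA" if self.datatype == "nt" else "PROT"
        return [f"{dtype}, {gene} = {a}-{b}"
                for gene, (a, b) in self.partitions.items()]


def _gene_order(gas: GeneAlignmentSet, order=None) -> list[str]:
    if order is None:
        order = [g for g in PCG_NAMES if g in gas.alignments]
        order += [g for g in gas.genes if g not in order]
    return list(order)


def _concatenate(gas: GeneAlignmentSet, transform, datatype: str,
                 allow_missing: bool, order) -> Supermatrix:
    """Concatenate per-gene alignments; ``transform(taxon, gene, row)``
    maps an aligned row to its output characters (gap rows for missing
    taxa when ``allow_missing``)."""
    genes = _gene_order(gas, order)
    taxa = gas.taxa
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for gene in genes:
        rows = gas.alignments[gene]
        width = len(next(iter(rows.values())))
        out_width = None
        for t in taxa:
            if t not in rows and not allow_missing:
                raise ValueError(f"taxon {t!r} missing from gene {gene}")
            piece = transform(t, gene, rows.get(t, GAP * width).upper())
            out_width = len(piece)
            pieces[t].append(piece)
        partitions[gene] = (col + 1, col + out_width)
        col += out_width
    return Supermatrix(rows={t: "".join(p) for t, p in pieces.items()},
                       partitions=partitions, datatype=datatype)


def build_pcg123(gas: GeneAlignmentSet, allow_missing: bool = False,
                 order=None) -> Supermatrix:
    """All codon positions, genes concatenated in canonical order."""
    return _concatenate(gas, lambda t, g, s: s, "nt", allow_missing, order)


def build_pcg12(gas: GeneAlignmentSet, allow_missing: bool = False,
                order=None) -> Supermatrix:
    """First and second codon positions only (gap columns count toward the
    codon frame)."""
    def drop_third(t, g, s):
        return "".join(c for i, c in enumerate(s) if i % 3 != 2)
    return _concatenate(gas, drop_third, "nt", allow_missing, order)


def build_aa(gas: GeneAlignmentSet, code: GeneticCode = INVERTEBRATE_MITO,
             allow_missing: bool = False, order=None) -> Supermatrix:
    """Amino-acid dataset; codons containing any gap translate to the gap
    character.  Internal stops are reported with taxon, gene and codon
    index."""
    def xlate(taxon, gene, s):
        aa = []
        for i in range(0, len(s), 3):
            codon = s[i:i + 3]
            if GAP in codon:
                aa.append(GAP)
            elif codon in code.stop_codons:
                raise ValueError(
                    f"internal stop codon {codon} in {taxon}/{gene} at "
                    f"codon {i // 3 + 1}")
            else:
                aa.append(code.forward.get(codon, "X"))
        return "".join(aa)
    return _concatenate(gas, xlate, "aa", allow_missing, order)


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in sm.rows.items():
            fh.write(f">{taxon}\n{row}\n")


def write_supermatrix_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: full taxon names, two-space separator."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.rows)} {sm.width}\n")
        pad = max((len(t) for t in sm.rows), default=0)
        for taxon, row in sm.rows.items():
            fh.write(f"{taxon:<{pad}}  {row}\n")


def write_partition_file(sm: Supermatrix, path: str | Path) -> None:
    Path(path).write_text("\n".join(sm.partition_lines()) + "\n")


def read_supermatrix_fasta(path: str | Path, datatype: str = "nt") -> Supermatrix:
    rows: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    rows[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        rows[name] = "".join(chunks)
    return Supermatrix(rows=rows, partitions={}, datatype=datatype)
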