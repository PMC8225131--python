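"""Domain types, circular-coordinate arithmetic, and the readers/writers shared
by every analysis stage.

Conventions
-----------
* Genome coordinates are 1-based, closed intervals on the majority (J) strand,
  the strand on which the genome sequence is written.
* Insect mitogenomes are circular; a feature may wrap the origin, in which case
  ``end < start`` and the feature carries an explicit ``wraps`` flag.
* ``strand`` is ``"J"`` (majority) or ``"N"`` (minority).  A feature on the N
  strand is read as the reverse complement of its J-strand interval.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region")
STRANDS = ("J", "N")

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

#: The 13 mitochondrial protein-coding genes in their canonical positional order.
PCG_NAMES = ("ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
             "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1")

FEATURE_TABLE_COLUMNS = ("record_id", "gene", "category", "strand",
                         "start", "end", "anticodon", "genome_length")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; IUPAC ambiguity codes preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureTableError(ValueError):
    """Malformed feature-table content, reported with the offending row number."""


@dataclass
class MitogenomeRecord:
    """A circular mitochondrial genome, J-strand as written."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """One annotated gene: 1-based closed interval on the J-strand.

    ``wraps`` marks features crossing the origin (then ``end < start``).
    ``anticodon`` is meaningful for tRNAs only, written in the DNA alphabet
    5'->3' on the gene's own strand (e.g. trnM = CAT).
    """

    name: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if self.end < self.start and not self.wraps:
            raise ValueError(
                f"{self.name}: end < start is only allowed for origin-wrapping "
                "features flagged with wraps=True")
        if self.anticodon is not None and self.category != "tRNA":
            raise ValueError(f"{self.name}: anticodon given for non-tRNA feature")


@dataclass
class AnnotationSet:
    """The ordered annotation of one genome."""

    record_id: str
    features: list[GeneFeature]
    genome_length: int

    def __post_init__(self) -> None:
        cr = [f for f in self.features if f.category == "control_region"]
        if len(cr) > 1:
            raise ValueError(f"{self.record_id}: more than one control region")
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(
                f"{self.record_id}: duplicate feature names {sorted(dupes)}; "
                "the two trnL/trnS genes must carry suffixes (trnL1/trnL2, "
                "trnS1/trnS2)")

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.record_id}: no feature named {name!r}")

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]


# ---------------------------------------------------------------------------
# circular arithmetic
# ---------------------------------------------------------------------------

def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length``."""
    if not (1 <= f.start <= genome_length and 1 <= f.end <= genome_length):
        raise ValueError(
            f"{f.name}: coordinates ({f.start}, {f.end}) outside "
            f"[1, {genome_length}]")
    if f.wraps:
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


def extract_sequence(rec: MitogenomeRecord, f: GeneFeature) -> str:
    """The feature's sequence 5'->3' on its own coding strand.

    J-strand features are the genome interval as written; N-strand features
    are its reverse complement.  Wrapping features concatenate the suffix of
    the genome with its prefix before orienting.
    """
    L = len(rec)
    n = feature_length(f, L)
    if f.wraps:
        raw = rec.sequence[f.start - 1:] + rec.sequence[:f.end]
    else:
        raw = rec.sequence[f.start - 1:f.end]
    assert len(raw) == n
    return raw if f.strand == "J" else reverse_complement(raw)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[MitogenomeRecord]:
    records = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        if sr.id in seen:
            raise ValueError(f"duplicate FASTA id {sr.id!r} in {path}")
        seen.add(sr.id)
        if len(sr.seq) == 0:
            raise ValueError(f"empty sequence for FASTA record {sr.id!r}")
        records.append(MitogenomeRecord(id=sr.id, sequence=str(sr.seq)))
    return records


def write_fasta(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    seqrecords = [SeqRecord(Seq(r.sequence), id=r.id, description="")
                  for r in records]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# feature-table TSV
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> list[AnnotationSet]:
    """Read the gene feature table (TSV).

    Required columns: record_id, gene, category, strand, start, end,
    anticodon, genome_length.  An optional ``wraps`` column (0/1) marks
    origin-wrapping features; extra columns are ignored.  Features are kept
    in file order, grouped by record_id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureTableError(f"{path}: missing columns {missing}")

    annos: dict[str, AnnotationSet] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after the header line
        rid = row["record_id"].strip()
        name = row["gene"].strip()
        category = row["category"].strip()
        strand = row["strand"].strip()
        if not strand and category == "control_region":
            strand = "J"  # the A+T-rich region is conventionally unassigned
        if strand not in STRANDS:
            raise FeatureTableError(
                f"{path} row {rowno} ({name}): strand must be J or N, "
                f"got {row['strand']!r}")
        try:
            start = int(row["start"])
            end = int(row["end"])
            glen = int(row["genome_length"])
        except ValueError as exc:
            raise FeatureTableError(
                f"{path} row {rowno} ({name}): non-integer coordinate "
                f"({exc})") from None
        anticodon = row["anticodon"].strip().upper() or None
        wraps = bool(int(row["wraps"])) if "wraps" in df.columns and row["wraps"].strip() else False
        try:
            feat = GeneFeature(name=name, category=category, strand=strand,
                               start=start, end=end,
                               anticodon=anticodon if category == "tRNA" else None,
                               wraps=wraps)
        except ValueError as exc:
            raise FeatureTableError(f"{path} row {rowno}: {exc}") from None
        if rid not in annos:
            annos[rid] = AnnotationSet(record_id=rid, features=[], genome_length=glen)
        if name in (f.name for f in annos[rid].features):
            kind = "unsuffixed tRNA" if name in ("trnL", "trnS") else "feature"
            raise FeatureTableError(
                f"{path} row {rowno}: duplicate {kind} name {name!r} for "
                f"record {rid!r}")
        annos[rid].features.append(feat)
    return list(annos.values())


def write_feature_table(annos: Iterable[AnnotationSet], path: str | Path) -> None:
    rows = []
    for ann in annos:
        for f in ann.features:
            rows.append({
                "record_id": ann.record_id, "gene": f.name,
                "category": f.category, "strand": f.strand,
                "start": f.start, "end": f.end,
                "anticodon": f.anticodon or "",
                "genome_length": ann.genome_length,
                "wraps": int(f.wraps),
            })
    pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS) + ["wraps"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenBank flat-file subset
# ---------------------------------------------------------------------------

_GB_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "D-loop": "control_region", "misc_feature": "control_region"}


def read_genbank(path: str | Path) -> list[tuple[MitogenomeRecord, AnnotationSet]]:
    """Read a GenBank flat file (LOCUS/FEATURES/ORIGIN subset).

    CDS, tRNA and rRNA features (plus D-loop/misc_feature control regions)
    are converted to the internal 1-based closed J-strand convention;
    ``complement()`` spans become N-strand features and origin-spanning
    ``join()`` spans become wrapping features.  Bare ``gene`` features are
    ignored (they duplicate the typed features).
    """
    out = []
    for sr in SeqIO.parse(str(path), "genbank"):
        rec = MitogenomeRecord(id=sr.id, sequence=str(sr.seq))
        feats: list[GeneFeature] = []
        for gf in sr.features:
            if gf.type not in _GB_CATEGORY:
                continue
            quals = gf.qualifiers
            name = (quals.get("gene") or quals.get("product") or [gf.type])[0]
            strand = "N" if gf.location.strand == -1 else "J"
            parts = list(gf.location.parts)
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
            wraps = len(parts) > 1 and int(parts[0].start) > int(parts[-1].start)
            anticodon = None
            if gf.type == "tRNA" and "anticodon" in quals:
                anticodon = quals["anticodon"][0].upper().replace("U", "T")
            feats.append(GeneFeature(
                name=name, category=_GB_CATEGORY[gf.type], strand=strand,
                start=start, end=end, anticodon=anticodon, wraps=wraps))
        out.append((rec, AnnotationSet(record_id=sr.id, features=feats,
                                       genome_length=len(rec))))
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Advisory findings about an annotation; inputs are never mutated."""

    record_id: str
    coordinate_violations: list[str] = field(default_factory=list)
    overlap_violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.coordinate_violations or self.overlap_violations)


def validate_annotation(rec: Optional[MitogenomeRecord], ann: AnnotationSet,
                        max_pcg_overlap: int = 10) -> ValidationReport:
    """Check an annotation against its genome length.

    Flags coordinates outside [1, genome_length], same-strand PCG pairs that
    overlap by more than ``max_pcg_overlap`` bp, and tRNAs lacking an
    anticodon.  Report only; nothing is corrected.
    """
    L = len(rec) if rec is not None else ann.genome_length
    report = ValidationReport(record_id=ann.record_id)
    if rec is not None and len(rec) != ann.genome_length:
        report.warnings.append(
            f"annotation genome_length {ann.genome_length} != sequence "
            f"length {len(rec)}")
    for f in ann.features:
        if f.start > L or f.end > L:
            report.coordinate_violations.append(
                f"{f.name}: interval ({f.start}, {f.end}) exceeds genome "
                f"length {L}")
        if f.category == "tRNA" and not f.anticodon:
            report.warnings.append(f"{f.name}: tRNA without anticodon")
    pcgs = [f for f in ann.features if f.category == "PCG"
            and f.end <= L and f.start <= L and not f.wraps]
    for a, b in zip(pcgs, pcgs[1:]):
        if a.strand != b.strand:
            continue
        overlap = a.end - b.start + 1
        if overlap > max_pcg_overlap:
            report.overlap_violations.append(
                f"{a.name}/{b.name}: same-strand PCG overlap of {overlap} bp")
    return report


# ---------------------------------------------------------------------------
# packaged study data
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("mitochar.data").joinpath(name)


def load_study_annotations() -> list[AnnotationSet]:
    """The published annotations of the three Odontiinae mitogenomes
    (Dausara latiterminalis NW732137, Heortia vitessoides NW732138,
    Pseudonoorda nigropunctalis NW732139), coordinates as printed."""
    return read_feature_table(_data_path("odontiinae_features.tsv"))


def load_study_table() -> pd.DataFrame:
    """Same data as :func:`load_study_annotations` with the printed
    length / intergenic-spacer / start- and stop-codon columns retained,
    for printed-versus-computed comparisons."""
    return pd.read_csv(_data_path("odontiinae_features.tsv"), sep="\t",
                       keep_default_na=False)


def load_ancestral_order() -> list[str]:
    """The ancestral insect mitochondrial gene order (trnI-trnQ-trnM leading),
    used as the reference for rearrangement detection."""
    with _data_path("ancestral_gene_order.yaml").open() as fh:
        return yaml.safe_load(fh)["gene_order"]
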