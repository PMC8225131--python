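"""Synthetic annotated mitogenomes with the architecture of lepidopteran
(pyraloid) mitochondrial genomes, plus a truth record scoring every
downstream observable.

The generator emulates the organization the analysis modules assume: a
~15.1 kb circle carrying 37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus an
A+T-rich control region, the derived lepidopteran gene order with
trnM-trnI-trnQ at the origin, ATN starts and TAA/TAG or truncated-T stops,
cloverleaf-foldable tRNAs with trnS1 lacking the DHU arm, and a control
region carrying the conserved ATAG/poly-T, ATTTA/(AT)n and poly-A elements.
Everything is deterministic given the seed (NumPy PCG64 integer-state
generator).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .core import (AnnotationSet, GeneFeature, MitogenomeRecord,
                   reverse_complement, validate_annotation)
from .trna import (CloverleafTemplate, DEFAULT_TEMPLATE, enumerate_layouts,
                   fold_cloverleaf, WOBBLE_PAIRS)

#: Derived lepidopteran gene order (trnM first), with strand and category.
OBSERVED_GENE_ORDER: tuple[tuple[str, str, str], ...] = (
    ("trnM", "tRNA", "J"), ("trnI", "tRNA", "J"), ("trnQ", "tRNA", "N"),
    ("ND2", "PCG", "J"), ("trnW", "tRNA", "J"), ("trnC", "tRNA", "N"),
    ("trnY", "tRNA", "N"), ("COX1", "PCG", "J"), ("trnL2", "tRNA", "J"),
    ("COX2", "PCG", "J"), ("trnK", "tRNA", "J"), ("trnD", "tRNA", "J"),
    ("ATP8", "PCG", "J"), ("ATP6", "PCG", "J"), ("COX3", "PCG", "J"),
    ("trnG", "tRNA", "J"), ("ND3", "PCG", "J"), ("trnA", "tRNA", "J"),
    ("trnR", "tRNA", "J"), ("trnN", "tRNA", "J"), ("trnS1", "tRNA", "J"),
    ("trnE", "tRNA", "J"), ("trnF", "tRNA", "N"), ("ND5", "PCG", "N"),
    ("trnH", "tRNA", "N"), ("ND4", "PCG", "N"), ("ND4L", "PCG", "N"),
    ("trnT", "tRNA", "J"), ("trnP", "tRNA", "N"), ("ND6", "PCG", "J"),
    ("CYTB", "PCG", "J"), ("trnS2", "tRNA", "J"), ("ND1", "PCG", "N"),
    ("trnL1", "tRNA", "N"),
    ("rrnL", "rRNA", "N"), ("trnV", "tRNA", "N"), ("rrnS", "rRNA", "N"),
)

#: Default PCG lengths (bp, including start and stop), typical of pyraloid
#: mitogenomes; COX2 carries a truncated single-T stop.
PCG_LENGTHS = {"ND2": 1014, "COX1": 1551, "COX2": 682, "ATP8": 162,
               "ATP6": 681, "COX3": 789, "ND3": 354, "ND5": 1734,
               "ND4": 1344, "ND4L": 291, "ND6": 534, "CYTB": 1149,
               "ND1": 939}
PCG_STARTS = {"ND2": "ATT", "COX1": "ATT", "COX2": "ATG", "ATP8": "ATT",
              "ATP6": "ATG", "COX3": "ATG", "ND3": "ATT", "ND5": "ATT",
              "ND4": "ATG", "ND4L": "ATG", "ND6": "ATA", "CYTB": "ATG",
              "ND1": "ATG"}
PCG_STOPS = {"ND2": "TAA", "COX1": "TAA", "COX2": "T", "ATP8": "TAA",
             "ATP6": "TAA", "COX3": "TAA", "ND3": "TAA", "ND5": "TAA",
             "ND4": "TAA", "ND4L": "TAA", "ND6": "TAA", "CYTB": "TAA",
             "ND1": "TAA"}

#: tRNA anticodons, DNA alphabet, 5'->3' on the gene strand.
TRNA_ANTICODONS = {"trnM": "CAT", "trnI": "GAT", "trnQ": "TTG",
                   "trnW": "TCA", "trnC": "GCA", "trnY": "GTA",
                   "trnL2": "TAA", "trnK": "CTT", "trnD": "GTC",
                   "trnG": "TCC", "trnA": "TGC", "trnR": "TCG",
                   "trnN": "GTT", "trnS1": "GCT", "trnE": "TTC",
                   "trnF": "GAA", "trnH": "GTG", "trnT": "TGT",
                   "trnP": "TGG", "trnS2": "TGA", "trnL1": "TAG",
                   "trnV": "TAC"}

RRNA_LENGTHS = {"rrnL": 1369, "rrnS": 783}

STOP_CODONS = ("TAA", "TAG")


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic mitogenomes.

    Per-class A+T fractions and architectural defaults emulate published
    pyraloid mitogenomes: whole genome ~0.81, PCGs 0.78 (the lowest class),
    control region 0.96 (the highest).  The tRNA/rRNA fractions are set so
    the class mixture realizes the whole-genome target.
    """

    seed: int = 0
    record_id: str = "synthetic_mitogenome"
    gene_order: tuple[tuple[str, str, str], ...] = OBSERVED_GENE_ORDER
    pcg_lengths: dict = field(default_factory=lambda: dict(PCG_LENGTHS))
    pcg_starts: dict = field(default_factory=lambda: dict(PCG_STARTS))
    pcg_stops: dict = field(default_factory=lambda: dict(PCG_STOPS))
    trna_anticodons: dict = field(default_factory=lambda: dict(TRNA_ANTICODONS))
    rrna_lengths: dict = field(default_factory=lambda: dict(RRNA_LENGTHS))
    at_whole: float = 0.81
    at_pcg: float = 0.78
    # tRNA/rRNA sampling levels are set so the class mixture centers the
    # realized whole-genome A+T on at_whole: fixed anticodons and wobble
    # pairs pull realized tRNA composition a few points below the nominal
    # sampling level, and the remaining classes must absorb that.
    at_trna: float = 0.91
    at_rrna: float = 0.885
    at_cr: float = 0.96
    cr_length: int = 335
    spacer_range: tuple[int, int] = (0, 3)
    trna_template: CloverleafTemplate = DEFAULT_TEMPLATE
    trna_length_range: tuple[int, int] = (63, 71)
    wobble_rate: float = 0.05
    dhu_loss_genes: tuple[str, ...] = ("trnS1",)
    #: re-emit a tRNA (fresh randomness) until its planted layout is the
    #: unique fold optimum; attempts are capped
    ensure_unique_fold: bool = True
    #: DHU-loss layouts have few stem positions and lose to chance-paired
    #: full layouts in most single draws on A/T-rich sequence, so the
    #: rejection loop needs headroom (expected ~5 draws for trnS1)
    max_fold_attempts: int = 100
    divergence_rate: float = 0.05


@dataclass
class TruthRecord:
    """Planted values for every downstream observable of one genome."""

    record_id: str
    genome_length: int = 0
    gene_order: list = field(default_factory=list)        # (name, strand)
    coordinates: dict = field(default_factory=dict)       # name -> (start, end)
    cds: dict = field(default_factory=dict)               # PCG -> coding seq
    start_codons: dict = field(default_factory=dict)
    stop_codons: dict = field(default_factory=dict)
    anticodons: dict = field(default_factory=dict)
    trna_sequences: dict = field(default_factory=dict)
    trna_segments: dict = field(default_factory=dict)     # name -> {seg: [lo, hi]}
    trna_dhu_lost: dict = field(default_factory=dict)
    cr_interval: tuple = (0, 0)
    cr_sequence: str = ""
    motifs: dict = field(default_factory=dict)            # CR-relative, 1-based
    class_counts: dict = field(default_factory=dict)      # class -> {base: n}
    substitutions: int = 0                                # vs the set ancestor

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


# ---------------------------------------------------------------------------
# sequence emission helpers
# ---------------------------------------------------------------------------

def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


_BASES = np.array(list("ACGT"))


def _iid_seq(rng: np.random.Generator, n: int, at: float) -> str:
    if n == 0:
        return ""
    return "".join(rng.choice(_BASES, size=n, p=_base_probs(at)))


def _exact_seq(rng: np.random.Generator, n: int, at: float) -> str:
    """Sequence of length n whose A+T count is exactly round(at * n)."""
    n_at = int(round(at * n))
    n_a = n_at // 2 + (int(rng.integers(2)) if n_at % 2 else 0)
    n_gc = n - n_at
    n_g = n_gc // 2 + (int(rng.integers(2)) if n_gc % 2 else 0)
    arr = np.array(list("A" * n_a + "T" * (n_at - n_a)
                        + "G" * n_g + "C" * (n_gc - n_g)))
    rng.shuffle(arr)
    return "".join(arr)


def _stop_adjusted_at(target: float) -> float:
    """Per-base A+T level whose accepted (non-stop) codons average the
    target A+T fraction.

    Rejecting TAA/TAG preferentially discards A/T-rich codons, so sampling
    bases directly at the target would bias coding regions low; invert the
    conditional expectation by bisection.
    """
    def conditional(a: float) -> float:
        p_taa = (a / 2) ** 3
        p_tag = (a / 2) ** 2 * (1 - a) / 2
        return (3 * a - 3 * p_taa - 2 * p_tag) / (3 * (1 - p_taa - p_tag))

    lo, hi = target, min(1.0, target + 0.1)
    for _ in range(60):
        mid = (lo + hi) / 2
        if conditional(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _emit_pcg(rng: np.random.Generator, start: str, stop: str, length: int,
              at: float) -> str:
    mid = length - 3 - len(stop)
    if mid < 0 or mid % 3:
        raise ValueError(
            f"PCG length {length} incompatible with start {start!r} and "
            f"stop {stop!r}")
    at_adj = _stop_adjusted_at(at)
    codons = []
    for _ in range(mid // 3):
        while True:
            c = _iid_seq(rng, 3, at_adj)
            if c not in STOP_CODONS:
                codons.append(c)
                break
    return start + "".join(codons) + stop


_WOBBLE_LIST = sorted(WOBBLE_PAIRS)


def _emit_trna_once(rng: np.random.Generator, params: GeneratorParams,
                    anticodon: str, dhu_lost: bool):
    tmpl = params.trna_template
    lo, hi = params.trna_length_range
    layouts = [l for L in range(lo, hi + 1)
               for l in enumerate_layouts(L, tmpl, dhu_lost)]
    if not layouts:
        raise ValueError("no tRNA layout fits the template and length range")
    lengths = layouts[int(rng.integers(len(layouts)))]
    order = ("acc5", "dhu_region", "ac5", "ac_loop", "ac3", "var_loop",
             "t5", "t_loop", "t3", "acc3") if dhu_lost else (
        "acc5", "dhu5", "dhu_loop", "dhu3", "ac5", "ac_loop", "ac3",
        "var_loop", "t5", "t_loop", "t3", "acc3")
    seg_seq: dict[str, str] = {}
    # loops first
    for name in order:
        if name in ("acc5", "dhu5", "ac5", "t5", "acc3", "dhu3", "ac3", "t3"):
            continue
        if name == "ac_loop":
            n = lengths[name]
            flank = (n - 3) // 2
            seg_seq[name] = (_iid_seq(rng, flank, params.at_trna) + anticodon
                            + _iid_seq(rng, n - 3 - flank, params.at_trna))
        else:
            seg_seq[name] = _iid_seq(rng, lengths[name], params.at_trna)
    # stems: 5' side random, 3' side reverse complement with wobble noise
    for five, three in (("acc5", "acc3"), ("dhu5", "dhu3"),
                        ("ac5", "ac3"), ("t5", "t3")):
        if five not in lengths:
            continue
        top = _iid_seq(rng, lengths[five], params.at_trna)
        bottom = list(reverse_complement(top))
        for k in range(len(top)):
            if rng.random() < params.wobble_rate:
                a, b = _WOBBLE_LIST[int(rng.integers(len(_WOBBLE_LIST)))]
                top = top[:k] + a + top[k + 1:]
                bottom[len(top) - 1 - k] = b
        seg_seq[five] = top
        seg_seq[three] = "".join(bottom)
    seq = "".join(seg_seq[name] for name in order)
    segments = {}
    pos = 0
    for name in order:
        segments[name] = (pos, pos + lengths[name])
        pos += lengths[name]
    return seq, segments


def _emit_trna(rng: np.random.Generator, params: GeneratorParams,
               anticodon: str, dhu_lost: bool):
    """Emit a tRNA whose planted layout is (when feasible) the unique fold
    optimum under the template."""
    attempts = params.max_fold_attempts if params.ensure_unique_fold else 1
    seq = segments = None
    for _ in range(attempts):
        seq, segments = _emit_trna_once(rng, params, anticodon, dhu_lost)
        if not params.ensure_unique_fold:
            break
        st = fold_cloverleaf(seq, params.trna_template)
        if (st is not None and st.dhu_lost == dhu_lost
                and st.segments == segments):
            break
    return seq, segments


def _emit_control_region(rng: np.random.Generator, params: GeneratorParams):
    """Control region with the planted element plan:
    filler | ATAG | poly-T | filler | ATTTA | (AT)n | filler | poly-A | filler.

    Guard bases (placed by swapping, preserving composition) keep every
    planted run maximal at its planted coordinate.
    """
    L = params.cr_length
    poly_t = 7 + int(rng.integers(6))      # 7..12
    at_reps = 3 + int(rng.integers(4))     # (AT)3..(AT)6
    poly_a = 5 + int(rng.integers(5))      # 5..9
    blocks = 4 + poly_t + 5 + 2 * at_reps + poly_a
    filler_total = L - blocks
    if filler_total < 10:
        raise ValueError("control region too short for the motif plan")
    # minimum filler sizes keep room for the guard bases
    mins = (1, 1, 3, 1)
    extra = filler_total - sum(mins)
    alloc = rng.multinomial(extra, [0.25] * 4)
    fa, fb, fc, fd = (m + int(x) for m, x in zip(mins, alloc))

    def filler(n: int, first: str = "", last: str = "") -> str:
        s = list(_exact_seq(rng, n, params.at_cr))
        for idx, want in [(0, first[0:1]), (1, first[1:2]), (-1, last)]:
            if not want:
                continue
            pos = idx if idx >= 0 else n - 1
            if s[pos] != want:
                for j in range(n):
                    if s[j] == want and j not in (0, 1, n - 1):
                        s[pos], s[j] = s[j], s[pos]
                        break
                else:
                    s[pos] = want  # no donor base; accept a tiny drift
        return "".join(s)

    a = filler(fa)
    b = filler(fb, first="A")            # stops the poly-T run
    c = filler(fc, first="AA", last="T")  # stops (AT)n and guards poly-A
    d = filler(fd, first="T")            # ends the poly-A run
    seq = (a + "ATAG" + "T" * poly_t + b + "ATTTA" + "AT" * at_reps
           + c + "A" * poly_a + d)
    assert len(seq) == L
    p_atag = fa + 1
    p_polyt = p_atag + 4
    p_attta = p_polyt + poly_t + fb
    p_atrep = p_attta + 5
    p_polya = p_atrep + 2 * at_reps + fc
    motifs = {
        "atag": [p_atag],
        "poly_t": [[p_polyt, poly_t]],
        "attta": [p_attta],
        "at_repeats": [[p_atrep, 2 * at_reps]],
        "poly_a": [[p_polya, poly_a]],
    }
    return seq, motifs


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def generate_mitogenome(params: GeneratorParams = GeneratorParams()
                        ) -> tuple[MitogenomeRecord, AnnotationSet, TruthRecord]:
    """Generate one annotated mitogenome plus its truth record.

    Deterministic given ``params.seed``.  trnM starts at position 1; the
    control region fills the interval from the end of rrnS to the end of
    the genome, so the rrnS->trnM rule recovers it exactly.  N-strand genes
    are emitted on their coding strand and placed as reverse complements.
    """
    rng = np.random.default_rng(params.seed)
    truth = TruthRecord(record_id=params.record_id)
    parts: list[str] = []
    features: list[GeneFeature] = []
    spacer_seqs: list[str] = []
    pos = 1
    lo_sp, hi_sp = params.spacer_range
    class_strings: dict[str, list[str]] = {"PCGs": [], "tRNAs": [], "rRNAs": []}

    for i, (name, category, strand) in enumerate(params.gene_order):
        if i > 0:
            sp = int(rng.integers(lo_sp, hi_sp + 1))
            if sp:
                s = _iid_seq(rng, sp, params.at_whole)
                parts.append(s)
                spacer_seqs.append(s)
                pos += sp
        anticodon = None
        if category == "PCG":
            coding = _emit_pcg(rng, params.pcg_starts[name],
                               params.pcg_stops[name],
                               params.pcg_lengths[name], params.at_pcg)
            truth.cds[name] = coding
            truth.start_codons[name] = params.pcg_starts[name]
            truth.stop_codons[name] = params.pcg_stops[name]
            class_strings["PCGs"].append(coding)
        elif category == "tRNA":
            anticodon = params.trna_anticodons[name]
            dhu_lost = name in params.dhu_loss_genes
            coding, segments = _emit_trna(rng, params, anticodon, dhu_lost)
            truth.anticodons[name] = anticodon
            truth.trna_sequences[name] = coding
            truth.trna_segments[name] = {k: list(v) for k, v in segments.items()}
            truth.trna_dhu_lost[name] = dhu_lost
            class_strings["tRNAs"].append(coding)
        elif category == "rRNA":
            coding = _exact_seq(rng, params.rrna_lengths[name], params.at_rrna)
            class_strings["rRNAs"].append(coding)
        else:
            raise ValueError(f"unexpected category {category!r} in gene order")
        parts.append(coding if strand == "J" else reverse_complement(coding))
        end = pos + len(coding) - 1
        features.append(GeneFeature(name=name, category=category,
                                    strand=strand, start=pos, end=end,
                                    anticodon=anticodon))
        truth.coordinates[name] = (pos, end)
        truth.gene_order.append((name, strand))
        pos = end + 1

    cr_seq, motifs = _emit_control_region(rng, params)
    parts.append(cr_seq)
    cr_start, cr_end = pos, pos + len(cr_seq) - 1
    features.append(GeneFeature(name="CR", category="control_region",
                                strand="J", start=cr_start, end=cr_end))
    truth.coordinates["CR"] = (cr_start, cr_end)
    truth.cr_interval = (cr_start, cr_end)
    truth.cr_sequence = cr_seq
    truth.motifs = motifs

    genome = "".join(parts)
    truth.genome_length = len(genome)
    rec = MitogenomeRecord(id=params.record_id, sequence=genome)
    ann = AnnotationSet(record_id=params.record_id, features=features,
                        genome_length=len(genome))
    report = validate_annotation(rec, ann)
    assert report.ok, report

    counts = {
        "whole": Counter(genome),
        "PCGs": Counter("".join(class_strings["PCGs"])),
        "tRNAs": Counter("".join(class_strings["tRNAs"])),
        "rRNAs": Counter("".join(class_strings["rRNAs"])),
        "control_region": Counter(cr_seq),
        "spacers": Counter("".join(spacer_seqs)),
    }
    truth.class_counts = {cls: {b: c.get(b, 0) for b in "ACGT"}
                          for cls, c in counts.items()}
    return rec, ann, truth


# ---------------------------------------------------------------------------
# multi-genome sets
# ---------------------------------------------------------------------------

def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> tuple[str, int]:
    """Substitute mid-codon sites at the given per-site rate; start and stop
    codons are kept and no internal stop is ever created.  Returns the new
    CDS and the substitution count."""
    stop_len = len(cds) % 3 or 3
    head, tail = cds[:3], cds[-stop_len:]
    mid = cds[3:len(cds) - stop_len]
    codons = [mid[i:i + 3] for i in range(0, len(mid), 3)]
    nsub = 0
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for ci, codon in enumerate(codons):
        flags = rng.random(3) < rate
        if not flags.any():
            continue
        while True:
            new = list(codon)
            for k in range(3):
                if flags[k]:
                    new[k] = others[codon[k]][int(rng.integers(3))]
            cand = "".join(new)
            if cand not in STOP_CODONS:
                codons[ci] = cand
                break
        nsub += int(flags.sum())
    return head + "".join(codons) + tail, nsub


def generate_genome_set(n: int, params: GeneratorParams = GeneratorParams()
                        ) -> list[tuple[MitogenomeRecord, AnnotationSet, TruthRecord]]:
    """A set of n genomes diverged from a common ancestor.

    The first genome is the ancestor itself; each further genome carries
    independent substitutions in the protein-coding genes at
    ``params.divergence_rate`` per mid-codon site (substitutions only, so
    per-gene alignments are the identity).  Truth records carry the
    substitution counts.
    """
    if n < 2:
        raise ValueError("a genome set needs n >= 2")
    base_rec, base_ann, base_truth = generate_mitogenome(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    out = []
    for k in range(n):
        taxon = f"taxon{k + 1}"
        features = [replace(f) for f in base_ann.features]
        ann = AnnotationSet(record_id=taxon, features=features,
                            genome_length=base_ann.genome_length)
        truth = TruthRecord(**{**asdict(base_truth), "record_id": taxon})
        genome = base_rec.sequence
        if k > 0 and params.divergence_rate > 0:
            total = 0
            for f in ann.by_category("PCG"):
                cds, nsub = _mutate_cds(rng, truth.cds[f.name],
                                        params.divergence_rate)
                truth.cds[f.name] = cds
                total += nsub
                block = cds if f.strand == "J" else reverse_complement(cds)
                genome = genome[:f.start - 1] + block + genome[f.end:]
            truth.substitutions = total
        out.append((MitogenomeRecord(id=taxon, sequence=genome), ann, truth))
    return out


def alignment_cds(truth: TruthRecord, gene: str) -> str:
    """The gene's coding sequence with the (complete or truncated) stop
    removed — the per-gene 'alignment' row for gap-free synthetic sets."""
    cds = truth.cds[gene]
    r = len(cds) % 3
    if r:
        cds = cds[:-r]
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    return cds


def alignment_set_from_truths(truths: list[TruthRecord]):
    """Build the per-gene aligned input for the supermatrix stage from a
    generated genome set (substitutions only, so rows align as emitted)."""
    from .supermatrix import GeneAlignmentSet
    genes = list(truths[0].cds)
    return GeneAlignmentSet({
        g: {t.record_id: alignment_cds(t, g) for t in truths} for g in genes})
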