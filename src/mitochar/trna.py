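"""Template-constrained cloverleaf folding for mitochondrial tRNA genes.

Metazoan mitochondrial tRNAs keep a rigid cloverleaf skeleton: a 7-bp
acceptor stem, a 5-bp anticodon stem closing a 7-nt anticodon loop, a
variable-length DHU arm (3-4 bp stem) and TpsiC arm (4-5 bp stem), and short
connecting loops.  Rather than thermodynamic folding, the structure is
assigned by exhaustively enumerating every boundary layout the template
allows and scoring the implied stems: a Watson-Crick pair scores 2, a
wobble pair (G.T, T.T or G.A, the classes displayed in secondary-structure
figures of insect mitogenomes) scores 1, anything else 0.  trnS1 (AGN)
characteristically lacks the DHU arm; an alternative layout replacing that
arm with a plain loop is evaluated and reported only when it strictly
out-scores every full-cloverleaf layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional

#: segment order of a full cloverleaf; DHU-loss layouts replace the three
#: dhu_* segments with a single unpaired "dhu_region".
FULL_SEGMENTS = ("acc5", "dhu5", "dhu_loop", "dhu3", "ac5", "ac_loop", "ac3",
                 "var_loop", "t5", "t_loop", "t3", "acc3")
LOSS_SEGMENTS = ("acc5", "dhu_region", "ac5", "ac_loop", "ac3",
                 "var_loop", "t5", "t_loop", "t3", "acc3")

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G"), ("T", "T"), ("G", "A"), ("A", "G")}


def classify_pair(a: str, b: str) -> str:
    if (a, b) in WC_PAIRS:
        return "WC"
    if (a, b) in WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


_PAIR_SCORE = {"WC": 2, "wobble": 1, "mismatch": 0}


@dataclass(frozen=True)
class CloverleafTemplate:
    """Allowed element lengths; ranges are inclusive (lo, hi)."""

    acceptor_stem: int = 7
    dhu_stem: tuple[int, int] = (3, 4)
    dhu_loop: tuple[int, int] = (4, 9)
    anticodon_stem: int = 5
    anticodon_loop: int = 7
    var_loop: tuple[int, int] = (3, 6)
    t_stem: tuple[int, int] = (4, 5)
    t_loop: tuple[int, int] = (3, 8)
    #: length range of the plain loop replacing a lost DHU arm
    dhu_loss_region: tuple[int, int] = (4, 9)
    allow_dhu_loss: bool = True
    #: minimum acceptable score, as a fraction of the layout's own maximum
    #: (2 points per stem position)
    min_score_frac: float = 0.7


DEFAULT_TEMPLATE = CloverleafTemplate()


@dataclass
class TrnaStructure:
    """An arm-by-arm cloverleaf assignment for one tRNA gene.

    ``segments`` maps segment name -> (start, end) as 0-based half-open
    intervals tiling the sequence; ``pairs`` maps stem name -> list of
    (i, j, class) with i/j 0-based sequence positions.
    """

    sequence: str
    segments: dict[str, tuple[int, int]]
    pairs: dict[str, list[tuple[int, int, str]]]
    dhu_lost: bool
    score: int

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.pairs.values())

    @property
    def wc_count(self) -> int:
        return sum(1 for v in self.pairs.values() for (_, _, c) in v if c == "WC")

    @property
    def anticodon(self) -> str:
        lo, hi = self.segments["ac_loop"]
        mid = lo + (hi - lo) // 2
        return self.sequence[mid - 1:mid + 2]

    @property
    def layout(self) -> tuple[int, ...]:
        """Free element lengths: (dhu_stem, dhu_loop, var, t_stem, t_loop)
        for full cloverleafs, (dhu_region, var, t_stem, t_loop) otherwise."""
        seg = {k: hi - lo for k, (lo, hi) in self.segments.items()}
        if self.dhu_lost:
            return (seg["dhu_region"], seg["var_loop"], seg["t5"], seg["t_loop"])
        return (seg["dhu5"], seg["dhu_loop"], seg["var_loop"], seg["t5"],
                seg["t_loop"])


def _build(seq: str, lengths: dict[str, int], dhu_lost: bool) -> TrnaStructure:
    order = LOSS_SEGMENTS if dhu_lost else FULL_SEGMENTS
    segments = {}
    pos = 0
    for name in order:
        segments[name] = (pos, pos + lengths[name])
        pos += lengths[name]
    assert pos == len(seq)
    stems = [("acceptor", "acc5", "acc3"), ("anticodon", "ac5", "ac3"),
             ("tpsic", "t5", "t3")]
    if not dhu_lost:
        stems.insert(1, ("dhu", "dhu5", "dhu3"))
    pairs: dict[str, list[tuple[int, int, str]]] = {}
    score = 0
    for stem, five, three in stems:
        (a0, a1), (b0, b1) = segments[five], segments[three]
        n = a1 - a0
        plist = []
        for k in range(n):
            i, j = a0 + k, b1 - 1 - k
            cls = classify_pair(seq[i], seq[j])
            score += _PAIR_SCORE[cls]
            plist.append((i, j, cls))
        pairs[stem] = plist
    return TrnaStructure(sequence=seq, segments=segments, pairs=pairs,
                         dhu_lost=dhu_lost, score=score)


def _rng(r: tuple[int, int]) -> range:
    return range(r[0], r[1] + 1)


def enumerate_layouts(L: int, tmpl: CloverleafTemplate, dhu_lost: bool):
    """All element-length assignments of the template summing to L.

    Yields dicts segment name -> length.  For full cloverleafs the free
    lengths are (DHU stem, DHU loop, variable loop, T stem, T loop); for
    DHU-loss layouts (DHU region, variable loop, T stem, T loop).
    """
    fixed = 2 * tmpl.acceptor_stem + 2 * tmpl.anticodon_stem + tmpl.anticodon_loop
    base = {"acc5": tmpl.acceptor_stem, "acc3": tmpl.acceptor_stem,
            "ac5": tmpl.anticodon_stem, "ac3": tmpl.anticodon_stem,
            "ac_loop": tmpl.anticodon_loop}
    if dhu_lost:
        for r in _rng(tmpl.dhu_loss_region):
            for v in _rng(tmpl.var_loop):
                for t in _rng(tmpl.t_stem):
                    tl = L - fixed - r - v - 2 * t
                    if tmpl.t_loop[0] <= tl <= tmpl.t_loop[1]:
                        yield {**base, "dhu_region": r, "var_loop": v,
                               "t5": t, "t3": t, "t_loop": tl}
    else:
        for d in _rng(tmpl.dhu_stem):
            for dl in _rng(tmpl.dhu_loop):
                for v in _rng(tmpl.var_loop):
                    for t in _rng(tmpl.t_stem):
                        tl = L - fixed - 2 * d - dl - v - 2 * t
                        if tmpl.t_loop[0] <= tl <= tmpl.t_loop[1]:
                            yield {**base, "dhu5": d, "dhu_loop": dl,
                                   "dhu3": d, "var_loop": v,
                                   "t5": t, "t3": t, "t_loop": tl}


def _best(seq: str, tmpl: CloverleafTemplate, dhu_lost: bool) -> Optional[TrnaStructure]:
    best: Optional[TrnaStructure] = None
    for lengths in enumerate_layouts(len(seq), tmpl, dhu_lost):
        cand = _build(seq, lengths, dhu_lost)
        if best is None:
            best = cand
            continue
        # higher score, then more Watson-Crick pairs, then the
        # lexicographically smallest layout tuple (deterministic tie-break)
        key = (cand.score, cand.wc_count, tuple(-x for x in cand.layout))
        bkey = (best.score, best.wc_count, tuple(-x for x in best.layout))
        if key > bkey:
            best = cand
    return best


def min_score(structure_or_npairs, frac: float) -> int:
    n = (structure_or_npairs.n_pairs
         if isinstance(structure_or_npairs, TrnaStructure)
         else structure_or_npairs)
    return ceil(frac * 2 * n)


def fold_cloverleaf(seq: str, tmpl: CloverleafTemplate = DEFAULT_TEMPLATE
                    ) -> Optional[TrnaStructure]:
    """Best-scoring cloverleaf assignment of a tRNA gene sequence, or None.

    All boundary layouts the template admits are enumerated and scored
    (WC=2, wobble=1, mismatch=0 per stem position).  If ``allow_dhu_loss``,
    the DHU-arm-replaced-by-loop layouts are also evaluated and the winner
    is returned only when it strictly out-scores every full-cloverleaf
    layout.  Returns None when the winning layout scores below
    ``min_score_frac`` of its own maximum (2 x its stem positions).
    """
    seq = seq.upper().replace("U", "T")
    if not (55 <= len(seq) <= 80):
        raise ValueError(
            f"sequence length {len(seq)} outside the plausible tRNA range "
            "[55, 80]")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be over A/C/G/T (U accepted as T)")
    best_full = _best(seq, tmpl, dhu_lost=False)
    chosen = best_full
    if tmpl.allow_dhu_loss:
        best_loss = _best(seq, tmpl, dhu_lost=True)
        if best_loss is not None and (best_full is None
                                      or best_loss.score > best_full.score):
            chosen = best_loss
    if chosen is None or chosen.score < min_score(chosen, tmpl.min_score_frac):
        return None
    return chosen


def anticodon_of(structure: TrnaStructure) -> str:
    """Central triplet of the anticodon loop, 5'->3' on the gene strand,
    DNA alphabet."""
    return structure.anticodon


def mismatch_census(structure: TrnaStructure) -> dict[str, dict[str, int]]:
    """Pair-class counts per stem; per-stem counts sum to stem length."""
    out: dict[str, dict[str, int]] = {}
    for stem, plist in structure.pairs.items():
        c = {"WC": 0, "wobble": 0, "mismatch": 0}
        for (_, _, cls) in plist:
            c[cls] += 1
        out[stem] = c
    return out


_PAIR_MARK = {"WC": "|", "wobble": ".", "mismatch": " "}


def structure_diagram(structure: TrnaStructure, name: str = "") -> str:
    """Plain-text arm-annotated rendering of a folded tRNA."""
    s = structure.sequence
    seg = structure.segments
    lines = []
    if name:
        lines.append(f"# {name}  score={structure.score}"
                     f"{'  (DHU arm lost)' if structure.dhu_lost else ''}"
                     f"  anticodon={structure.anticodon}")
    arms = [("acceptor", "acc5", "acc3"),
            ("DHU", "dhu5", "dhu3"), ("anticodon", "ac5", "ac3"),
            ("TpsiC", "t5", "t3")]
    for arm, five, three in arms:
        if five not in seg:
            continue
        stem = {"acceptor": "acceptor", "DHU": "dhu",
                "anticodon": "anticodon", "TpsiC": "tpsic"}[arm]
        a0, a1 = seg[five]
        b0, b1 = seg[three]
        top = s[a0:a1]
        bot = s[b0:b1][::-1]
        marks = "".join(_PAIR_MARK[c] for (_, _, c) in structure.pairs[stem])
        lines.append(f"{arm + ' stem':<15} 5' {top}")
        lines.append(f"{'':<15}    {marks}")
        lines.append(f"{'':<15} 3' {bot}")
    loops = [("DHU loop", "dhu_loop"), ("DHU region", "dhu_region"),
             ("anticodon loop", "ac_loop"), ("variable loop", "var_loop"),
             ("TpsiC loop", "t_loop")]
    for label, key in loops:
        if key in seg:
            lo, hi = seg[key]
            lines.append(f"{label:<15}    {s[lo:hi]}")
    return "\n".join(lines) + "\n"
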