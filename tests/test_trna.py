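"""Cloverleaf folding: planted-structure recovery and a no-pruning oracle."""

import itertools
import random

import pytest

from mitochar import (CloverleafTemplate, DEFAULT_TEMPLATE, GeneratorParams,
                      anticodon_of, extract_sequence, fold_cloverleaf,
                      mismatch_census)
from mitochar.simulate import _emit_trna, TRNA_ANTICODONS
import numpy as np


# -- independent no-pruning oracle ------------------------------------------

def _oracle_pair_score(x, y):
    if (x, y) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return 2, "WC"
    if (x, y) in (("G", "T"), ("T", "G"), ("T", "T"), ("G", "A"), ("A", "G")):
        return 1, "wobble"
    return 0, "mismatch"


def _oracle_score(seq, d, dl, v, t, tl, lost):
    """Score one layout by explicit segment walking."""
    if lost:
        segs = [("acc5", 7), ("dhu_region", d), ("ac5", 5), ("ac_loop", 7),
                ("ac3", 5), ("var", v), ("t5", t), ("t_loop", tl),
                ("t3", t), ("acc3", 7)]
    else:
        segs = [("acc5", 7), ("dhu5", d), ("dhu_loop", dl), ("dhu3", d),
                ("ac5", 5), ("ac_loop", 7), ("ac3", 5), ("var", v),
                ("t5", t), ("t_loop", tl), ("t3", t), ("acc3", 7)]
    if sum(n for _, n in segs) != len(seq):
        return None
    bounds = {}
    pos = 0
    for name, n in segs:
        bounds[name] = (pos, pos + n)
        pos += n
    score = wc = 0
    pairs = [("acc5", "acc3"), ("ac5", "ac3"), ("t5", "t3")]
    if not lost:
        pairs.append(("dhu5", "dhu3"))
    for five, three in pairs:
        (a0, a1), (b0, b1) = bounds[five], bounds[three]
        for k in range(a1 - a0):
            s, cls = _oracle_pair_score(seq[a0 + k], seq[b1 - 1 - k])
            score += s
            wc += cls == "WC"
    return score, wc, bounds


def oracle_fold(seq, tmpl=DEFAULT_TEMPLATE):
    """Exhaustive enumeration of every layout tuple in the template's
    ranges, no pruning, independent scoring; returns (score, dhu_lost,
    layout) of the winner under the same tie-break, or None."""
    best = None
    full_iter = itertools.product(
        range(tmpl.dhu_stem[0], tmpl.dhu_stem[1] + 1),
        range(tmpl.dhu_loop[0], tmpl.dhu_loop[1] + 1),
        range(tmpl.var_loop[0], tmpl.var_loop[1] + 1),
        range(tmpl.t_stem[0], tmpl.t_stem[1] + 1),
        range(tmpl.t_loop[0], tmpl.t_loop[1] + 1))
    cands = []
    for d, dl, v, t, tl in full_iter:
        r = _oracle_score(seq, d, dl, v, t, tl, lost=False)
        if r is not None:
            cands.append((r[0], r[1], False, (d, dl, v, t, tl), r[2]))
    best_full = max(cands, key=lambda c: (c[0], c[1], tuple(-x for x in c[3])),
                    default=None)
    loss_cands = []
    if tmpl.allow_dhu_loss:
        for d, v, t, tl in itertools.product(
                range(tmpl.dhu_loss_region[0], tmpl.dhu_loss_region[1] + 1),
                range(tmpl.var_loop[0], tmpl.var_loop[1] + 1),
                range(tmpl.t_stem[0], tmpl.t_stem[1] + 1),
                range(tmpl.t_loop[0], tmpl.t_loop[1] + 1)):
            r = _oracle_score(seq, d, None, v, t, tl, lost=True)
            if r is not None:
                loss_cands.append((r[0], r[1], True, (d, v, t, tl), r[2]))
    best_loss = max(loss_cands,
                    key=lambda c: (c[0], c[1], tuple(-x for x in c[3])),
                    default=None)
    best = best_full
    if best_loss is not None and (best is None or best_loss[0] > best[0]):
        best = best_loss
    if best is None:
        return None
    npairs = 7 + 5 + best[3][-2] + (0 if best[2] else best[3][0])
    import math
    if best[0] < math.ceil(tmpl.min_score_frac * 2 * npairs):
        return None
    return best


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFoldCloverleaf:
    def test_planted_boundaries_recovered(self):
        rng = np.random.default_rng(11)
        params = GeneratorParams(seed=11)
        for name in ("trnM", "trnI", "trnF"):
            seq, segments = _emit_trna(rng, params,
                                       TRNA_ANTICODONS[name], dhu_lost=False)
            st = fold_cloverleaf(seq)
            assert st is not None and not st.dhu_lost
            assert st.segments == segments

    def test_dhu_loss_detected_on_planted_loop(self):
        rng = np.random.default_rng(12)
        params = GeneratorParams(seed=12)
        seq, segments = _emit_trna(rng, params, TRNA_ANTICODONS["trnS1"],
                                   dhu_lost=True)
        st = fold_cloverleaf(seq)
        assert st is not None and st.dhu_lost
        assert st.segments == segments

    def test_homopolymer_rejected(self):
        assert fold_cloverleaf("A" * 66) is None

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            fold_cloverleaf("ACGT" * 10)  # 40 nt

    def test_matches_no_pruning_oracle_on_random_sequences(self):
        rng = random.Random(3)
        agree = 0
        for _ in range(30):
            n = rng.randint(60, 75)
            seq = random_seq(rng, n)
            ours = fold_cloverleaf(seq)
            ref = oracle_fold(seq)
            if ref is None:
                assert ours is None
            else:
                assert ours is not None
                assert ours.score == ref[0]
                assert ours.dhu_lost == ref[2]
                assert ours.wc_count == ref[1]
            agree += 1
        assert agree == 30

    def test_generated_trna_lengths_within_observed_range(self, default_genome):
        rec, ann, _ = default_genome
        lengths = [f.end - f.start + 1 for f in ann.by_category("tRNA")]
        assert min(lengths) >= 63 and max(lengths) <= 71


class TestAnticodon:
    def test_planted_anticodons_reported(self, default_genome):
        rec, ann, truth = default_genome
        for f in ann.by_category("tRNA"):
            st = fold_cloverleaf(extract_sequence(rec, f))
            assert anticodon_of(st) == truth.anticodons[f.name]

    def test_central_triplet_of_loop(self):
        rng = np.random.default_rng(13)
        seq, segments = _emit_trna(rng, GeneratorParams(seed=13), "CAT",
                                   dhu_lost=False)
        st = fold_cloverleaf(seq)
        lo, hi = st.segments["ac_loop"]
        mid = lo + (hi - lo) // 2
        assert anticodon_of(st) == seq[mid - 1:mid + 2] == "CAT"


class TestMismatchCensus:
    def test_all_wc_planted_stems(self):
        rng = np.random.default_rng(14)
        params = GeneratorParams(seed=14, wobble_rate=0.0)
        seq, _ = _emit_trna(rng, params, "CAT", dhu_lost=False)
        st = fold_cloverleaf(seq)
        census = mismatch_census(st)
        assert all(c["wobble"] == 0 and c["mismatch"] == 0
                   for c in census.values())

    def test_counts_equal_independent_recount(self):
        rng = random.Random(9)
        checked = 0
        while checked < 10:
            seq = random_seq(rng, rng.randint(63, 71))
            st = fold_cloverleaf(seq)
            if st is None:
                continue
            census = mismatch_census(st)
            for stem, plist in st.pairs.items():
                recount = {"WC": 0, "wobble": 0, "mismatch": 0}
                for (i, j, _) in plist:
                    _, cls = _oracle_pair_score(seq[i], seq[j])
                    recount[cls] += 1
                assert census[stem] == recount
                assert sum(recount.values()) == len(plist)
            checked += 1
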