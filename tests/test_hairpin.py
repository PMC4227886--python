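"""Folding dynamic program and biogenesis evaluation of hairpin candidates."""

import numpy as np
import pytest

from srnapipe import hairpin
from srnapipe._util import revcomp
from srnapipe.hairpin import (HairpinCandidate, Thresholds, call_novel,
                              evaluate_precursor, fold, pair_weight,
                              predict_star, score_structure)


def enumerate_structures(seq, min_loop=3):
    """All nested pair sets (exponential enumeration oracle, <= ~14 nt)."""
    n = len(seq)

    def rec_full(positions):
        if not positions:
            yield []
            return
        i, rest = positions[0], positions[1:]
        # i unpaired
        yield from rec_full(rest)
        # i paired with some j
        for b, j in enumerate(rest):
            if j - i <= min_loop or pair_weight(seq[i], seq[j]) == 0:
                continue
            inside = [p for p in rest if p < j]
            outside = [p for p in rest if p > j]
            for s_in in rec_full(inside):
                for s_out in rec_full(outside):
                    yield [(i, j)] + s_in + s_out

    yield from rec_full(list(range(n)))


def valid_nested(pairs, n, min_loop=3):
    used = set()
    for i, j in pairs:
        if i in used or j in used or j - i <= min_loop:
            return False
        used.update((i, j))
    for i, j in pairs:
        for k, l in pairs:
            if i < k < j < l:
                return False
    return True


class TestFold:
    def test_perfect_gc_stem(self):
        fr = fold("GGGAAACCC")
        assert fr.structure == "(((...)))" and fr.score == 9

    def test_homopolymer_has_no_pairs(self):
        fr = fold("AAAAAAAA")
        assert fr.structure == "........" and fr.score == 0

    def test_score_recount_matches(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            s = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 60))))
            fr = fold(s)
            assert score_structure(s, fr.pairs) == fr.score

    def test_min_loop_respected(self):
        for i, j in fold("GGGGAAACCCCGGGGAAACCCC").pairs:
            assert j - i >= 4

    def test_matches_exhaustive_enumeration_small(self):
        """DP optimum equals brute-force enumeration over all nested
        structures for short sequences."""
        rng = np.random.default_rng(13)
        for _ in range(60):
            n = int(rng.integers(5, 13))
            s = "".join(rng.choice(list("ACGT"), n))
            best = max(score_structure(s, p)
                       for p in enumerate_structures(s))
            fr = fold(s)
            assert fr.score == best
            assert valid_nested(fr.pairs, n)

    def test_reverse_complement_strand_consistency(self):
        """Watson-Crick pairs mirror exactly onto the reverse complement;
        G:U wobble does not (its complement C:A cannot pair), so the
        reverse-complement score equals the forward score whenever neither
        optimal structure uses wobble pairs, and is never below the
        mirrored Watson-Crick score otherwise."""
        rng = np.random.default_rng(23)
        exact_checked = 0
        for _ in range(60):
            s = "".join(rng.choice(list("ACGT"), int(rng.integers(15, 50))))
            n = len(s)
            fr = fold(s)
            rc = fold(revcomp(s))

            def is_wobble(seq, i, j):
                return {seq[i], seq[j]} == {"G", "T"}

            wc_pairs = [(i, j) for i, j in fr.pairs if not is_wobble(s, i, j)]
            mirrored = [(n - 1 - j, n - 1 - i) for i, j in wc_pairs]
            wc_score = score_structure(s, wc_pairs)
            assert score_structure(revcomp(s), mirrored) == wc_score
            assert rc.score >= wc_score
            if wc_pairs == fr.pairs and \
                    all(not is_wobble(revcomp(s), i, j) for i, j in rc.pairs):
                assert rc.score == fr.score
                exact_checked += 1
        assert exact_checked >= 5      # the exact branch is exercised

    def test_rna_input_accepted(self):
        assert fold("GGGAAACCC").score == fold("GGGAAACCC".replace("T", "U")).score

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            fold("GGGAXACCC")


def make_precursor(rng, mature_len=22, arm="5p", star_mismatches=2):
    mature = "".join(rng.choice(list("ACGT"), mature_len))
    loop = "".join(rng.choice(list("ACGT"), 12))
    star = list(revcomp(mature))
    for p in rng.choice(np.arange(3, len(star) - 3), star_mismatches,
                        replace=False):
        star[p] = str(rng.choice([b for b in "ACGT" if b != star[p]]))
    star = "".join(star)
    if arm == "5p":
        return mature + loop + star, 0, mature_len
    return star + loop + mature, len(star) + len(loop), mature_len


class TestEvaluate:
    def test_clean_hairpin_passes(self, sim_data):
        refs = sim_data.references
        for name, pre in list(refs.hairpins.items())[:5]:
            mir = name.removesuffix("-pre")
            mat = refs.known_mature[mir]
            cand = HairpinCandidate.from_sequence(pre, pre.find(mat),
                                                  len(mat))
            ev = evaluate_precursor(cand)
            assert ev.passed, ev.reasons
            assert ev.arm == refs.arms[mir]

    def test_loop_spanning_mature_fails_with_reason(self):
        rng = np.random.default_rng(31)
        pre, _off, ml = make_precursor(rng, arm="5p")
        # centre the "mature" on the terminal loop
        cand = HairpinCandidate.from_sequence(pre, 12, ml)
        ev = evaluate_precursor(cand)
        assert not ev.passed
        assert any("loop" in r for r in ev.reasons)

    def test_random_windows_rarely_pass(self):
        """Shuffle null: windows of random sequence with an end-positioned
        mature pass in fewer than 5% of 200 cases."""
        rng = np.random.default_rng(41)
        passes = 0
        for _ in range(200):
            s = "".join(rng.choice(list("ACGT"), 102))
            cand = HairpinCandidate.from_sequence(s, 80, 22)
            passes += evaluate_precursor(cand).passed
        assert passes / 200 < 0.05

    def test_structure_length_mismatch_rejected(self):
        cand = HairpinCandidate(precursor_sequence="ACGT" * 10,
                                mature_offset=0, mature_length=20,
                                structure="...")
        with pytest.raises(ValueError):
            evaluate_precursor(cand)


class TestPredictStar:
    def test_perfect_stem_star_is_shifted_reverse_complement(self):
        rng = np.random.default_rng(7)
        mature = "".join(rng.choice(list("ACGT"), 22))
        pre = mature + "A" * 12 + revcomp(mature)
        cand = HairpinCandidate.from_sequence(pre, 0, 22)
        ev = evaluate_precursor(cand, Thresholds(min_norm_score=0.0))
        assert ev.arm == "5p"
        star = predict_star(cand)
        assert star.defined
        n = len(pre)
        # partner of mature position p is n-1-p on a perfect palindromic
        # stem; the 2 nt 3' overhang shifts the star window right by 2
        expect_lo, expect_hi = n - 1 - (22 - 3), min(n, n - 1 + 3)
        assert (star.start, star.end) == (expect_lo, expect_hi)
        assert star.sequence == pre[expect_lo:expect_hi]

    def test_bulged_mature_changes_star_length(self):
        rng = np.random.default_rng(8)
        mature = "".join(rng.choice(list("ACGT"), 22))
        # 2 nt bulge inside the star arm
        star = revcomp(mature)
        pre = mature + "AAAT" * 3 + star[:10] + "GG" + star[10:]
        cand = HairpinCandidate.from_sequence(pre, 0, 22)
        evaluate_precursor(cand, Thresholds(min_norm_score=0.0))
        s = predict_star(cand)
        if s.defined:
            assert abs((s.end - s.start) - 22) <= 4

    def test_loop_spanning_candidate_flagged(self):
        rng = np.random.default_rng(9)
        pre, _off, ml = make_precursor(rng)
        cand = HairpinCandidate.from_sequence(pre, 12, ml)
        evaluate_precursor(cand)
        star = predict_star(cand)
        assert not star.defined


class TestCallNovel:
    def _passing_candidate(self, rng):
        pre, off, ml = make_precursor(rng)
        return HairpinCandidate.from_sequence(pre, off, ml)

    def test_single_passing_window_emitted(self):
        rng = np.random.default_rng(51)
        good = self._passing_candidate(rng)
        bad = HairpinCandidate.from_sequence(
            "".join(rng.choice(list("ACGT"), 60)), 0, 22)
        locus = ("chr1", 100, 122, "+")
        recs = call_novel([(locus, [good, bad])], search_boundaries=False)
        assert len(recs) == 1
        assert recs[0].name == "novel-m0001-5p"
        assert recs[0].locus == locus

    def test_no_passing_window_drops_locus(self):
        rng = np.random.default_rng(52)
        bad = HairpinCandidate.from_sequence(
            "".join(rng.choice(list("ACGT"), 60)), 0, 22)
        assert call_novel([(("chr1", 0, 22, "+"), [bad])],
                          search_boundaries=False) == []

    def test_tie_prefers_five_prime_window(self):
        rng = np.random.default_rng(53)
        good = self._passing_candidate(rng)
        recs = call_novel([(("chr1", 0, 22, "+"), [good, good])],
                          search_boundaries=False)
        assert len(recs) == 1     # both pass with equal score; window A wins

    def test_names_assigned_in_discovery_order(self):
        rng = np.random.default_rng(54)
        a = self._passing_candidate(rng)
        b = self._passing_candidate(rng)
        recs = call_novel([(("chr1", 0, 22, "+"), [a]),
                           (("chr1", 500, 522, "+"), [b])],
                          search_boundaries=False)
        assert [r.name.split("-")[1] for r in recs] == ["m0001", "m0002"]

    def test_planted_novel_recovery(self, sim_data, run_result):
        """>= 90% of planted novel loci recovered, no calls elsewhere."""
        gt = sim_data.ground_truth
        planted = {tuple(v) for k, v in gt.mirna_loci.items()
                   if k.startswith("sim-nov")}
        called = {tuple(n.locus) for n in run_result.novel}
        assert len(called & planted) >= 0.9 * len(planted)
        assert not (called - planted)
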