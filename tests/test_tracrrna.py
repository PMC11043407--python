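"""Anti-repeat search, terminator rule, sgRNA assembly, folding, modules."""

import itertools

import pytest

from casforge.core_io import SequenceRecord, revcomp, rng, transcribe
from casforge.tracrrna import (
    StructurePrediction,
    TracrRNACandidate,
    assemble_sgrna,
    can_pair,
    check_modules,
    dot_bracket,
    extract_tracr_candidates,
    find_anti_repeats,
    fold,
    predict_terminators,
)
from conftest import random_dna


# ---------------------------------------------------------------------------
# independent oracles


def smith_waterman(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1) -> int:
    """Plain affine-gap local alignment, independent of the search path."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_structures(seq: str, min_loop=3, noLP=True):
    """All valid pair sets by brute-force recursion over intervals."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    def helices_ok(pairs):
        ps = set(pairs)
        for (i, j) in ps:
            if (i - 1, j + 1) not in ps and (i + 1, j - 1) not in ps:
                return False
        return True

    def rec(i, j):
        if j - i < min_loop + 1:
            yield frozenset()
            return
        # j unpaired
        for s in rec(i, j - 1):
            yield s
        # j paired with k
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                for inner in rec(k + 1, j - 1):
                    for outer in rec(i, k - 1):
                        yield frozenset({(k, j)}) | inner | outer

    seen = set()
    for s in rec(0, n - 1):
        if s in seen:
            continue
        seen.add(s)
        if not noLP or helices_ok(s):
            yield s


def brute_force_max_pairs(seq: str) -> int:
    return max(len(s) for s in enumerate_structures(seq))


# ---------------------------------------------------------------------------
# anti-repeat search


class TestFindAntiRepeats:
    def test_exact_reverse_complement_hit(self):
        flank = random_dna(11, 3000, "flank")
        repeat = random_dna(11, 24, "rep")
        planted = flank[:1200] + revcomp(repeat) + flank[1200:]
        hits = find_anti_repeats(planted, repeat)
        assert hits[0].score == 24
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (1201, 1224)
        assert hits[0].aligned_fraction == 1.0

    def test_null_flank_no_strong_hit_vs_sw_oracle(self):
        flank = random_dna(11, 3000, "flank")
        repeat = random_dna(11, 24, "rep")
        oracle = max(
            smith_waterman(flank, repeat), smith_waterman(revcomp(flank), repeat)
        )
        assert oracle < 16
        hits = find_anti_repeats(flank, repeat)
        assert all(h.score < 16 for h in hits)
        # every reported hit score is bounded by the optimal local alignment
        assert all(h.score <= oracle for h in hits)

    def test_three_mismatches_score_18(self, mutate):
        flank = random_dna(11, 3000, "flank")
        repeat = random_dna(11, 24, "rep")
        # mismatches leave an exact 8-word so the seeded search can find it
        anti = mutate(revcomp(repeat), [2, 12, 22])
        planted = flank[:1500] + anti + flank[1500:]
        hits = find_anti_repeats(planted, repeat)
        assert hits[0].score == 18  # 21 matches - 3 mismatches

    def test_reverse_complement_swaps_strands(self):
        flank = random_dna(4, 2000, "flank")
        repeat = random_dna(4, 28, "rep")
        planted = flank[:800] + revcomp(repeat) + flank[800:]
        fwd = find_anti_repeats(planted, repeat)
        rev = find_anti_repeats(revcomp(planted), repeat)
        assert fwd[0].strand == "-" and rev[0].strand == "+"
        assert fwd[0].score == rev[0].score
        n = len(planted)
        assert (rev[0].start, rev[0].end) == (n - fwd[0].end + 1, n - fwd[0].start + 1)

    def test_short_repeat_rejected(self):
        with pytest.raises(ValueError, match="word_size"):
            find_anti_repeats("ACGTACGTAC" * 30, "ACGT")

    def test_score_never_exceeds_repeat_length(self):
        flank = random_dna(8, 2500, "flank")
        repeat = random_dna(8, 30, "rep")
        planted = flank[:700] + revcomp(repeat) + flank[700:]
        for h in find_anti_repeats(planted, repeat):
            assert h.score <= len(repeat)


class TestTerminators:
    def test_stem7_loop4_utract6(self):
        terms = predict_terminators("GGGGCGCAAAAGCGCCCCTTTTTT")
        assert len(terms) == 1
        t = terms[0]
        assert (t.stem_len, t.loop_len, t.u_tract_len) == (7, 4, 6)
        assert t.score == 20

    def test_hairpin_without_t_tract(self):
        assert predict_terminators("GGGGCGCAAAAGCGCCCCAAAAAA") == []

    def test_poly_a_window(self):
        assert predict_terminators("A" * 60) == []

    def test_wobble_pairs_allowed_in_stem(self):
        # stem pairs G.T at two positions
        stem_l, stem_r = "GGTGG", "CCGCC"  # G:C G:C T:G G:C G:C reversed
        seq = stem_l + "AAAA" + stem_r + "TTTTT"
        terms = predict_terminators(seq)
        assert terms and terms[0].stem_len >= 5


class TestAssembleSgrna:
    def _candidate(self, repeat, mism=()):
        anti = revcomp(repeat)
        anti = "".join(
            c if i not in mism else "ACGT"[("ACGT".index(c) + 1) % 4] for i, c in enumerate(anti)
        )
        body = "CCCC" + "ATGCAT" + "CAAC" + "ATGCAT" + "CC" + "GCATACGC" + "TTCG" + "GCGTATGC" + "TTTTTT"
        return TracrRNACandidate(transcribe(anti + body), len(anti), None)

    def test_fs_contains_tetraloop_once(self):
        repeat = "GTTTTAGAGCTATGCTGTTTTG"
        sc = assemble_sgrna(repeat, self._candidate(repeat), "FS")
        assert sc.sequence.count("GAAA") >= 1
        tl = sc.annotations.tetraloop_span
        assert sc.sequence[tl[0] : tl[1] + 1] == "GAAA"
        # tetraloop sits exactly at the repeat/anti-repeat junction
        assert tl[0] == sc.annotations.repeat_span[1] + 1
        assert tl[1] == sc.annotations.anti_span[0] - 1

    def test_ts_trims_duplex_to_six_pairs(self):
        repeat = random_dna(3, 24, "rep")
        sc = assemble_sgrna(repeat, self._candidate(repeat), "TS", trim_len=6)
        assert len(sc.annotations.duplex_pairs) == 6

    def test_opt_requires_substitutions(self):
        repeat = random_dna(3, 24, "rep")
        with pytest.raises(ValueError, match="substitutions"):
            assemble_sgrna(repeat, self._candidate(repeat), "FS-opt")

    def test_no_duplex_error(self):
        repeat = "GTTTTAGAGCTATGCTGTTTTG"
        bad = TracrRNACandidate(transcribe("C" * 20 + "TTTT"), 20, None)
        with pytest.raises(ValueError, match="no duplex"):
            assemble_sgrna(repeat, bad, "FS")


class TestFold:
    def test_forced_hairpin(self):
        pred = fold("GGGAAACCC")
        assert pred.dot_brackets()[0] == "(((...)))"
        assert pred.scores[0] == 3

    def test_unpairable_sequence(self):
        pred = fold("AAAAAAAA")
        assert pred.structures == [frozenset()]
        assert pred.scores == [0.0]

    def test_random_20mer_matches_brute_force(self):
        seq = random_dna(3, 20, "rna")
        assert fold(seq).scores[0] == brute_force_max_pairs(seq)

    def test_optimum_matches_brute_force_on_corpus(self):
        corpus = [random_dna(s, 12 + s, "rna") for s in range(8)]
        corpus += ["GGGAAACCCGGGAAACCC", "GCGCAAAAGCGC", "AUAUAUAUAUAU"]
        for seq in corpus:
            assert fold(seq).scores[0] == brute_force_max_pairs(seq), seq

    def test_no_lonely_pairs_and_min_loop(self):
        for seq in (random_dna(s, 40, "rna2") for s in range(5)):
            for pairs in fold(seq).structures:
                ps = set(pairs)
                for (i, j) in ps:
                    assert j - i - 1 >= 3
                    assert (i - 1, j + 1) in ps or (i + 1, j - 1) in ps

    def test_extension_monotone(self):
        seq = random_dna(6, 30, "rna3")
        base = fold(seq).scores[0]
        extended = fold("GGG" + seq + "CCC").scores[0]
        assert extended >= base

    def test_rejects_non_rna(self):
        with pytest.raises(ValueError):
            fold("ACGX")


class TestCheckModules:
    def _scaffold_and_prediction(self, scramble_anti=False, truncate=False):
        repeat = random_dna(9, 30, "rep")
        anti = revcomp(repeat)
        if scramble_anti:
            g = rng(9, "scramble")
            anti = list(anti)
            g.shuffle(anti)
            anti = "".join(anti)
        body = "CCCC" + "ATGCAT" + "CAAC" + "ATGCAT" + "CC" + "GCATACGC" + "TTCG" + "GCGTATGC" + "TTTTTT"
        if truncate:
            body = body[: len(body) - 32]  # drop the terminator hairpin
        cand = TracrRNACandidate(transcribe(anti + body), len(anti), None)
        sc = assemble_sgrna(repeat, cand, "FS")
        return sc, fold(sc.sequence)

    def test_planted_scaffold_passes(self):
        sc, pred = self._scaffold_and_prediction()
        ok, reasons = check_modules(sc, pred)
        assert ok, reasons

    def test_scrambled_anti_fails_duplex(self):
        try:
            sc, pred = self._scaffold_and_prediction(scramble_anti=True)
        except ValueError as exc:
            assert "no duplex" in str(exc)
            return
        ok, reasons = check_modules(sc, pred)
        assert not ok and "duplex" in reasons

    def test_truncated_fails_three_prime_hairpin(self):
        sc, pred = self._scaffold_and_prediction(truncate=True)
        ok, reasons = check_modules(sc, pred)
        assert not ok and "3' hairpin" in reasons


def test_extract_candidate_ends_at_terminator():
    flank = random_dna(15, 1000, "flank")
    repeat = random_dna(15, 30, "rep")
    term = "GCATACGC" + "TTCG" + "GCGTATGC" + "TTTTTT"
    tracr = revcomp(repeat) + "CCCCATGCATCAACATGCATCC" + term
    seq = flank[:400] + tracr + flank[400:]
    hits = find_anti_repeats(seq, repeat)
    cands = extract_tracr_candidates(seq, hits)
    cand = cands[0]
    assert cand is not None
    assert cand.terminator is not None
    assert cand.sequence == transcribe(tracr)


def test_dot_bracket_round_trips():
    pairs = frozenset({(0, 8), (1, 7)})
    assert dot_bracket(pairs, 9) == "((.....))"
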