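"""Array detection, locus assembly, discovery filters and clustering."""

import statistics

import pytest

from casforge.core_io import ArrayParams, FeatureRecord, SequenceRecord
from casforge.locus_mining import (
    CrisprArray,
    assemble_loci,
    cluster_sequences,
    dedupe_by_coverage,
    detect_crispr_arrays,
    filter_length_outliers,
    filter_loci,
    SequenceCluster,
)
from conftest import random_dna


def plant_array(background: str, at: int, repeat: str, spacers: list[str]) -> str:
    arr = repeat + "".join(s + repeat for s in spacers)
    return background[:at] + arr + background[at + len(arr) :]


class TestDetectArrays:
    def test_three_planted_repeats_single_array(self):
        bg = random_dna(7, 5000)
        repeat = random_dna(7, 30, "rep")
        spacers = [random_dna(7, 35, "sp1"), random_dna(7, 35, "sp2")]
        contig = SequenceRecord("c", plant_array(bg, 2000, repeat, spacers))
        arrays = detect_crispr_arrays(contig)
        assert len(arrays) == 1
        assert arrays[0].n_repeats == 3
        assert arrays[0].n_spacers == 2

    def test_repeats_below_length_bound_rejected(self):
        bg = random_dna(7, 5000)
        repeat = random_dna(7, 20, "rep")  # below the 23-bp minimum
        spacers = [random_dna(7, 35, "sp1"), random_dna(7, 35, "sp2")]
        contig = SequenceRecord("c", plant_array(bg, 2000, repeat, spacers))
        assert detect_crispr_arrays(contig) == []

    def test_two_arrays_recover_planted_spans(self):
        bg = random_dna(13, 12000)
        r1, r2 = random_dna(13, 32, "r1"), random_dna(13, 36, "r2")
        sp = [random_dna(13, 30, f"s{i}") for i in range(3)]
        seq = plant_array(bg, 1000, r1, sp[:2])
        seq = plant_array(seq, 7000, r2, sp)
        arrays = detect_crispr_arrays(SequenceRecord("c", seq))
        assert len(arrays) == 2
        expect1 = (1001, 1000 + 3 * 32 + 2 * 30)
        expect2 = (7001, 7000 + 4 * 36 + 3 * 30)
        got = sorted(a.span for a in arrays)
        for g, e in zip(got, [expect1, expect2]):
            assert abs(g[0] - e[0]) <= 3 and abs(g[1] - e[1]) <= 3

    def test_short_contig_empty(self):
        assert detect_crispr_arrays(SequenceRecord("c", "ACGT" * 10)) == []

    def test_spacer_lengths_within_bounds_and_no_overlap(self):
        params = ArrayParams()
        bg = random_dna(21, 9000)
        repeat = random_dna(21, 36, "rep")
        spacers = [random_dna(21, 28 + 3 * i, f"s{i}") for i in range(5)]
        contig = SequenceRecord("c", plant_array(bg, 3000, repeat, spacers))
        arrays = detect_crispr_arrays(contig, params)
        spans = sorted(a.span for a in arrays)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for a in arrays:
            for _, _, spacer in a.units:
                if spacer is not None:
                    assert params.spacer_min <= len(spacer) <= params.spacer_max


def _feat(contig, start, end, kind, **attrs):
    return FeatureRecord(contig, start, end, "+", kind, attrs)


def _array(contig, start, end, n_spacers=24):
    units = [(start + i, start + i + 35, "A" * 30) for i in range(n_spacers)]
    units.append((end - 35, end, None))
    return CrisprArray(contig, start, end, "G" * 36, units)


class TestAssembleLoci:
    def test_all_within_gap(self):
        arr = _array("c", 20_000, 21_700)
        feats = [
            _feat("c", 12_000, 15_000, "cas9", protein_length_aa=1004, coverage=20, species="s"),
            _feat("c", 15_200, 16_100, "cas1"),
            _feat("c", 16_200, 16_500, "cas2"),
        ]
        loci = assemble_loci([arr], feats)
        assert len(loci) == 1
        assert loci[0].complete

    def test_component_beyond_10kbp_rejected(self):
        arr = _array("c", 20_000, 21_700)
        feats = [
            _feat("c", 12_000, 15_000, "cas9", protein_length_aa=1004),
            _feat("c", 15_200, 16_100, "cas1"),
            _feat("c", 33_800, 34_100, "cas2"),  # 12 kbp from the array
        ]
        assert assemble_loci([arr], feats) == []

    def test_missing_cas1_rejected(self):
        arr = _array("c", 20_000, 21_700)
        feats = [
            _feat("c", 12_000, 15_000, "cas9", protein_length_aa=1004),
            _feat("c", 16_200, 16_500, "cas2"),
        ]
        assert assemble_loci([arr], feats) == []


class TestFilterLoci:
    def _locus(self, aa, n_spacers):
        arr = _array("c", 20_000, 21_700, n_spacers)
        feats = [
            _feat("c", 12_000, 15_100, "cas9", protein_length_aa=aa, coverage=10, species="s"),
            _feat("c", 15_200, 16_100, "cas1"),
            _feat("c", 16_200, 16_500, "cas2"),
        ]
        return assemble_loci([arr], feats)[0]

    @pytest.mark.parametrize(
        "aa,n_spacers,kept",
        [(1004, 24, True), (900, 24, False), (1004, 5, False), (1100, 24, False), (950, 6, True)],
    )
    def test_length_and_spacer_rules(self, aa, n_spacers, kept):
        loci = [self._locus(aa, n_spacers)]
        assert (len(filter_loci(loci)) == 1) is kept

    def test_idempotent_and_subset(self):
        loci = [self._locus(a, s) for a, s in [(1004, 24), (900, 24), (1050, 10)]]
        once = filter_loci(loci)
        assert filter_loci(once) == once
        assert all(l in loci for l in once)

    def test_missing_length_errors(self):
        locus = self._locus(1004, 24)
        del locus.cas9.attributes["protein_length_aa"]
        with pytest.raises(ValueError, match="protein_length_aa"):
            filter_loci([locus])


class TestDedupe:
    def _locus(self, species, coverage, protein, ident="x"):
        arr = _array("c" + ident, 20_000, 21_700)
        feats = [
            _feat("c" + ident, 12_000, 15_100, "cas9",
                  protein_length_aa=len(protein), protein_sequence=protein,
                  coverage=coverage, species=species, ID=ident),
            _feat("c" + ident, 15_200, 16_100, "cas1"),
            _feat("c" + ident, 16_200, 16_500, "cas2"),
        ]
        return assemble_loci([arr], feats)[0]

    def test_highest_coverage_wins(self):
        prot = "M" + "ACDEFGHIKLMNPQRSTVWY" * 20
        a = self._locus("sp", 12, prot, "a")
        b = self._locus("sp", 30, prot, "b")
        out = dedupe_by_coverage([a, b])
        assert out == [b]

    def test_domain_deletion_discarded_despite_coverage(self):
        prot = "M" + "ACDEFGHIKLMNPQRSTVWY" * 20
        deleted = prot[:100] + prot[110:]  # 10-aa deletion at positions 101-110
        full = self._locus("sp", 12, prot, "a")
        high_cov_deleted = self._locus("sp", 40, deleted, "b")
        out = dedupe_by_coverage([full, high_cov_deleted], [(90, 130)])
        assert out == [full]

    def test_single_member_kept_unconditionally(self):
        prot = "M" + "AC" * 50
        a = self._locus("sp", 1, prot, "a")
        assert dedupe_by_coverage([a], [(1, 50)]) == [a]


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        recs = [SequenceRecord("a", "MKVL" * 50, "protein"), SequenceRecord("b", "MKVL" * 50, "protein")]
        assert len(cluster_sequences(recs, 0.95, 0.5)) == 1

    def test_unrelated_sequences_two_clusters(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        s1 = "".join(aas[i % 20] for i in range(300))
        s2 = "".join(aas[(7 * i + 3) % 20] for i in range(300))
        recs = [SequenceRecord("a", s1, "protein"), SequenceRecord("b", s2, "protein")]
        assert len(cluster_sequences(recs, 0.95, 0.5)) == 2

    def test_96_percent_identity_joins_at_095(self, mutate):
        base = random_dna(5, 100, "prot").replace("T", "W")  # 4-letter pseudo-protein
        other = list(base)
        for p in (10, 35, 60, 85):
            other[p] = "Y" if other[p] != "Y" else "H"
        recs = [
            SequenceRecord("a", base, "protein"),
            SequenceRecord("b", "".join(other), "protein"),
        ]
        # oracle: gapless global alignment of equal-length sequences
        ident = sum(x == y for x, y in zip(base, "".join(other))) / 100
        assert ident == 0.96
        assert len(cluster_sequences(recs, 0.95, 0.5)) == 1

    def test_identity_one_gives_singletons(self):
        recs = [
            SequenceRecord("a", "MKVLAHGW" * 30, "protein"),
            SequenceRecord("b", "MKVLAHGY" * 30, "protein"),
        ]
        assert len(cluster_sequences(recs, 1.0, 0.5)) == 2

    def test_empty_input(self):
        assert cluster_sequences([], 0.9, 0.5) == []


class TestLengthOutliers:
    def test_short_member_excluded(self):
        cl = SequenceCluster("a", ["a", "b", "c", "d", "e"], 0.95, 0.5)
        lengths = {"a": 1000, "b": 1000, "c": 1000, "d": 1000, "e": 400}
        out = filter_length_outliers(cl, lengths)
        # population sd: median 1000, sd 240, cutoff 520 -> the 400-aa member drops
        assert statistics.pstdev(lengths.values()) == pytest.approx(240.0)
        assert out.member_ids == ["a", "b", "c", "d"]

    def test_equal_lengths_unchanged(self):
        cl = SequenceCluster("a", ["a", "b", "c"], 0.95, 0.5)
        out = filter_length_outliers(cl, {"a": 500, "b": 500, "c": 500})
        assert out.member_ids == ["a", "b", "c"]

    def test_single_member_unchanged(self):
        cl = SequenceCluster("a", ["a"], 0.95, 0.5)
        assert filter_length_outliers(cl, {"a": 10}).member_ids == ["a"]
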