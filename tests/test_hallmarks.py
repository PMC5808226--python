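"""Sequence hallmark annotation: ORF, pI/MW, motifs, hydropathy, alignment, PCR."""

import itertools
import re

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings, strategies as st

from aquapore.hallmarks import (
    IUPAC_DNA,
    SequenceRecord,
    cterm_motif,
    find_longest_orf,
    global_align,
    hydropathy_profile,
    in_silico_pcr,
    map_selectivity_filter,
    protein_mw,
    protein_pi,
    reverse_complement,
    scan_motif,
    variant_length_diff,
)

# ---------------------------------------------------------------- oracles

_STOPS = {"TAA", "TAG", "TGA"}
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def orf_oracle(nt: str):
    """Exhaustive enumeration of every ATG..stop span in the 3 forward frames."""
    best = None  # (span, start) with span max, start min
    for start in range(len(nt) - 2):
        if nt[start : start + 3] != "ATG":
            continue
        for stop in range(start + 3, len(nt) - 2, 3):
            codon = nt[stop : stop + 3]
            if codon in _STOPS:
                span = stop + 3 - start
                if best is None or span > best[0] or (span == best[0] and start < best[1]):
                    best = (span, start)
                break
    if best is None:
        return None
    span, start = best
    protein = "".join(
        _CODE[nt[i : i + 3]] for i in range(start, start + span - 3, 3)
    )
    return start + 1, start + span, protein


def expand_degenerate(primer: str):
    return ("".join(p) for p in itertools.product(*(IUPAC_DNA[b] for b in primer)))


def pcr_oracle(template: str, fwd: str, rev: str):
    """All (forward_start, reverse_end) pairs by full degeneracy expansion."""
    fwd_starts = set()
    for concrete in expand_degenerate(fwd):
        fwd_starts.update(
            m.start() + 1 for m in re.finditer(f"(?={concrete})", template)
        )
    rev_ends = set()
    for concrete in expand_degenerate(reverse_complement(rev)):
        rev_ends.update(
            m.start() + len(concrete) for m in re.finditer(f"(?={concrete})", template)
        )
    return sorted(
        (fs, re_)
        for fs in fwd_starts
        for re_ in rev_ends
        if re_ - len(rev) >= fs - 1 + len(fwd)
    )


# ---------------------------------------------------------------- ORF


class TestFindLongestOrf:
    def test_minimal_orf(self):
        orf = find_longest_orf("ATGAAATAA")
        assert (orf.start, orf.end, orf.protein) == (1, 9, "MK")

    def test_longest_of_two_planted(self):
        # frame 1: ATG + 3 codons + stop (4-codon ORF incl. start);
        # later: ATG + 6 codons + stop — the longer one must win
        nt = "ATGAAACCCTAA" + "G" + "ATGAAACCCGGGACCTAA"
        orf = find_longest_orf(nt)
        assert orf.protein == "MKPGT"
        assert orf.start == 14

    def test_no_orf_returns_none(self):
        assert find_longest_orf("ATGAAACCCGGG") is None  # start but no stop

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_longest_orf("ATGA")

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_agrees_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nt = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        got = find_longest_orf(nt)
        expected = orf_oracle(nt)
        if expected is None:
            assert got is None
        else:
            assert (got.start, got.end, got.protein) == expected
            # translated length accounts for every codon but the stop
            assert len(got.protein) * 3 + 3 == got.end - got.start + 1


# ---------------------------------------------------------------- pI / MW


class TestMassAndIsoelectricPoint:
    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            protein_mw("")
        with pytest.raises(ValueError):
            protein_pi("")

    def test_gg_mass(self):
        # 2 x 57.0519 (Gly residue) + 18.0153 (water)
        assert protein_mw("GG") == pytest.approx(132.12, abs=0.005)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            protein_mw("GXZ")

    def test_gg_isoelectric_point(self):
        # midpoint of the Gly terminal pKas, (7.5 + 3.55)/2
        assert protein_pi("GG") == pytest.approx(5.5, abs=0.1)

    def test_basic_exceeds_acidic(self):
        assert protein_pi("K" * 10) > protein_pi("D" * 10)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=60))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_cross_check_against_protparam(self, protein):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        assert protein_mw(protein) == pytest.approx(
            ProteinAnalysis(protein).molecular_weight(), rel=1e-4)
        # full 0..14 bracket: ProtParam's default search floor is pH 4.05
        assert protein_pi(protein) == pytest.approx(
            IsoelectricPoint(protein).pi(7.0, 0.0, 14.0), abs=0.02)

    @given(st.permutations(list("ACDEFGHIKLMNPQRSTVWY")))
    @settings(derandomize=True, deadline=None, max_examples=20)
    def test_mass_is_composition_invariant(self, perm):
        assert protein_mw("".join(perm)) == pytest.approx(
            protein_mw("ACDEFGHIKLMNPQRSTVWY"), abs=1e-9)


# ---------------------------------------------------------------- motifs


class TestMotifs:
    @pytest.mark.parametrize(
        "protein, motif, expected",
        [
            ("NPAXXXNPA", "NPA", [1, 7]),
            ("AAAA", "NPA", []),
            ("AAAAA", "AA", [1, 2, 3, 4]),  # overlaps allowed
        ],
    )
    def test_scan(self, protein, motif, expected):
        assert scan_motif(protein, motif) == expected

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_motif("NPA", "")

    @pytest.mark.parametrize("protein", ["SYDF", "AAASYDF"])
    def test_cterm(self, protein):
        assert cterm_motif(protein, 4) == "SYDF"

    def test_cterm_too_short(self):
        with pytest.raises(ValueError):
            cterm_motif("YDF", 4)


# ---------------------------------------------------------------- hydropathy


class TestHydropathy:
    def test_polyalanine_single_window(self):
        prof = hydropathy_profile("A" * 19, window=19)
        assert prof.values.tolist() == pytest.approx([1.8])
        assert prof.centers.tolist() == [10]

    def test_alternating_arg_ala_never_crosses(self):
        prof = hydropathy_profile("RA" * 20, window=19, threshold=1.6)
        # window mean is about (-4.5 + 1.8)/2, far below threshold
        assert prof.values.max() < 1.6
        assert prof.segments == []

    def test_hydrophobic_core_called_once(self):
        protein = "D" * 20 + "I" * 25 + "D" * 20
        prof = hydropathy_profile(protein)
        assert len(prof.segments) == 1
        start, end = prof.segments[0]
        # pure-I windows (centers 30..36) must lie inside the called segment
        assert start <= 30 and end >= 36

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("A" * 30, window=10)


# ---------------------------------------------------------------- alignment


def brute_force_alignments(a: str, b: str):
    """Enumerate every global alignment of two short sequences."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in brute_force_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in brute_force_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in brute_force_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def affine_score(row_a: str, row_b: str, matrix, gap_open=10.0, gap_extend=0.5):
    score = 0.0
    for row in (row_a, row_b):
        for run in re.finditer("-+", row):
            n = run.end() - run.start()
            score -= gap_open + gap_extend * (n - 1)
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            score += matrix[x, y]
    return score


class TestGlobalAlign:
    def test_identical(self):
        assert global_align("ACDE", "ACDE").percent_identity == 100.0

    def test_single_mismatch(self):
        res = global_align("ACDE", "ACDD")
        assert res.percent_identity == 75.0
        assert "-" not in res.aligned_a + res.aligned_b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACDE")

    @pytest.mark.parametrize("a, b", [("MKT", "MT"), ("ACDE", "AD"), ("WW", "WAW")])
    def test_matches_brute_force_enumeration(self, a, b):
        matrix = substitution_matrices.load("BLOSUM62")
        scored = [
            (affine_score(ra, rb, matrix), ra, rb)
            for ra, rb in brute_force_alignments(a, b)
        ]
        best = max(s for s, _, _ in scored)
        optimal_identities = {
            100.0 * sum(x == y and x != "-" for x, y in zip(ra, rb)) / len(ra)
            for s, ra, rb in scored
            if s == best
        }
        res = global_align(a, b)
        assert res.score == pytest.approx(best)
        assert res.percent_identity in optimal_identities

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_identity_symmetric(self, a, b):
        assert global_align(a, b).percent_identity == pytest.approx(
            global_align(b, a).percent_identity)


class TestSelectivityFilterMapping:
    def test_identity_maps_to_self(self):
        q = "MKTAYIAKQRQISFVKSHFSRQL"
        sites = map_selectivity_filter(q, q, [3, 10, 20])
        assert [(s.query_position, s.query_residue) for s in sites] == [
            (3, "T"), (10, "R"), (20, "S")]

    def test_nterminal_extension_shifts_by_one(self):
        template = "GMKTAYIAKQRQISFVKSHFSRQL"
        query = template[1:]
        sites = map_selectivity_filter(query, template, [4, 11, 21])
        assert [s.query_position for s in sites] == [3, 10, 20]
        assert [s.query_residue for s in sites] == ["T", "R", "S"]

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            map_selectivity_filter("MKT", "MKT", [4])


# ---------------------------------------------------------------- PCR


class TestInSilicoPcr:
    def test_toy_template(self):
        products = in_silico_pcr("AAACATCAGTTTGGGCCCAAA", "CAYCAR", "GGGCCC",
                                 min_primer_len=6)
        oracle = pcr_oracle("AAACATCAGTTTGGGCCCAAA", "CAYCAR", "GGGCCC")
        assert [(p.forward_start, p.reverse_end) for p in products] == oracle
        assert products[0].length_bp == oracle[0][1] - oracle[0][0] + 1

    def test_degenerate_base_matching(self):
        # Y = C/T: CAY must hit CAT and CAC but never CAA
        for tail, hits in (("CATTTTTTTTT", 1), ("CACTTTTTTTT", 1), ("CAATTTTTTTT", 0)):
            found = in_silico_pcr(tail + "AAAAAAAAAA", "CAY" + "T" * 7,
                                  "TTTTTTTTTT", min_primer_len=10)
            assert len(found) == hits

    def test_template_n_matches_nothing(self):
        template = "CANCATTTTTTTTTTAAAAAAAAAA"
        found = in_silico_pcr(template, "CANCATTTTT", "TTTTTTTTTT", min_primer_len=10)
        assert found == []

    def test_short_primer_rejected_by_default(self):
        with pytest.raises(ValueError):
            in_silico_pcr("A" * 50, "AAAA", "TTTT")

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_agrees_with_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        fwd, rev = "GCRTAYGACG", "CCYTGRTCGG"  # 4-fold degeneracy each
        # plant one concrete site pair so products are common
        concrete_f = "GCATACGACG"
        concrete_r_rc = reverse_complement("CCTTGATCGG")
        template = template[:20] + concrete_f + template[30:120] + concrete_r_rc + template[130:]
        got = [(p.forward_start, p.reverse_end) for p in
               in_silico_pcr(template, fwd, rev, max_products=100)]
        assert sorted(got) == pcr_oracle(template, fwd, rev)


class TestVariantLengthDiff:
    def test_equal(self):
        assert variant_length_diff("ACGTAC", "TTTTTT") == 0

    def test_difference(self):
        assert variant_length_diff("A" * 10, "C" * 17) == 7

    def test_records(self):
        a = SequenceRecord("a", "dna", "ACGT" * 100)
        b = SequenceRecord("b", "dna", "ACGT" * 150)
        assert variant_length_diff(a, b) == 200


class TestSequenceRecord:
    def test_rejects_non_iupac(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "dna", "ACGU")

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "dna", "")

    def test_protein_alphabet(self):
        SequenceRecord("x", "protein", "MKTAYX")  # X tolerated
        with pytest.raises(ValueError):
            SequenceRecord("x", "protein", "MKTA*")
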