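import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import nw_score_oracle, sw_score_oracle
from taxogenomics.align import (
    DNA_SCHEME,
    PROTEIN_SCHEME,
    AlignmentError,
    AlignmentResult,
    ScoringScheme,
    needleman_wunsch,
    percent_identity,
    smith_waterman,
)

SMALL = ScoringScheme(match=5, mismatch=-4, gap_open=10, gap_extend=0.5)
seqs_ac = st.text(alphabet="AC", min_size=1, max_size=6)


class TestSchemeValidation:
    def test_gap_extend_cannot_exceed_open(self):
        with pytest.raises(AlignmentError):
            ScoringScheme(gap_open=1, gap_extend=2)

    def test_match_must_beat_mismatch(self):
        with pytest.raises(AlignmentError):
            ScoringScheme(match=-1, mismatch=0)


class TestNeedlemanWunsch:
    def test_identical_sequences(self):
        r = needleman_wunsch("ACGT", "ACGT", SMALL)
        assert r.identity_percent == 100.0 and r.n_gap_columns == 0
        assert r.score == 20.0

    def test_one_deletion_matches_oracle(self):
        r = needleman_wunsch("ACGT", "ACG", SMALL)
        assert r.score == nw_score_oracle("ACGT", "ACG", SMALL)
        assert (r.aligned_a, r.aligned_b) == ("ACGT", "ACG-")

    def test_all_mismatch(self):
        r = needleman_wunsch("AAAA", "TTTT", SMALL)
        assert r.n_match == 0 and r.identity_percent == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(AlignmentError):
            needleman_wunsch("", "ACGT", SMALL)

    def test_mixed_alphabet_rejected(self):
        with pytest.raises(AlignmentError):
            needleman_wunsch("MKVL", "ACGT", SMALL)

    def test_gap_columns_recover_inputs(self):
        r = needleman_wunsch("ACGTACGT", "ACGCGT", SMALL)
        assert r.aligned_a.replace("-", "") == "ACGTACGT"
        assert r.aligned_b.replace("-", "") == "ACGCGT"
        assert len(r.aligned_a) == len(r.aligned_b)

    def test_n_scores_as_mismatch_even_to_n(self):
        r = needleman_wunsch("NN", "NN", SMALL)
        assert r.score == 2 * SMALL.mismatch
        assert r.n_match == 0  # N==N never counts as identity

    @given(a=seqs_ac, b=seqs_ac)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_equals_enumeration_oracle(self, a, b):
        assert needleman_wunsch(a, b, SMALL).score == pytest.approx(
            nw_score_oracle(a, b, SMALL)
        )

    @given(a=seqs_ac, b=seqs_ac)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_score_symmetry(self, a, b):
        assert needleman_wunsch(a, b, SMALL).score == pytest.approx(
            needleman_wunsch(b, a, SMALL).score
        )

    @given(a=seqs_ac, b=seqs_ac, suffix=st.text(alphabet="AC", min_size=1, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_identical_suffix_never_decreases_score(self, a, b, suffix):
        base = needleman_wunsch(a, b, SMALL).score
        extended = needleman_wunsch(a + suffix, b + suffix, SMALL).score
        assert extended >= base - 1e-9

    @given(a=st.text(alphabet="ACGT", min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_self_alignment_identity_is_100(self, a):
        assert needleman_wunsch(a, a, SMALL).identity_percent == 100.0

    def test_matches_biopython_pairwise_aligner(self):
        # independent implementation cross-check on random nucleotide pairs
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 5
        aligner.mismatch_score = -4
        aligner.open_gap_score = -10.5
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), rng.integers(5, 40)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(5, 40)))
            assert needleman_wunsch(a, b, SMALL).score == pytest.approx(aligner.score(a, b))

    def test_free_end_gaps_do_not_penalize_overhang(self):
        r = needleman_wunsch("AAACGTAAA", "CGT", SMALL, free_end_gaps=True)
        assert r.score == 15.0
        assert r.aligned_b.strip("-") == "CGT"


class TestSmithWaterman:
    def test_identical_equals_global(self):
        r = smith_waterman("ACGTACGT", "ACGTACGT", SMALL)
        g = needleman_wunsch("ACGTACGT", "ACGTACGT", SMALL)
        assert r.score == g.score and r.identity_percent == 100.0

    def test_no_positive_pair_gives_empty_alignment(self):
        r = smith_waterman("AAAA", "TTTT", SMALL)
        assert r.score == 0.0 and r.n_columns == 0

    def test_matches_bruteforce_substring_oracle(self):
        cases = [("ACCA", "CCAA"), ("ACACA", "CACAC"), ("AACC", "CCAA"), ("ACGTA", "TACGT")]
        for a, b in cases:
            assert smith_waterman(a, b, SMALL).score == pytest.approx(sw_score_oracle(a, b, SMALL))

    def test_reports_aligned_region_coordinates(self):
        r = smith_waterman("TTTACGTTTT", "ACG", SMALL)
        assert (r.a_start, r.a_end) == (3, 6)
        assert r.aligned_a == "ACG"

    def test_protein_blosum62_scores_match_biopython(self):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(15):
            a = "".join(rng.choice(aas, rng.integers(10, 50)))
            b = "".join(rng.choice(aas, rng.integers(10, 50)))
            assert smith_waterman(a, b, PROTEIN_SCHEME).score == pytest.approx(aligner.score(a, b))


class TestPercentIdentity:
    def _aln(self, a, b, score=0.0):
        n_gap = sum(1 for x, y in zip(a, b) if "-" in (x, y))
        n_match = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        ident = 100.0 * n_match / len(a)
        return AlignmentResult(a, b, score, n_match, len(a), n_gap, ident)

    def test_modes_disagree_as_expected(self):
        # 8 matches over 10 columns, 2 of which are gap columns
        aln = self._aln("ACGTACGT--", "ACGTACGTAC")
        assert percent_identity(aln, "all_columns") == 80.0
        assert percent_identity(aln, "ungapped_columns") == 100.0

    def test_identical_inputs_100_in_every_mode(self):
        aln = self._aln("ACGT", "ACGT")
        for mode in ("all_columns", "ungapped_columns", "shorter_seq"):
            assert percent_identity(aln, mode) == 100.0

    def test_hand_counted_five_column_alignment(self):
        # A C - G T  vs  A G A G T : matches at columns 1, 4, 5 -> 60%
        aln = self._aln("AC-GT", "AGAGT")
        assert percent_identity(aln, "all_columns") == 60.0

    def test_zero_length_alignment_is_an_error(self):
        empty = AlignmentResult("", "", 0.0, 0, 0, 0, None)
        with pytest.raises(AlignmentError):
            percent_identity(empty)

    def test_unknown_mode_rejected(self):
        aln = self._aln("AC", "AC")
        with pytest.raises(AlignmentError):
            percent_identity(aln, "bogus")
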