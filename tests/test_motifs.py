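"""Motif scanning, reference-coverage alignment, and architecture typing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p25screen.motifs import (
    AlignScoring,
    CoverageClass,
    DEFAULT_REFERENCE,
    DomainArchitecture,
    MotifPattern,
    NTERM,
    ROSSMANN,
    ReferenceDomain,
    TpppType,
    align_to_reference,
    classify_architecture,
    coverage_class,
    scan_motif,
    scan_nucleotide,
    scan_protein,
)
from p25screen.sequence_io import (
    Alphabet,
    AlphabetError,
    SequenceRecord,
    reverse_complement,
)

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=500)


def naive_scan(seq: str, pattern: MotifPattern) -> list[int]:
    """Oracle: sliding-window membership check, 1-based starts."""
    starts = []
    k = len(pattern)
    for i in range(len(seq) - k + 1):
        if all(
            p is None or c in p
            for c, p in zip(seq[i : i + k], pattern.positions)
        ):
            starts.append(i + 1)
    return starts


class TestScanMotif:
    def test_rossmann_example(self):
        hits = scan_motif("MGAGAGKAGRW", ROSSMANN)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].matched) == (2, 10, "GAGAGKAGR")

    def test_tandem_rossmann_two_hits(self):
        assert [h.start for h in scan_motif("GAGAGKAGRGAGAGKAGR", ROSSMANN)] == [1, 10]

    @pytest.mark.parametrize("seq", ["LAAAFAAFAAF", "FAAAFAAYAAF"])
    def test_nterm_alternative_residues(self, seq):
        hits = scan_motif(seq, NTERM)
        assert len(hits) == 1 and hits[0].start == 1

    def test_x_matches_only_any_positions(self):
        # X at a fixed G position kills the match; X at a wildcard does not
        assert scan_motif("XAGAGKAGR", ROSSMANN) == []
        assert len(scan_motif("GXGAGKAGR", ROSSMANN)) == 1

    def test_nucleotide_like_input_rejected(self):
        with pytest.raises(AlphabetError):
            scan_motif("ACGTACGTACGT", ROSSMANN)

    def test_one_mismatch_allowed_when_configured(self):
        assert scan_motif("GAGAGKAGW", ROSSMANN) == []
        assert len(scan_motif("GAGAGKAGW", ROSSMANN, max_mismatch=1)) == 1

    @settings(derandomize=True, max_examples=300)
    @given(proteins)
    def test_equals_naive_sliding_window_oracle(self, seq):
        for pattern in (ROSSMANN, NTERM):
            assert [h.start for h in scan_motif(seq, pattern)] == naive_scan(
                seq, pattern
            )


def sw_oracle(a: str, b: str, match=2.0, mismatch=-1.0, gap=-2.0):
    """Quadratic Smith-Waterman DP oracle: (best score, ref interval 1-based)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    score = H.max()
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    end = int(i)
    # traceback for the ref start of the best path
    while H[i, j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return float(score), (int(i) + 1, end)


class TestAlignToReference:
    def test_identity_covers_whole_reference(self):
        cons = DEFAULT_REFERENCE.consensus
        assert align_to_reference(cons) == [(1, len(cons))]

    def test_prefix_covers_first_half(self):
        cons = DEFAULT_REFERENCE.consensus
        segs = align_to_reference(cons[: len(cons) // 2])
        assert len(segs) == 1
        a, b = segs[0]
        assert a == 1 and abs(b - len(cons) // 2) <= 2

    def test_unrelated_sequence_yields_no_segments(self):
        rng = np.random.default_rng(5)
        junk = "".join(rng.choice(list("DEHIKMNPQSTVW"), size=120))
        assert align_to_reference(junk) == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_to_reference("")

    @pytest.mark.parametrize("lo,hi", [(0, 25), (10, 40), (20, 50)])
    def test_fragment_interval_matches_dp_oracle(self, lo, hi):
        ref = ReferenceDomain(consensus=DEFAULT_REFERENCE.consensus[:50])
        frag = ref.consensus[lo:hi]
        segs = align_to_reference(frag, ref)
        _, (a, b) = sw_oracle(ref.consensus, frag)
        assert segs == [(a, b)] == [(lo + 1, hi)]

    @settings(derandomize=True, max_examples=50)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=50),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=50),
    )
    def test_alignment_score_matches_dp_oracle(self, a, b):
        from Bio import Align

        sc = AlignScoring()
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = sc.match
        aligner.mismatch_score = sc.mismatch
        aligner.open_gap_score = sc.gap
        aligner.extend_gap_score = sc.gap
        expected, _ = sw_oracle(a, b)
        got = aligner.align(a, b).score if expected > 0 else 0.0
        assert got == pytest.approx(expected)


class TestCoverageClass:
    @pytest.mark.parametrize(
        "segments,expected",
        [
            ([(1, 160)], CoverageClass.full),
            ([(121, 160)], CoverageClass.cterm_only),
            ([(1, 100)], CoverageClass.cterm_missing),
            ([(1, 130)], CoverageClass.cterm_partial),
            ([], CoverageClass.none),
            ([(1, 20)], CoverageClass.none),
        ],
    )
    def test_examples(self, segments, expected):
        assert coverage_class(segments, DEFAULT_REFERENCE) == expected


ARCH_CASES = [
    # (nterm, n_rossmann, dcx, coverage, expected)
    (True, 2, False, CoverageClass.full, TpppType.fungal_type),
    (False, 0, True, CoverageClass.cterm_only, TpppType.apicortin),
    (True, 0, False, CoverageClass.cterm_missing, TpppType.truncated),
    (True, 0, False, CoverageClass.cterm_partial, TpppType.short),
    (True, 1, False, CoverageClass.full, TpppType.long),
    (False, 0, False, CoverageClass.none, TpppType.none),
    (True, 1, False, CoverageClass.cterm_only, TpppType.ambiguous),
    # DCX + C-terminal fragment wins even with a Rossmann inside the fragment
    (False, 1, True, CoverageClass.cterm_only, TpppType.apicortin),
]


class TestClassifyArchitecture:
    @pytest.mark.parametrize("nterm,nross,dcx,cov,expected", ARCH_CASES)
    def test_decision_list(self, nterm, nross, dcx, cov, expected):
        arch = DomainArchitecture(
            has_nterm_motif=nterm, n_rossmann=nross, coverage_class=cov, has_dcx=dcx
        )
        assert classify_architecture(arch) == expected

    def test_total_over_evidence_space(self):
        for nterm in (False, True):
            for nross in (0, 1, 2, 3):
                for dcx in (False, True):
                    for cov in CoverageClass:
                        arch = DomainArchitecture(nterm, nross, cov, dcx)
                        assert classify_architecture(arch) in TpppType


def back_translate_simple(protein: str) -> str:
    """Fixed-codon back-translation for strand-symmetry fixtures."""
    from p25screen.synth import _codons_by_aa

    return "".join(_codons_by_aa()[aa][0] for aa in protein)


class TestScanNucleotide:
    def test_planted_motif_found_in_frame_plus_one(self):
        nt = back_translate_simple("GAGAGKAGR")
        rec = SequenceRecord("r", nt, Alphabet.nucleotide)
        res = scan_nucleotide(rec)
        ross = [h for h in res.hits if h.pattern_name == "rossmann"]
        assert len(ross) == 1 and ross[0].frame == 1

    def test_reverse_complement_finds_same_hit_negative_frame(self):
        nt = reverse_complement(back_translate_simple("GAGAGKAGR"))
        res = scan_nucleotide(SequenceRecord("r", nt, Alphabet.nucleotide))
        ross = [h for h in res.hits if h.pattern_name == "rossmann"]
        assert len(ross) == 1 and ross[0].frame == -1

    def test_protein_record_rejected(self):
        rec = SequenceRecord("r", "MKLVF", Alphabet.protein)
        with pytest.raises(AlphabetError):
            scan_nucleotide(rec)

    def test_strand_symmetry_of_architecture(self):
        from p25screen.synth import gen_tppp_protein
        import p25screen.synth as synth

        rng = np.random.default_rng(3)
        prot, _ = gen_tppp_protein(TpppType.long, 340, 3)
        nt = synth.back_translate(prot.residues, rng)
        fwd = scan_nucleotide(SequenceRecord("f", nt, Alphabet.nucleotide))
        rev = scan_nucleotide(
            SequenceRecord("f", reverse_complement(nt), Alphabet.nucleotide)
        )
        assert fwd.tppp_type == rev.tppp_type == TpppType.long
        assert fwd.architecture.frame == -rev.architecture.frame

    def test_random_nucleotide_matches_brute_force_frame_scan(self):
        """Architecture equals the best over an explicit all-frame scan."""
        from p25screen.sequence_io import six_frame_translate

        for seed in range(40):
            rng = np.random.default_rng(seed)
            nt = "".join(rng.choice(list("ACGT"), size=600))
            rec = SequenceRecord("r", nt, Alphabet.nucleotide)
            res = scan_nucleotide(rec)
            # oracle: scan every frame independently, pick max evidence
            best = None
            for ft in six_frame_translate(rec):
                fr = scan_protein(ft.peptide, "r", frame=ft.frame)
                from p25screen.motifs import covered_fraction

                ev = len(fr.hits) + covered_fraction(
                    list(fr.segments), len(DEFAULT_REFERENCE)
                )
                key = (-ev, abs(ft.frame), 0 if ft.frame > 0 else 1)
                if best is None or key < best[0]:
                    best = (key, fr)
            assert res.tppp_type == best[1].tppp_type
            assert res.architecture == best[1].architecture
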