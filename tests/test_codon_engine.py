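"""Codon engine: reverse complement, frame estimation, codon calls."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import GENETIC_CODE, naive_stop_counts
from snpannot import codon_engine
from snpannot.fixtures import _random_orf
from snpannot.models import CodingContext, GtfFeature, SnpQuery, TranscriptModel

BASES = "ACGT"


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("CCT", "AGG"), ("N", "N"), ("RY", "RY"), ("", "")],
    )
    def test_known_values(self, seq, expected):
        assert codon_engine.reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACGTN", max_size=1000))
    def test_involution(self, seq):
        rc = codon_engine.reverse_complement
        assert rc(rc(seq)) == seq

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            codon_engine.reverse_complement("AC!T")


def ctx(seq, offset=0, strand="+"):
    return CodingContext(sequence=seq, snp_offset=offset, strand=strand)


class TestEstimateFrame:
    def test_clean_orf_frame_zero(self):
        est = codon_engine.estimate_frame(ctx("ATGAAACCCGGGTTTTAA"))
        assert (est.frame, est.stop_count, est.source) == (0, 0, "estimated")

    def test_annotated_frame_takes_precedence(self):
        est = codon_engine.estimate_frame(ctx("ATGAAACCCGGGTTTTAA"), annotated_frame=2)
        assert (est.frame, est.source) == (2, "annotated")

    def test_terminal_stop_not_counted_against_true_frame(self):
        # TAA internal in frame 1 counts; the flush terminal TAA does not.
        est = codon_engine.estimate_frame(ctx("ATGTAA"))
        assert (est.frame, est.stop_count) == (0, 0)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="frame"):
            codon_engine.estimate_frame(ctx("AT", offset=0))

    def test_matches_naive_per_frame_scan(self):
        rng = random.Random(21)
        for _ in range(200):
            seq = "".join(rng.choice(BASES) for _ in range(300))
            est = codon_engine.estimate_frame(ctx(seq))
            counts = naive_stop_counts(seq)
            assert est.frame == min(range(3), key=lambda f: (counts[f], f))
            assert est.stop_count == counts[est.frame]

    @pytest.mark.parametrize("true_frame", [0, 1, 2])
    def test_recovers_planted_frame(self, true_frame):
        """ORFs with clean true frames and stops in both wrong frames are
        recovered exactly, with zero internal stops in the chosen frame."""
        rng = random.Random(40 + true_frame)
        for _ in range(40):
            orf = _random_orf(rng, rng.randint(25, 70))
            prefix = "".join(rng.choice(BASES) for _ in range(true_frame))
            est = codon_engine.estimate_frame(ctx(prefix + orf))
            assert (est.frame, est.stop_count) == (true_frame, 0)


class TestExtractCodon:
    def test_middle_position_nonsynonymous(self):
        # codon CCT, SNP at its second position, mutation C->G: Pro -> Arg
        call = codon_engine.extract_codon(
            ctx("ATGCCTTAA", offset=4),
            codon_engine.estimate_frame(ctx("ATGCCTTAA"), annotated_frame=0),
            "C",
            "G",
        )
        assert call.codon_display == "C[C/G]T"
        assert (call.ref_aa, call.mut_aa) == ("P", "R")
        assert call.synonymous is False
        assert call.codon_position == 2

    def test_third_position_wobble_synonymous(self):
        call = codon_engine.extract_codon(
            ctx("GGA", offset=2),
            codon_engine.estimate_frame(ctx("GGA"), annotated_frame=0),
            "A",
            "G",
        )
        assert call.codon_display == "GG[A/G]"
        assert call.synonymous is True

    def test_reference_mismatch_warns_but_annotates(self):
        call = codon_engine.extract_codon(
            ctx("GGA", offset=2),
            codon_engine.estimate_frame(ctx("GGA"), annotated_frame=0),
            "T",  # sequence says A
            "G",
        )
        assert call.synonymous is True
        assert any("does not match" in m for m in call.messages)

    def test_ambiguous_codon_gives_na(self):
        call = codon_engine.extract_codon(
            ctx("GNA", offset=2),
            codon_engine.FrameEstimate(frame=0, stop_count=0, source="annotated"),
            "A",
            "G",
        )
        assert call.ref_aa is None and call.synonymous is None

    def test_exhaustive_576_substitutions_match_codon_table(self):
        """All 64 codons x 3 positions x 3 alternate bases: synonymy equals
        translation equality in the hand-frozen code, and the display string
        regenerates both codons exactly."""
        frames = codon_engine.FrameEstimate(frame=0, stop_count=0, source="annotated")
        n = 0
        for codon in GENETIC_CODE:
            for pos in (1, 2, 3):
                ref_base = codon[pos - 1]
                for alt in BASES:
                    if alt == ref_base:
                        continue
                    call = codon_engine.extract_codon(
                        ctx(codon, offset=pos - 1), frames, ref_base, alt
                    )
                    mut_codon = codon[: pos - 1] + alt + codon[pos:]
                    assert call.codon_position == pos
                    assert call.synonymous is (
                        GENETIC_CODE[codon] == GENETIC_CODE[mut_codon]
                    )
                    assert (call.ref_aa, call.mut_aa) == (
                        GENETIC_CODE[codon],
                        GENETIC_CODE[mut_codon],
                    )
                    # display regenerates both codons
                    left, bracket = call.codon_display.split("[")
                    inside, right = bracket.split("]")
                    r, m = inside.split("/")
                    assert left + r + right == codon
                    assert left + m + right == mut_codon
                    n += 1
        assert n == 576


class TestBuildCodingContext:
    def _model(self, segments, strand="+"):
        feats = [
            GtfFeature(
                chrom="c",
                source="s",
                feature_type="CDS",
                start=s,
                end=e,
                strand=strand,
                frame=None,
                transcript_id="T",
            )
            for s, e in segments
        ]
        return TranscriptModel(
            transcript_id="T", strand=strand, cds_segments=feats, total_exon_count=len(feats)
        )

    def test_plus_strand_slice(self):
        chrom = "XXXXXXXXXXATGCCTTAAX".replace("X", "G")
        got = codon_engine.build_coding_context(
            self._model([(11, 19)]), chrom, SnpQuery("c", 14, "C", "G")
        )
        assert (got.sequence, got.snp_offset) == ("ATGCCTTAA", 3)

    def test_minus_strand_reverse_complements_and_remaps_offset(self):
        chrom = "GGGGGGGGGGATGCCTTAAG"
        got = codon_engine.build_coding_context(
            self._model([(11, 19)], strand="-"), chrom, SnpQuery("c", 14, "C", "G")
        )
        assert (got.sequence, got.snp_offset) == ("TTAAGGCAT", 5)

    def test_junction_codon_assembles_across_segments(self):
        # spliced CDS ATG CCT TAA split as ATGC | CTTAA: codon 2 straddles
        chrom = "ATGC" + "TTTTT" + "CTTAA"
        model = self._model([(1, 4), (10, 14)])
        got = codon_engine.build_coding_context(model, chrom, SnpQuery("c", 10, "C", "G"))
        assert got.sequence == "ATGCCTTAA"
        assert got.snp_offset == 4
        frame = codon_engine.estimate_frame(got, annotated_frame=0)
        call = codon_engine.extract_codon(got, frame, "C", "G")
        assert call.codon_display == "C[C/G]T"
        assert (call.ref_aa, call.mut_aa) == ("P", "R")

    def test_out_of_range_segment_raises_sequence_mismatch(self):
        with pytest.raises(codon_engine.SequenceMismatch):
            codon_engine.build_coding_context(
                self._model([(11, 50)]), "A" * 20, SnpQuery("c", 14, "", "G")
            )

    def test_snp_outside_cds_raises(self):
        with pytest.raises(ValueError, match="not inside"):
            codon_engine.build_coding_context(
                self._model([(11, 19)]), "A" * 20, SnpQuery("c", 5, "", "G")
            )

    def test_consistent_phases_yield_zero_offset(self):
        """GTF phases written the standard way reduce to a frame-0 offset
        on the spliced CDS, for either strand."""
        for strand in "+-":
            segs = [(1, 4), (10, 14)]
            feats = []
            lengths = [4, 5]
            order = [0, 1] if strand == "+" else [1, 0]
            cum = 0
            phases = {}
            for gi in order:
                phases[gi] = (3 - (cum % 3)) % 3
                cum += lengths[gi]
            for gi, (s, e) in enumerate(segs):
                feats.append(
                    GtfFeature(
                        chrom="c",
                        source="s",
                        feature_type="CDS",
                        start=s,
                        end=e,
                        strand=strand,
                        frame=phases[gi],
                        transcript_id="T",
                    )
                )
            model = TranscriptModel(
                transcript_id="T", strand=strand, cds_segments=feats, total_exon_count=2
            )
            for f in feats:
                assert codon_engine.effective_frame_offset(model, f) == 0
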