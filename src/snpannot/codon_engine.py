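"""Strand-aware codon-level consequence calling.

Given a transcript's spliced CDS (segments concatenated in transcription
order, reverse-complemented for minus-strand transcripts), this module
estimates the reading frame when the annotation does not provide one —
using the number of stop codons in each candidate frame as a proxy, the
frame with the fewest internal stops being the most plausible open reading
frame — then extracts the codon containing a SNP, translates reference and
mutant codons with the standard nuclear genetic code, and calls synonymy.

Codons that straddle exon junctions are handled naturally because all
arithmetic happens on the spliced sequence, never on a single feature's
raw genomic slice.
"""

from __future__ import annotations

from typing import Optional

from Bio.Data import IUPACData
from Bio.Seq import Seq

from .models import (
    CodingContext,
    CodonCall,
    FrameEstimate,
    GtfFeature,
    SnpQuery,
    TranscriptModel,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans(
    IUPACData.ambiguous_dna_complement
    | {k.lower(): v.lower() for k, v in IUPACData.ambiguous_dna_complement.items()}
)
_VALID_CHARS = frozenset(IUPACData.ambiguous_dna_letters + IUPACData.ambiguous_dna_letters.lower())


class SequenceMismatch(Exception):
    """CDS coordinates fall outside the available chromosome sequence."""


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support (N -> N, R -> Y ...).

    Raises ValueError naming the offending position for any character that
    is not a nucleotide code.
    """
    for i, ch in enumerate(seq):
        if ch not in _VALID_CHARS:
            raise ValueError(f"non-nucleotide character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    if base not in _VALID_CHARS:
        raise ValueError(f"non-nucleotide character {base!r}")
    return base.translate(_COMPLEMENT)


def count_stop_codons(sequence: str, frame: int) -> int:
    """Stop codons among the complete codons of ``sequence`` read at offset
    ``frame``, excluding a stop codon that terminates the sequence exactly.

    A correct CDS ends in a stop codon; counting that terminal stop would
    penalise the true frame, so only internal stops count.
    """
    n = 0
    for i in range(frame, len(sequence) - 2, 3):
        # a stop flush with the sequence end is the normal end of a CDS,
        # not evidence against the frame
        if sequence[i : i + 3].upper() in STOP_CODONS and i + 3 != len(sequence):
            n += 1
    return n


def estimate_frame(
    ctx: CodingContext, annotated_frame: Optional[int] = None
) -> FrameEstimate:
    """Determine the reading frame in force for a coding context.

    When the annotation supplies a frame it takes precedence (source
    ``"annotated"``) and the stop count is computed in that frame. Otherwise
    internal stop codons are counted at each of the three offsets and the
    frame with the fewest wins, ties broken by the smallest offset.
    """
    if len(ctx.sequence) < 3:
        raise ValueError("spliced CDS shorter than one codon; frame undecidable")
    if annotated_frame is not None:
        return FrameEstimate(
            frame=annotated_frame,
            stop_count=count_stop_codons(ctx.sequence, annotated_frame),
            source="annotated",
        )
    counts = [count_stop_codons(ctx.sequence, f) for f in (0, 1, 2)]
    best = min(range(3), key=lambda f: (counts[f], f))
    return FrameEstimate(frame=best, stop_count=counts[best], source="estimated")


def _translate_codon(codon: str) -> Optional[str]:
    """Single-letter amino acid ('*' for stop), or None when the codon
    contains ambiguity codes and the residue cannot be determined."""
    if len(codon) != 3 or any(b not in "ACGT" for b in codon.upper()):
        return None
    return str(Seq(codon.upper()).translate())


def extract_codon(
    ctx: CodingContext,
    frame: FrameEstimate,
    ref_allele: str,
    alt_allele: str,
) -> CodonCall:
    """Codon display, codon position, amino acids and synonymy for a SNP.

    ``ref_allele``/``alt_allele`` must already be oriented to the spliced
    sequence (i.e. complemented for minus-strand transcripts); ``ref_allele``
    may be empty when the query did not supply one. The reference base is
    always taken from the sequence itself; a supplied reference allele that
    disagrees is annotated anyway with a mismatch message.
    """
    messages: list[str] = []
    offset = ctx.snp_offset
    codon_start = offset - ((offset - frame.frame) % 3)
    codon_position = (offset - frame.frame) % 3 + 1
    if codon_start < 0 or codon_start + 3 > len(ctx.sequence):
        return CodonCall(
            codon_display="NA",
            codon_position=codon_position,
            ref_aa=None,
            mut_aa=None,
            synonymous=None,
            messages=("SNP falls in an incomplete terminal codon",),
        )
    ref_codon = ctx.sequence[codon_start : codon_start + 3].upper()
    seq_ref_base = ref_codon[codon_position - 1]
    if ref_allele and ref_allele.upper() != seq_ref_base:
        messages.append(
            f"supplied reference allele {ref_allele.upper()} does not match "
            f"sequence base {seq_ref_base}"
        )
    alt = alt_allele.upper()
    mut_codon = (
        ref_codon[: codon_position - 1] + alt + ref_codon[codon_position:]
    )
    display = (
        ref_codon[: codon_position - 1]
        + f"[{seq_ref_base}/{alt}]"
        + ref_codon[codon_position:]
    )
    ref_aa = _translate_codon(ref_codon)
    mut_aa = _translate_codon(mut_codon)
    if ref_aa is None or mut_aa is None:
        messages.append("codon contains ambiguous bases; amino acid undetermined")
        synonymous = None
    else:
        synonymous = ref_aa == mut_aa
    return CodonCall(
        codon_display=display,
        codon_position=codon_position,
        ref_aa=ref_aa,
        mut_aa=mut_aa,
        synonymous=synonymous,
        messages=tuple(messages),
    )


def build_coding_context(
    model: TranscriptModel, chrom_seq: str, snp: SnpQuery
) -> CodingContext:
    """Splice a transcript's CDS out of the chromosome and locate the SNP.

    Segments are sliced in genomic order and concatenated; for minus-strand
    transcripts the concatenation is reverse-complemented and the SNP offset
    recomputed from the 3' genomic side, so the returned sequence always
    reads in the direction of translation. An unknown strand is treated as
    plus.

    Raises SequenceMismatch when a CDS segment extends beyond the available
    sequence, and ValueError when the SNP is in none of the CDS segments.
    """
    if not model.cds_segments:
        raise ValueError(f"transcript {model.transcript_id} has no CDS segments")
    pieces: list[str] = []
    plus_offset: Optional[int] = None
    consumed = 0
    for seg in model.cds_segments:  # genomic order
        if seg.end > len(chrom_seq) or seg.start < 1:
            raise SequenceMismatch(
                f"CDS segment {seg.start}-{seg.end} of {model.transcript_id} "
                f"exceeds sequence length {len(chrom_seq)}"
            )
        pieces.append(chrom_seq[seg.start - 1 : seg.end])
        if seg.contains(snp.pos):
            plus_offset = consumed + (snp.pos - seg.start)
        consumed += seg.end - seg.start + 1
    if plus_offset is None:
        raise ValueError(
            f"SNP {snp.chrom}:{snp.pos} not inside any CDS segment of "
            f"{model.transcript_id}"
        )
    spliced_plus = "".join(pieces)
    if model.strand == "-":
        return CodingContext(
            sequence=reverse_complement(spliced_plus),
            snp_offset=len(spliced_plus) - 1 - plus_offset,
            strand="-",
        )
    return CodingContext(sequence=spliced_plus, snp_offset=plus_offset, strand="+")


def effective_frame_offset(model: TranscriptModel, feature: GtfFeature) -> Optional[int]:
    """Convert a CDS segment's annotated GTF frame (phase) into an offset
    into the transcript's spliced, translation-oriented CDS.

    GTF frame counts bases to skip at the segment's transcription-order
    start before the first complete codon; adding the cumulative spliced
    length preceding the segment and reducing mod 3 yields the global
    frame offset. Returns None when the feature carries no frame.
    """
    if feature.frame is None:
        return None
    segments = model.cds_segments
    if model.strand == "-":
        segments = list(reversed(segments))  # transcription order
    cum = 0
    for seg in segments:
        if seg.start == feature.start and seg.end == feature.end:
            return (cum + feature.frame) % 3
        cum += seg.end - seg.start + 1
    # Feature not one of the model's segments: fall back to its raw phase.
    return feature.frame % 3
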