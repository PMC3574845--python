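"""Core domain types shared across the annotation pipeline.

Coordinates are 1-based inclusive throughout (the native convention of both
GTF and VCF), so no half-open conversion ever appears at module boundaries.
Missing or inapplicable values are ``None`` in memory and rendered as the
literal string ``NA`` on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Sentinel string used for every inapplicable/unknown output field.
NA = "NA"

#: Feature types treated as exonic when they contain a SNP.
EXONIC_FEATURE_TYPES = frozenset({"CDS", "exon", "start_codon", "stop_codon"})


def is_exonic_feature_type(feature_type: str) -> bool:
    """True for feature types whose containment makes a SNP exonic.

    UTR rows come in several GTF dialects (``UTR``, ``five_prime_utr``,
    ``3UTR`` ...); any type mentioning UTR counts as exonic.
    """
    return feature_type in EXONIC_FEATURE_TYPES or "utr" in feature_type.lower()


def is_intron_feature_type(feature_type: str) -> bool:
    return "intron" in feature_type.lower()


@dataclass(frozen=True)
class SnpQuery:
    """One queried variant: a single-base substitution at a genomic position.

    ``ref_allele`` may be empty when the input dialect supplies only the
    mutation; ``alt_allele`` is always the mutant base on the plus strand.
    """

    chrom: str
    pos: int
    ref_allele: str  # "" when unknown
    alt_allele: str
    source_line: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError("SNP chromosome identifier must be non-empty")
        if self.alt_allele not in {"A", "C", "G", "T"}:
            raise ValueError(f"alt allele must be one of A/C/G/T, got {self.alt_allele!r}")


@dataclass(frozen=True)
class GtfFeature:
    """One GTF annotation row (1-based inclusive interval)."""

    chrom: str
    source: str
    feature_type: str
    start: int
    end: int
    strand: str  # "+", "-", or "" for unknown
    frame: Optional[int]  # 0/1/2 or None for unknown
    gene_id: str = ""
    gene_name: str = ""
    transcript_id: str = ""
    transcript_name: str = ""
    protein_id: str = ""
    exon_number: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature start {self.start} exceeds end {self.end} ({self.feature_type})"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def boundary_distance(self, pos: int) -> int:
        """Distance in bp from ``pos`` to the nearer feature boundary.

        Zero when the position lies inside the feature.
        """
        if self.contains(pos):
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


class CrossRefTable:
    """Position-keyed lookup of known-SNP rs identifiers.

    Lookup of an absent key returns ``None`` (rendered NA), never an error.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, int], str] = {}

    def add(self, chrom: str, pos: int, rs_id: str) -> bool:
        """Insert one entry; first entry wins on duplicate keys.

        Returns False when the key was already present (caller logs a warning).
        """
        key = (chrom, pos)
        if key in self._entries:
            return False
        self._entries[key] = rs_id
        return True

    def lookup(self, chrom: str, pos: int) -> Optional[str]:
        return self._entries.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._entries)


@dataclass
class TranscriptModel:
    """Ordered CDS/exon structure of one transcript on one chromosome.

    Segments are kept in genomic order (ascending start); transcription
    order for minus-strand transcripts is the reverse.
    """

    transcript_id: str
    gene_id: str = ""
    strand: str = ""
    cds_segments: list[GtfFeature] = field(default_factory=list)
    exon_segments: list[GtfFeature] = field(default_factory=list)
    total_exon_count: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def extent(self) -> tuple[int, int]:
        """Genomic span (min start, max end) over all CDS and exon segments."""
        segs = self.cds_segments + self.exon_segments
        return min(f.start for f in segs), max(f.end for f in segs)

    def contains_in_extent(self, pos: int) -> bool:
        segs = self.cds_segments + self.exon_segments
        if not segs:
            return False
        lo, hi = self.extent
        return lo <= pos <= hi

    def cds_segment_containing(self, pos: int) -> Optional[GtfFeature]:
        for seg in self.cds_segments:
            if seg.contains(pos):
                return seg
        return None


@dataclass(frozen=True)
class NearestHit:
    """A feature attaining the minimum boundary distance to a query position."""

    feature: GtfFeature
    distance: int  # bp, always >= 1; containment is never a nearest hit
    side: str  # "upstream" (feature at lower coordinates) or "downstream"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("nearest-hit distance must be >= 1")


@dataclass(frozen=True)
class CodingContext:
    """Spliced CDS of a transcript, oriented in the direction of translation.

    ``sequence`` concatenates the CDS segments in transcription order
    (reverse-complemented for minus-strand transcripts); ``snp_offset`` is
    the 0-based position of the queried SNP inside that sequence.
    """

    sequence: str
    snp_offset: int
    strand: str  # "+" or "-" after unknown->"+" defaulting

    def __post_init__(self) -> None:
        if not 0 <= self.snp_offset < len(self.sequence):
            raise ValueError(
                f"snp_offset {self.snp_offset} outside spliced sequence of "
                f"length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class FrameEstimate:
    """A reading frame in force for codon extraction.

    ``frame`` is the 0-based offset into the spliced CDS at which codons
    begin. ``source`` records whether it came from the annotation or was
    estimated by stop-codon counting; when estimated, ``stop_count`` is the
    minimum over the three candidate frames.
    """

    frame: int  # 0, 1 or 2
    stop_count: int
    source: str  # "annotated" or "estimated"
    annotated_frame_field: Optional[int] = None  # verbatim GTF frame, for display


@dataclass(frozen=True)
class CodonCall:
    """Codon-level consequence of a single-base substitution."""

    codon_display: str  # e.g. "C[C/G]T"
    codon_position: int  # 1, 2 or 3
    ref_aa: Optional[str]  # single letter, "*" for stop, None when undecidable
    mut_aa: Optional[str]
    synonymous: Optional[bool]  # None when either amino acid is unknown
    messages: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegionCall:
    """Region classification of one SNP."""

    region: str  # "Exonic", "Intronic" or "Intergenic"
    in_feature_flag: str  # "Y" or "N"


# Order and names of the 25 output columns.
COLUMN_NAMES = (
    "chromosome",
    "position",
    "in_feature",
    "region",
    "distance_to_feature",
    "feature",
    "n_features",
    "feature_annotation",
    "feature_start",
    "feature_end",
    "gene_id",
    "gene_name",
    "transcript_id",
    "transcript_name",
    "exon",
    "strand",
    "annotated_frame",
    "estimated_frame",
    "stop_codons",
    "codon",
    "amino_acid",
    "synonymous",
    "protein_id",
    "rs_id",
    "messages",
)


@dataclass
class AnnotationRow:
    """One 25-field output record.

    Columns 1-2 echo the query verbatim; every inapplicable field renders
    as the literal ``NA``.
    """

    chrom: str
    pos: int
    in_feature: str = "N"  # col 3: Y/N
    region: str = NA  # col 4
    distance: Optional[int] = None  # col 5
    feature: str = NA  # col 6
    n_features: Optional[int] = None  # col 7
    feature_annotation: str = NA  # col 8: "[i/n]"
    feature_start: Optional[int] = None  # col 9
    feature_end: Optional[int] = None  # col 10
    gene_id: str = NA  # col 11
    gene_name: str = NA  # col 12
    transcript_id: str = NA  # col 13
    transcript_name: str = NA  # col 14
    exon: str = NA  # col 15: "[e/total]"
    strand: str = NA  # col 16
    annotated_frame: Optional[int] = None  # col 17
    estimated_frame: Optional[int] = None  # col 18
    stop_codons: Optional[int] = None  # col 19
    codon: str = NA  # col 20: e.g. "C[C/G]T"
    amino_acid: str = NA  # col 21: e.g. "[P/R]"
    synonymous: str = NA  # col 22: Y/N/NA
    protein_id: str = NA  # col 23
    rs_id: str = NA  # col 24
    messages: str = NA  # col 25

    def to_fields(self) -> list[str]:
        """Render the row as exactly 25 string fields."""

        def s(value) -> str:
            if value is None or value == "":
                return NA
            return str(value)

        fields = [
            s(self.chrom),
            s(self.pos),
            s(self.in_feature),
            s(self.region),
            s(self.distance),
            s(self.feature),
            s(self.n_features),
            s(self.feature_annotation),
            s(self.feature_start),
            s(self.feature_end),
            s(self.gene_id),
            s(self.gene_name),
            s(self.transcript_id),
            s(self.transcript_name),
            s(self.exon),
            s(self.strand),
            s(self.annotated_frame),
            s(self.estimated_frame),
            s(self.stop_codons),
            s(self.codon),
            s(self.amino_acid),
            s(self.synonymous),
            s(self.protein_id),
            s(self.rs_id),
            s(self.messages),
        ]
        assert len(fields) == 25
        return fields
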