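"""Readers and writers for the pipeline's external formats.

Input side: SNP query lists (VCF or tab-delimited), GTF annotations,
FASTA reference sequences and dbSNP-style cross-reference tables.
Output side: the 25-column tab-delimited annotation report.

All genomic coordinates are 1-based inclusive, matching GTF and VCF.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO
from cyvcf2 import VCF

from .models import NA, COLUMN_NAMES, AnnotationRow, CrossRefTable, GtfFeature, SnpQuery

PathLike = Union[str, Path]

VALID_BASES = frozenset("ACGT")


class FormatError(Exception):
    """Fatal input-format problem (unreadable file, unparseable structure)."""


@dataclass(frozen=True)
class LineWarning:
    """A non-fatal problem tied to one input line."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


# ---------------------------------------------------------------------------
# SNP query lists
# ---------------------------------------------------------------------------

def _parse_mutation_field(raw: str) -> tuple[str, str]:
    """Split a mutation field into (ref, alt).

    Accepts a single base ("G" -> unknown ref) or a slash pair ("C/G" ->
    ref C, alt G).
    """
    token = raw.strip().upper()
    if "/" in token:
        parts = token.split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse mutation field {raw!r}")
        return parts[0], parts[1]
    return "", token


def _read_snps_tab(path: PathLike) -> tuple[list[SnpQuery], list[LineWarning]]:
    snps: list[SnpQuery] = []
    warnings: list[LineWarning] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.append(LineWarning(line_no, "expected >= 3 tab-delimited fields"))
                continue
            chrom = fields[0].strip()
            if not chrom:
                warnings.append(LineWarning(line_no, "empty chromosome identifier"))
                continue
            if not fields[1].strip().lstrip("+-").isdigit():
                warnings.append(
                    LineWarning(line_no, f"non-numeric SNP location {fields[1]!r}")
                )
                continue
            pos = int(fields[1])
            if pos < 1:
                warnings.append(LineWarning(line_no, f"SNP location {pos} is < 1"))
                continue
            try:
                ref, alt = _parse_mutation_field(fields[2])
            except ValueError as exc:
                warnings.append(LineWarning(line_no, str(exc)))
                continue
            # An optional 4th column supplies the reference allele explicitly.
            if len(fields) >= 4 and fields[3].strip():
                ref = fields[3].strip().upper()
            if alt not in VALID_BASES:
                warnings.append(
                    LineWarning(line_no, f"mutation {alt!r} is not a single A/C/G/T base")
                )
                continue
            if ref and ref not in VALID_BASES:
                warnings.append(
                    LineWarning(line_no, f"reference allele {ref!r} ignored (not A/C/G/T)")
                )
                ref = ""
            snps.append(SnpQuery(chrom, pos, ref, alt, source_line=line_no))
    return snps, warnings


def _read_snps_vcf(path: PathLike) -> tuple[list[SnpQuery], list[LineWarning]]:
    snps: list[SnpQuery] = []
    warnings: list[LineWarning] = []
    try:
        reader = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise FormatError(f"cannot open VCF file {path}: {exc}") from exc
    for record_no, variant in enumerate(reader, start=1):
        ref = (variant.REF or "").upper()
        alts = [a.upper() for a in (variant.ALT or [])]
        if not alts:
            warnings.append(LineWarning(record_no, "VCF record without ALT allele"))
            continue
        for alt in alts:
            if len(ref) != 1 or len(alt) != 1 or alt not in VALID_BASES:
                warnings.append(
                    LineWarning(
                        record_no,
                        f"record {variant.CHROM}:{variant.POS} {ref}>{alt} "
                        "is not a single-base substitution; skipped",
                    )
                )
                continue
            snps.append(
                SnpQuery(
                    variant.CHROM,
                    variant.POS,
                    ref if ref in VALID_BASES else "",
                    alt,
                    source_line=record_no,
                )
            )
    return snps, warnings


def read_snps(
    path: PathLike, format: str = "auto"
) -> tuple[list[SnpQuery], list[LineWarning]]:
    """Read a SNP query file.

    Parameters
    ----------
    path:
        Input file, either a VCF (sites fields only; genotypes ignored) or a
        tab-delimited list of ``chrom<TAB>position<TAB>mutation`` with an
        optional 4th reference-allele column. The mutation field accepts a
        single base or a ``ref/alt`` slash pair.
    format:
        ``"vcf"``, ``"tab"``, or ``"auto"`` (by file extension).

    Returns the queries in input order plus per-line warnings; malformed
    lines warn rather than abort, a VCF record with k alternate alleles
    expands to k queries, and indel records are skipped with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"SNP input file not found: {path}")
    if format == "auto":
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf"} else "tab"
    if format == "vcf":
        return _read_snps_vcf(path)
    if format == "tab":
        return _read_snps_tab(path)
    raise FormatError(f"unrecognized SNP input format {format!r} (use 'vcf' or 'tab')")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;?')

_CAPTURED_ATTRS = (
    "gene_id",
    "gene_name",
    "transcript_id",
    "transcript_name",
    "protein_id",
)


def parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    """Parse the GTF 9th field's ``key "value";`` pairs into a dict."""
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: PathLike) -> dict[str, list[GtfFeature]]:
    """Read a GTF annotation into per-chromosome feature lists.

    Comment lines are skipped; ``.`` strand and frame map to unknown; the
    gene/transcript/protein identifier attributes and ``exon_number`` are
    captured when present. A non-comment line with fewer than 8 tab
    fields is a fatal parse error naming the line number.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"GTF file not found: {path}")
    by_chrom: dict[str, list[GtfFeature]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"{path}: line {line_no} has {len(fields)} tab-delimited "
                    "fields; a GTF line needs at least 8"
                )
            chrom, source, feature_type, start_s, end_s, _score, strand, frame_s = fields[:8]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {line_no}: non-numeric coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            attrs = parse_gtf_attributes(fields[8]) if len(fields) > 8 else {}
            exon_number: Optional[int] = None
            if attrs.get("exon_number", "").isdigit():
                exon_number = int(attrs["exon_number"])
            feature = GtfFeature(
                chrom=chrom,
                source=source,
                feature_type=feature_type,
                start=start,
                end=end,
                strand=strand if strand in {"+", "-"} else "",
                frame=int(frame_s) if frame_s in {"0", "1", "2"} else None,
                gene_id=attrs.get("gene_id", ""),
                gene_name=attrs.get("gene_name", ""),
                transcript_id=attrs.get("transcript_id", ""),
                transcript_name=attrs.get("transcript_name", ""),
                protein_id=attrs.get("protein_id", ""),
                exon_number=exon_number,
            )
            by_chrom.setdefault(chrom, []).append(feature)
    return by_chrom


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def stream_fasta(
    path: PathLike, wanted: Optional[set[str]] = None
) -> Iterator[tuple[str, str]]:
    """Stream a FASTA file one chromosome at a time.

    Yields ``(chrom, sequence)`` with the sequence upper-cased, for records
    whose first header token is in ``wanted`` (all records when ``wanted``
    is None). Records are materialised one at a time, so peak memory is
    proportional to the longest single chromosome, not the genome; unwanted
    chromosomes are skipped without error.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"FASTA file not found: {path}")
    for record in SeqIO.parse(str(path), "fasta"):
        if wanted is not None and record.id not in wanted:
            continue
        yield record.id, str(record.seq).upper()


# ---------------------------------------------------------------------------
# Cross-reference table
# ---------------------------------------------------------------------------

def read_crossref(
    path: PathLike, log: Optional[TextIO] = None
) -> tuple[CrossRefTable, list[LineWarning]]:
    """Read a tab-delimited chrom/position/rs-identifier table.

    Duplicate (chrom, pos) keys keep the first rs identifier; each
    duplicate is reported as a warning (and echoed to ``log`` if given).
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"cross-reference file not found: {path}")
    table = CrossRefTable()
    warnings: list[LineWarning] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not fields[1].strip().isdigit():
                warnings.append(
                    LineWarning(line_no, "expected chrom<TAB>position<TAB>rs_id")
                )
                continue
            chrom, pos, rs_id = fields[0].strip(), int(fields[1]), fields[2].strip()
            if not table.add(chrom, pos, rs_id):
                warnings.append(
                    LineWarning(
                        line_no, f"duplicate cross-reference key {chrom}:{pos}; first kept"
                    )
                )
    if log is not None:
        for warning in warnings:
            print(f"crossref warning: {warning}", file=log)
    return table, warnings


# ---------------------------------------------------------------------------
# 25-column report
# ---------------------------------------------------------------------------

def write_rows(rows: Iterable[AnnotationRow], path: PathLike) -> None:
    """Write the annotation report: a header naming all 25 columns, then
    one tab-separated 25-field line per row. Output is byte-stable for
    identical input."""
    path = Path(path)
    try:
        handle = open(path, "w", newline="\n")
    except OSError as exc:
        raise FormatError(f"cannot write output file {path}: {exc}") from exc
    with handle:
        handle.write("\t".join(COLUMN_NAMES) + "\n")
        for row in rows:
            handle.write("\t".join(row.to_fields()) + "\n")


def read_rows(path: PathLike) -> list[list[str]]:
    """Re-read a written report as raw field lists (header excluded)."""
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines or lines[0].split("\t") != list(COLUMN_NAMES):
        raise FormatError(f"{path} does not start with the 25-column header")
    return [line.split("\t") for line in lines[1:]]
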