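"""Per-SNP annotation orchestration.

Each queried SNP is classified as Exonic, Intronic or Intergenic (with
precedence Exonic > Intronic > Intergenic across overlapping transcripts)
and expanded into one output row per containing feature (exonic) or per
nearest-feature tie (non-coding). Codon-level columns are filled for CDS
hits when the chromosome sequence is available; every failure mode
degrades to a message in the final column rather than aborting the run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

from . import codon_engine, io_formats
from .feature_index import FeatureIndex, build_index, nearest_among
from .models import (
    NA,
    AnnotationRow,
    CrossRefTable,
    GtfFeature,
    RegionCall,
    SnpQuery,
    TranscriptModel,
    is_exonic_feature_type,
    is_intron_feature_type,
)

PathLike = Union[str, Path]


def classify_snp(snp: SnpQuery, index: FeatureIndex) -> RegionCall:
    """Region call for one SNP against its chromosome's feature index.

    Exonic when the position falls inside any exon/CDS/UTR/start/stop
    feature; else Intronic when it falls inside an explicit intron (or
    other gene-spanning) feature row, or inside some transcript's genomic
    extent; else Intergenic. The in-feature flag reports containment in an
    actual annotation row, so a SNP in an intron derived from the gap
    between exons carries flag N.
    """
    containing = index.containing_features(snp.pos)
    if any(is_exonic_feature_type(f.feature_type) for f in containing):
        return RegionCall("Exonic", "Y")
    if containing:
        # explicit intron rows, or gene/transcript-spanning rows
        return RegionCall("Intronic", "Y")
    if index.transcripts_spanning(snp.pos):
        return RegionCall("Intronic", "N")
    return RegionCall("Intergenic", "N")


def _fmt_bracket(i: int, n: int) -> str:
    return f"[{i}/{n}]"


def _exon_display(
    feature: GtfFeature, model: Optional[TranscriptModel]
) -> str:
    """Column-15 "[exon/total]" display for a feature, when determinable."""
    if model is None or model.total_exon_count <= 0:
        return NA
    e = feature.exon_number
    if e is None:
        # locate the exon segment containing this feature's start
        for i, seg in enumerate(model.exon_segments, start=1):
            if seg.contains(feature.start):
                e = seg.exon_number if seg.exon_number is not None else i
                break
    if e is None:
        return NA
    return _fmt_bracket(e, model.total_exon_count)


def _adhoc_model(feature: GtfFeature) -> TranscriptModel:
    """Single-segment transcript stand-in for a CDS row that belongs to no
    assembled transcript (missing transcript_id)."""
    return TranscriptModel(
        transcript_id=feature.transcript_id or "(unassigned)",
        gene_id=feature.gene_id,
        strand=feature.strand,
        cds_segments=[feature],
        exon_segments=[],
        total_exon_count=1,
    )


def _base_row(snp: SnpQuery, region: RegionCall, rs_id: Optional[str]) -> AnnotationRow:
    return AnnotationRow(
        chrom=snp.chrom,
        pos=snp.pos,
        in_feature=region.in_feature_flag,
        region=region.region,
        rs_id=rs_id if rs_id else NA,
    )


def _fill_feature_columns(row: AnnotationRow, feature: GtfFeature) -> None:
    row.feature = feature.feature_type
    row.feature_start = feature.start
    row.feature_end = feature.end
    row.gene_id = feature.gene_id or NA
    row.gene_name = feature.gene_name or NA
    row.transcript_id = feature.transcript_id or NA
    row.transcript_name = feature.transcript_name or NA
    row.strand = feature.strand or NA
    row.annotated_frame = feature.frame
    row.protein_id = feature.protein_id or NA


def _fill_codon_columns(
    row: AnnotationRow,
    snp: SnpQuery,
    feature: GtfFeature,
    model: TranscriptModel,
    chrom_seq: str,
    messages: list[str],
) -> None:
    """Columns 18-22 for a SNP inside a CDS feature with sequence in hand."""
    try:
        ctx = codon_engine.build_coding_context(model, chrom_seq, snp)
    except codon_engine.SequenceMismatch as exc:
        messages.append(str(exc))
        return
    annotated_offset = codon_engine.effective_frame_offset(model, feature)
    try:
        frame = codon_engine.estimate_frame(ctx, annotated_offset)
    except ValueError as exc:
        messages.append(str(exc))
        return
    if frame.source == "estimated":
        row.estimated_frame = frame.frame
    row.stop_codons = frame.stop_count
    ref, alt = snp.ref_allele, snp.alt_allele
    if ctx.strand == "-":
        ref = codon_engine.complement_base(ref) if ref else ""
        alt = codon_engine.complement_base(alt)
    call = codon_engine.extract_codon(ctx, frame, ref, alt)
    row.codon = call.codon_display
    if call.ref_aa is not None and call.mut_aa is not None:
        row.amino_acid = f"[{call.ref_aa}/{call.mut_aa}]"
        row.synonymous = "Y" if call.synonymous else "N"
    messages.extend(call.messages)


def annotate_snp(
    snp: SnpQuery,
    index: FeatureIndex,
    chrom_seq: Optional[str] = None,
    crossref: Optional[CrossRefTable] = None,
) -> list[AnnotationRow]:
    """Annotate one validated SNP into one or more 25-column rows.

    Exonic SNPs yield one row per containing exonic feature, with codon
    columns filled for CDS hits; intronic and intergenic SNPs yield one
    row per nearest-feature tie carrying the distance. Column 7 counts the
    rows emitted for the SNP and column 8 indexes each row among those of
    the same feature type. When ``chrom_seq`` is None (chromosome absent
    from the FASTA) the sequence-derived columns 18-22 stay NA.
    """
    rs_id = crossref.lookup(snp.chrom, snp.pos) if crossref is not None else None
    region = classify_snp(snp, index)
    rows: list[AnnotationRow] = []

    if region.region == "Exonic":
        features = [
            f
            for f in index.containing_features(snp.pos)
            if is_exonic_feature_type(f.feature_type)
        ]
        for feature in features:
            row = _base_row(snp, region, rs_id)
            messages: list[str] = []
            model = index.transcripts.get(feature.transcript_id)
            _fill_feature_columns(row, feature)
            row.exon = _exon_display(feature, model)
            if feature.feature_type == "CDS" and chrom_seq is not None:
                cds_model = model if model and model.cds_segments else _adhoc_model(feature)
                _fill_codon_columns(row, snp, feature, cds_model, chrom_seq, messages)
            elif chrom_seq is None:
                messages.append("no sequence for chromosome; columns 18-22 unavailable")
            if model:
                messages.extend(model.warnings)
            row.messages = "; ".join(messages) if messages else NA
            rows.append(row)
    else:
        hits = _nearest_hits_for_region(snp, index, region)
        if not hits:
            row = _base_row(snp, region, rs_id)
            row.messages = "no annotated features on this chromosome"
            rows.append(row)
        for hit in hits:
            row = _base_row(snp, region, rs_id)
            messages = []
            _fill_feature_columns(row, hit.feature)
            row.distance = hit.distance
            model = index.transcripts.get(hit.feature.transcript_id)
            row.exon = _exon_display(hit.feature, model)
            if chrom_seq is None:
                messages.append("no sequence for chromosome; columns 18-22 unavailable")
            row.messages = "; ".join(messages) if messages else NA
            rows.append(row)

    # Column 7: rows for this SNP; column 8: index within same feature type.
    n = len(rows)
    type_totals = Counter(r.feature for r in rows)
    seen: Counter = Counter()
    for row in rows:
        row.n_features = n
        seen[row.feature] += 1
        row.feature_annotation = _fmt_bracket(seen[row.feature], type_totals[row.feature])
    return rows


def _nearest_hits_for_region(snp: SnpQuery, index: FeatureIndex, region: RegionCall):
    """Candidate set for the nearest-feature search.

    Intronic SNPs measure distance to the nearest exon of the transcripts
    spanning them (CDS segments standing in when a transcript has no exon
    rows); intergenic SNPs measure distance to the nearest feature of any
    kind on the chromosome.
    """
    if region.region == "Intronic":
        candidates: list[GtfFeature] = []
        for model in index.transcripts_spanning(snp.pos):
            candidates.extend(model.exon_segments or model.cds_segments)
        if candidates:
            return nearest_among(candidates, snp.pos)
        # explicit intron containment without assembled transcripts
        non_containing = [f for f in index.features if not f.contains(snp.pos)]
        return nearest_among(non_containing, snp.pos)
    return index.nearest_features(snp.pos)


def validate_snps(
    snps: Sequence[SnpQuery],
    indexes: dict[str, FeatureIndex],
    chrom_lengths: Optional[dict[str, int]] = None,
) -> tuple[list[SnpQuery], dict[int, AnnotationRow]]:
    """Check queries against the annotation (and sequence lengths if known).

    Returns the valid queries plus a map from input position to a 25-column
    warning row for each rejected query: chromosomes absent from the
    annotation, and positions beyond the known chromosome length.
    """
    valid: list[SnpQuery] = []
    warning_rows: dict[int, AnnotationRow] = {}
    for i, snp in enumerate(snps):
        if snp.chrom not in indexes:
            row = AnnotationRow(chrom=snp.chrom, pos=snp.pos, in_feature=NA)
            row.messages = (
                f"chromosome {snp.chrom!r} does not exist in the annotation"
            )
            warning_rows[i] = row
        elif (
            chrom_lengths is not None
            and snp.chrom in chrom_lengths
            and snp.pos > chrom_lengths[snp.chrom]
        ):
            row = AnnotationRow(chrom=snp.chrom, pos=snp.pos, in_feature=NA)
            row.messages = (
                f"position {snp.pos} exceeds length "
                f"{chrom_lengths[snp.chrom]} of chromosome {snp.chrom}"
            )
            warning_rows[i] = row
        else:
            valid.append(snp)
    return valid, warning_rows


# ---------------------------------------------------------------------------
# Run summaries
# ---------------------------------------------------------------------------

def _round_percent(count: int, total: int) -> float:
    """Percentage to 2 decimals, rounding halves away from zero."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunSummary:
    """Aggregate tables over a completed annotation run."""

    n_snps: int = 0
    region_counts: dict[str, int] = field(default_factory=dict)
    feature_breakdown: dict[str, int] = field(default_factory=dict)
    total_nonsynonymous: int = 0
    total_synonymous: int = 0
    nonsyn_by_position: dict[int, int] = field(default_factory=dict)
    nonsyn_percent_by_position: dict[int, float] = field(default_factory=dict)
    intergenic_distances: dict[str, list[int]] = field(default_factory=dict)
    intronic_distances: list[int] = field(default_factory=list)


def _codon_position_from_display(display: str) -> Optional[int]:
    i = display.find("[")
    return i + 1 if 0 <= i <= 2 else None


def summarize(rows: Sequence[AnnotationRow]) -> RunSummary:
    """Summary statistics over an annotation report.

    Counts each queried position once for the region table; classifies
    exonic positions into CDS/UTR/other-exon buckets by their best feature
    hit; tallies non-synonymous calls by codon position (with percentages
    of the non-synonymous total); and collects intergenic distances split
    by whether the nearest feature lies upstream or downstream, plus
    intronic distance-to-exon lists.
    """
    summary = RunSummary()
    by_snp: dict[tuple[str, int], list[AnnotationRow]] = {}
    for row in rows:
        by_snp.setdefault((row.chrom, row.pos), []).append(row)
    summary.n_snps = len(by_snp)

    regions: Counter = Counter()
    breakdown: Counter = Counter()
    syn_keys: set = set()
    nonsyn_keys: set = set()
    intergenic: dict[str, list[int]] = {"upstream": [], "downstream": []}
    intronic: list[int] = []

    for key, snp_rows in by_snp.items():
        region = next((r.region for r in snp_rows if r.region != NA), "Unknown")
        regions[region] += 1
        if region == "Exonic":
            types = {r.feature for r in snp_rows}
            if "CDS" in types:
                breakdown["CDS"] += 1
            elif any("utr" in t.lower() for t in types):
                utr = next(t for t in sorted(types) if "utr" in t.lower())
                breakdown[utr] += 1
            else:
                breakdown["exon"] += 1
        elif region in {"Intronic", "Intergenic", "Unknown"}:
            breakdown[region] += 1
        for row in snp_rows:
            cp = _codon_position_from_display(row.codon)
            if row.synonymous == "N" and cp is not None:
                nonsyn_keys.add(key + (cp,))
            elif row.synonymous == "Y" and cp is not None:
                syn_keys.add(key + (cp,))
            if region == "Intergenic" and row.distance is not None:
                side = (
                    "upstream"
                    if row.feature_end is not None and row.feature_end < row.pos
                    else "downstream"
                )
                intergenic[side].append(row.distance)
            if region == "Intronic" and row.distance is not None:
                intronic.append(row.distance)

    position_counts = Counter(k[-1] for k in nonsyn_keys)
    total_nonsyn = sum(position_counts.values())
    summary.region_counts = dict(regions)
    summary.feature_breakdown = dict(breakdown)
    summary.total_nonsynonymous = total_nonsyn
    summary.total_synonymous = len(syn_keys)
    summary.nonsyn_by_position = {p: position_counts.get(p, 0) for p in (1, 2, 3)}
    summary.nonsyn_percent_by_position = {
        p: _round_percent(position_counts.get(p, 0), total_nonsyn) for p in (1, 2, 3)
    }
    summary.intergenic_distances = intergenic
    summary.intronic_distances = sorted(intronic)
    return summary


def write_summary(summary: RunSummary, path: PathLike) -> None:
    """Write the summary as tab-delimited sections."""
    with open(Path(path), "w", newline="\n") as out:
        out.write("# region counts\n")
        for region in ("Exonic", "Intronic", "Intergenic", "Unknown"):
            if region in summary.region_counts:
                out.write(f"{region}\t{summary.region_counts[region]}\n")
        out.write("# feature breakdown\n")
        for name, count in sorted(summary.feature_breakdown.items()):
            out.write(f"{name}\t{count}\n")
        out.write("# synonymy\n")
        out.write(f"non-synonymous\t{summary.total_nonsynonymous}\n")
        out.write(f"synonymous\t{summary.total_synonymous}\n")
        out.write("# non-synonymous by codon position\n")
        for p in (1, 2, 3):
            out.write(
                f"position {p}\t{summary.nonsyn_by_position[p]}\t"
                f"{summary.nonsyn_percent_by_position[p]:.2f}%\n"
            )
        out.write("# intergenic distances (bp)\n")
        for side in ("upstream", "downstream"):
            values = ",".join(map(str, summary.intergenic_distances.get(side, [])))
            out.write(f"{side}\t{values}\n")
        out.write("# intronic distances to nearest exon (bp)\n")
        out.write(",".join(map(str, summary.intronic_distances)) + "\n")


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def annotate_files(
    snp_path: PathLike,
    fasta_path: PathLike,
    gtf_path: PathLike,
    snp_format: str = "auto",
    crossref_path: Optional[PathLike] = None,
    log: Optional[TextIO] = None,
) -> tuple[list[AnnotationRow], list[str]]:
    """Run the full annotation pipeline on files, in input-SNP order.

    Load the GTF, validate SNPs against it, stream the FASTA one queried
    chromosome at a time (skipping chromosomes with no queries), annotate,
    and cross-reference. Returns the output rows — at least one per input
    SNP, warnings included — and the textual warnings raised along the way.
    """
    def note(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    snps, line_warnings = io_formats.read_snps(snp_path, snp_format)
    warnings = [f"{snp_path}: {w}" for w in line_warnings]
    features_by_chrom = io_formats.read_gtf(gtf_path)
    indexes = {chrom: build_index(fs) for chrom, fs in features_by_chrom.items()}

    crossref: Optional[CrossRefTable] = None
    if crossref_path is not None:
        crossref, xwarnings = io_formats.read_crossref(crossref_path)
        warnings.extend(f"{crossref_path}: {w}" for w in xwarnings)

    valid, warning_rows = validate_snps(snps, indexes)
    for i in sorted(warning_rows):
        warnings.append(f"SNP {snps[i].chrom}:{snps[i].pos}: {warning_rows[i].messages}")
        if crossref is not None:  # every query is cross-referenced, even degraded ones
            rs = crossref.lookup(snps[i].chrom, snps[i].pos)
            if rs:
                warning_rows[i].rs_id = rs

    wanted = {snp.chrom for snp in valid}
    rows_by_input: dict[int, list[AnnotationRow]] = {
        i: [row] for i, row in warning_rows.items()
    }
    index_of_snp = {id(snp): i for i, snp in enumerate(snps)}
    by_chrom: dict[str, list[SnpQuery]] = {}
    for snp in valid:
        by_chrom.setdefault(snp.chrom, []).append(snp)

    pending = set(by_chrom)
    for chrom, seq in io_formats.stream_fasta(fasta_path, wanted):
        if chrom not in pending:
            continue
        pending.discard(chrom)
        index = indexes[chrom]
        for snp in by_chrom[chrom]:
            i = index_of_snp[id(snp)]
            if snp.pos > len(seq):
                row = AnnotationRow(chrom=snp.chrom, pos=snp.pos, in_feature=NA)
                row.messages = (
                    f"position {snp.pos} exceeds length {len(seq)} of chromosome {chrom}"
                )
                warnings.append(f"SNP {chrom}:{snp.pos}: {row.messages}")
                rows_by_input[i] = [row]
                continue
            rows_by_input[i] = annotate_snp(snp, index, seq, crossref)
    # Chromosomes in the annotation but absent from the FASTA: degraded rows.
    for chrom in sorted(pending):
        note(f"chromosome {chrom} absent from FASTA; sequence columns will be NA")
        index = indexes[chrom]
        for snp in by_chrom[chrom]:
            rows_by_input[index_of_snp[id(snp)]] = annotate_snp(
                snp, index, None, crossref
            )

    rows: list[AnnotationRow] = []
    for i in range(len(snps)):
        rows.extend(rows_by_input.get(i, []))
    for w in warnings:
        note(f"warning: {w}")
    return rows, warnings
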