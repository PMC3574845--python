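"""Deterministic synthetic genomes with known ground-truth annotations.

The generator builds small multi-chromosome genomes whose transcripts carry
clean open reading frames: a start codon, zero internal stop codons in the
true frame, a terminal stop, and at least one stop codon in each wrong
frame — so reading-frame estimation by stop-codon counting is always
decidable. SNPs are planted in exons (including codons straddling exon
junctions), introns and intergenic gaps, on both strands, and the expected
annotation of every SNP (region, distance, codon position, amino-acid
change, synonymy) is computed at generation time by direct construction —
independently of the annotation pipeline, so the truth table can serve as
its oracle.

The fixture also exercises the pipeline's degraded paths: one chromosome
can be annotated in the GTF but omitted from the FASTA (sequence-less
annotation), and SNPs can be planted on a chromosome unknown to the GTF
(warning rows).

Identical seeds produce byte-identical fixture files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

from Bio.Seq import Seq

from .codon_engine import complement_base, reverse_complement

PathLike = Union[str, Path]

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults give a compact genome (a few kb per chromosome, a handful of
    multi-exon transcripts on mixed strands) that still covers every
    annotation path; scale ``n_*`` counts up for stress fixtures.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 8000
    transcripts_per_chrom: int = 3
    exons_per_transcript: tuple[int, int] = (1, 4)
    codons_per_cds: tuple[int, int] = (30, 60)
    intron_length: tuple[int, int] = (60, 200)
    minus_strand_fraction: float = 0.5
    n_exonic: int = 6
    n_intronic: int = 4
    n_intergenic: int = 4
    n_no_sequence: int = 2
    n_unknown_chrom: int = 1
    crossref_fraction: float = 0.5
    annotate_frames: bool = True  # write CDS phase in the GTF (else '.')


@dataclass
class _GtfRow:
    chrom: str
    feature: str
    start: int
    end: int
    strand: str
    frame: str  # "0"/"1"/"2"/"."
    gene_id: str
    transcript_id: str
    protein_id: str
    exon_number: int

    def to_line(self) -> str:
        attrs = (
            f'gene_id "{self.gene_id}"; transcript_id "{self.transcript_id}"; '
            f'gene_name "{self.gene_id}_NAME"; transcript_name "{self.transcript_id}_NAME"; '
            f'protein_id "{self.protein_id}"; exon_number "{self.exon_number}";'
        )
        return "\t".join(
            [
                self.chrom,
                "synthetic",
                self.feature,
                str(self.start),
                str(self.end),
                ".",
                self.strand,
                self.frame,
                attrs,
            ]
        )


@dataclass
class _Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    spliced: str  # transcription orientation, starts ATG, ends stop
    segments: list[tuple[int, int]]  # genomic order, 1-based inclusive
    cuts: list[int]  # spliced offsets of junctions (cumulative lengths)

    @property
    def extent(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]

    def genomic_pos(self, spliced_offset: int) -> int:
        """Map a 0-based offset in the spliced CDS to a genomic coordinate."""
        lengths = [e - s + 1 for s, e in self.segments]
        if self.strand == "-":
            # transcription order is genomic order reversed
            order = list(range(len(self.segments)))[::-1]
        else:
            order = list(range(len(self.segments)))
        cum = 0
        for gi in order:
            l = lengths[gi]
            if spliced_offset < cum + l:
                within = spliced_offset - cum
                s, e = self.segments[gi]
                return s + within if self.strand == "+" else e - within
            cum += l
        raise IndexError(f"offset {spliced_offset} outside spliced CDS")


@dataclass
class SnpTruth:
    """Expected annotation of one planted SNP."""

    chrom: str
    pos: int
    ref_plus: str  # reference base on the plus strand
    alt_plus: str  # mutant base on the plus strand
    region: Optional[str]  # None for unknown-chromosome SNPs
    distance: Optional[int] = None
    codon_position: Optional[int] = None
    codon_display: Optional[str] = None
    ref_aa: Optional[str] = None
    mut_aa: Optional[str] = None
    synonymous: Optional[str] = None  # "Y"/"N"
    rs_id: Optional[str] = None
    expect_warning: bool = False
    has_sequence: bool = True
    transcript_id: Optional[str] = None


@dataclass
class Fixture:
    """One generated fixture: in-memory data plus the files written from it."""

    spec: FixtureSpec
    outdir: Path
    sequences: dict[str, str] = field(default_factory=dict)  # all chroms, hidden too
    hidden_chroms: set[str] = field(default_factory=set)  # in GTF, not in FASTA
    gtf_rows: list[_GtfRow] = field(default_factory=list)
    transcripts: list[_Transcript] = field(default_factory=list)
    truth: list[SnpTruth] = field(default_factory=list)
    fasta_path: Path = Path()
    gtf_path: Path = Path()
    snp_path: Path = Path()
    vcf_path: Path = Path()
    crossref_path: Path = Path()
    truth_path: Path = Path()

    def write(self) -> None:
        """Write FASTA/GTF/SNP/VCF/cross-reference/truth files (byte-stable)."""
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.fasta_path = self.outdir / "genome.fa"
        self.gtf_path = self.outdir / "annotation.gtf"
        self.snp_path = self.outdir / "snps.tab"
        self.vcf_path = self.outdir / "snps.vcf"
        self.crossref_path = self.outdir / "crossref.tab"
        self.truth_path = self.outdir / "truth.tsv"

        with open(self.fasta_path, "w", newline="\n") as out:
            for chrom in sorted(self.sequences):
                if chrom in self.hidden_chroms:
                    continue
                out.write(f">{chrom} synthetic\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    out.write(seq[i : i + 60] + "\n")

        with open(self.gtf_path, "w", newline="\n") as out:
            out.write("# synthetic annotation\n")
            for row in sorted(
                self.gtf_rows, key=lambda r: (r.chrom, r.start, r.feature)
            ):
                out.write(row.to_line() + "\n")

        with open(self.snp_path, "w", newline="\n") as out:
            for t in self.truth:
                out.write(f"{t.chrom}\t{t.pos}\t{t.alt_plus}\t{t.ref_plus}\n")

        with open(self.vcf_path, "w", newline="\n") as out:
            out.write("##fileformat=VCFv4.2\n")
            chroms = sorted(set(self.sequences) | {t.chrom for t in self.truth})
            for chrom in chroms:
                if chrom in self.sequences:
                    out.write(
                        f"##contig=<ID={chrom},length={len(self.sequences[chrom])}>\n"
                    )
                else:
                    out.write(f"##contig=<ID={chrom}>\n")
            out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for t in self.truth:
                out.write(
                    f"{t.chrom}\t{t.pos}\t.\t{t.ref_plus}\t{t.alt_plus}\t.\t.\t.\n"
                )

        with open(self.crossref_path, "w", newline="\n") as out:
            for t in self.truth:
                if t.rs_id:
                    out.write(f"{t.chrom}\t{t.pos}\t{t.rs_id}\n")

        with open(self.truth_path, "w", newline="\n") as out:
            cols = (
                "chrom pos ref_plus alt_plus region distance codon_position "
                "codon_display ref_aa mut_aa synonymous rs_id expect_warning "
                "has_sequence transcript_id"
            ).split()
            out.write("\t".join(cols) + "\n")
            for t in self.truth:
                out.write(
                    "\t".join(
                        "NA" if getattr(t, c) is None else str(getattr(t, c))
                        for c in cols
                    )
                    + "\n"
                )


def _random_orf(rng: random.Random, n_codons: int) -> str:
    """A CDS with no internal stop in frame 0 and >= 1 stop in frames 1, 2."""
    while True:
        middle = [rng.choice(NON_STOP_CODONS) for _ in range(n_codons - 2)]
        seq = "ATG" + "".join(middle) + rng.choice(STOPS)
        ok = True
        for f in (1, 2):
            if not any(
                seq[i : i + 3] in STOPS for i in range(f, len(seq) - 2, 3)
            ):
                ok = False
                break
        if ok:
            return seq


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _build_transcript(
    rng: random.Random,
    spec: FixtureSpec,
    chrom: str,
    tid: str,
    gid: str,
    start_at: int,
) -> tuple[_Transcript, int]:
    """Place one transcript starting at/after ``start_at``; returns the model
    and the first free coordinate after it."""
    n_exons = rng.randint(*spec.exons_per_transcript)
    n_codons = rng.randint(*spec.codons_per_cds)
    spliced = _random_orf(rng, n_codons)
    total = len(spliced)
    if n_exons > 1:
        cuts = sorted(rng.sample(range(1, total), n_exons - 1))
    else:
        cuts = []
    lengths = [b - a for a, b in zip([0] + cuts, cuts + [total])]  # transcription order
    introns = [rng.randint(*spec.intron_length) for _ in range(n_exons - 1)]
    strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
    glengths = lengths if strand == "+" else lengths[::-1]
    gintrons = introns if strand == "+" else introns[::-1]
    segments: list[tuple[int, int]] = []
    cursor = start_at
    for i, l in enumerate(glengths):
        segments.append((cursor, cursor + l - 1))
        cursor += l
        if i < len(gintrons):
            cursor += gintrons[i]
    span_end = segments[-1][1]
    if span_end > spec.chrom_length - 50:
        raise ValueError(
            f"chromosome length {spec.chrom_length} too short for the requested "
            "transcript structures; increase chrom_length or shrink transcripts"
        )
    return (
        _Transcript(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            spliced=spliced,
            segments=segments,
            cuts=cuts,
        ),
        span_end + 1,
    )


def _transcript_sequence_patch(tx: _Transcript) -> list[tuple[int, str]]:
    """(genomic start, plus-strand sequence) for each CDS segment."""
    plus = tx.spliced if tx.strand == "+" else reverse_complement(tx.spliced)
    patches = []
    cum = 0
    for s, e in tx.segments:
        l = e - s + 1
        patches.append((s, plus[cum : cum + l]))
        cum += l
    return patches


def _gtf_rows_for(tx: _Transcript, annotate_frames: bool) -> list[_GtfRow]:
    rows = []
    k = len(tx.segments)
    lengths = [e - s + 1 for s, e in tx.segments]
    # transcription-order index of each genomic segment
    order = range(k) if tx.strand == "+" else range(k - 1, -1, -1)
    cum = 0
    phase_by_genomic: dict[int, int] = {}
    exon_no_by_genomic: dict[int, int] = {}
    for t_index, gi in enumerate(order, start=1):
        phase_by_genomic[gi] = (3 - (cum % 3)) % 3
        exon_no_by_genomic[gi] = t_index
        cum += lengths[gi]
    for gi, (s, e) in enumerate(tx.segments):
        common = dict(
            chrom=tx.chrom,
            start=s,
            end=e,
            strand=tx.strand,
            gene_id=tx.gene_id,
            transcript_id=tx.transcript_id,
            protein_id=tx.transcript_id.replace("TR", "PR"),
            exon_number=exon_no_by_genomic[gi],
        )
        rows.append(_GtfRow(feature="exon", frame=".", **common))
        rows.append(
            _GtfRow(
                feature="CDS",
                frame=str(phase_by_genomic[gi]) if annotate_frames else ".",
                **common,
            )
        )
    return rows


def _plant_exonic(
    rng: random.Random,
    tx: _Transcript,
    used: set[tuple[str, int]],
    prefer_junction: bool,
) -> Optional[SnpTruth]:
    """Plant one SNP inside the CDS (never in the terminal stop codon)."""
    total = len(tx.spliced)
    candidates = None
    if prefer_junction:
        straddles = [c for c in tx.cuts if c % 3 != 0 and 0 < c < total - 3]
        if straddles:
            cut = rng.choice(straddles)
            codon_start = cut - (cut % 3)
            candidates = [codon_start, codon_start + 1, codon_start + 2]
    for attempt in range(40):
        if candidates and attempt < 10:
            s = rng.choice(candidates)
        else:  # junction codon exhausted (or none requested): any CDS position
            s = rng.randrange(0, total - 3)
        pos = tx.genomic_pos(s)
        if (tx.chrom, pos) in used:
            continue
        used.add((tx.chrom, pos))
        ref_t = tx.spliced[s]  # transcript-orientation reference base
        alt_t = rng.choice([b for b in BASES if b != ref_t])
        codon_start = s - (s % 3)
        codon = tx.spliced[codon_start : codon_start + 3]
        cp = s % 3 + 1
        mut_codon = codon[: cp - 1] + alt_t + codon[cp:]
        display = codon[: cp - 1] + f"[{ref_t}/{alt_t}]" + codon[cp:]
        ref_aa, mut_aa = _translate(codon), _translate(mut_codon)
        if tx.strand == "-":
            ref_plus, alt_plus = complement_base(ref_t), complement_base(alt_t)
        else:
            ref_plus, alt_plus = ref_t, alt_t
        return SnpTruth(
            chrom=tx.chrom,
            pos=pos,
            ref_plus=ref_plus,
            alt_plus=alt_plus,
            region="Exonic",
            codon_position=cp,
            codon_display=display,
            ref_aa=ref_aa,
            mut_aa=mut_aa,
            synonymous="Y" if ref_aa == mut_aa else "N",
            transcript_id=tx.transcript_id,
        )
    return None


def _plant_intronic(
    rng: random.Random, tx: _Transcript, seq: str, used: set[tuple[str, int]]
) -> Optional[SnpTruth]:
    if len(tx.segments) < 2:
        return None
    for _ in range(40):
        gi = rng.randrange(len(tx.segments) - 1)
        left_end = tx.segments[gi][1]
        right_start = tx.segments[gi + 1][0]
        if right_start - left_end < 2:
            continue
        pos = rng.randint(left_end + 1, right_start - 1)
        if (tx.chrom, pos) in used:
            continue
        used.add((tx.chrom, pos))
        ref = seq[pos - 1]
        alt = rng.choice([b for b in BASES if b != ref])
        return SnpTruth(
            chrom=tx.chrom,
            pos=pos,
            ref_plus=ref,
            alt_plus=alt,
            region="Intronic",
            distance=min(pos - left_end, right_start - pos),
            transcript_id=tx.transcript_id,
        )
    return None


def _naive_nearest_distance(rows: list[_GtfRow], pos: int) -> Optional[int]:
    """Brute-force minimum boundary distance over all annotation rows."""
    best = None
    for r in rows:
        if r.start <= pos <= r.end:
            continue
        d = min(abs(pos - r.start), abs(pos - r.end))
        if best is None or d < best:
            best = d
    return best


def _plant_intergenic(
    rng: random.Random,
    chrom: str,
    seq: str,
    chrom_rows: list[_GtfRow],
    gaps: list[tuple[int, int]],
    used: set[tuple[str, int]],
) -> Optional[SnpTruth]:
    open_gaps = [(a, b) for a, b in gaps if b >= a]
    if not open_gaps:
        return None
    for _ in range(40):
        a, b = rng.choice(open_gaps)
        pos = rng.randint(a, b)
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = seq[pos - 1]
        alt = rng.choice([b_ for b_ in BASES if b_ != ref])
        return SnpTruth(
            chrom=chrom,
            pos=pos,
            ref_plus=ref,
            alt_plus=alt,
            region="Intergenic",
            distance=_naive_nearest_distance(chrom_rows, pos),
        )
    return None


def generate_fixture(spec: FixtureSpec, outdir: PathLike) -> Fixture:
    """Generate a complete fixture under ``outdir`` and return it.

    Raises ValueError when the spec is infeasible (chromosome too short for
    the requested transcript structures, or more SNPs requested than there
    are distinct plantable positions).
    """
    rng = random.Random(spec.seed)
    fixture = Fixture(spec=spec, outdir=Path(outdir))

    n_visible = spec.n_chromosomes
    n_total = n_visible + (1 if spec.n_no_sequence > 0 else 0)
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    tx_by_chrom: dict[str, list[_Transcript]] = {}

    tnum = 0
    for ci in range(n_total):
        chrom = f"chr{ci + 1}"
        if ci >= n_visible:
            fixture.hidden_chroms.add(chrom)
        seq = [rng.choice(BASES) for _ in range(spec.chrom_length)]
        cursor = rng.randint(120, 260)
        gaps: list[tuple[int, int]] = [(60, cursor - 60)]
        txs: list[_Transcript] = []
        for _ in range(spec.transcripts_per_chrom):
            tnum += 1
            tx, after = _build_transcript(
                rng, spec, chrom, f"TR{tnum:04d}", f"GENE{tnum:04d}", cursor
            )
            txs.append(tx)
            gap = rng.randint(150, 350)
            gaps.append((after + 60, after + gap - 60))
            cursor = after + gap
        gaps[-1] = (txs[-1].extent[1] + 60, spec.chrom_length - 60)
        for tx in txs:
            for start, patch in _transcript_sequence_patch(tx):
                seq[start - 1 : start - 1 + len(patch)] = list(patch)
            fixture.gtf_rows.extend(_gtf_rows_for(tx, spec.annotate_frames))
        fixture.sequences[chrom] = "".join(seq)
        fixture.transcripts.extend(txs)
        tx_by_chrom[chrom] = txs
        gaps_by_chrom[chrom] = gaps

    visible = [f"chr{i + 1}" for i in range(n_visible)]
    used: set[tuple[str, int]] = set()
    truth: list[SnpTruth] = []

    def visible_txs() -> list[_Transcript]:
        return [t for c in visible for t in tx_by_chrom[c]]

    # exonic SNPs (every 3rd one targets a junction-straddling codon)
    pool = visible_txs()
    for i in range(spec.n_exonic):
        tx = pool[i % len(pool)]
        t = _plant_exonic(rng, tx, used, prefer_junction=(i % 3 == 0))
        if t is None:
            raise ValueError("could not place the requested number of exonic SNPs")
        truth.append(t)

    # intronic SNPs
    multi = [t for t in pool if len(t.segments) >= 2]
    if spec.n_intronic and not multi:
        raise ValueError("no multi-exon transcripts available for intronic SNPs")
    for i in range(spec.n_intronic):
        tx = multi[i % len(multi)]
        t = _plant_intronic(rng, tx, fixture.sequences[tx.chrom], used)
        if t is None:
            raise ValueError("could not place the requested number of intronic SNPs")
        truth.append(t)

    # intergenic SNPs
    rows_by_chrom: dict[str, list[_GtfRow]] = {}
    for row in fixture.gtf_rows:
        rows_by_chrom.setdefault(row.chrom, []).append(row)
    for i in range(spec.n_intergenic):
        chrom = visible[i % len(visible)]
        t = _plant_intergenic(
            rng,
            chrom,
            fixture.sequences[chrom],
            rows_by_chrom[chrom],
            gaps_by_chrom[chrom],
            used,
        )
        if t is None:
            raise ValueError("could not place the requested number of intergenic SNPs")
        truth.append(t)

    # SNPs on the annotated-but-sequence-less chromosome
    if spec.n_no_sequence:
        hidden = sorted(fixture.hidden_chroms)[0]
        htxs = tx_by_chrom[hidden]
        for i in range(spec.n_no_sequence):
            tx = htxs[i % len(htxs)]
            if i % 2 == 0 or len(tx.segments) < 2:
                t = _plant_exonic(rng, tx, used, prefer_junction=False)
            else:
                t = _plant_intronic(rng, tx, fixture.sequences[hidden], used)
            if t is None:
                raise ValueError("could not place sequence-less-chromosome SNPs")
            t.has_sequence = False
            if t.region == "Exonic":
                # codon columns cannot be produced without sequence
                t.codon_display = t.ref_aa = t.mut_aa = t.synonymous = None
                t.codon_position = None
            truth.append(t)

    # SNPs on a chromosome unknown to the annotation
    for i in range(spec.n_unknown_chrom):
        pos = rng.randint(1, spec.chrom_length)
        while ("chrUn", pos) in used:
            pos = rng.randint(1, spec.chrom_length)
        used.add(("chrUn", pos))
        ref = rng.choice(BASES)
        alt = rng.choice([b for b in BASES if b != ref])
        truth.append(
            SnpTruth(
                chrom="chrUn",
                pos=pos,
                ref_plus=ref,
                alt_plus=alt,
                region=None,
                expect_warning=True,
                has_sequence=False,
            )
        )

    # known-SNP identifiers for a fraction of queries
    for t in truth:
        if rng.random() < spec.crossref_fraction:
            t.rs_id = f"rs{rng.randint(10_000_000, 99_999_999)}"

    rng.shuffle(truth)
    fixture.truth = truth
    fixture.write()
    return fixture


def mirror_fixture(fixture: Fixture, outdir: PathLike) -> Fixture:
    """Coordinate-mirrored copy of a fixture: every chromosome is
    reverse-complemented, intervals are reflected (start' = L+1-end),
    strands flip and SNP alleles are complemented.

    Codon-level truth (codon position, display, amino acids, synonymy) is
    unchanged by construction, which is exactly the strand-consistency
    property the mirrored fixture exists to test. Mirroring twice restores
    the original fixture data.
    """
    lengths = {c: len(s) for c, s in fixture.sequences.items()}

    def mpos(chrom: str, pos: int) -> int:
        return lengths[chrom] + 1 - pos if chrom in lengths else pos

    mirrored = Fixture(spec=fixture.spec, outdir=Path(outdir))
    mirrored.hidden_chroms = set(fixture.hidden_chroms)
    mirrored.sequences = {
        c: reverse_complement(s) for c, s in fixture.sequences.items()
    }
    flip = {"+": "-", "-": "+"}
    for row in fixture.gtf_rows:
        mirrored.gtf_rows.append(
            replace(
                row,
                start=mpos(row.chrom, row.end),
                end=mpos(row.chrom, row.start),
                strand=flip.get(row.strand, row.strand),
            )
        )
    for tx in fixture.transcripts:
        segments = sorted(
            (mpos(tx.chrom, e), mpos(tx.chrom, s)) for s, e in tx.segments
        )
        mirrored.transcripts.append(
            replace(tx, strand=flip[tx.strand], segments=segments)
        )
    for t in fixture.truth:
        mirrored.truth.append(
            replace(
                t,
                pos=mpos(t.chrom, t.pos),
                ref_plus=complement_base(t.ref_plus),
                alt_plus=complement_base(t.alt_plus),
            )
        )
    mirrored.write()
    return mirrored


def check_against_truth(
    fixture: Fixture, rows, crossref_used: bool = True
) -> list[str]:
    """Compare pipeline output rows against the fixture's truth table.

    Returns a list of human-readable mismatch descriptions (empty when the
    run agrees with the generator's ground truth on every checked field).
    """
    from .models import NA  # local import to keep module load order simple

    by_pos: dict[tuple[str, int], list] = {}
    for row in rows:
        by_pos.setdefault((row.chrom, row.pos), []).append(row)

    mismatches: list[str] = []

    def bad(t: SnpTruth, msg: str) -> None:
        mismatches.append(f"{t.chrom}:{t.pos}: {msg}")

    for t in fixture.truth:
        snp_rows = by_pos.get((t.chrom, t.pos), [])
        if not snp_rows:
            bad(t, "no output rows")
            continue
        if t.expect_warning:
            if not any(
                t.chrom in (r.messages or "") for r in snp_rows
            ):
                bad(t, "expected a warning naming the chromosome")
            if any(r.region != NA for r in snp_rows):
                bad(t, "warning row should leave the region NA")
            continue
        regions = {r.region for r in snp_rows}
        if regions != {t.region}:
            bad(t, f"region {regions} != {{{t.region}}}")
            continue
        if t.region in {"Intronic", "Intergenic"}:
            distances = {r.distance for r in snp_rows}
            if distances != {t.distance}:
                bad(t, f"distance {distances} != {{{t.distance}}}")
        if t.region == "Exonic":
            cds_rows = [r for r in snp_rows if r.feature == "CDS"]
            if not cds_rows:
                bad(t, "no CDS row for an exonic SNP")
                continue
            for r in cds_rows:
                if t.has_sequence:
                    if r.codon != t.codon_display:
                        bad(t, f"codon {r.codon!r} != {t.codon_display!r}")
                    if r.amino_acid != f"[{t.ref_aa}/{t.mut_aa}]":
                        bad(t, f"amino acids {r.amino_acid!r} != [{t.ref_aa}/{t.mut_aa}]")
                    if r.synonymous != t.synonymous:
                        bad(t, f"synonymy {r.synonymous!r} != {t.synonymous!r}")
                else:
                    for col in (r.estimated_frame, r.stop_codons):
                        if col is not None:
                            bad(t, "sequence-less row carries sequence-derived columns")
                    if r.codon != NA or r.amino_acid != NA or r.synonymous != NA:
                        bad(t, "sequence-less row carries codon columns")
        expected_rs = t.rs_id if (crossref_used and t.rs_id) else None
        for r in snp_rows:
            got = None if r.rs_id == NA else r.rs_id
            if got != expected_rs:
                bad(t, f"rs id {got!r} != {expected_rs!r}")
                break
    return mismatches
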