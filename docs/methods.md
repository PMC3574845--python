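# Methods

## The annotation model

`snpannot` annotates single-nucleotide substitutions against two inputs a
*de novo* sequencing project always has — a reference FASTA and a GTF gene
annotation — without any database construction or pre-processing. Every
query is a 1-based genomic position plus a mutant base (optionally a
reference base); every answer is one or more 25-column records.

**Region classification.** A SNP is *Exonic* when its position falls
inside any exon, CDS, start/stop-codon or UTR-typed feature row;
otherwise *Intronic* when it falls inside an explicit intron (or other
gene-spanning) feature row, or within the genomic extent (minimum start
to maximum end of CDS/exon segments) of any transcript; otherwise
*Intergenic*. Precedence is Exonic > Intronic > Intergenic across
overlapping transcripts, so each SNP receives exactly one region label
even when per-feature rows disagree in detail. The "in feature" flag
(column 3) reports containment in an actual annotation row; a SNP in an
intron that exists only as the gap between exon rows therefore carries
flag N. Introns are never required in the GTF — they are derived from
exon gaps, since annotations routinely omit them.

**Row expansion.** An exonic SNP emits one row per containing feature; a
non-coding SNP emits one row per feature attaining the minimum distance
(ties are expanded, never truncated). Column 7 is the number of rows
emitted for the SNP; column 8 indexes each row among the SNP's rows of
the same feature type, as `[i/n]`. Rows for one SNP are ordered by
(feature type, transcript id, start) so identical inputs give
byte-identical reports.

**Distances.** The distance to a feature is the bp offset to its nearer
boundary: `min(|pos − start|, |pos − end|)`, so a SNP one base outside a
feature is at distance 1, and a containing feature is never a "nearest"
hit. Intronic SNPs measure distance to the nearest exon of the
transcripts spanning them (CDS segments stand in when a transcript has
no exon rows); intergenic SNPs measure distance to the nearest feature
of any kind on the chromosome. Whether the original tool restricted the
intergenic search to transcript extents is not documented; the
any-feature rule used here is the one the distance summaries assume.

**Reading frame.** Codon arithmetic happens on the *spliced CDS*: the
transcript's CDS segments sliced from the chromosome, concatenated in
genomic order, and reverse-complemented for minus-strand transcripts
(unknown strand is treated as plus). When the GTF supplies a frame
(phase) for the containing CDS segment, it takes precedence: the phase
is converted to a global offset on the spliced CDS by adding the
cumulative transcription-order length preceding the segment, modulo 3 —
for a consistently phased annotation this offset is 0 — and column 18
(estimated frame) stays NA. Otherwise the frame is estimated by counting
stop codons (TAA/TAG/TGA) at each of the three offsets over complete
codons and choosing the offset with the fewest, ties broken toward the
smallest offset. A stop codon flush with the end of the spliced sequence
is *not* counted: a correct CDS ends in a stop, and counting it would
penalise the true frame. Column 19 reports the internal-stop count for
whichever frame is in force. Frame estimation is decidable whenever the
true frame has no internal stop and each wrong frame has at least one —
the regime the fixture generator guarantees.

**Codon calls.** The codon position is `((offset − frame) mod 3) + 1`.
The reference base is always taken from the sequence; a supplied
reference allele that disagrees is annotated anyway with a mismatch
message in column 25 (the tool's philosophy is to annotate everything
and carry warnings, not to drop queries). Alleles are complemented for
minus-strand transcripts before codon substitution. Translation uses the
standard nuclear genetic code (no mitochondrial/plastid variants);
codons containing ambiguity codes yield NA amino acids and NA synonymy
with a message rather than a guess. Because extraction operates on the
spliced sequence, codons straddling exon junctions are handled with no
special case.

**Degraded paths.** Queries on chromosomes absent from the GTF produce a
25-column warning row naming the chromosome. Chromosomes annotated in
the GTF but missing from the FASTA are still annotated, with the
sequence-derived columns 18–22 left NA. Positions beyond the known
chromosome length warn. Cross-referencing (column 24) applies to every
query, warning rows included; an absent key renders NA.

**Summaries.** `summarize` counts each queried position once: region
counts, an exonic breakdown (CDS / UTR / other exon, by best feature
hit), synonymous and non-synonymous tallies, non-synonymous counts and
percentages by codon position (2 decimals, halves rounded away from
zero), and distance lists — intergenic split by whether the nearest
feature lies upstream or downstream, intronic as distance-to-exon. A SNP
annotated to several transcripts is counted once per distinct
(position, codon-position, synonymy) combination.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `snp_format` | `auto` | `tab` (chrom/pos/mutation, optional ref column; mutation accepts `G` or `C/G`) or `vcf` (one query per alternate allele; indels skipped with a warning) |
| `crossref` | none | optional chrom/pos/rs-id table; duplicate keys keep the first entry with a warning |
| FixtureSpec `chrom_length` | 8000 bp | room for `transcripts_per_chrom` = 3 transcripts of 30–60 codons with 60–200 bp introns |
| FixtureSpec `minus_strand_fraction` | 0.5 | both strands exercised equally |
| FixtureSpec SNP counts | 6/4/4 (+2 sequence-less, +1 unknown-chrom) | one compact fixture touches every annotation path |

## What the fixture generator emulates — and what it does not

The generator plants clean open reading frames (start codon, no internal
stop in frame, terminal stop, ≥1 stop in each wrong frame) in random
background sequence, splits them across exons at random cut points
(every third exonic SNP targets a junction-straddling codon), and
computes each planted SNP's expected annotation by direct construction,
independently of the pipeline. It does not model GC bias, repeats,
overlapping genes, alternative transcripts sharing exons, UTR rows, or
annotation errors — so closure against the truth table demonstrates the
engine's arithmetic and bookkeeping, not robustness to messy real-world
annotations. `mirror_fixture` reverse-complements every chromosome and
reflects all coordinates; codon-level truth is invariant under this
transformation, which is the strand-consistency property the test suite
checks.

## Numerical and edge-case choices

- Coordinates are 1-based inclusive end to end; the interval tree's
  half-open representation is an internal detail.
- Deterministic ordering everywhere (feature sort keys, first-wins
  cross-reference dedup, smallest-offset frame ties) so reports are
  byte-stable and golden-file friendly.
- Nearest-feature queries run in O(log n) per query via sorted boundary
  arrays; containment via an interval tree; the naive O(n·m) scans live
  only in the test oracles.
- Empty chromosomes give a single Intergenic row with NA distance and a
  message; transcripts with conflicting segment strands resolve to
  unknown strand with a warning.
- Problem sizes: the default suite uses 17–1,000-SNP fixtures over 8–9 kb
  chromosomes and 500-interval/200-query oracle instances over 20 seeds,
  all generated at run time.

## Known limitations

- GTF attribute dialect only (no GFF3 `key=value` attributes).
- Single-base substitutions only; indels and multi-nucleotide variants
  are reported as warnings, never annotated.
- No protein-level effect prediction, splice-site scoring, bgzip/tabix
  support, or multi-sample genotype awareness.
- Exon totals (column 15) count the transcript's exons (max
  `exon_number`, else observed exon rows), which may differ from a
  gene-level exon count when transcripts of a gene differ.
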