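# snpannot

Functional annotation of single-nucleotide polymorphisms for any organism
with a draft genome and a GTF annotation — including non-model species
with little or no presence in SNP databases.

SNP discovery pipelines emit thousands of `chromosome, position, mutation`
triples; interpreting them requires knowing, for each variant, whether it
lands in coding sequence, an intron, or between genes, how far it sits
from the nearest annotated feature, and — for coding variants — what it
does to the protein. Most annotation tools assume a densely catalogued
species (human, mouse) or require building a local database first.
`snpannot` needs only three files, all standard downloads for any
annotated assembly:

1. the SNP queries (VCF, or a tab-delimited `chrom  pos  mutation` list),
2. the reference sequence (FASTA), and
3. the gene annotation (GTF).

An optional fourth file (`chrom  pos  rs-identifier`) cross-references
queries against known SNPs.

## What it computes

For each SNP it emits one or more rows of a 25-column tab-delimited
report: region call (Exonic / Intronic / Intergenic), distance to the
nearest feature for non-coding SNPs (with equidistant ties each on their
own row), the containing/nearest feature's coordinates and
gene/transcript/protein identifiers, and — for SNPs in coding sequence —
the reading frame, the codon containing the SNP, and the amino-acid
consequence.

The codon logic operates on the spliced CDS *S* (segments concatenated in
transcription order, reverse-complemented for minus-strand transcripts).
With frame offset *f* and SNP offset *i* in *S*, the codon position is
((*i* − *f*) mod 3) + 1. When the GTF supplies no frame, *f* is estimated
by counting stop codons at each of the three offsets and taking the
offset with the fewest — a correct reading frame of a true CDS contains
no internal stops, so the stop count is a proxy for frame correctness
(a stop flush with the CDS end is not counted). Reference and mutant
codons are translated with the standard genetic code; a substitution is
synonymous when both codons encode the same residue. See
`docs/methods.md` for the full model and its edge cases.

## Worked example

The package ships a deterministic synthetic-genome generator used by its
own tests; it makes a complete input set with known ground truth:

```python
import snpannot
fx = snpannot.generate_fixture(snpannot.FixtureSpec(seed=11), "demo")
```

```sh
snpannot --snps demo/snps.tab --fasta demo/genome.fa --gtf demo/annotation.gtf \
         --dbsnp demo/crossref.tab --out demo/annotated.tsv \
         --summary demo/summary.tsv --verbose
# chromosome chr3 absent from FASTA; sequence columns will be NA
# warning: SNP chrUn:5326: chromosome 'chrUn' does not exist in the annotation
# wrote 29 rows to demo/annotated.tsv (1 warnings)
```

Selected columns of three output rows:

```
chromosome position in_feature region     distance feature n  annot  strand frame est stops codon    amino  syn rs_id
chr2       1646     Y          Exonic     NA       CDS     2  [1/1]  +      0     NA  0     [C/A]AC  [H/N]  N   NA
chr1       1048     N          Intergenic 123      CDS     2  [1/1]  -      0     NA  NA    NA       NA    NA   NA
chr2       1237     N          Intronic   66       exon    1  [1/1]  +      NA    NA  NA    NA       NA    NA   NA
```

Reading them: the SNP at chr2:1646 sits at the first position of codon
CAC on a plus-strand CDS in annotated frame 0 with zero internal stop
codons; the C→A change turns His into Asn (non-synonymous, `N`). The SNP
at chr1:1048 is intergenic, 123 bp from the nearest feature (a CDS and
its identical exon row — hence two tied rows, `n = 2`). The SNP at
chr2:1237 is intronic, 66 bp from the nearest exon of its transcript.
The `--summary` file tallies regions, synonymy, non-synonymous counts by
codon position, and the distance distributions.

Queries on chromosomes missing from the FASTA are still annotated from
the GTF alone (sequence-derived columns left NA), and queries on
chromosomes unknown to the GTF produce warning rows — both visible in
the run above.

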