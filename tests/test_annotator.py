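"""Annotator: region classification, row expansion, validation, summaries."""

import random

import pytest

from snpannot import annotator, build_index
from snpannot.models import NA, AnnotationRow, GtfFeature, SnpQuery, is_exonic_feature_type


def mk(start, end, ftype="exon", tid="T1", strand="+", frame=None, **kw):
    return GtfFeature(
        chrom="chr1",
        source="s",
        feature_type=ftype,
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        transcript_id=tid,
        gene_id=kw.pop("gene_id", tid.replace("T", "G")),
        **kw,
    )


def snp(pos, alt="A", ref=""):
    return SnpQuery("chr1", pos, ref, alt)


class TestClassifySnp:
    def test_inside_cds_is_exonic(self):
        index = build_index([mk(286859, 287050, "CDS")])
        call = annotator.classify_snp(snp(286966), index)
        assert (call.region, call.in_feature_flag) == ("Exonic", "Y")

    def test_between_genes_is_intergenic(self):
        index = build_index([mk(100, 200), mk(500, 600, tid="T2")])
        call = annotator.classify_snp(snp(350), index)
        assert (call.region, call.in_feature_flag) == ("Intergenic", "N")

    def test_gap_between_exons_is_intronic_without_feature_flag(self):
        index = build_index([mk(100, 200, exon_number=1), mk(500, 600, exon_number=2)])
        call = annotator.classify_snp(snp(350), index)
        assert (call.region, call.in_feature_flag) == ("Intronic", "N")

    def test_explicit_intron_row_sets_feature_flag(self):
        index = build_index(
            [mk(100, 200), mk(201, 499, "intron"), mk(500, 600, exon_number=2)]
        )
        call = annotator.classify_snp(snp(350), index)
        assert (call.region, call.in_feature_flag) == ("Intronic", "Y")

    def test_matches_naive_per_transcript_scan(self):
        rng = random.Random(17)
        feats = []
        extents = {}
        for t in range(12):
            tid = f"T{t}"
            base = rng.randint(1, 20_000)
            n = rng.randint(1, 4)
            lo, hi = None, None
            for j in range(n):
                s = base + 400 * j
                e = s + rng.randint(20, 120)
                feats.append(mk(s, e, "exon", tid=tid, exon_number=j + 1))
                lo = s if lo is None else min(lo, s)
                hi = e if hi is None else max(hi, e)
            extents[tid] = (lo, hi)
        index = build_index(feats)
        for _ in range(300):
            pos = rng.randint(1, 22_000)
            got = annotator.classify_snp(snp(pos), index).region
            if any(
                f.start <= pos <= f.end and is_exonic_feature_type(f.feature_type)
                for f in feats
            ):
                want = "Exonic"
            elif any(lo <= pos <= hi for lo, hi in extents.values()):
                want = "Intronic"
            else:
                want = "Intergenic"
            assert got == want, pos


class TestAnnotateSnp:
    def test_multi_feature_expansion_and_counters(self):
        # SNP inside overlapping CDS rows of two transcripts
        index = build_index(
            [mk(100, 200, "CDS", tid="T1", frame=0), mk(150, 260, "CDS", tid="T2", frame=0)]
        )
        rows = annotator.annotate_snp(snp(180), index)
        assert len(rows) == 2
        assert all(r.n_features == 2 for r in rows)
        assert [r.feature_annotation for r in rows] == ["[1/2]", "[2/2]"]
        assert [r.transcript_id for r in rows] == ["T1", "T2"]

    def test_feature_annotation_indexes_within_feature_type(self):
        index = build_index(
            [mk(100, 200, "CDS", frame=0), mk(90, 210, "exon", exon_number=1)]
        )
        rows = annotator.annotate_snp(snp(150), index)
        assert {(r.feature, r.feature_annotation) for r in rows} == {
            ("CDS", "[1/1]"),
            ("exon", "[1/1]"),
        }
        assert all(r.n_features == 2 for r in rows)

    def test_equidistant_intergenic_snp_reports_both_features(self):
        index = build_index([mk(100, 200, tid="A"), mk(300, 400, tid="B")])
        rows = annotator.annotate_snp(snp(250), index)
        assert len(rows) == 2
        assert {r.distance for r in rows} == {50}
        assert all(r.region == "Intergenic" for r in rows)

    def test_intronic_distance_to_nearest_exon(self):
        index = build_index(
            [mk(100, 200, exon_number=1), mk(500, 600, exon_number=2)]
        )
        (row,) = annotator.annotate_snp(snp(210), index)
        assert (row.region, row.distance, row.feature) == ("Intronic", 10, "exon")

    def test_sequence_less_chromosome_degrades_columns_18_to_22(self, small_run):
        fixture, rows, _ = small_run
        hidden = fixture.hidden_chroms
        degraded = [r for r in rows if r.chrom in hidden]
        assert degraded, "fixture should include sequence-less chromosomes"
        for r in degraded:
            assert r.estimated_frame is None and r.stop_codons is None
            assert r.codon == NA and r.amino_acid == NA and r.synonymous == NA
            assert "no sequence" in r.messages
        # column 24 still resolves for sequence-less SNPs with known rs ids
        with_rs = [
            t
            for t in fixture.truth
            if not t.has_sequence and not t.expect_warning and t.rs_id
        ]
        for t in with_rs:
            assert any(
                r.chrom == t.chrom and r.pos == t.pos and r.rs_id == t.rs_id
                for r in degraded
            )

    def test_empty_chromosome_yields_na_distance_row(self):
        index = build_index([])
        (row,) = annotator.annotate_snp(snp(5), index)
        assert row.region == "Intergenic"
        assert row.distance is None
        assert "no annotated features" in row.messages


class TestValidateSnps:
    def test_unknown_chromosome_warns_by_name(self):
        indexes = {"chr1": build_index([mk(1, 10)])}
        valid, warning_rows = annotator.validate_snps(
            [SnpQuery("chrUn", 5, "", "A")], indexes
        )
        assert not valid
        (row,) = warning_rows.values()
        assert "chrUn" in row.messages
        assert len(row.to_fields()) == 25

    def test_all_valid_yields_no_warnings(self):
        indexes = {"chr1": build_index([mk(1, 10)])}
        valid, warning_rows = annotator.validate_snps([snp(3)], indexes)
        assert len(valid) == 1 and not warning_rows

    def test_mixed_valid_invalid_counts(self):
        indexes = {"chr1": build_index([mk(1, 1000)])}
        snps = [snp(i + 1) for i in range(50)]
        snps += [SnpQuery(f"chrBad{i}", 1, "", "A") for i in range(10)]
        valid, warning_rows = annotator.validate_snps(snps, indexes)
        assert len(valid) == 50
        assert len(warning_rows) == 10

    def test_position_beyond_sequence_warns(self):
        indexes = {"chr1": build_index([mk(1, 10)])}
        valid, warning_rows = annotator.validate_snps(
            [snp(50)], indexes, chrom_lengths={"chr1": 20}
        )
        assert not valid
        (row,) = warning_rows.values()
        assert "exceeds length" in row.messages


class TestPipelineInvariants:
    def test_every_snp_yields_rows_and_column7_consistency(self, small_run):
        fixture, rows, _ = small_run
        assert len(rows) >= len(fixture.truth)
        by_pos = {}
        for r in rows:
            by_pos.setdefault((r.chrom, r.pos), []).append(r)
        assert set(by_pos) == {(t.chrom, t.pos) for t in fixture.truth}
        for snp_rows in by_pos.values():
            n = snp_rows[0].n_features
            if n is not None:  # warning rows leave column 7 NA
                assert len(snp_rows) == n
                assert all(r.n_features == n for r in snp_rows)

    def test_each_snp_gets_exactly_one_region(self, small_run):
        fixture, rows, _ = small_run
        by_pos = {}
        for r in rows:
            by_pos.setdefault((r.chrom, r.pos), set()).add(r.region)
        n_classified = 0
        for regions in by_pos.values():
            assert len(regions) == 1
            if regions != {NA}:
                n_classified += 1
        n_expected = sum(1 for t in fixture.truth if not t.expect_warning)
        assert n_classified == n_expected


class TestSummarize:
    @staticmethod
    def _nonsyn_row(i, codon_position):
        displays = {1: "[A/C]TT", 2: "A[A/C]T", 3: "AT[A/C]"}
        return AnnotationRow(
            chrom="c",
            pos=i,
            region="Exonic",
            feature="CDS",
            codon=displays[codon_position],
            synonymous="N",
        )

    def test_codon_position_percentages(self):
        rows = []
        i = 0
        for position, count in ((1, 96), (2, 103), (3, 32)):
            for _ in range(count):
                i += 1
                rows.append(self._nonsyn_row(i, position))
        summary = annotator.summarize(rows)
        assert summary.total_nonsynonymous == 231
        assert summary.nonsyn_by_position == {1: 96, 2: 103, 3: 32}
        assert summary.nonsyn_percent_by_position == {1: 41.56, 2: 44.59, 3: 13.85}

    def test_empty_rows_give_zero_tables(self):
        summary = annotator.summarize([])
        assert summary.n_snps == 0
        assert summary.total_nonsynonymous == 0
        assert summary.nonsyn_by_position == {1: 0, 2: 0, 3: 0}
        assert summary.intronic_distances == []

    def test_distance_lists_split_by_side(self, small_run):
        fixture, rows, _ = small_run
        summary = annotator.summarize(rows)
        n_sides = sum(len(v) for v in summary.intergenic_distances.values())
        n_intergenic_rows = sum(
            1 for r in rows if r.region == "Intergenic" and r.distance is not None
        )
        assert n_sides == n_intergenic_rows
        assert all(d >= 1 for d in summary.intronic_distances)

    def test_region_counts_partition_snps(self, small_run):
        fixture, rows, _ = small_run
        summary = annotator.summarize(rows)
        assert sum(summary.region_counts.values()) == summary.n_snps
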