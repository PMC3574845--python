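"""Per-chromosome in-memory index of GTF features.

Supports three query patterns the annotator needs:

* containment — which features overlap a genomic position (interval tree);
* nearest with ties — all features attaining the minimum boundary distance
  to a position outside them (bisection over sorted boundaries); and
* transcript assembly — CDS/exon segments grouped into transcript models.

Distance is measured in bp to the nearer feature boundary, so a SNP one
base outside a feature is at distance 1; a containing feature is never a
nearest hit.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .models import GtfFeature, NearestHit, TranscriptModel


def _feature_sort_key(feature: GtfFeature) -> tuple:
    return (feature.feature_type, feature.transcript_id, feature.start, feature.end)


def nearest_among(features: Iterable[GtfFeature], pos: int) -> list[NearestHit]:
    """Nearest-with-ties by direct scan over an explicit candidate set.

    Used for small, pre-restricted sets (e.g. the exons of the transcripts
    containing an intronic SNP). Features containing ``pos`` are excluded.
    """
    best: Optional[int] = None
    hits: list[tuple[GtfFeature, int]] = []
    for feature in features:
        if feature.contains(pos):
            continue
        d = feature.boundary_distance(pos)
        if best is None or d < best:
            best = d
            hits = [(feature, d)]
        elif d == best:
            hits.append((feature, d))
    hits.sort(key=lambda fd: _feature_sort_key(fd[0]))
    return [
        NearestHit(feature=f, distance=d, side="upstream" if f.end < pos else "downstream")
        for f, d in hits
    ]


class FeatureIndex:
    """Query index over the features of a single chromosome."""

    def __init__(self, features: Sequence[GtfFeature]):
        chroms = {f.chrom for f in features}
        if len(chroms) > 1:
            raise ValueError(f"features span multiple chromosomes: {sorted(chroms)}")
        self.chrom: Optional[str] = next(iter(chroms)) if chroms else None
        self.features: list[GtfFeature] = sorted(features, key=_feature_sort_key)
        # Interval tree uses half-open ends internally; inputs stay 1-based
        # inclusive so end+1 restores inclusivity.
        self._tree = IntervalTree()
        for i, f in enumerate(self.features):
            self._tree.addi(f.start, f.end + 1, i)
        # Sorted boundary arrays for nearest queries.
        self._by_start = sorted(range(len(self.features)), key=lambda i: self.features[i].start)
        self._starts = [self.features[i].start for i in self._by_start]
        self._by_end = sorted(range(len(self.features)), key=lambda i: self.features[i].end)
        self._ends = [self.features[i].end for i in self._by_end]
        self.transcripts: dict[str, TranscriptModel] = assemble_transcripts(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def containing_features(self, pos: int) -> list[GtfFeature]:
        """All features with start <= pos <= end, deterministically ordered
        by (feature_type, transcript_id, start)."""
        hits = [self.features[iv.data] for iv in self._tree.at(pos)]
        hits.sort(key=_feature_sort_key)
        return hits

    def nearest_features(self, pos: int) -> list[NearestHit]:
        """All features at the minimum boundary distance from ``pos``.

        Equidistant features all appear (ties expand, never truncate);
        each hit records whether the feature lies upstream (lower
        coordinates) or downstream of the position. Features containing
        ``pos`` are never returned. Empty list on an empty chromosome.
        """
        if not self.features:
            return []
        # Candidates to the right: features starting strictly after pos.
        right_i = bisect_right(self._starts, pos)
        d_right = self._starts[right_i] - pos if right_i < len(self._starts) else None
        # Candidates to the left: features ending strictly before pos.
        left_i = bisect_left(self._ends, pos) - 1
        d_left = pos - self._ends[left_i] if left_i >= 0 else None
        if d_right is None and d_left is None:
            return []  # every feature contains pos
        best = min(d for d in (d_left, d_right) if d is not None)
        hits: list[NearestHit] = []
        if d_left == best:
            lo = bisect_left(self._ends, pos - best)
            hi = bisect_right(self._ends, pos - best)
            for j in range(lo, hi):
                f = self.features[self._by_end[j]]
                if not f.contains(pos):
                    hits.append(NearestHit(f, best, "upstream"))
        if d_right == best:
            lo = bisect_left(self._starts, pos + best)
            hi = bisect_right(self._starts, pos + best)
            for j in range(lo, hi):
                f = self.features[self._by_start[j]]
                if not f.contains(pos):
                    hits.append(NearestHit(f, best, "downstream"))
        hits.sort(key=lambda h: _feature_sort_key(h.feature))
        return hits

    def transcripts_spanning(self, pos: int) -> list[TranscriptModel]:
        """Transcripts whose genomic extent (min start .. max end) contains
        ``pos``, in transcript_id order."""
        return [
            t
            for _tid, t in sorted(self.transcripts.items())
            if t.contains_in_extent(pos)
        ]


def build_index(features: Sequence[GtfFeature]) -> FeatureIndex:
    """Build the per-chromosome query index (features must share one
    chromosome; group with :func:`snpannot.io_formats.read_gtf` first)."""
    return FeatureIndex(features)


def assemble_transcripts(features: Iterable[GtfFeature]) -> dict[str, TranscriptModel]:
    """Group CDS/exon features into transcript models keyed by transcript_id.

    Segments are sorted by genomic start. The total exon count is the
    maximum ``exon_number`` attribute when any segment carries one,
    otherwise the number of exon rows, falling back to the number of CDS
    rows for degenerate CDS-only transcripts. Conflicting strands within
    one transcript resolve to unknown with a warning recorded on the model.
    """
    models: dict[str, TranscriptModel] = {}
    for feature in features:
        if not feature.transcript_id:
            continue
        if feature.feature_type not in {"CDS", "exon"}:
            continue
        model = models.setdefault(
            feature.transcript_id,
            TranscriptModel(transcript_id=feature.transcript_id),
        )
        if not model.gene_id:
            model.gene_id = feature.gene_id
        if feature.strand:
            if not model.strand:
                model.strand = feature.strand
            elif model.strand != feature.strand and model.strand != "?":
                model.warnings.append(
                    f"conflicting strands for transcript {feature.transcript_id}; "
                    "strand treated as unknown"
                )
                model.strand = "?"
        if feature.feature_type == "CDS":
            model.cds_segments.append(feature)
        else:
            model.exon_segments.append(feature)
    for model in models.values():
        if model.strand == "?":
            model.strand = ""
        model.cds_segments.sort(key=lambda f: f.start)
        model.exon_segments.sort(key=lambda f: f.start)
        numbers = [
            f.exon_number
            for f in model.cds_segments + model.exon_segments
            if f.exon_number is not None
        ]
        if numbers:
            model.total_exon_count = max(numbers)
        elif model.exon_segments:
            model.total_exon_count = len(model.exon_segments)
        else:
            model.total_exon_count = len(model.cds_segments)
    return models
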