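"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (hand-frozen codon
table, O(n*m) interval scans, per-frame stop counting) kept separate from
the package code paths they check.
"""

from __future__ import annotations

import pytest

from snpannot import FixtureSpec, annotate_files, generate_fixture

# Standard nuclear genetic code, written out by hand ('*' = stop).
GENETIC_CODE: dict[str, str] = {}
for _codons, _aa in [
    (("TTT", "TTC"), "F"),
    (("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "L"),
    (("ATT", "ATC", "ATA"), "I"),
    (("ATG",), "M"),
    (("GTT", "GTC", "GTA", "GTG"), "V"),
    (("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"), "S"),
    (("CCT", "CCC", "CCA", "CCG"), "P"),
    (("ACT", "ACC", "ACA", "ACG"), "T"),
    (("GCT", "GCC", "GCA", "GCG"), "A"),
    (("TAT", "TAC"), "Y"),
    (("TAA", "TAG", "TGA"), "*"),
    (("CAT", "CAC"), "H"),
    (("CAA", "CAG"), "Q"),
    (("AAT", "AAC"), "N"),
    (("AAA", "AAG"), "K"),
    (("GAT", "GAC"), "D"),
    (("GAA", "GAG"), "E"),
    (("TGT", "TGC"), "C"),
    (("TGG",), "W"),
    (("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"), "R"),
    (("GGT", "GGC", "GGA", "GGG"), "G"),
]:
    for _c in _codons:
        GENETIC_CODE[_c] = _aa
assert len(GENETIC_CODE) == 64


def naive_containing(intervals, pos):
    """O(n) containment scan over (start, end) 1-based inclusive pairs."""
    return [i for i, (s, e) in enumerate(intervals) if s <= pos <= e]


def naive_nearest(intervals, pos):
    """O(n) nearest-with-ties scan; returns (min distance, index list)."""
    best, hits = None, []
    for i, (s, e) in enumerate(intervals):
        if s <= pos <= e:
            continue
        d = min(abs(pos - s), abs(pos - e))
        if best is None or d < best:
            best, hits = d, [i]
        elif d == best:
            hits.append(i)
    return best, hits


def naive_stop_counts(seq, stops=("TAA", "TAG", "TGA")):
    """Per-frame internal-stop counts (terminal flush stop excluded)."""
    counts = []
    for f in range(3):
        n = 0
        i = f
        while i + 3 <= len(seq):
            if seq[i : i + 3] in stops and i + 3 != len(seq):
                n += 1
            i += 3
        counts.append(n)
    return counts


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Default-sized synthetic fixture spanning every annotation path."""
    return generate_fixture(FixtureSpec(seed=11), tmp_path_factory.mktemp("fx-small"))


@pytest.fixture(scope="session")
def small_run(small_fixture):
    """(fixture, rows, warnings) from a full pipeline run on small_fixture."""
    rows, warnings = annotate_files(
        small_fixture.snp_path,
        small_fixture.fasta_path,
        small_fixture.gtf_path,
        crossref_path=small_fixture.crossref_path,
    )
    return small_fixture, rows, warnings
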