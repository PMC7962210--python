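"""NUMT discovery: doubled query, unique-hit compression, blocks, coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from numtforge.core_io import GenomeSequence, HomologyHit, Interval, ReadAlignment
from numtforge.numt import (
    CircularUnit, NumtFragment, build_doubled_query, classify_mt_reads,
    compress_unique, count_spanning_reads, filter_hits, merge_blocks,
    mtdna_coverage, wrap_to_unit,
)


def make_hit(s_id="chr1", s_start=0, s_end=100, q_start=0, q_end=None,
             bitscore=100.0, evalue=1e-50, strand="+"):
    if q_end is None:
        q_end = q_start + (s_end - s_start)
    return HomologyHit(query_id="mt_x2", q_start=q_start, q_end=q_end,
                       s_id=s_id, s_start=s_start, s_end=s_end,
                       strand=strand, bitscore=bitscore, evalue=evalue)


def frag(seq_id, start, end):
    return NumtFragment(genomic=Interval(seq_id, start, end),
                        mt_segments=[(0, end - start)], strand="+")


class TestDoubledQuery:
    def test_doubling(self):
        mt = GenomeSequence("mt", "ACGTACGTAC", circular=True)
        doubled, unit = build_doubled_query(mt)
        assert doubled.length == 20
        assert unit.unit_length == 10 and unit.doubled_length == 20
        L = unit.unit_length
        assert all(doubled.residues[i] == doubled.residues[i + L] for i in range(L))

    def test_non_circular_rejected(self):
        with pytest.raises(ValueError):
            build_doubled_query(GenomeSequence("mt", "ACGT", circular=False))


class TestWrapToUnit:
    UNIT = CircularUnit("mt", 16761)

    @pytest.mark.parametrize("interval, expected", [
        ((10, 100), [(10, 100)]),                       # identity
        ((16771, 16861), [(10, 100)]),                  # modular shift by L
        ((16711, 16791), [(16711, 16761), (0, 30)]),    # origin-spanning split
    ])
    def test_examples(self, interval, expected):
        assert wrap_to_unit(*interval, self.UNIT) == expected

    @pytest.mark.parametrize("interval", [(-1, 10), (0, 20000), (33000, 34000)])
    def test_domain_errors(self, interval):
        with pytest.raises(ValueError):
            wrap_to_unit(*interval, self.UNIT)

    @given(st.integers(0, 2 * 16761 - 1), st.integers(1, 16761))
    @settings(max_examples=200, deadline=None)
    def test_length_conserved_and_positions_mod_L(self, start, length):
        L = self.UNIT.unit_length
        end = start + length
        if end > 2 * L:
            end = 2 * L
        segments = wrap_to_unit(start, end, self.UNIT)
        assert sum(b - a for a, b in segments) == end - start
        # concatenated segments reproduce the input positions mod L
        positions = [p for a, b in segments for p in range(a, b)]
        assert positions == [(p % L) for p in range(start, end)]


class TestFilterHits:
    def test_strict_cutoff(self):
        hits = [make_hit(evalue=e) for e in (1e-5, 1e-3, 1e-4, 0.0, 5e-5)]
        kept = filter_hits(hits, max_evalue=1e-4)
        assert [h.evalue for h in kept] == [1e-5, 0.0, 5e-5]


class TestCompressUnique:
    def test_single_hit_identity(self):
        (fragment,) = compress_unique([make_hit(s_start=10, s_end=200)])
        assert (fragment.genomic.start, fragment.genomic.end) == (10, 200)

    def test_overlap_trimmed_to_best(self):
        # A (score 100) keeps [0,500); B (score 90) is trimmed to [500,900)
        hits = [make_hit(s_start=0, s_end=500, bitscore=100),
                make_hit(s_start=400, s_end=900, q_start=1000, bitscore=90)]
        fragments = compress_unique(hits)
        spans = [(f.genomic.start, f.genomic.end) for f in fragments]
        assert spans == [(0, 500), (500, 900)]

    def test_doubled_query_duplicates_collapse(self):
        L = 16761
        hits = [make_hit(s_start=100, s_end=400, q_start=50),
                make_hit(s_start=100, s_end=400, q_start=50 + L)]
        fragments = compress_unique(hits, unit=CircularUnit("mt", L))
        assert len(fragments) == 1
        assert fragments[0].mt_segments == [(50, 350)]

    def test_short_trim_residue_discarded(self):
        hits = [make_hit(s_start=0, s_end=500, bitscore=100),
                make_hit(s_start=490, s_end=520, q_start=600, bitscore=50)]
        fragments = compress_unique(hits, min_frag=25)
        assert [(f.genomic.start, f.genomic.end) for f in fragments] == [(0, 500)]

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(ValueError, match="unknown scaffold"):
            compress_unique([make_hit(s_id="nope")], known_seqs={"chr1"})

    def test_matches_per_base_best_hit_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            hits = []
            for _h in range(int(rng.integers(2, 12))):
                start = int(rng.integers(0, 1900))
                end = start + int(rng.integers(30, 400))
                hits.append(make_hit(s_start=start, s_end=min(end, 2000),
                                     q_start=int(rng.integers(0, 5000)),
                                     bitscore=float(rng.integers(10, 200))))
            got = {(f.genomic.start, f.genomic.end)
                   for f in compress_unique(hits, min_frag=1)}
            assert got == per_base_oracle(hits)


def per_base_oracle(hits, genome_len=3000):
    """Assign each base to its best covering hit; fragments = equal-winner runs."""
    order = sorted(
        range(len(hits)),
        key=lambda i: (-hits[i].bitscore, -hits[i].s_len, hits[i].s_id,
                       hits[i].s_start, hits[i].q_start, i),
    )
    rank = {idx: r for r, idx in enumerate(order)}
    winner = np.full(genome_len, -1)
    best_rank = np.full(genome_len, len(hits) + 1)
    for idx, hit in enumerate(hits):
        sl = slice(hit.s_start, hit.s_end)
        better = rank[idx] < best_rank[sl]
        winner[sl] = np.where(better, idx, winner[sl])
        best_rank[sl] = np.where(better, rank[idx], best_rank[sl])
    fragments = set()
    pos = 0
    while pos < genome_len:
        if winner[pos] == -1:
            pos += 1
            continue
        start = pos
        while pos < genome_len and winner[pos] == winner[start]:
            pos += 1
        fragments.add((start, pos))
    return fragments


class TestMergeBlocks:
    def test_gap_at_and_beyond_threshold(self):
        fragments = [frag("chr1", 0, 100), frag("chr1", 5000, 5100)]
        (block,) = merge_blocks(fragments, merge_gap=8000)
        assert (block.span.start, block.span.end) == (0, 5100)
        far = [frag("chr1", 0, 100), frag("chr1", 8101, 8200)]  # gap 8001
        assert len(merge_blocks(far, merge_gap=8000)) == 2
        at = [frag("chr1", 0, 100), frag("chr1", 8100, 8200)]  # gap exactly 8000
        assert len(merge_blocks(at, merge_gap=8000)) == 1

    def test_transitive_and_scaffold_bounded(self):
        fragments = [frag("chr1", 0, 100), frag("chr1", 7000, 7100),
                     frag("chr1", 14000, 14100), frag("chr2", 0, 100)]
        blocks = merge_blocks(fragments, merge_gap=8000)
        assert [len(b.member_fragments) for b in blocks] == [3, 1]
        # every fragment lands in exactly one block
        assert sum(len(b.member_fragments) for b in blocks) == len(fragments)
        assert all(b.block_length >= b.summed_fragment_length for b in blocks)

    def test_unsorted_input_tolerated(self):
        fragments = [frag("chr1", 5000, 5100), frag("chr1", 0, 100)]
        (block,) = merge_blocks(fragments)
        assert block.span.start == 0


class TestMtdnaCoverage:
    def test_full_length_fragment(self):
        unit = CircularUnit("mt", 1000)
        fragment = NumtFragment(genomic=Interval("chr1", 0, 1000),
                                mt_segments=[(0, 1000)], strand="+")
        coverage, copies = mtdna_coverage([fragment], unit)
        assert (coverage == 1).all() and copies == 1.0

    def test_copy_equivalent_rounding(self):
        # fragments totalling 190.5 kb over a 16,761 bp unit -> 11.4 copies
        unit = CircularUnit("mt", 16761)
        fragments = [NumtFragment(genomic=Interval("chr1", i * 20000, i * 20000 + 10000),
                                  mt_segments=[(0, 10000)], strand="+")
                     for i in range(19)]
        fragments.append(NumtFragment(genomic=Interval("chr2", 0, 500),
                                      mt_segments=[(0, 500)], strand="+"))
        _, copies = mtdna_coverage(fragments, unit)
        assert copies == 11.4

    def test_no_fragments(self):
        coverage, copies = mtdna_coverage([], CircularUnit("mt", 100))
        assert coverage.sum() == 0 and copies == 0.0


class TestSpanningReads:
    FRAGMENT = NumtFragment(genomic=Interval("chr1", 4000, 4100),
                            mt_segments=[(0, 100)], strand="+")

    def test_flank_coverage_rules(self):
        wide = [ReadAlignment("r1", 10000, "chr1", 0, 10000)]
        assert count_spanning_reads(wide, self.FRAGMENT, 1000, 50000) == 1
        tight = [ReadAlignment("r2", 200, "chr1", 3950, 4150)]
        assert count_spanning_reads(tight, self.FRAGMENT, 100, 50000) == 0
        assert count_spanning_reads(tight, self.FRAGMENT, 0, 50000) == 1

    def test_flank_truncation_at_scaffold_end(self):
        near_end = NumtFragment(genomic=Interval("chr1", 9900, 9950),
                                mt_segments=[(0, 50)], strand="+")
        reads = [ReadAlignment("r", 6000, "chr1", 4000, 10000)]
        # 5 kb right flank is impossible on a 10 kb scaffold but truncates
        assert count_spanning_reads(reads, near_end, 5000, 10000) == 1

    def test_monotone_in_flank_vs_bruteforce(self):
        rng = np.random.default_rng(7)
        reads = [ReadAlignment(f"r{i}", 0, "chr1",
                               int(start), int(start) + int(rng.integers(200, 12000)))
                 for i, start in enumerate(rng.integers(0, 40000, size=20))]
        previous = None
        for flank in (0, 100, 1000, 5000):
            count = count_spanning_reads(reads, self.FRAGMENT, flank, 50000)
            brute = sum(
                1 for r in reads
                if r.start <= max(0, 4000 - flank) and r.end >= min(50000, 4100 + flank)
            )
            assert count == brute
            if previous is not None:
                assert count <= previous
            previous = count


class TestClassifyMtReads:
    UNIT = CircularUnit("mt", 16761)

    def _hit(self, read_id, q_start, q_end, s_start, s_end):
        return HomologyHit(query_id=read_id, q_start=q_start, q_end=q_end,
                           s_id="mt_x2", s_start=s_start, s_end=s_end)

    def test_three_way_classification(self):
        L = self.UNIT.unit_length
        hits = [
            self._hit("full", 0, 16500, 100, 16600 + 200),   # covers ~99.6% of unit
            self._hit("short", 0, 2000, 0, 2000),            # fully aligned 2 kb read
            self._hit("half", 0, 5000, 0, 5000),             # half-aligned read
        ]
        lengths = {"full": 16500, "short": 2000, "half": 10000, "nohit": 3000}
        out = classify_mt_reads(hits, lengths, self.UNIT)
        assert out == {"full": "pure_complete", "short": "partial",
                       "half": "non_mt", "nohit": "non_mt"}
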