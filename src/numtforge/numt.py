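"""Nuclear mitochondrial DNA (NUMT) fragment discovery and block merging.

NUMTs are fragments of the mitochondrial genome inserted into nuclear
chromosomes. Because mtDNA is circular, a NUMT may derive from a segment
spanning the replication origin; searching against a doubled (two tandem
copies) mtDNA query makes such insertions appear as a single contiguous hit.
The pipeline is: homology search upstream (blastn/minimap2), e-value filter,
compression of overlapping hits to unique genomic fragments, merging of
nearby fragments into blocks, and quantification of mtDNA-unit coverage and
long-read spanning support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GenomeSequence, HomologyHit, Interval, ReadAlignment

DEFAULT_MAX_EVALUE = 1e-4
DEFAULT_MERGE_GAP = 8000
DEFAULT_MIN_FRAG = 25
DEFAULT_FLANKS = (0, 100, 1000, 5000)


@dataclass
class CircularUnit:
    """The circular mtDNA unit underlying a doubled search query."""

    mt_id: str
    unit_length: int

    @property
    def doubled_length(self) -> int:
        return 2 * self.unit_length


@dataclass
class NumtFragment:
    """One unique genomic NUMT interval with its mtDNA-unit segment(s)."""

    genomic: Interval
    mt_segments: list[tuple[int, int]]  # intervals on [0, L) of the unit
    strand: str
    source_hits: list[int] = field(default_factory=list)
    span_support: dict[int, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.genomic.length


@dataclass
class NumtBlock:
    """Fragments on one scaffold separated by at most merge_gap bases."""

    seq_id: str
    span: Interval
    member_fragments: list[NumtFragment]

    @property
    def block_length(self) -> int:
        return self.span.length

    @property
    def summed_fragment_length(self) -> int:
        return sum(f.length for f in self.member_fragments)


def build_doubled_query(mtdna: GenomeSequence) -> tuple[GenomeSequence, CircularUnit]:
    """Concatenate a circular mtDNA with itself to form the search query."""
    if not mtdna.circular:
        raise ValueError(f"mtDNA sequence {mtdna.id!r} is not marked circular")
    doubled = GenomeSequence(
        id=f"{mtdna.id}_x2", residues=mtdna.residues * 2, circular=False
    )
    return doubled, CircularUnit(mt_id=mtdna.id, unit_length=mtdna.length)


def filter_hits(hits: list[HomologyHit], max_evalue: float = DEFAULT_MAX_EVALUE) -> list[HomologyHit]:
    """Keep hits with e-value strictly below the cutoff."""
    return [h for h in hits if h.evalue < max_evalue]


def wrap_to_unit(q_start: int, q_end: int, unit: CircularUnit) -> list[tuple[int, int]]:
    """Map an interval on the doubled query back onto the circular unit [0, L).

    Returns one interval, or two when the input crosses position L (an
    origin-spanning segment splits into a suffix [x, L) and prefix [0, y)).
    Total output length always equals the input length.
    """
    L = unit.unit_length
    if not (0 <= q_start < q_end <= 2 * L):
        raise ValueError(f"interval [{q_start},{q_end}) outside doubled query [0,{2 * L})")
    if q_end - q_start > L:
        raise ValueError("interval longer than the circular unit")
    if q_start >= L:
        return [(q_start - L, q_end - L)]
    if q_end <= L:
        return [(q_start, q_end)]
    return [(q_start, L), (0, q_end - L)]


def _hit_priority(indexed_hit: tuple[int, HomologyHit]):
    """Greedy acceptance order: bitscore desc, subject length desc, then
    ascending (s_id, s_start, q_start) for determinism."""
    i, h = indexed_hit
    return (-h.bitscore, -h.s_len, h.s_id, h.s_start, h.q_start, i)


def _project_query(hit: HomologyHit, sub_start: int, sub_end: int) -> tuple[int, int]:
    """Project a genomic sub-interval of a hit back onto its query interval,
    scaling proportionally (exact for ungapped hits)."""
    scale = hit.q_len / hit.s_len
    if hit.strand == "+":
        q0 = hit.q_start + int(round((sub_start - hit.s_start) * scale))
        q1 = hit.q_start + int(round((sub_end - hit.s_start) * scale))
    else:
        q0 = hit.q_start + int(round((hit.s_end - sub_end) * scale))
        q1 = hit.q_start + int(round((hit.s_end - sub_start) * scale))
    return max(hit.q_start, q0), min(hit.q_end, max(q1, q0 + 1))


def compress_unique(
    hits: list[HomologyHit],
    unit: CircularUnit | None = None,
    min_frag: int = DEFAULT_MIN_FRAG,
    known_seqs: set[str] | None = None,
) -> list[NumtFragment]:
    """Compress overlapping hits to unique, non-overlapping genomic fragments.

    Hits are accepted greedily in priority order; each accepted hit is trimmed
    on the subject (genomic) side against previously accepted fragments, the
    query side shrinking proportionally. Trimmed pieces shorter than
    ``min_frag`` are discarded. Duplicate hits produced by a doubled circular
    query collapse onto one fragment. Equivalent to a per-base best-hit-wins
    assignment at min_frag=1.
    """
    if known_seqs is not None:
        unknown = {h.s_id for h in hits} - known_seqs
        if unknown:
            raise ValueError(f"hits reference unknown scaffolds: {sorted(unknown)}")
    accepted: dict[str, list[tuple[int, int]]] = {}  # seq_id -> sorted occupied intervals
    fragments: list[NumtFragment] = []
    for idx, hit in sorted(enumerate(hits), key=_hit_priority):
        occupied = accepted.setdefault(hit.s_id, [])
        for sub_start, sub_end in _subtract(hit.s_start, hit.s_end, occupied):
            if sub_end - sub_start < min_frag:
                continue
            q0, q1 = _project_query(hit, sub_start, sub_end)
            mt_segments = wrap_to_unit(q0, q1, unit) if unit is not None else []
            fragments.append(NumtFragment(
                genomic=Interval(hit.s_id, sub_start, sub_end, hit.strand),
                mt_segments=mt_segments,
                strand=hit.strand,
                source_hits=[idx],
            ))
            _insert(occupied, sub_start, sub_end)
    fragments.sort(key=lambda f: (f.genomic.seq_id, f.genomic.start))
    return fragments


def _subtract(start: int, end: int, occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sub-intervals of [start, end) not covered by the sorted occupied list."""
    pieces = []
    cursor = start
    for o_start, o_end in occupied:
        if o_end <= cursor:
            continue
        if o_start >= end:
            break
        if o_start > cursor:
            pieces.append((cursor, o_start))
        cursor = max(cursor, o_end)
        if cursor >= end:
            break
    if cursor < end:
        pieces.append((cursor, end))
    return pieces


def _insert(occupied: list[tuple[int, int]], start: int, end: int) -> None:
    import bisect

    bisect.insort(occupied, (start, end))


def merge_blocks(fragments: list[NumtFragment], merge_gap: int = DEFAULT_MERGE_GAP) -> list[NumtBlock]:
    """Merge fragments on the same scaffold with inter-fragment gap <= merge_gap.

    Merging is transitive and strand-agnostic; blocks never span scaffolds.
    """
    frags = sorted(fragments, key=lambda f: (f.genomic.seq_id, f.genomic.start))
    blocks: list[NumtBlock] = []
    current: list[NumtFragment] = []
    for frag in frags:
        if current and (
            frag.genomic.seq_id == current[-1].genomic.seq_id
            and frag.genomic.start - current[-1].genomic.end <= merge_gap
        ):
            current.append(frag)
        else:
            if current:
                blocks.append(_close_block(current))
            current = [frag]
    if current:
        blocks.append(_close_block(current))
    return blocks


def _close_block(members: list[NumtFragment]) -> NumtBlock:
    seq_id = members[0].genomic.seq_id
    return NumtBlock(
        seq_id=seq_id,
        span=Interval(seq_id, members[0].genomic.start, members[-1].genomic.end),
        member_fragments=list(members),
    )


def mtdna_coverage(fragments: list[NumtFragment], unit: CircularUnit) -> tuple[np.ndarray, float]:
    """Per-base coverage of the mtDNA unit by fragment mt-segments, plus the
    genome-wide mtDNA copy equivalent (total fragment bp / unit length, 1 dp)."""
    coverage = np.zeros(unit.unit_length, dtype=np.int64)
    total_bp = 0
    for frag in fragments:
        total_bp += frag.length
        for seg_start, seg_end in frag.mt_segments:
            coverage[seg_start:seg_end] += 1
    copies_equivalent = round(total_bp / unit.unit_length, 1)
    return coverage, copies_equivalent


def count_spanning_reads(
    read_alignments: list[ReadAlignment],
    fragment: NumtFragment,
    flank: int,
    scaffold_length: int,
) -> int:
    """Count reads whose alignment covers the fragment plus a flank each side.

    The flank is truncated at scaffold boundaries, so a fragment close to a
    scaffold end can still gain support from reads reaching the end.
    """
    left = max(0, fragment.genomic.start - flank)
    right = min(scaffold_length, fragment.genomic.end + flank)
    n = 0
    for read in read_alignments:
        if read.seq_id != fragment.genomic.seq_id:
            continue
        if read.start <= left and read.end >= right:
            n += 1
    return n


def attach_span_support(
    fragments: list[NumtFragment],
    read_alignments: list[ReadAlignment],
    scaffold_lengths: dict[str, int],
    flanks: tuple[int, ...] = DEFAULT_FLANKS,
) -> None:
    """Populate span_support for each fragment at each requested flank."""
    by_seq: dict[str, list[ReadAlignment]] = {}
    for read in read_alignments:
        by_seq.setdefault(read.seq_id, []).append(read)
    for frag in fragments:
        reads = by_seq.get(frag.genomic.seq_id, [])
        for flank in flanks:
            frag.span_support[flank] = count_spanning_reads(
                reads, frag, flank, scaffold_lengths[frag.genomic.seq_id]
            )


def classify_mt_reads(
    read_hits: list[HomologyHit],
    read_lengths: dict[str, int],
    unit: CircularUnit,
    min_fraction: float = 0.99,
) -> dict[str, str]:
    """Classify reads by mtDNA content from their hits against the doubled unit.

    pure_complete: >= 99% of the read aligns to mtDNA AND the union of its
    subject segments covers >= 99% of the unit (suitable for contamination-free
    mitochondrial assembly). partial: only the read-length criterion holds.
    non_mt: otherwise.
    """
    per_read_q: dict[str, list[tuple[int, int]]] = {}
    per_read_mt: dict[str, np.ndarray] = {}
    L = unit.unit_length
    for hit in read_hits:
        per_read_q.setdefault(hit.query_id, []).append((hit.q_start, hit.q_end))
        mask = per_read_mt.setdefault(hit.query_id, np.zeros(L, dtype=bool))
        for seg_start, seg_end in wrap_to_unit(hit.s_start, min(hit.s_end, hit.s_start + L), unit):
            mask[seg_start:seg_end] = True
    result = {}
    for read_id, length in read_lengths.items():
        q_intervals = per_read_q.get(read_id, [])
        aligned = _union_length(q_intervals)
        read_frac = aligned / length if length else 0.0
        mt_frac = per_read_mt[read_id].mean() if read_id in per_read_mt else 0.0
        if read_frac >= min_fraction and mt_frac >= min_fraction:
            result[read_id] = "pure_complete"
        elif read_frac >= min_fraction:
            result[read_id] = "partial"
        else:
            result[read_id] = "non_mt"
    return result


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cursor = None
    for start, end in sorted(intervals):
        if cursor is None or start > cursor:
            total += end - start
            cursor = end
        elif end > cursor:
            total += end - cursor
            cursor = end
    return total
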