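"""Shared coordinate/data model and parsers for every external format.

Internal convention: all coordinates are 0-based half-open. Conversion to and
from 1-based inclusive formats (BLAST tabular, BUSCO full tables, VCF, GFF3)
happens only at parse/write boundaries.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger("numtforge")

# Bases kept verbatim on ingestion; every other (IUPAC ambiguity) code -> N.
_CANONICAL = frozenset("ACGTN")

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenomeSequence:
    """A single assembly scaffold or organelle sequence."""

    id: str
    residues: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.seq_id}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class HomologyHit:
    """One local alignment between a query and a subject sequence."""

    query_id: str
    q_start: int
    q_end: int
    s_id: str
    s_start: int
    s_end: int
    strand: str = "+"
    bitscore: float = 0.0
    evalue: float = 0.0
    identity_pct: float = 100.0

    def __post_init__(self):
        if self.q_end <= self.q_start or self.s_end <= self.s_start:
            raise ValueError("hit intervals must be non-empty")
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity outside [0, 100]")

    @property
    def s_len(self) -> int:
        return self.s_end - self.s_start

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start


@dataclass
class ReadAlignment:
    """Genomic footprint of one aligned read (PAF-derived)."""

    read_id: str
    read_len: int
    seq_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class DepthTrack:
    """Per-base read depth with a mask of assembly-gap (N) positions."""

    depth: dict[str, np.ndarray]
    gap_mask: dict[str, np.ndarray]

    def region_values(self, region: Interval, exclude_gaps: bool = True) -> np.ndarray:
        arr = self.depth[region.seq_id][region.start:region.end]
        if exclude_gaps:
            mask = self.gap_mask[region.seq_id][region.start:region.end]
            arr = arr[~mask]
        return arr

    def mean_depth(self, region: Interval, exclude_gaps: bool = True) -> float:
        vals = self.region_values(region, exclude_gaps=exclude_gaps)
        if vals.size == 0:
            raise ValueError(f"region {region.seq_id}:{region.start}-{region.end} has no non-gap bases")
        return float(vals.mean())

    def genome_mean(self, exclude_gaps: bool = True) -> float:
        total = 0.0
        n = 0
        for seq_id, arr in self.depth.items():
            if exclude_gaps:
                arr = arr[~self.gap_mask[seq_id]]
            total += float(arr.sum())
            n += arr.size
        if n == 0:
            raise ValueError("empty depth track")
        return total / n


@dataclass
class BuscoGene:
    busco_id: str
    status: str  # Complete, Duplicated, Fragmented, Missing
    location: Interval | None = None
    on_excluded_seq: bool = False


@dataclass
class SVRecord:
    """Structural variant normalised from a long-read caller VCF.

    sv_len is always a positive magnitude; for insertions the location is a
    1 bp breakpoint interval.
    """

    sv_type: str  # DEL, INS, INV, DUP, BND
    location: Interval
    sv_len: int
    sample_id: str = ""
    source_platform: str = "other"  # ONT, SMRT, other
    record_id: str = ""

    def __post_init__(self):
        if self.sv_type != "BND" and self.sv_len <= 0:
            raise ValueError("sv_len must be positive")


@dataclass
class GeneModel:
    gene_id: str
    span: Interval
    exons: list[Interval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, circular: bool = False) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records.

    Residues are uppercased and IUPAC ambiguity codes mapped to N; the number
    of converted bases is logged. Duplicate ids and empty files are errors.
    """
    records = []
    seen: set[str] = set()
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not set(residues) <= _CANONICAL:
            cleaned = "".join(c if c in _CANONICAL else "N" for c in residues)
            n_ambiguous += sum(1 for a, b in zip(residues, cleaned) if a != b)
            residues = cleaned
        records.append(GenomeSequence(id=rec.id, residues=residues, circular=circular))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if n_ambiguous:
        logger.info("mapped %d ambiguity bases to N while reading %s", n_ambiguous, path)
    return records


def write_fasta(seqs: list[GenomeSequence], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.length, width):
                fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Homology hit tables (BLAST outfmt 6 and PAF)
# ---------------------------------------------------------------------------

def read_hits(path: str | os.PathLike, dialect: str = "blast6") -> list[HomologyHit]:
    """Parse a homology hit table.

    blast6: 1-based inclusive coordinates converted to 0-based half-open;
    hits with sstart > send stored on strand '-' with coordinates swapped.
    paf: coordinates are already 0-based half-open; strand from column 5.
    """
    if dialect not in ("blast6", "paf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "blast6":
                    hits.append(_parse_blast6(fields, lineno))
                else:
                    hits.append(_parse_paf(fields, lineno))
            except (ValueError, IndexError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return hits


def _parse_blast6(fields: list[str], lineno: int) -> HomologyHit:
    if len(fields) < 12:
        raise FormatError(f"line {lineno}: expected 12 blast6 columns, got {len(fields)}")
    (qseqid, sseqid, pident, _length, _mm, _go,
     qstart, qend, sstart, send, evalue, bitscore) = fields[:12]
    qstart, qend, sstart, send = int(qstart), int(qend), int(sstart), int(send)
    strand = "+"
    if sstart > send:
        sstart, send = send, sstart
        strand = "-"
    return HomologyHit(
        query_id=qseqid, q_start=qstart - 1, q_end=qend,
        s_id=sseqid, s_start=sstart - 1, s_end=send,
        strand=strand, bitscore=float(bitscore), evalue=float(evalue),
        identity_pct=float(pident),
    )


def _parse_paf(fields: list[str], lineno: int) -> HomologyHit:
    if len(fields) < 12:
        raise FormatError(f"line {lineno}: expected >= 12 PAF columns, got {len(fields)}")
    qname, _qlen, qstart, qend, strand, tname, _tlen, tstart, tend, nmatch, blocklen, _mapq = fields[:12]
    blocklen = int(blocklen)
    nmatch = int(nmatch)
    return HomologyHit(
        query_id=qname, q_start=int(qstart), q_end=int(qend),
        s_id=tname, s_start=int(tstart), s_end=int(tend),
        strand=strand,
        # PAF has no bitscore; alignment block length is the score surrogate.
        bitscore=float(blocklen),
        evalue=0.0,
        identity_pct=100.0 * nmatch / blocklen if blocklen else 0.0,
    )


def write_hits_blast6(hits: list[HomologyHit], path: str | os.PathLike) -> None:
    """Write hits back to the 12-column blast6 dialect (inverse of read_hits)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BLAST6_COLUMNS) + "\n")
        for h in hits:
            if h.strand == "-":
                sstart, send = h.s_end, h.s_start + 1
            else:
                sstart, send = h.s_start + 1, h.s_end
            fh.write("\t".join(map(str, [
                h.query_id, h.s_id, h.identity_pct, h.s_len, 0, 0,
                h.q_start + 1, h.q_end, sstart, send, h.evalue, h.bitscore,
            ])) + "\n")


def read_paf_reads(path: str | os.PathLike) -> list[ReadAlignment]:
    """Parse PAF lines into per-read genomic footprints."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path} line {lineno}: expected >= 12 PAF columns")
            reads.append(ReadAlignment(
                read_id=fields[0], read_len=int(fields[1]),
                seq_id=fields[5], start=int(fields[7]), end=int(fields[8]),
                strand=fields[4],
            ))
    return reads


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

def _gap_mask_from(assembly: list[GenomeSequence]) -> dict[str, np.ndarray]:
    return {
        s.id: np.frombuffer(s.residues.encode(), dtype=np.uint8) == ord("N")
        for s in assembly
    }


def read_depth(path: str | os.PathLike, assembly: list[GenomeSequence]) -> DepthTrack:
    """Read per-base depth from a 3-column TSV (1-based pos) or 4-column bedGraph.

    Positions absent from the file get depth 0. Overlapping bedGraph runs,
    positions beyond the sequence length, and negative depths are errors.
    """
    lengths = {s.id: s.length for s in assembly}
    depth = {s.id: np.zeros(s.length, dtype=np.int64) for s in assembly}
    written = {s.id: np.zeros(s.length, dtype=bool) for s in assembly}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                seq_id, pos, value = fields[0], int(fields[1]), int(fields[2])
                start, end = pos - 1, pos  # 1-based position
            elif len(fields) == 4:
                seq_id, start, end, value = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
            else:
                raise FormatError(f"{path} line {lineno}: expected 3 or 4 columns")
            if seq_id not in lengths:
                raise FormatError(f"{path} line {lineno}: unknown sequence {seq_id!r}")
            if value < 0:
                raise FormatError(f"{path} line {lineno}: negative depth")
            if start < 0 or end > lengths[seq_id] or start >= end:
                raise FormatError(
                    f"{path} line {lineno}: interval [{start},{end}) outside {seq_id} "
                    f"(length {lengths[seq_id]})"
                )
            if written[seq_id][start:end].any():
                raise FormatError(f"{path} line {lineno}: overlapping depth runs")
            depth[seq_id][start:end] = value
            written[seq_id][start:end] = True
    return DepthTrack(depth=depth, gap_mask=_gap_mask_from(assembly))


def write_depth_bedgraph(track: DepthTrack, path: str | os.PathLike) -> None:
    """Write a depth track as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        fh.write("#seq\tstart\tend\tdepth\n")
        for seq_id in track.depth:
            arr = track.depth[seq_id]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{seq_id}\t{s}\t{e}\t{arr[s]}\n")


# ---------------------------------------------------------------------------
# BUSCO v3 full table
# ---------------------------------------------------------------------------

def read_busco_table(path: str | os.PathLike, exclude_seqs: list[str] | None = None) -> list[BuscoGene]:
    """Parse a BUSCO v3 full_table TSV.

    Complete/Duplicated/Fragmented entries carry 1-based inclusive coordinates
    converted to internal intervals; entries on `exclude_seqs` are flagged.
    """
    exclude = set(exclude_seqs or [])
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path} line {lineno}: expected >= 2 columns")
            busco_id, status = fields[0], fields[1]
            location = None
            excluded = False
            if status != "Missing":
                if len(fields) < 5:
                    raise FormatError(
                        f"{path} line {lineno}: {status} row lacks coordinate columns"
                    )
                seq_id, start, end = fields[2], int(fields[3]), int(fields[4])
                if end < start:  # some BUSCO versions emit strand-flipped coords
                    start, end = end, start
                location = Interval(seq_id, start - 1, end)
                excluded = seq_id in exclude
            genes.append(BuscoGene(busco_id=busco_id, status=status,
                                   location=location, on_excluded_seq=excluded))
    return genes


# ---------------------------------------------------------------------------
# Structural variant VCF (long-read caller dialect: SVTYPE/SVLEN/END)
# ---------------------------------------------------------------------------

def read_sv_vcf(path: str | os.PathLike, sample_id: str = "",
                platform: str = "other") -> list[SVRecord]:
    """Read SVs from a VCF using SVTYPE/SVLEN/END INFO keys.

    SVLEN magnitude is used; a missing END for DEL/INV/DUP is reconstructed
    as POS + |SVLEN|. Records lacking both END and SVLEN are skipped with a
    logged warning count.
    """
    records = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            sv_type = info.get("SVTYPE")
            if sv_type is None:
                n_skipped += 1
                continue
            svlen = info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            # trust an explicit END; otherwise reconstruct from SVLEN below
            end = rec.stop if "END" in info else None
            pos0 = rec.pos - 1
            if sv_type == "BND":
                records.append(SVRecord(
                    sv_type="BND",
                    location=Interval(rec.chrom, pos0, pos0 + 1),
                    sv_len=0, sample_id=sample_id, source_platform=platform,
                    record_id=rec.id or "",
                ))
                continue
            if svlen is None and (end is None or end <= pos0 + 1):
                n_skipped += 1
                continue
            if sv_type == "INS":
                if svlen is None:
                    n_skipped += 1
                    continue
                location = Interval(rec.chrom, pos0, pos0 + 1)
                length = abs(int(svlen))
            else:
                if svlen is not None:
                    length = abs(int(svlen))
                    if end is None or end <= pos0 + 1:
                        end = pos0 + length
                else:
                    length = end - pos0
                location = Interval(rec.chrom, pos0, max(end, pos0 + 1))
            records.append(SVRecord(
                sv_type=sv_type, location=location, sv_len=length,
                sample_id=sample_id, source_platform=platform,
                record_id=rec.id or "",
            ))
    if n_skipped:
        logger.warning("skipped %d VCF records lacking SVTYPE/END/SVLEN in %s", n_skipped, path)
    return records


def write_sv_vcf(svs: list[SVRecord], contigs: dict[str, int],
                 path: str | os.PathLike) -> None:
    """Write SVs as a minimal VCF 4.2 with SVTYPE/SVLEN/END INFO keys."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, sv in enumerate(sorted(svs, key=lambda s: (s.location.seq_id, s.location.start))):
            rec = out.new_record(
                contig=sv.location.seq_id,
                start=sv.location.start,
                alleles=("N", f"<{sv.sv_type}>"),
                id=sv.record_id or f"sv{i}",
            )
            rec.info["SVTYPE"] = sv.sv_type
            rec.info["SVLEN"] = sv.sv_len if sv.sv_type != "DEL" else -sv.sv_len
            rec.stop = sv.location.end if sv.sv_type != "INS" else sv.location.start + 1
            out.write(rec)


# ---------------------------------------------------------------------------
# Gene models (GFF3 / BED6)
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models (gene spans + exons) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        span = Interval(g.seqid, g.start - 1, g.end, g.strand if g.strand in "+-" else ".")
        exons = [
            Interval(e.seqid, e.start - 1, e.end, e.strand if e.strand in "+-" else ".")
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(GeneModel(gene_id=g.id, span=span, exons=exons))
    return genes


def read_bed6(path: str | os.PathLike) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: expected >= 3 BED columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(Interval(fields[0], int(fields[1]), int(fields[2]), strand))
    return intervals


def write_bed6(intervals: list[tuple[Interval, str]], path: str | os.PathLike) -> None:
    """Write (interval, name) pairs as BED6 with score 0."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv, name in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
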