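"""Synthetic genomes with known truth for exercising every pipeline stage.

The generator plants, with exact recorded coordinates: NUMT copies of a
random circular mtDNA (including origin-spanning ones and clusters that
merge into known blocks), a tandem gene array whose true copy number exceeds
its assembled copy count, regions of known copy number, single-copy genes
standing in for BUSCO Complete genes, haplotig scaffolds duplicating primary
segments, and structural variants re-emitted as two jittered platform call
sets. Per-base depth is independent Poisson with a region-specific
copy-number multiplier. All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    DepthTrack, GenomeSequence, HomologyHit, Interval, ReadAlignment, SVRecord,
)
from .numt import CircularUnit, build_doubled_query

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_scaffolds: int = 4
    scaffold_len: int = 150_000
    mt_len: int = 16_700
    n_numts: int = 10
    numt_len_range: tuple[int, int] = (34, 6580)
    include_origin_spanning: bool = True
    n_tandem_gene_copies: int = 6
    assembled_gene_copies: int = 2
    gene_len: int = 2000
    base_depth: float = 30.0
    planted_cn: tuple[int, ...] = (1, 2, 3, 6)
    cn_region_len: int = 2000
    n_busco_genes: int = 200
    busco_gene_len: int = 1000
    n_haplotigs: int = 2
    haplotig_len: int = 20_000
    # sv_type -> (count, min_len, max_len)
    sv_spec: dict[str, tuple[int, int, int]] = field(default_factory=lambda: {
        "DEL": (15, 150, 3000),
        "INS": (10, 120, 1000),
        "INV": (4, 300, 2000),
        "DUP": (4, 300, 2000),
    })
    read_length: int = 12_000
    read_coverage: float = 20.0
    cluster_gap_range: tuple[int, int] = (500, 4000)   # intra-block NUMT gaps
    isolation_gap: int = 12_000                        # keeps blocks apart

    def validate(self) -> None:
        lo, hi = self.numt_len_range
        if not 25 <= lo <= hi <= self.mt_len:
            raise ValueError("numt_len_range must lie within [25, mt_len]")
        if self.assembled_gene_copies < 1 or self.n_tandem_gene_copies < 1:
            raise ValueError("gene copy counts must be positive")


@dataclass
class PlantedNumt:
    genomic: Interval
    mt_segments: list[tuple[int, int]]
    strand: str
    block_id: int


@dataclass
class TruthTable:
    numts: list[PlantedNumt] = field(default_factory=list)
    gene_array: list[Interval] = field(default_factory=list)
    gene_true_copies: int = 0
    cn_regions: list[tuple[Interval, float]] = field(default_factory=list)
    busco_genes: list[tuple[str, Interval]] = field(default_factory=list)
    haplotig_pairs: list[tuple[str, Interval]] = field(default_factory=list)
    svs: list[SVRecord] = field(default_factory=list)

    def block_partition(self) -> dict[int, list[Interval]]:
        blocks: dict[int, list[Interval]] = {}
        for numt in self.numts:
            blocks.setdefault(numt.block_id, []).append(numt.genomic)
        return blocks


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_genome(config: SimulationConfig,
                    ) -> tuple[list[GenomeSequence], GenomeSequence, TruthTable]:
    """Build the assembly, the circular mtDNA and the truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthTable(gene_true_copies=config.n_tandem_gene_copies)
    mt_res = _random_seq(rng, config.mt_len)
    mtdna = GenomeSequence(id="mt", residues=mt_res, circular=True)
    L = config.mt_len

    # --- plan the feature queue -------------------------------------------
    lo, hi = config.numt_len_range
    numt_lens = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_numts))
    numt_lens = numt_lens.astype(int).tolist()
    clusters: list[list[int]] = []
    i = 0
    while i < len(numt_lens):
        size = int(rng.integers(1, 4))
        clusters.append(numt_lens[i:i + size])
        i += size

    gene_seq = _random_seq(rng, config.gene_len)

    items: list[tuple[str, object]] = []
    for cluster in clusters:
        items.append(("numt_cluster", cluster))
    items.append(("gene_array", None))
    for cn in config.planted_cn:
        items.append(("cn_region", float(cn)))
    for b in range(config.n_busco_genes):
        items.append(("busco", b))

    # --- lay items onto scaffolds sequentially ----------------------------
    scaffolds: list[list[str]] = [[] for _ in range(config.n_scaffolds)]
    cursors = [0] * config.n_scaffolds
    scaffold_idx = 0
    origin_used = not config.include_origin_spanning
    block_counter = 0

    def _append(seq_i: int, piece: str) -> None:
        scaffolds[seq_i].append(piece)
        cursors[seq_i] += len(piece)

    def _item_length(kind: str, payload, rng_preview: np.random.Generator) -> int:
        if kind == "numt_cluster":
            gaps = (len(payload) - 1) * config.cluster_gap_range[1]
            return sum(payload) + gaps
        if kind == "gene_array":
            return config.assembled_gene_copies * (config.gene_len + 100)
        if kind == "cn_region":
            return config.cn_region_len
        return config.busco_gene_len

    for kind, payload in items:
        spacer = config.isolation_gap if kind == "numt_cluster" else 800
        needed = spacer + _item_length(kind, payload, rng) + config.isolation_gap
        while cursors[scaffold_idx] + needed > config.scaffold_len:
            pad = config.scaffold_len - cursors[scaffold_idx]
            if pad:
                _append(scaffold_idx, _random_seq(rng, pad))
            scaffold_idx += 1
            if scaffold_idx >= config.n_scaffolds:
                raise ValueError("planted features exceed scaffold bounds; "
                                 "increase n_scaffolds or scaffold_len")
        seq_id = f"chr{scaffold_idx + 1}"
        _append(scaffold_idx, _random_seq(rng, spacer))

        if kind == "numt_cluster":
            block_counter += 1
            for k, numt_len in enumerate(payload):
                if k > 0:
                    gap = int(rng.integers(*config.cluster_gap_range))
                    _append(scaffold_idx, _random_seq(rng, gap))
                if not origin_used:
                    # force one origin-spanning NUMT: segment crossing position L
                    left = max(1, min(numt_len - 1, numt_len // 2))
                    mt_start = L - left
                    origin_used = True
                else:
                    mt_start = int(rng.integers(0, L))
                segs = []
                if mt_start + numt_len <= L:
                    segs = [(mt_start, mt_start + numt_len)]
                    piece = mt_res[mt_start:mt_start + numt_len]
                else:
                    over = mt_start + numt_len - L
                    segs = [(mt_start, L), (0, over)]
                    piece = mt_res[mt_start:] + mt_res[:over]
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    piece = _revcomp(piece)
                start = cursors[scaffold_idx]
                _append(scaffold_idx, piece)
                truth.numts.append(PlantedNumt(
                    genomic=Interval(seq_id, start, start + numt_len, strand),
                    mt_segments=segs, strand=strand, block_id=block_counter,
                ))
        elif kind == "gene_array":
            for _c in range(config.assembled_gene_copies):
                start = cursors[scaffold_idx]
                _append(scaffold_idx, gene_seq)
                truth.gene_array.append(Interval(seq_id, start, start + config.gene_len))
                _append(scaffold_idx, _random_seq(rng, 100))
        elif kind == "cn_region":
            start = cursors[scaffold_idx]
            _append(scaffold_idx, _random_seq(rng, config.cn_region_len))
            truth.cn_regions.append(
                (Interval(seq_id, start, start + config.cn_region_len), payload))
        else:  # busco
            start = cursors[scaffold_idx]
            _append(scaffold_idx, _random_seq(rng, config.busco_gene_len))
            truth.busco_genes.append(
                (f"busco{payload:04d}", Interval(seq_id, start, start + config.busco_gene_len)))

    # pad out remaining scaffolds to full length
    for s in range(config.n_scaffolds):
        pad = config.scaffold_len - cursors[s]
        if pad:
            _append(s, _random_seq(rng, pad))

    assembly = [
        GenomeSequence(id=f"chr{s + 1}", residues="".join(parts))
        for s, parts in enumerate(scaffolds)
    ]

    # --- haplotigs: verbatim copies of primary segments at half depth -----
    occupied_by_numt = {
        (n.genomic.seq_id, n.genomic.start, n.genomic.end) for n in truth.numts
    }
    for h in range(config.n_haplotigs):
        primary = assembly[h % config.n_scaffolds]
        # avoid duplicating planted NUMTs so homology truth stays exact
        numt_ends = [n.genomic.end for n in truth.numts if n.genomic.seq_id == primary.id]
        floor = max(numt_ends) if numt_ends else 0
        span = min(config.haplotig_len, primary.length - floor - 1)
        if span < 1000:
            raise ValueError("no NUMT-free space left for haplotig duplication")
        offset = int(np.random.default_rng(config.seed + 7_000 + h).integers(
            floor, primary.length - span))
        region = Interval(primary.id, offset, offset + span)
        hap_id = f"hap{h + 1}"
        assembly.append(GenomeSequence(
            id=hap_id, residues=primary.residues[offset:offset + span]))
        truth.haplotig_pairs.append((hap_id, region))

    # --- structural variants (coordinates only) ---------------------------
    sv_rng = np.random.default_rng(config.seed + 11_000)
    sv_id = 0
    for sv_type, (count, min_len, max_len) in sorted(config.sv_spec.items()):
        for _k in range(count):
            scaf = assembly[sv_id % config.n_scaffolds]
            length = int(sv_rng.integers(min_len, max_len + 1))
            start = int(sv_rng.integers(2000, scaf.length - max_len - 2000))
            if sv_type == "INS":
                loc = Interval(scaf.id, start, start + 1)
            else:
                loc = Interval(scaf.id, start, start + length)
            truth.svs.append(SVRecord(
                sv_type=sv_type, location=loc, sv_len=length,
                sample_id="truth", record_id=f"planted{sv_id}",
            ))
            sv_id += 1
    truth.svs = _thin_overlapping(truth.svs)
    return assembly, mtdna, truth


def _thin_overlapping(svs: list[SVRecord], min_separation: int = 3000) -> list[SVRecord]:
    """Drop planted SVs too close to an earlier same-scaffold SV, so that
    platform jitter cannot create ambiguous cross-matches."""
    kept: list[SVRecord] = []
    for sv in sorted(svs, key=lambda s: (s.location.seq_id, s.location.start)):
        if kept and kept[-1].location.seq_id == sv.location.seq_id and \
                sv.location.start - kept[-1].location.end < min_separation:
            continue
        kept.append(sv)
    return kept


# ---------------------------------------------------------------------------
# Derived artefacts
# ---------------------------------------------------------------------------

def simulate_hits(truth: TruthTable, unit: CircularUnit,
                  add_decoys: int = 0, seed: int = 0) -> list[HomologyHit]:
    """Exact-coordinate hits for each planted NUMT against the doubled query.

    Each non-origin-spanning NUMT also gets the duplicate hit offset by the
    unit length (the doubling artifact the compressor must collapse);
    origin-spanning NUMTs appear as one contiguous hit crossing position L.
    Optional decoy hits carry e-value 1e-3 and should be removed by the
    e-value filter.
    """
    L = unit.unit_length
    query_id = f"{unit.mt_id}_x2"
    hits = []
    for numt in truth.numts:
        segs = numt.mt_segments
        if len(segs) == 1:
            q0, q1 = segs[0]
        else:
            q0 = segs[0][0]
            q1 = L + segs[1][1]
        base = dict(query_id=query_id, s_id=numt.genomic.seq_id,
                    s_start=numt.genomic.start, s_end=numt.genomic.end,
                    strand=numt.strand, evalue=1e-180,
                    bitscore=2.0 * numt.genomic.length)
        hits.append(HomologyHit(q_start=q0, q_end=q1, **base))
        if q1 + L <= 2 * L:
            hits.append(HomologyHit(q_start=q0 + L, q_end=q1 + L, **base))
    if add_decoys:
        rng = np.random.default_rng(seed + 23_000)
        for d in range(add_decoys):
            numt = truth.numts[d % len(truth.numts)]
            start = numt.genomic.end + 500 + d * 40
            hits.append(HomologyHit(
                query_id=query_id, q_start=0, q_end=30,
                s_id=numt.genomic.seq_id, s_start=start, s_end=start + 30,
                strand="+", evalue=1e-3, bitscore=30.0,
            ))
    return hits


def cn_multipliers(assembly: list[GenomeSequence], truth: TruthTable,
                   config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-base expected-copy multiplier implied by the truth table."""
    mult = {s.id: np.ones(s.length) for s in assembly}
    gene_mult = config.n_tandem_gene_copies / config.assembled_gene_copies
    for region in truth.gene_array:
        mult[region.seq_id][region.start:region.end] = gene_mult
    for region, cn in truth.cn_regions:
        mult[region.seq_id][region.start:region.end] = cn
    for hap_id, _primary in truth.haplotig_pairs:
        mult[hap_id][:] = 0.5
    return mult


def simulate_depth(assembly: list[GenomeSequence], truth: TruthTable,
                   config: SimulationConfig) -> DepthTrack:
    """Independent Poisson per-base depth at rate base_depth x multiplier."""
    rng = np.random.default_rng(config.seed + 31_000)
    mult = cn_multipliers(assembly, truth, config)
    depth = {
        s.id: rng.poisson(config.base_depth * mult[s.id]).astype(np.int64)
        for s in assembly
    }
    gap_mask = {
        s.id: np.frombuffer(s.residues.encode(), dtype=np.uint8) == ord("N")
        for s in assembly
    }
    return DepthTrack(depth=depth, gap_mask=gap_mask)


def simulate_reads(assembly: list[GenomeSequence], config: SimulationConfig,
                   ) -> list[ReadAlignment]:
    """Uniformly placed fixed-length read footprints at the target coverage."""
    rng = np.random.default_rng(config.seed + 41_000)
    reads = []
    R = config.read_length
    counter = 0
    for seq in assembly:
        if seq.length < R:
            continue
        n_reads = int(round(config.read_coverage * seq.length / R))
        starts = rng.integers(0, seq.length - R + 1, size=n_reads)
        for start in np.sort(starts):
            reads.append(ReadAlignment(
                read_id=f"read{counter:06d}", read_len=R,
                seq_id=seq.id, start=int(start), end=int(start) + R,
            ))
            counter += 1
    return reads


def expected_spanning_count(config: SimulationConfig, scaffold_len: int,
                            fragment_len: int, flank: int) -> float:
    """Closed-form expected spanning-read count for a uniformly placed,
    fixed-length read set (flank truncation at scaffold ends ignored for
    interior fragments)."""
    R = config.read_length
    span = fragment_len + 2 * flank
    if R < span:
        return 0.0
    n_reads = round(config.read_coverage * scaffold_len / R)
    p = (R - span + 1) / (scaffold_len - R + 1)
    return n_reads * p


def simulate_sv_sets(truth: TruthTable, config: SimulationConfig,
                     jitter: float = 20.0, fn_rate: float = 0.0,
                     ) -> tuple[list[SVRecord], list[SVRecord],
                                list[str], list[str]]:
    """Re-emit the planted SVs as two platform call sets.

    Each platform independently drops each SV with probability fn_rate and
    shifts its breakpoints by Normal(0, jitter). Returns (set_A, set_B,
    retained_ids_A, retained_ids_B); platforms are labelled ONT and SMRT.
    """
    rng = np.random.default_rng(config.seed + 51_000)
    sets: list[list[SVRecord]] = []
    retained: list[list[str]] = []
    for platform, sample in (("ONT", "platformA"), ("SMRT", "platformB")):
        calls = []
        ids = []
        for sv in truth.svs:
            if rng.random() < fn_rate:
                continue
            shift = int(round(rng.normal(0.0, jitter))) if jitter > 0 else 0
            loc = sv.location
            start = max(0, loc.start + shift)
            if sv.sv_type == "INS":
                new_loc = Interval(loc.seq_id, start, start + 1)
            else:
                new_loc = Interval(loc.seq_id, start, start + sv.sv_len)
            calls.append(SVRecord(
                sv_type=sv.sv_type, location=new_loc, sv_len=sv.sv_len,
                sample_id=sample, source_platform=platform,
                record_id=sv.record_id,
            ))
            ids.append(sv.record_id)
        sets.append(calls)
        retained.append(ids)
    return sets[0], sets[1], retained[0], retained[1]


def simulate_selfmap_hits(truth: TruthTable) -> list[HomologyHit]:
    """Self-alignment hits mapping each haplotig fully onto its primary."""
    hits = []
    for hap_id, region in truth.haplotig_pairs:
        hits.append(HomologyHit(
            query_id=hap_id, q_start=0, q_end=region.length,
            s_id=region.seq_id, s_start=region.start, s_end=region.end,
            strand="+", bitscore=2.0 * region.length, evalue=1e-180,
        ))
    return hits


# ---------------------------------------------------------------------------
# Truth table round-trip and BUSCO table emission
# ---------------------------------------------------------------------------

def write_truth(truth: TruthTable, path: str) -> None:
    """Serialise the truth table to a single JSON-lines-in-TSV-free file."""
    payload = {
        "numts": [
            {
                "seq_id": n.genomic.seq_id, "start": n.genomic.start,
                "end": n.genomic.end, "strand": n.strand,
                "mt_segments": n.mt_segments, "block_id": n.block_id,
            }
            for n in truth.numts
        ],
        "gene_array": [[r.seq_id, r.start, r.end] for r in truth.gene_array],
        "gene_true_copies": truth.gene_true_copies,
        "cn_regions": [[r.seq_id, r.start, r.end, cn] for r, cn in truth.cn_regions],
        "busco_genes": [[bid, r.seq_id, r.start, r.end] for bid, r in truth.busco_genes],
        "haplotig_pairs": [[h, r.seq_id, r.start, r.end] for h, r in truth.haplotig_pairs],
        "svs": [
            [s.sv_type, s.location.seq_id, s.location.start, s.location.end,
             s.sv_len, s.record_id]
            for s in truth.svs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str) -> TruthTable:
    with open(path) as fh:
        payload = json.load(fh)
    truth = TruthTable(gene_true_copies=payload["gene_true_copies"])
    for n in payload["numts"]:
        truth.numts.append(PlantedNumt(
            genomic=Interval(n["seq_id"], n["start"], n["end"], n["strand"]),
            mt_segments=[tuple(seg) for seg in n["mt_segments"]],
            strand=n["strand"], block_id=n["block_id"],
        ))
    truth.gene_array = [Interval(s, a, b) for s, a, b in payload["gene_array"]]
    truth.cn_regions = [(Interval(s, a, b), cn) for s, a, b, cn in payload["cn_regions"]]
    truth.busco_genes = [(bid, Interval(s, a, b)) for bid, s, a, b in payload["busco_genes"]]
    truth.haplotig_pairs = [(h, Interval(s, a, b)) for h, s, a, b in payload["haplotig_pairs"]]
    truth.svs = [
        SVRecord(sv_type=t, location=Interval(s, a, b), sv_len=l,
                 sample_id="truth", record_id=rid)
        for t, s, a, b, l, rid in payload["svs"]
    ]
    return truth


def write_busco_table(truth: TruthTable, path: str,
                      n_missing: int = 3) -> None:
    """Emit the planted single-copy genes as a BUSCO v3 full_table."""
    with open(path, "w") as fh:
        fh.write("# Synthetic BUSCO v3 full table\n")
        fh.write("# Busco id\tStatus\tContig\tStart\tEnd\tScore\tLength\n")
        for bid, region in truth.busco_genes:
            fh.write(f"{bid}\tComplete\t{region.seq_id}\t{region.start + 1}\t"
                     f"{region.end}\t999.0\t{region.length}\n")
        for m in range(n_missing):
            fh.write(f"missing{m:03d}\tMissing\n")


# ---------------------------------------------------------------------------
# Optional exact matcher (end-to-end runs without an external aligner)
# ---------------------------------------------------------------------------

def exact_match_hits(assembly: list[GenomeSequence], doubled: GenomeSequence,
                     k: int = 31, min_len: int = 34) -> list[HomologyHit]:
    """Find maximal exact matches of assembly scaffolds to the doubled mtDNA.

    Seed-and-extend over a k-mer index of the doubled query, on both strands.
    Only suitable for mutation-free synthetic data; real searches belong to
    an external aligner.
    """
    index: dict[str, list[int]] = {}
    q = doubled.residues
    for i in range(len(q) - k + 1):
        index.setdefault(q[i:i + k], []).append(i)
    hits = []
    for seq in assembly:
        for strand in ("+", "-"):
            text = seq.residues if strand == "+" else _revcomp(seq.residues)
            seen: set[tuple[int, int]] = set()  # (diagonal, end) of reported runs
            pos = 0
            n = len(text)
            while pos <= n - k:
                kmer = text[pos:pos + k]
                starts = index.get(kmer)
                if not starts:
                    pos += 1
                    continue
                advanced = False
                for qpos in starts:
                    diag = qpos - pos
                    # extend left and right maximally
                    left = 0
                    while pos - left - 1 >= 0 and qpos - left - 1 >= 0 and \
                            text[pos - left - 1] == q[qpos - left - 1]:
                        left += 1
                    right = k
                    while pos + right < n and qpos + right < len(q) and \
                            text[pos + right] == q[qpos + right]:
                        right += 1
                    run_start, run_end = pos - left, pos + right
                    key = (diag, run_end)
                    if key in seen or run_end - run_start < min_len:
                        continue
                    seen.add(key)
                    q0, q1 = qpos - left, qpos + right
                    if strand == "+":
                        s0, s1 = run_start, run_end
                    else:
                        s0, s1 = n - run_end, n - run_start
                    hits.append(HomologyHit(
                        query_id=doubled.id, q_start=q0, q_end=q1,
                        s_id=seq.id, s_start=s0, s_end=s1, strand=strand,
                        bitscore=2.0 * (run_end - run_start), evalue=1e-180,
                    ))
                    pos = run_end - k + 1
                    advanced = True
                    break
                if not advanced:
                    pos += 1
    return hits
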