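"""Multi-platform structural-variant consensus and comparative statistics.

Two call sets against the same reference (e.g. nanopore vs SMRT reads from
one individual) are intersected to a conservative consensus: deletions,
inversions and duplications match by reciprocal overlap; insertions, being
breakpoints, match by breakpoint distance plus size ratio. Matching is
greedy, injective and deterministic. The same matcher drives cross-sample
Venn counts. Also here: gene/exon overlap annotation of SV sets, row-centred
comparative read-mapping statistics, and annotation QC (reciprocal best
hits and protein length ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_io import GeneModel, SVRecord

RECIPROCAL_TYPES = ("DEL", "INV", "DUP")


@dataclass(frozen=True)
class MatchParams:
    """Matching criteria: reciprocal overlap for span SVs; breakpoint
    distance + size ratio for insertions."""

    reciprocal_overlap: float = 0.5
    ins_max_distance: int = 1000
    ins_min_size_ratio: float = 0.5


@dataclass
class ConsensusSV:
    representative: SVRecord
    partner_a: SVRecord
    partner_b: SVRecord
    match_stat: float  # reciprocal overlap (span types) or bp distance (INS)


@dataclass
class OverlapSummary:
    """Venn counts per SV type between two consensus sets."""

    only_a: dict[str, int] = field(default_factory=dict)
    only_b: dict[str, int] = field(default_factory=dict)
    shared: dict[str, int] = field(default_factory=dict)

    def shared_pct(self, sv_type: str, side: str = "a") -> float:
        shared = self.shared.get(sv_type, 0)
        only = (self.only_a if side == "a" else self.only_b).get(sv_type, 0)
        total = shared + only
        return round(100.0 * shared / total, 2) if total else 0.0


def filter_length(svs: list[SVRecord], min_len: int = 100, strict: bool = True) -> list[SVRecord]:
    """Keep SVs longer than min_len (>= when strict is False); BND always dropped."""
    out = []
    for sv in svs:
        if sv.sv_type == "BND":
            continue
        if (sv.sv_len > min_len) if strict else (sv.sv_len >= min_len):
            out.append(sv)
    return out


def restrict_to_chroms(svs: list[SVRecord], chroms: set[str]) -> list[SVRecord]:
    return [sv for sv in svs if sv.location.seq_id in chroms]


def _reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    ov = a.location.overlap_len(b.location)
    if ov == 0:
        return 0.0
    return min(ov / a.location.length, ov / b.location.length)


def _candidate_pairs(set_a: list[SVRecord], set_b: list[SVRecord], params: MatchParams):
    """All admissible (score, i, j) pairs, sorted for greedy consumption."""
    refs_a = {sv.location.seq_id for sv in set_a}
    refs_b = {sv.location.seq_id for sv in set_b}
    if set_a and set_b and not (refs_a & refs_b):
        raise ValueError(
            f"call sets share no sequence ids ({sorted(refs_a)[:3]} vs {sorted(refs_b)[:3]}); "
            "are they on the same reference?"
        )
    pairs = []
    by_type_b: dict[tuple[str, str], list[tuple[int, SVRecord]]] = {}
    for j, sv in enumerate(set_b):
        by_type_b.setdefault((sv.sv_type, sv.location.seq_id), []).append((j, sv))
    for i, a in enumerate(set_a):
        for j, b in by_type_b.get((a.sv_type, a.location.seq_id), []):
            if a.sv_type == "INS":
                dist = abs(a.location.start - b.location.start)
                if dist > params.ins_max_distance:
                    continue
                ratio = min(a.sv_len, b.sv_len) / max(a.sv_len, b.sv_len)
                if ratio < params.ins_min_size_ratio:
                    continue
                # ascending distance, ties by position
                pairs.append((dist, a.location.start, b.location.start, i, j))
            elif a.sv_type in RECIPROCAL_TYPES:
                ro = _reciprocal_overlap(a, b)
                if ro < params.reciprocal_overlap:
                    continue
                # descending reciprocal overlap, ties by position
                pairs.append((-ro, a.location.start, b.location.start, i, j))
    pairs.sort()
    return pairs


def intersect_platforms(
    set_a: list[SVRecord],
    set_b: list[SVRecord],
    params: MatchParams = MatchParams(),
) -> list[ConsensusSV]:
    """Greedy injective best-match intersection of two SV call sets.

    Each record partners at most one record of the other set; unmatched
    records are dropped. The representative is the partner with the smaller
    start (tie: the A-side record).
    """
    used_a: set[int] = set()
    used_b: set[int] = set()
    consensus = []
    for key in _candidate_pairs(set_a, set_b, params):
        score, _, _, i, j = key
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = set_a[i], set_b[j]
        rep = b if b.location.start < a.location.start else a
        stat = -score if a.sv_type in RECIPROCAL_TYPES else float(score)
        consensus.append(ConsensusSV(representative=rep, partner_a=a, partner_b=b,
                                     match_stat=stat))
    consensus.sort(key=lambda c: (c.representative.location.seq_id,
                                  c.representative.location.start))
    return consensus


def overlap_samples(
    consensus_a: list[SVRecord],
    consensus_b: list[SVRecord],
    params: MatchParams = MatchParams(),
) -> OverlapSummary:
    """Venn counts per SV type between two samples' (consensus) call sets."""
    matched = intersect_platforms(consensus_a, consensus_b, params)
    summary = OverlapSummary()
    types = {sv.sv_type for sv in consensus_a} | {sv.sv_type for sv in consensus_b}
    for sv_type in sorted(types):
        n_shared = sum(1 for c in matched if c.partner_a.sv_type == sv_type)
        n_a = sum(1 for sv in consensus_a if sv.sv_type == sv_type)
        n_b = sum(1 for sv in consensus_b if sv.sv_type == sv_type)
        summary.shared[sv_type] = n_shared
        summary.only_a[sv_type] = n_a - n_shared
        summary.only_b[sv_type] = n_b - n_shared
    return summary


def annotate_gene_overlap(
    svs: list[SVRecord],
    genes: list[GeneModel],
) -> tuple[pd.DataFrame, int]:
    """Flag each SV for gene and exon overlap (>= 1 bp intersection).

    Returns a per-SV table and the number of distinct exons overlapped by
    any SV.
    """
    gene_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    for gene in genes:
        gene_trees.setdefault(gene.span.seq_id, IntervalTree()).addi(
            gene.span.start, gene.span.end, gene.gene_id)
        for k, exon in enumerate(gene.exons):
            exon_trees.setdefault(exon.seq_id, IntervalTree()).addi(
                exon.start, exon.end, (gene.gene_id, k))
    rows = []
    hit_exons: set[tuple[str, int]] = set()
    for sv in svs:
        loc = sv.location
        g_hits = gene_trees.get(loc.seq_id, IntervalTree()).overlap(loc.start, loc.end)
        e_hits = exon_trees.get(loc.seq_id, IntervalTree()).overlap(loc.start, loc.end)
        hit_exons.update(iv.data for iv in e_hits)
        rows.append({
            "seq_id": loc.seq_id, "start": loc.start, "end": loc.end,
            "sv_type": sv.sv_type, "sv_len": sv.sv_len,
            "overlaps_gene": bool(g_hits), "n_genes": len({iv.data for iv in g_hits}),
            "overlaps_exon": bool(e_hits), "n_exons": len({iv.data for iv in e_hits}),
        })
    return pd.DataFrame(rows), len(hit_exons)


def relative_mapping(scores: pd.DataFrame) -> pd.DataFrame:
    """Centre a sample x reference matrix of percent-mapped on row means.

    Rows with missing cells are excluded (with a warning); every returned row
    sums to ~0.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two reference genomes")
    complete = scores.dropna(axis=0)
    if len(complete) < len(scores):
        import logging
        logging.getLogger("numtforge").warning(
            "excluded %d samples with missing mapping cells", len(scores) - len(complete))
    return complete.sub(complete.mean(axis=1), axis=0)


def annotation_qc(
    best_hits_a_to_b: dict[str, str],
    best_hits_b_to_a: dict[str, str],
    protein_lengths_a: dict[str, int],
    protein_lengths_b: dict[str, int],
) -> pd.DataFrame:
    """Reciprocal-best-hit orthologue flags and protein length ratios.

    A gene is an RBH orthologue iff its best hit's own best hit points back
    to it. Length ratio = predicted length / reference (best-hit) length.
    """
    rows = []
    for gene, hit in best_hits_a_to_b.items():
        ref_len = protein_lengths_b.get(hit)
        if ref_len is not None and ref_len <= 0:
            raise ValueError(f"zero reference protein length for {hit}")
        rows.append({
            "gene_id": gene,
            "best_hit": hit,
            "rbh": best_hits_b_to_a.get(hit) == gene,
            "length_ratio": (protein_lengths_a[gene] / ref_len
                             if ref_len and gene in protein_lengths_a else np.nan),
        })
    return pd.DataFrame(rows)
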