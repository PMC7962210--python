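"""Read-depth copy-number estimation anchored to BUSCO single-copy genes.

The single-copy baseline X_SC is the modal per-base depth pooled over BUSCO
single-copy Complete genes (gap bases excluded, sequences such as a male X
chromosome excludable). A region's copy number is N_reg = X_reg / X_SC where
X_reg is its mean non-gap depth. Dispersion of per-gene copy numbers across
the BUSCO set provides the uncertainty model: a region's standard error is
scaled by the coefficient of variation of the single-copy distribution.
Gene-family totals (e.g. a tandem amylase array) sum per-hit copy numbers
weighted by the fraction of the query each hit covers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import BuscoGene, DepthTrack, Interval, ReadAlignment

logger = logging.getLogger("numtforge")

ASSEMBLY_BINS = ("Missing", "Partial (<50%)", "1n", "2n", "3n+")
LONGREAD_BINS = ("0n", "0.5n", "1n", "1.5n", "2n", "2.5n+")


@dataclass
class SingleCopyDepthModel:
    """Modal single-copy depth and the per-gene copy-number distribution."""

    x_sc: int
    per_gene_cn: np.ndarray
    gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.per_gene_cn)

    @property
    def mean_cn(self) -> float:
        return float(self.per_gene_cn.mean())

    @property
    def sd_cn(self) -> float:
        if self.n_genes < 2:
            return float("nan")
        return float(self.per_gene_cn.std(ddof=1))

    @property
    def ci95_halfwidth(self) -> float:
        if self.n_genes < 2:
            return float("nan")
        return 1.96 * self.sd_cn / math.sqrt(self.n_genes)


@dataclass
class RegionCopyNumber:
    region: Interval
    x_reg: float
    n_reg: float
    se: float
    ci95: float


@dataclass
class GeneFamilyEstimate:
    per_hit: list[tuple[RegionCopyNumber, float, float]]  # (region CN, qcov, copies)

    @property
    def total_copies(self) -> float:
        return sum(copies for _, _, copies in self.per_hit)


def fit_single_copy_model(
    depth: DepthTrack,
    busco: list[BuscoGene],
    exclude_seqs: list[str] | None = None,
) -> SingleCopyDepthModel:
    """Estimate X_SC as the mode of pooled per-base depth over eligible genes.

    Eligible genes are status Complete, off the excluded sequences, with at
    least one non-gap base. Ties on the mode break toward the lower depth.
    """
    exclude = set(exclude_seqs or [])
    pooled = []
    gene_means = []
    gene_ids = []
    for gene in busco:
        if gene.status != "Complete" or gene.location is None:
            continue
        if gene.on_excluded_seq or gene.location.seq_id in exclude:
            continue
        vals = depth.region_values(gene.location)
        if vals.size == 0:
            continue
        pooled.append(vals)
        gene_means.append(float(vals.mean()))
        gene_ids.append(gene.busco_id)
    if not pooled:
        raise ValueError("no eligible single-copy Complete BUSCO genes with coverage")
    counts = np.bincount(np.concatenate(pooled))
    x_sc = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    if x_sc == 0:
        raise ValueError("insufficient coverage: modal single-copy depth is zero")
    per_gene_cn = np.array(gene_means) / x_sc
    return SingleCopyDepthModel(x_sc=x_sc, per_gene_cn=per_gene_cn, gene_ids=gene_ids)


def region_cn(depth: DepthTrack, region: Interval, model: SingleCopyDepthModel) -> RegionCopyNumber:
    """Copy number of a region: N_reg = X_reg / X_SC with CV-scaled uncertainty."""
    x_reg = depth.mean_depth(region)
    n_reg = x_reg / model.x_sc
    cv = model.sd_cn / model.mean_cn if model.n_genes >= 2 else float("nan")
    se = cv * n_reg
    return RegionCopyNumber(region=region, x_reg=x_reg, n_reg=n_reg, se=se, ci95=1.96 * se)


def busco_cn_summary(model: SingleCopyDepthModel) -> tuple[float, float | None]:
    """Mean single-copy CN and its 95% CI half-width (None below 2 genes)."""
    if model.n_genes < 2:
        return model.mean_cn, None
    return model.mean_cn, model.ci95_halfwidth


def gene_family_cn(
    depth: DepthTrack,
    hits: list[tuple[Interval, float]],
    model: SingleCopyDepthModel,
) -> GeneFamilyEstimate:
    """Total gene-family copy number: sum over hits of N_reg x query coverage.

    Hits must be non-overlapping on the genome; query_coverage is the fraction
    of the query gene each assembled region covers, in (0, 1].
    """
    for i, (a, _) in enumerate(hits):
        for b, _ in hits[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"overlapping family hits: {a} / {b}")
    if not hits:
        logger.warning("gene_family_cn called with an empty hit list")
    per_hit = []
    for region, qcov in hits:
        if not 0 < qcov <= 1:
            raise ValueError(f"query coverage {qcov} outside (0, 1]")
        rc = region_cn(depth, region, model)
        per_hit.append((rc, qcov, rc.n_reg * qcov))
    return GeneFamilyEstimate(per_hit=per_hit)


def filter_reads_by_length(
    read_alignments: list[ReadAlignment], min_len: int = 0
) -> list[ReadAlignment]:
    """Keep reads at least min_len long (repeat-robust depth re-estimation)."""
    return [r for r in read_alignments if r.read_len >= min_len]


def depth_from_reads(
    read_alignments: list[ReadAlignment],
    scaffold_lengths: dict[str, int],
    gap_mask: dict[str, np.ndarray] | None = None,
) -> DepthTrack:
    """Rebuild a per-base depth track from read alignment footprints."""
    depth = {s: np.zeros(n, dtype=np.int64) for s, n in scaffold_lengths.items()}
    for read in read_alignments:
        if read.seq_id in depth:
            depth[read.seq_id][read.start:read.end] += 1
    if gap_mask is None:
        gap_mask = {s: np.zeros(n, dtype=bool) for s, n in scaffold_lengths.items()}
    return DepthTrack(depth=depth, gap_mask=gap_mask)


def short_read_ratio_cn(
    gene_regions: list[Interval],
    depth: DepthTrack,
    genome_mean_depth: float,
) -> float:
    """Depth-ratio copy number from short reads.

    Total copies = sum over annotated gene copies of (mean gene depth) divided
    by the genome-wide mean depth.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    return sum(depth.mean_depth(region) for region in gene_regions) / genome_mean_depth


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bin_gene_coverage(value: float, mode: str = "assembly") -> str:
    """Bin a per-gene coverage/copy value into a categorical label.

    assembly mode (whole-assembly mapping, nearest integer):
        0 -> Missing; (0, 0.5) -> Partial (<50%); 1 -> 1n; 2 -> 2n; >=3 -> 3n+.
    longread mode (long-read depth, nearest 0.5):
        0 -> 0n; (0, 0.5) -> 0.5n; then 1n/1.5n/2n, capped at 2.5n+.
    Midpoints round half up.
    """
    if value < 0:
        raise ValueError("coverage value must be non-negative")
    if mode == "assembly":
        if value == 0:
            return "Missing"
        if value < 0.5:
            return "Partial (<50%)"
        n = max(1, _round_half_up(value))
        return f"{n}n" if n <= 2 else "3n+"
    if mode == "longread":
        if value == 0:
            return "0n"
        if value < 0.5:
            return "0.5n"
        n_half = max(1, _round_half_up(value * 2))  # units of 0.5n
        if n_half >= 5:
            return "2.5n+"
        return f"{n_half / 2:g}n"
    raise ValueError(f"unknown binning mode {mode!r}")
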