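"""Rule-based scaffold classification from read-depth bins and self-mapping.

Each scaffold's non-gap bases are binned into low / haploid / diploid / high
depth classes (thresholds derived from the single-copy depth), and combined
with the fraction of the scaffold aligning onto another scaffold to assign a
rating: KEEP, LOWCOV_FILTER (median depth below a hard floor), HAPLOTIG
(alternate-haplotype duplicate at ~half depth), LOWCOV_ARTEFACT,
COLLAPSED_REPEAT (excess depth: multiple genomic copies assembled once), or
REPEAT (normal depth but largely alignable elsewhere). Tidying iterates to a
fixpoint: removing a haplotig can strand its partner, so self-mapping is
recomputed against the surviving set each round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_io import DepthTrack, HomologyHit, Interval

# Multipliers reproducing low/mid/high = 8/25/68 at a single-copy depth of 35.
LOW_MULT, MID_MULT, HIGH_MULT = 0.23, 0.71, 1.94

RATING_ORDER = ("LOWCOV_FILTER", "HAPLOTIG", "LOWCOV_ARTEFACT",
                "COLLAPSED_REPEAT", "REPEAT", "KEEP")


@dataclass(frozen=True)
class DepthThresholds:
    """Depth cutoffs defining bins low [0,low), haploid [low,mid),
    diploid [mid,high) and high [high, inf)."""

    low: int
    mid: int
    high: int

    def __post_init__(self):
        if not 0 < self.low < self.mid < self.high:
            raise ValueError(f"thresholds must satisfy 0 < low < mid < high, got {self}")


@dataclass
class ScaffoldProfile:
    seq_id: str
    frac_low: float
    frac_haploid: float
    frac_diploid: float
    frac_high: float
    median_cov: float
    selfmap_frac: float

    def __post_init__(self):
        total = self.frac_low + self.frac_haploid + self.frac_diploid + self.frac_high
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"bin fractions sum to {total}, not 1")


@dataclass
class ScaffoldRating:
    seq_id: str
    rating: str
    rule_id: str
    round_number: int = 1


def default_thresholds(x_sc: float) -> DepthThresholds:
    """Derive low/mid/high cutoffs from the single-copy depth."""
    if x_sc <= 0:
        raise ValueError("single-copy depth must be positive")
    return DepthThresholds(
        low=int(math.floor(LOW_MULT * x_sc + 0.5)),
        mid=int(math.floor(MID_MULT * x_sc + 0.5)),
        high=int(math.floor(HIGH_MULT * x_sc + 0.5)),
    )


def profile_scaffold(
    depth: DepthTrack,
    seq_id: str,
    thresholds: DepthThresholds,
    selfmap_frac: float = 0.0,
) -> ScaffoldProfile:
    """Bin fractions and median depth over the scaffold's non-gap bases."""
    import numpy as np

    arr = depth.depth[seq_id]
    mask = depth.gap_mask[seq_id]
    vals = arr[~mask]
    if vals.size == 0:
        raise ValueError(f"scaffold {seq_id} is all gap")
    n = vals.size
    frac_low = float((vals < thresholds.low).sum()) / n
    frac_haploid = float(((vals >= thresholds.low) & (vals < thresholds.mid)).sum()) / n
    frac_diploid = float(((vals >= thresholds.mid) & (vals < thresholds.high)).sum()) / n
    frac_high = float((vals >= thresholds.high).sum()) / n
    return ScaffoldProfile(
        seq_id=seq_id,
        frac_low=frac_low,
        frac_haploid=frac_haploid,
        frac_diploid=frac_diploid,
        frac_high=frac_high,
        median_cov=float(np.median(vals)),
        selfmap_frac=selfmap_frac,
    )


def classify(profile: ScaffoldProfile, min_median: float = 3.0,
             round_number: int = 1) -> ScaffoldRating:
    """Apply the rating rules in fixed precedence order.

    1. median depth < min_median            -> LOWCOV_FILTER
    2. low+haploid >= 80% and selfmap >= 95% -> HAPLOTIG
    3. low >= 80%                            -> LOWCOV_ARTEFACT
    4. diploid < 20% and high >= 50%         -> COLLAPSED_REPEAT
    5. diploid dominant and selfmap > 50%    -> REPEAT
    else KEEP. "Dominant" means strictly the largest of the four bins.
    """
    p = profile
    if p.median_cov < min_median:
        return ScaffoldRating(p.seq_id, "LOWCOV_FILTER", "rule1_median_cov", round_number)
    if p.frac_low + p.frac_haploid >= 0.80 and p.selfmap_frac >= 0.95:
        return ScaffoldRating(p.seq_id, "HAPLOTIG", "rule2_haplotig", round_number)
    if p.frac_low >= 0.80:
        return ScaffoldRating(p.seq_id, "LOWCOV_ARTEFACT", "rule3_lowcov", round_number)
    if p.frac_diploid < 0.20 and p.frac_high >= 0.50:
        return ScaffoldRating(p.seq_id, "COLLAPSED_REPEAT", "rule4_collapsed", round_number)
    bins = (p.frac_low, p.frac_haploid, p.frac_diploid, p.frac_high)
    diploid_dominant = all(p.frac_diploid > b for i, b in enumerate(bins) if i != 2)
    if diploid_dominant and p.selfmap_frac > 0.50:
        return ScaffoldRating(p.seq_id, "REPEAT", "rule5_repeat", round_number)
    return ScaffoldRating(p.seq_id, "KEEP", "keep", round_number)


def selfmap_fractions(
    self_hits: list[HomologyHit],
    scaffold_lengths: dict[str, int],
    restrict_to: set[str] | None = None,
) -> dict[str, float]:
    """Fraction of each scaffold covered by alignments onto *other* scaffolds.

    Computed from self-alignment PAF/blast6 hits by unioning query-side
    covered intervals; self-self hits and hits onto scaffolds outside
    ``restrict_to`` are ignored.
    """
    covered: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffold_lengths}
    for hit in self_hits:
        if hit.query_id == hit.s_id:
            continue
        if restrict_to is not None and hit.s_id not in restrict_to:
            continue
        if hit.query_id in covered:
            covered[hit.query_id].append((hit.q_start, hit.q_end))
    fractions = {}
    for seq_id, intervals in covered.items():
        length = scaffold_lengths[seq_id]
        total = 0
        cursor = None
        for start, end in sorted(intervals):
            if cursor is None or start > cursor:
                total += end - start
                cursor = end
            elif end > cursor:
                total += end - cursor
                cursor = end
        fractions[seq_id] = total / length if length else 0.0
    return fractions


def tidy_assembly(
    depth: DepthTrack,
    scaffold_lengths: dict[str, int],
    thresholds: DepthThresholds,
    self_hits: list[HomologyHit] | None = None,
    min_median: float = 3.0,
    max_rounds: int = 10,
) -> list[ScaffoldRating]:
    """Iteratively classify scaffolds until the keep-set reaches a fixpoint.

    Scaffolds rated non-KEEP are removed from the reference set used for
    self-mapping in subsequent rounds, so haplotigs whose primary partner was
    itself removed can be re-rated.
    """
    self_hits = self_hits or []
    active = set(scaffold_lengths)
    ratings: dict[str, ScaffoldRating] = {}
    for round_number in range(1, max_rounds + 1):
        fractions = selfmap_fractions(self_hits, scaffold_lengths, restrict_to=active)
        removed_this_round = []
        for seq_id in sorted(active):
            profile = profile_scaffold(depth, seq_id, thresholds,
                                       selfmap_frac=fractions.get(seq_id, 0.0))
            rating = classify(profile, min_median=min_median, round_number=round_number)
            ratings[seq_id] = rating
            if rating.rating != "KEEP":
                removed_this_round.append(seq_id)
        if not removed_this_round:
            break
        active -= set(removed_this_round)
    return [ratings[s] for s in sorted(scaffold_lengths)]
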