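# Methods

This note documents the models and procedures numtforge implements, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical choices made where the design was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to and from
1-based inclusive conventions (BLAST tabular, BUSCO full tables, VCF, GFF3)
happens only at parse/write boundaries, and each converter is the inverse of
its writer on its domain. BLAST hits with subject start > end are stored as
strand `-` with coordinates swapped. IUPAC ambiguity codes are mapped to `N`
on FASTA ingestion (with a logged count) rather than rejected, because real
assemblies contain them. Depth is ingested from per-base TSV or bedGraph
text rather than BAM pileup, keeping the algorithmic core independent of
alignment binaries; positions absent from a depth file are depth 0, and
assembly-gap (`N`) positions carry a mask that excludes them from every
depth statistic.

## NUMT discovery

A circular mtDNA of length *L* is doubled (two tandem copies) before the
homology search so that an insertion derived from a segment spanning the
replication origin appears as a single contiguous hit rather than two
artificially split ones. Consequences handled downstream:

- every non-origin-spanning locus produces a duplicate hit offset by *L*;
  unique-hit compression must collapse it;
- query intervals are wrapped back onto [0, *L*) (`wrap_to_unit`), splitting
  at position *L*; total length is conserved exactly.

**Unique-hit compression.** Hits surviving the e-value filter (default
e < 1e-4) are accepted greedily in order (bitscore desc, subject length
desc, then subject position asc for determinism) and trimmed on the subject
(genomic) side against previously accepted fragments, the query side
shrinking proportionally. This is exactly equivalent to assigning each
genomic base to its best covering hit and taking maximal equal-winner runs
(property-tested against that oracle). The published tie-breaking of the
original interval-compression tool is not documented, so the order above is
this package's own fixed convention. Trim residues shorter than `min_frag`
(default 25 bp — below the smallest fragment scale of interest, so no
real fragment is excluded while 1–2 bp residue is) are discarded. The
proportional query projection is exact for ungapped hits and approximate
for gapped ones.

**Blocks.** Fragments on one scaffold merge transitively into a block when
the inter-fragment genomic gap is ≤ `merge_gap` (default 8000 bp),
strand-agnostic and mtDNA-order-agnostic; blocks never span scaffolds,
because genomic distance is undefined across them. Both the block span
length and the summed member-fragment length are reported, since summaries
in the field use either.

**Spanning support.** A read supports a fragment at flank *f* when its
alignment covers the fragment plus *f* bases each side, with the flank
truncated at scaffold ends (a fragment near a scaffold end can still gain
5 kb-flank support from reads reaching the end; the alternative — an
unsatisfiable flank — was rejected). Counts are non-increasing in *f* by
construction. Default flanks: 0, 100, 1000, 5000 bp.

**mtDNA read classification.** For mitochondrial assembly, reads are called
`pure_complete` when ≥ 99% of the read aligns to mtDNA *and* the union of
their mtDNA segments covers ≥ 99% of the unit, `partial` when only the first
holds, else `non_mt`. Only pure-complete reads are safe against NUMT
contamination of an mtDNA assembly.

## Depth-based copy number

`X_SC` is the mode of the pooled per-base depth histogram over BUSCO
single-copy Complete genes (integer resolution, gap bases excluded,
sequences in the exclude list — e.g. chromosome X for a male — left out).
Ties break toward the lower depth, which is conservative for copy-number
calls. Integer resolution quantises the estimate: for Poisson-distributed
depth at integer rate λ the histogram mass at λ−1 and λ is equal, so the
fitted mode is legitimately either; downstream estimates inherit a relative
bias of at most 1/λ. This matters for calibration checks (below) but is
immaterial at typical long-read depths.

`N_reg = X_reg / X_SC` with `X_reg` the mean non-gap depth of the region.
The original description of the estimate's variance is ambiguous about
whether per-gene means or pooled bases feed it; we compute the per-gene CN
distribution (one mean per BUSCO gene), report its mean and
`1.96·sd/√n` 95% CI half-width, and scale a region's standard error by the
distribution's coefficient of variation: `se(N_reg) = (sd_CN/mean_CN)·N_reg`.
Both the region-level and the BUSCO-mean uncertainties are emitted as
separate columns rather than collapsed.

Gene-family totals multiply each hit's `N_reg` by the fraction of the query
gene that hit covers and sum over (non-overlapping) hits; a single
full-coverage hit reduces exactly to `region_cn`. The short-read estimator
is the ratio of summed mean per-gene-copy depth to genome-wide mean depth.
Read-length-restricted re-runs (≥ 5 kb, ≥ 10 kb) rebuild the depth track
from the retained read footprints.

**Coverage binning.** Assembly-mapping mode rounds coverage to the nearest
integer: {Missing (0), Partial (< 50%), 1n, 2n, 3n+}; long-read mode rounds
to the nearest 0.5n: {0n, 0.5n, 1n, 1.5n, 2n, 2.5n+}, with values above the
top bin collapsed into it and sub-50% non-zero coverage assigned 0.5n.
Midpoints (e.g. 1.25) round half up — deterministic and documented, since
the convention is otherwise unstated.

## Scaffold tidying

Depth thresholds low/mid/high default to round(0.23·X_SC), round(0.71·X_SC),
round(1.94·X_SC) — multipliers back-derived so a 35x single-copy depth gives
the reference values 8/25/68 — and are overridable. Non-gap bases are binned
into low/haploid/diploid/high fractions; ratings apply in fixed precedence:

1. median coverage < 3 → LOWCOV_FILTER
2. low+haploid ≥ 80% and ≥ 95% self-mapped → HAPLOTIG
3. low ≥ 80% → LOWCOV_ARTEFACT
4. diploid < 20% and high ≥ 50% → COLLAPSED_REPEAT
5. diploid strictly the largest bin and > 50% self-mapped → REPEAT
6. else KEEP

"Dominant diploid coverage" has no published numeric definition; we
operationalise it as strictly largest of the four bins. The ordering of
rules 4–5 is this package's choice and is recorded per scaffold via the
triggering rule id. Self-mapping fraction is the unioned query-side coverage
of alignments onto *other* scaffolds, consumed from an external
self-alignment (PAF/blast6). Tidying iterates: scaffolds rated non-KEEP
leave the reference set used for self-mapping, and survivors are re-rated
until a fixpoint or `max_rounds` (default 10, emulating the iterative
multi-round curation such assemblies receive).

## SV consensus

Two call sets on the same reference intersect by greedy injective matching:
DEL/INV/DUP pairs require reciprocal overlap ≥ 0.5 (both directions);
insertions, being breakpoints, require breakpoint distance ≤ 1000 bp and
size ratio ≥ 0.5. Candidates are consumed best-first (largest reciprocal
overlap / smallest distance, ties by position), each record partnering at
most once; the match count is symmetric in the operands. The source
analyses never state their overlap criterion, and their printed counts and
percentages are not mutually consistent, so exact reproduction is not
attempted: the defaults follow common SV-merging practice and are
CLI-exposed. Length filtering keeps SVs strictly over 100 bp by default and
always drops BND records. Gene/exon overlap is ≥ 1 bp interval
intersection, via interval trees. Comparative mapping statistics centre
each sample's percent-mapped row on its own mean across references, so rows
sum to zero and a positive cell means "maps better than this sample's
average reference".

Annotation QC marks a gene as a predicted orthologue when it is a
reciprocal best hit (its best hit's own best hit points back), and reports
the predicted/reference protein length ratio.

## Synthetic data generator

The generator emulates the study conditions the estimators were built for:

- **genome**: 4 primary scaffolds of 150 kb of uniform random sequence plus
  a 16,700 bp circular mtDNA (the real dog unit is 16,761 bp);
- **NUMTs**: 10 insertions with log-uniform lengths on [34, 6580] bp (the
  published fragment size range), verbatim mtDNA subsequences on either
  strand, at least one spanning the origin; placed in clusters with
  intra-cluster gaps of 0.5–4 kb (merging into known blocks) and ≥ 12 kb
  isolation between clusters, so the truth block partition is unambiguous;
- **tandem gene array**: 2 assembled copies of a 2 kb gene carrying the read
  depth of 6 true copies (the assembled-2/true-~6 structure of the dog
  amylase locus);
- **copy-number regions**: 2 kb regions at CN 1, 2, 3, 6;
- **single-copy genes**: 200 × 1 kb intervals emitted as a BUSCO v3 full
  table; 200 kb of pooled bases keeps the integer-mode depth estimate within
  ±1 of the true rate with high probability;
- **depth**: independent Poisson per base at rate `base_depth × CN(pos)`,
  default `base_depth` 30 (the ~35x long-read coverage regime of the source
  study; haplotigs at 0.5×). No autocorrelation, GC or mappability effects —
  so passing recovery tests demonstrates estimator correctness under the
  stated model, not robustness to real-coverage artefacts;
- **haplotigs**: 2 scaffolds duplicating 20 kb NUMT-free segments of
  primaries verbatim, at half depth, with full-length self-map hits;
- **reads**: fixed 12 kb footprints placed uniformly at 20x, giving a
  closed-form expected spanning count
  `n_reads · (R − span + 1)/(scaffold_len − R + 1)`;
- **SVs**: DEL/INS/INV/DUP planted with ≥ 3 kb separation (so platform
  jitter cannot create ambiguous cross-matches), re-emitted per platform
  with Normal(0, 20 bp) breakpoint jitter and independent dropout.

All outputs are pure functions of (config, seed); hits are emitted from
truth coordinates by default (with the doubled-query duplicate and optional
decoy hits above the e-value cutoff), and an exact k-mer seed-and-extend
matcher is available for aligner-free end-to-end runs. Maximal exact
matches can extend a few bases past a planted boundary when a flanking
random base coincidentally matches the mtDNA, so only the truth-driven hit
path is boundary-exact.

## Calibration and problem sizes

The test suite and acceptance script run entirely on the generator at the
sizes above (seconds per experiment). Copy-number recovery is checked to 5%
relative error for planted CN ∈ {1, 2, 3, 6} at 30x; at that depth the
integer quantisation of `X_SC` contributes up to ~3.4% of that budget. The
null calibration of the BUSCO-mean CN (expected 1, tolerance ±2%) is run at
60x, where a ±1 mode error contributes at most 1/60 ≈ 1.7% — at 30x the
quantisation alone can exceed the band, which is a property of
integer-resolution modal estimation, not of the data. The SV dropout
experiment checks the consensus fraction at 30% per-platform dropout
against its binomial 99% interval around 0.7² = 0.49.

## Known limitations

- Proportional query-side trimming is exact only for ungapped hits; gapped
  alignments would need CIGAR-aware projection.
- The depth model ignores coverage autocorrelation; uncertainty estimates
  on real data are therefore optimistic.
- The consensus matcher is greedy (maximal, not maximum-cardinality
  matching); for well-separated call sets the two coincide, and tests bound
  the difference on random sets.
- Scaffold tidying consumes self-mapping fractions from an external
  aligner's output; it does not compute alignments.
- Full-scale NUMT counts on a real assembly additionally depend on the
  aligner version producing the hit table; the toolkit operates downstream
  of that choice.
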