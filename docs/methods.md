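# Methods

## Overview

`scgerm` re-implements, as a reusable tested pipeline, three analyses of
testis single-cell RNA-seq: inference of de novo germline substitutions from
barcoded read evidence; cell-type expression-bias statistics for gene groups
on scaled expression; and pseudotime expression-pattern classification. The
package consumes the outputs of standard upstream tools (a count-matrix
triplet, a cell-annotation table with pseudotime, VCFs from a conventional
caller, a per-read allele-evidence table); demultiplexing, clustering,
marker-based cell-type assignment and trajectory inference are out of scope.

Coordinates are 1-based (VCF convention) throughout. Variants are keyed by
the exact `(chrom, pos, ref, alt)` tuple; strand is ignored and substitution
classes are reference-strand base changes without complementing. All
thresholds are inclusive at their stated boundary.

## Expression transforms

Normalization follows the standard single-cell convention: feature counts of
each cell are divided by the cell total, multiplied by a scale factor
(default 10,000), and log1p-transformed. Zeros map to zeros, so sparsity is
preserved, and the transform is invariant to rescaling a cell's counts by a
positive factor. Cells with zero total counts are dropped with a warning by
default (configurable to an error).

Scaling is a per-gene z-score of the normalized layer across all cells, with
the n−1 sd denominator. Genes with zero sd map to all-zero rows rather than
NaN, for testability. No clipping is applied by default — common toolchains
clip scaled values at ±10, and whether the original analysis did is
unknowable from its description — but a symmetric `clip_z` option is
provided; none of the downstream rank-based statistics are sensitive to
clipping at that level.

`proportion_expressed` divides the number of detected set members by the
size of the set∩matrix intersection, not the full set: genes absent from the
matrix cannot be detected, and dividing by the full size would deflate every
proportion by a constant. The literal behaviour (`denominator="full"`) is
available.

## Gene-group expression bias

For every gene the mean scaled expression is computed within each cell type.
A focal group is compared with a comparison group (default: all other
genes, with focal members removed) in each cell type by a two-sample
Wilcoxon rank-sum (Mann–Whitney) test, two-sided, normal approximation with
tie correction and continuity correction. The description this re-implements
names a "Wilcoxon signed test", but a paired signed-rank test is undefined
for two unequal-size gene groups; the rank-sum form is the only well-defined
reading, and the paired signed-rank form is available when the groups are
equal-size and explicitly paired.

P values are adjusted by Hochberg's step-up procedure
(`p_adj(i) = min_{j≥i} (m−j+1)·p_(j)` on the sorted sequence, capped at 1),
with the family being the cell types within one focal/comparison pair —
matching a per-column presentation of such tables — via
`statsmodels.multipletests(method="simes-hochberg")`. Direction (UP/DOWN) is
the sign of the focal-minus-comparison median difference, reported as NS
when the adjusted p exceeds alpha. Because scaled expression is relative, a
group genuinely enriched in one stage will typically test DOWN in others;
this is a property of the statistic, not an artifact.

## Pseudotime patterns

Cells without pseudotime (the somatic branch forced onto the trajectory) are
excluded. Pseudotime is min-max rescaled to [0, 1], cells are binned into 50
equal-width bins, empty bins are filled from their nearest non-empty
neighbour (logged), and the bin means are smoothed with a local-linear
lowess fit (span 0.3 of the axis, no robustifying iterations).

The original classification of profiles into early / mid / late / bimodal
was qualitative; this package substitutes an explicit rule so the categories
are reproducible. The smoothed curve is min-max normalized; peaks are local
maxima — boundaries included, detected on a curve padded below its minimum —
with prominence ≥ 0.25 on the normalized curve. If the two tallest retained
peaks are ≥ 0.3 of the axis apart the profile is BIMODAL; otherwise the
dominant peak's position picks a tercile (EARLY < 1/3 ≤ MID ≤ 2/3 < LATE).
Curves whose range is below 0.05 of their maximum absolute value are flagged
flat and returned as MID. All four thresholds are keyword arguments. The
rule is invariant to affine transforms of the curve except where the
transform pushes a curve into the near-flat regime (flatness must be judged
relative to the curve's own scale, since a z-scored curve carries no
external unit), and relabelling pseudotime t → 1−t swaps EARLY and LATE
while fixing MID and BIMODAL. When several peaks tie, the tallest wins, so
genuinely ambiguous multi-peak curves resolve deterministically.

Parent–child concordance for duplicate gene pairs counts pairs whose two
members receive the same pattern label; pairs with a missing call are
skipped and logged.

## Germline-substitution inference

The cascade, in order, with per-step survivor counts reported:

1. **Quality**: call quality ≥ 25.
2. **Known sites**: exact-key exclusion against the union of one or more
   known-polymorphism VCFs (e.g. population panels for the sequenced
   strain). Multiallelic records in any VCF are skipped and counted, never
   split — silent splitting could double-count events.
3. **Reference depth**: reference-allele read coverage ≥ 10.
4. **Cell attachment**: per-read evidence is grouped per variant and
   barcode; distinct UMIs are counted per allele. Variants without at least
   one annotated alternate-allele cell are dropped.
5. **Somatic exclusion**: a variant whose alternate allele appears in any
   hub, cyst or epithelial cell is treated as inherited and removed. Only
   the ALT allele disqualifies — reference reads in somatic cells are
   expected for a genuine de novo variant and are recorded separately.
6. **Bulk (RNA editing)**: variants present in bulk-tissue calls are
   removed; recurrent editing would appear there. The A>G fraction of the
   spectrum before and after this step is reported as a diagnostic.
7. **Transcriptional-error screen**: a variant must meet ≥ 2 of:
   (C1) alternate allele in ≥ 2 germ cells; (C2) in every carrier the
   reference allele is absent or has UMI count ≤ the alternate's;
   (C3) for single-carrier variants, ≥ 2 alternate UMIs. C3 is counted as
   unmet (not "not applicable") for multi-carrier variants: such variants
   meet C1 anyway, so the choice only matters for variants that would
   otherwise pass on C2 alone, where the stricter reading was kept.
   "Multiple" means ≥ 2, configurable.

Surviving substitutions on the same chromosome within 10 bp (inclusive) of
each other that share ≥ 1 carrier cell are merged into events as connected
components of the resulting graph. Transitive closure is deliberate: a
chain a–b–c with |pos_c − pos_a| > 10 bp is still one event, since a single
mutational process (multi-nucleotide misincorporation, error-prone repair
tract) can span more than one pairwise window and member variants are
unevenly sampled across cells. Carrier-set *intersection* (≥ 1 shared cell),
not equality, links variants, because sampling noise makes exact carrier-set
equality too strict. The source texts give both "within 10 bp" and "< 20 bp"
for this window; the conservative 10 bp is the default and the window is
configurable.

An event is attributed to every cell type among its carrier cells, so
per-type counts may sum to more than the event total. Load is
L_t = E_t/(N_t·B_t) with E_t merged events by default (raw variants as an
option, since the two descriptions of the numerator differ), N_t the cells
of the type and B_t the type's callable bases (≥ 10 reads). Mutated-cell
proportions M_t/N_t get 95% Wilson score intervals (no continuity
correction; normal approximation available) — Wilson behaves correctly at
M = 0 and M = N, where the error bars must touch 0 and 1.

The trend test is the Cochran–Armitage chi-square for linear trend in
proportions with equally spaced scores 1..k over the declared stage order,
1 df, two-sided; it matches R's `prop.trend.test` exactly (frozen
cross-check in the tests) and reduces to the two-proportion chi-square for
k = 2. Degenerate inputs (pooled proportion 0 or 1, zero score variance)
return chi2 = 0, p = 1. The statistic is invariant under reversing the group
order; the reported direction is the sign of the score–proportion
covariance.

## Synthetic world

The generator's defaults are a fixed stated world, not tuning knobs.

**Cells.** Six germ stages × 200 cells and three somatic types × 50 cells.
Counts are gamma-Poisson (negative binomial, dispersion 2) over 1500 genes
with lognormal gene weights; mean cell depth is stage-specific (8k, 12k,
15k, 9k, 3k, 3k UMIs along the germline; 6k somatic) with lognormal jitter,
emulating RNA content that peaks in spermatocytes and collapses in
spermatids — gene detection falls with depth without separate modelling.
Pseudotime for a stage-s cell is uniform on [(s−1)/6, s/6]; somatic cells
carry none. Planted gene sets occupy disjoint gene blocks: a commonly
expressed set (5× weight), a rarely expressed set (0.2×), and a
spermatocyte-biased set (+1 log-fold in early spermatocytes); 25 genes per
pattern archetype modulate their mean by a bump template along pseudotime
(Gaussian bumps at 0.12 / 0.50 / 0.88, and a two-bump template at
0.15 + 0.85 for BIMODAL).

**Variants.** Per-stage true event counts derive from the planted loads
(5, 4, 3, 2, 1, 0)×10⁻⁸ per cell per base as E_t = round(L_t·N_t·B_t).
Callable bases default to a constant 10⁶ per type, which makes those counts
the exact integers (10, 8, 6, 4, 2, 0) — 30 events; a saturating
depth-proportional model is available but would subject the planted world to
rounding. Each event draws 2–4 carrier cells from its own stage, 2–4 ALT
UMIs per carrier with REF absent or ≤ ALT, and REF reads in 5 somatic cells
(securing reference depth ≥ 10); 10 of the 30 events are clustered, emitting
2–3 member variants 3–5 bp apart sharing the carriers. Contaminant classes
are constructed to fail exactly one filter each: 15 somatic-cell variants,
15 transcriptional errors (one germ carrier, one ALT UMI, REF > ALT), 10 A>G
editing sites listed in the bulk VCF, 10 known-site variants, 10 low-quality
calls (qual < 25), 10 calls with reference depth < 10. Unrelated variants
sit on a 50 bp grid so no accidental clustering is possible. All randomness
flows from one seed; identical seeds give byte-identical files.

**What a green test does not establish.** The generator has no ambient RNA,
doublets, read-level sequencing error, allele-specific expression, mappable
vs unmappable regions, or overlap between contaminant classes; each planted
class is removable by exactly one filter by construction. Exact ground-truth
recovery therefore validates the cascade's logic and bookkeeping, not its
operating characteristics on real data, where classes overlap and the
criteria trade sensitivity against specificity. A "hard mode" for power
analysis (ambiguous planted cases) would be a natural extension. Similarly,
the VCF `AD` depths are drawn, not derived read-by-read from the evidence
table, so depth-vs-evidence consistency is not exercised.

## Numerical notes

- VCF QUAL values pass through a float32 when re-read (htslib storage), so
  round-trips preserve quality only to ~7 significant digits; integer fields
  and strings are exact.
- The rank-sum p value uses the asymptotic normal approximation with tie
  correction; with ≥ 2000 comparison genes this is accurate far beyond the
  0.05 decision boundary, and its empirical type-I error at alpha = 0.05 is
  verified to lie in [0.03, 0.07].
- Event clustering is exact (checked against brute-force transitive closure
  on 1000 random instances), and scans sorted positions with early exit, so
  it is linear-ish in practice for sparse variant sets.
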