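# scgerm

Germline mutational load and cell-type expression bias from *Drosophila*
testis single-cell RNA-seq.

Single-cell RNA-seq of the testis captures every stage of spermatogenesis in
one experiment: germline stem cells and early spermatogonia, late
spermatogonia, early and late spermatocytes, early and late spermatids, plus
somatic hub, cyst and epithelial cells. Because the reads carry cell
barcodes and UMIs, the same data can be mined for two very different
signals, and this package implements the bespoke statistics for both:

1. **De novo germline substitutions.** Candidate SNVs from a conventional
   caller are passed through a filter cascade — call quality ≥ 25, exclusion
   of known population polymorphisms, reference-allele coverage ≥ 10, then,
   using per-read (barcode, UMI, allele) evidence: exclusion of any variant
   whose alternate allele appears in a somatic cell (inherited, not de
   novo), exclusion of variants present in bulk-tissue calls (recurrent RNA
   editing), and a 2-of-3 criterion screen against transcriptional errors
   (multiple germ-cell carriers; REF absent or ≤ ALT in every carrier;
   multiple ALT UMIs for single-cell variants). Surviving substitutions
   within 10 bp of each other sharing a carrier cell are merged (with
   transitive closure) into single *mutational events*. Per cell type *t*
   the pipeline reports the mutational load

   L_t = E_t / (N_t · B_t)

   (events per cell per callable base, with B_t the bases covered by ≥ 10
   reads), the proportion of mutated cells M_t / N_t with Wilson 95%
   intervals, a Cochran–Armitage chi-square test for linear trend in those
   proportions across the ordered germ stages, and the 12-class substitution
   spectrum (the A>G fraction diagnoses residual RNA editing).

2. **Cell-type expression bias of gene groups.** Counts are library-size
   normalized (`ln(1 + 10,000·c/total)`) and z-scaled per gene; for every
   gene the mean scaled expression per cell type is computed, and a focal
   gene group (de novo genes, DNA-repair genes, ribosomal proteins, …) is
   compared against all other genes within each cell type by a two-sided
   Wilcoxon rank-sum test, Hochberg-corrected across cell types, reported as
   a direction (UP/DOWN/NS) plus adjusted p.

3. **Pseudotime expression patterns.** Scaled expression is binned over the
   germline pseudotime axis, loess-smoothed, and classified by an explicit
   peak-based rule into EARLY / MID / LATE / BIMODAL, with per-group pattern
   proportions and parent–child concordance counts for duplicate gene pairs.

A fully seeded synthetic-data module (`scgerm.simulate`) generates every
input the pipeline consumes — count matrix, annotations, candidate / known /
bulk VCFs, read-evidence and coverage tables — with ground-truth labels, so
the whole analysis is testable end to end without the original data.

## Worked example

```python
import scgerm

bundle = scgerm.generate_bundle(scgerm.SimulationConfig(seed=1))
report = scgerm.run_pipeline(
    bundle.variants, bundle.evidence, bundle.annotation,
    bundle.known_keys, bundle.bulk_keys, bundle.coverage,
    scgerm.MutationPipelineConfig(),
)
print(report.steps.to_string(index=False))
```

```
          step  n_surviving
    candidates          117
       quality          107
   known_sites           97
     ref_depth           87
      attached           87
       somatic           72
          bulk           62
error_criteria           47
        events           30
```

Of 117 candidate variants, each filter removes exactly its planted
contaminant class (10 low-quality, 10 known polymorphisms, 10 with
insufficient reference coverage, 15 somatic-cell variants, 10 RNA-editing
sites, 15 transcriptional errors); the 47 surviving substitutions merge into
30 mutational events, recovering the planted per-stage load gradient
exactly:

```
              cell_type  n_events  n_cells  callable_bases         load
GSC/early spermatogonia        10      200         1000000 5.000000e-08
     late spermatogonia         8      200         1000000 4.000000e-08
    early spermatocytes         6      200         1000000 3.000000e-08
     late spermatocytes         4      200         1000000 2.000000e-08
       early spermatids         2      200         1000000 1.000000e-08
        late spermatids         0      200         1000000 0.000000e+00
```

and the trend in mutated-cell proportions is strongly decreasing
(`chi2=37.951, p=7.254e-10`), as planted. The same bundle demonstrates the
expression-bias test: the gene set planted with a +1 log-fold shift in early
spermatocytes comes out `UP` there (adjusted p ≈ 3.9e-31) and `DOWN` in the
other stages — scaled expression is relative, so enrichment in one stage
implies depletion elsewhere.

## Command line

```bash
scgerm simulate --seed 1 --outdir bundle
scgerm mutload --candidates bundle/cand.vcf --known bundle/known.vcf \
    --bulk bundle/bulk.vcf --evidence bundle/ev.tsv \
    --annotations bundle/ann.tsv --coverage bundle/cov.tsv --outdir out
scgerm normalize --mtx bundle --out metrics.tsv
scgerm bias --mtx bundle --annotations bundle/ann.tsv --gene-set focal.txt --out bias.tsv
scgerm patterns --mtx bundle --annotations bundle/ann.tsv --out patterns.tsv
```

`mutload` writes `steps.tsv` (per-filter survivor counts), `events.tsv`,
`load.tsv`, `proportions.tsv`, `trend.json` and `spectrum.tsv`.

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic world from the
given seed and re-runs the complete analysis from scratch — the filter
cascade with event clustering, load and proportion tables, the trend test,
the gene-group bias test on the planted set, and pattern-archetype
classification — printing the summary above and writing a JSON results file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical model, parameter defaults and the
limits of what the synthetic world can establish.
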