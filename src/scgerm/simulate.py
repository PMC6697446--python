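"""Seeded generators for every input the pipeline consumes, with ground truth.

The generator emulates the statistical structure the analysis assumes:

* stage-ordered germ-cell types with stage-specific RNA content (mean UMIs)
  and gene-detection complexity, plus somatic cell types without pseudotime;
* gene groups with planted per-stage expression shifts and baseline
  detection-rate differences;
* pseudotime expression archetypes (early / mid / late / bimodal bumps);
* variant read evidence containing true germline events with a stage-graded
  mutational load (some as clustered multi-nucleotide events), plus the
  contaminant classes the filter cascade exists to remove: somatic-cell
  variants, single-molecule transcriptional errors, A>G RNA-editing sites
  present in bulk calls, known population polymorphisms, and low-quality or
  low-reference-coverage calls.

Each contaminant class is constructed to pass every filter except the one
meant to remove it, so the class-conditional confusion matrix of the cascade
is diagonal under the default configuration.  All randomness flows from a
single seed; the same seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .io import (
    GERM_STAGES,
    SOMATIC_TYPES,
    CellAnnotation,
    ExpressionMatrix,
    GeneSet,
    ReadEvidence,
    VariantCall,
    VariantKey,
    write_annotations,
    write_count_matrix,
    write_coverage_table,
    write_evidence_table,
    write_sites_vcf,
    write_variants_vcf,
)

import pandas as pd

# Archetype bump centres on the [0, 1] pseudotime axis.
_ARCHETYPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "EARLY": lambda t: np.exp(-(((t - 0.12) / 0.18) ** 2)),
    "MID": lambda t: np.exp(-(((t - 0.50) / 0.18) ** 2)),
    "LATE": lambda t: np.exp(-(((t - 0.88) / 0.18) ** 2)),
    "BIMODAL": lambda t: np.maximum(
        np.exp(-(((t - 0.15) / 0.10) ** 2)), np.exp(-(((t - 0.85) / 0.10) ** 2))
    ),
}


def archetype_curve(pattern: str, t: np.ndarray) -> np.ndarray:
    """Noise-free template profile of a pattern archetype at pseudotime ``t``."""
    return _ARCHETYPES[pattern](np.asarray(t, dtype=float))


@dataclass
class GeneSetSpec:
    """A planted gene group: baseline detection scale and per-stage shifts.

    ``base_scale`` multiplies the baseline expression weight of every member
    (values > 1 make the set commonly expressed, < 1 rarely expressed);
    ``stage_shift`` maps a stage label to a log-fold expression change
    planted in that stage only.
    """

    name: str
    size: int
    base_scale: float = 1.0
    stage_shift: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """The stated world of the synthetic testis dataset.

    Defaults: six germ stages of 200 cells with RNA content peaking in
    spermatocytes and lowest in spermatids, three somatic types of 50 cells,
    1500 genes, a per-stage true mutational load declining linearly from
    5e-8 to 0 events per cell per callable base, 10 of the 30 resulting true
    events clustered as 2-3-variant multi-nucleotide events, and 15 / 15 /
    10 / 10 / 10 / 10 planted somatic, transcriptional-error, RNA-editing,
    known-site, low-quality and low-reference-depth contaminants.
    """

    seed: int = 1
    n_genes: int = 1500
    germ_cells_per_stage: dict[str, int] = field(
        default_factory=lambda: {s: 200 for s in GERM_STAGES}
    )
    somatic_cells_per_type: dict[str, int] = field(
        default_factory=lambda: {s: 50 for s in SOMATIC_TYPES}
    )
    stage_depth: dict[str, float] = field(
        default_factory=lambda: {
            "GSC/early spermatogonia": 8000.0,
            "late spermatogonia": 12000.0,
            "early spermatocytes": 15000.0,
            "late spermatocytes": 9000.0,
            "early spermatids": 3000.0,
            "late spermatids": 3000.0,
            "hub": 6000.0,
            "cyst": 6000.0,
            "epithelial": 6000.0,
        }
    )
    nb_dispersion: float = 2.0
    gene_sets: list[GeneSetSpec] = field(
        default_factory=lambda: [
            GeneSetSpec("commonly_expressed", 100, base_scale=5.0),
            GeneSetSpec("rarely_expressed", 100, base_scale=0.2),
            GeneSetSpec("spermatocyte_biased", 50,
                        stage_shift={"early spermatocytes": 1.0}),
        ]
    )
    n_pattern_genes_per_archetype: int = 25
    pattern_amplitude: float = 2.0
    # variant world
    chrom: str = "chrS"
    genome_length: int = 1_000_000
    stage_load: dict[str, float] = field(
        default_factory=lambda: dict(zip(GERM_STAGES, (5e-8, 4e-8, 3e-8, 2e-8, 1e-8, 0.0)))
    )
    callable_bases: int = 1_000_000
    callable_model: str = "constant"  # or "depth" (saturating in stage depth)
    n_clustered_events: int = 10
    n_somatic_contaminants: int = 15
    n_transcriptional_errors: int = 15
    n_editing_sites: int = 10
    n_known_sites: int = 10
    n_low_quality: int = 10
    n_low_ref_depth: int = 10
    carriers_per_event: tuple[int, int] = (2, 4)
    alt_umis_per_carrier: tuple[int, int] = (2, 4)


@dataclass
class SyntheticBundle:
    """In-memory form of the full input bundle plus its ground truth."""

    matrix: ExpressionMatrix
    annotation: CellAnnotation
    variants: list[VariantCall]
    known_keys: set[VariantKey]
    bulk_keys: set[VariantKey]
    evidence: list[ReadEvidence]
    coverage: dict[str, int]
    truth: dict


# ---------------------------------------------------------------------------
# Cells and expression
# ---------------------------------------------------------------------------


def generate_cells(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, CellAnnotation, dict]:
    """Simulate the count matrix and cell annotation with planted structure.

    Counts are gamma-Poisson (negative binomial) per gene and cell, with a
    cell mean depth set by the stage and per-cell lognormal jitter, so lower-
    depth stages naturally detect fewer genes.  Pattern-archetype genes
    modulate their expression along each germ cell's pseudotime; gene-set
    members apply their baseline scale and per-stage shifts.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    barcodes, cell_types, pseudotime = [], [], []
    stage_index = {s: i for i, s in enumerate(GERM_STAGES)}
    i_cell = 0
    for stage in GERM_STAGES:
        n = cfg.germ_cells_per_stage.get(stage, 0)
        k = stage_index[stage]
        t = rng.uniform(k / 6, (k + 1) / 6, size=n)
        for j in range(n):
            barcodes.append(f"BC{i_cell:05d}")
            cell_types.append(stage)
            pseudotime.append(t[j])
            i_cell += 1
    for stype in SOMATIC_TYPES:
        for _ in range(cfg.somatic_cells_per_type.get(stype, 0)):
            barcodes.append(f"BC{i_cell:05d}")
            cell_types.append(stype)
            pseudotime.append(np.nan)
            i_cell += 1
    n_cells = len(barcodes)
    pt = np.asarray(pseudotime)

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    weights = rng.lognormal(mean=0.0, sigma=1.2, size=cfg.n_genes)

    # planted gene sets: disjoint blocks of gene ids, recorded in the truth
    gene_sets: dict[str, GeneSet] = {}
    cursor = 0
    set_scale = np.ones(cfg.n_genes)
    stage_shift = np.zeros((cfg.n_genes, 9))  # per (gene, cell-type) log-fold shift
    all_types = list(GERM_STAGES) + list(SOMATIC_TYPES)
    type_index = {t: i for i, t in enumerate(all_types)}
    for spec in cfg.gene_sets:
        members = gene_ids[cursor: cursor + spec.size]
        if len(members) < spec.size:
            raise ValueError("gene sets exceed n_genes")
        cursor += spec.size
        gene_sets[spec.name] = GeneSet(spec.name, members)
        idx = slice(cursor - spec.size, cursor)
        set_scale[idx] = spec.base_scale
        for stage, shift in spec.stage_shift.items():
            stage_shift[idx, type_index[stage]] = shift

    # pattern archetypes occupy the genes after the planted sets
    pattern_truth: dict[str, str] = {}
    pattern_of_gene = np.full(cfg.n_genes, "", dtype=object)
    for pattern in ("EARLY", "MID", "LATE", "BIMODAL"):
        for _ in range(cfg.n_pattern_genes_per_archetype):
            if cursor >= cfg.n_genes:
                raise ValueError("pattern genes exceed n_genes")
            pattern_truth[gene_ids[cursor]] = pattern
            pattern_of_gene[cursor] = pattern
            cursor += 1

    depth = np.array([cfg.stage_depth[t] for t in cell_types])
    depth = depth * rng.lognormal(mean=0.0, sigma=0.25, size=n_cells)

    w = weights * set_scale
    factors = np.ones((cfg.n_genes, n_cells))
    type_col = np.array([type_index[t] for t in cell_types])
    factors *= np.exp(stage_shift[:, type_col])
    germ = ~np.isnan(pt)
    for gi in np.flatnonzero(pattern_of_gene != ""):
        f = np.full(n_cells, 0.2)
        f[germ] = 0.2 + cfg.pattern_amplitude * archetype_curve(pattern_of_gene[gi], pt[germ])
        factors[gi] *= f

    mean = (w / w.sum())[:, None] * depth[None, :] * factors
    theta = cfg.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = ExpressionMatrix(gene_ids, barcodes, sp.csr_matrix(counts))
    ann = CellAnnotation(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "cell_type": cell_types,
                "pseudotime": pt,
                "is_somatic": [t in SOMATIC_TYPES for t in cell_types],
            }
        )
    )
    truth = {"gene_sets": gene_sets, "patterns": pattern_truth}
    return matrix, ann, truth


def generate_archetype_profiles(
    n_genes: int,
    n_cells: int,
    noise_sd: float,
    rng: np.random.Generator,
    patterns: tuple[str, ...] = ("EARLY", "MID", "LATE", "BIMODAL"),
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-cell expression profiles drawn from the pattern archetypes.

    Returns ``(values, pseudotime, labels)`` where ``values`` is genes x
    cells, pseudotime is uniform on [0, 1] and each gene's label cycles
    through ``patterns``.
    """
    pt = rng.uniform(0.0, 1.0, size=n_cells)
    labels = [patterns[i % len(patterns)] for i in range(n_genes)]
    values = np.empty((n_genes, n_cells))
    for i, lab in enumerate(labels):
        values[i] = archetype_curve(lab, pt) + rng.normal(0.0, noise_sd, size=n_cells)
    return values, pt, labels


# ---------------------------------------------------------------------------
# Variants and read evidence
# ---------------------------------------------------------------------------

_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _random_substitution(rng) -> tuple[str, str]:
    ref = "ACGT"[rng.integers(4)]
    alt = _OTHER[ref][rng.integers(3)]
    return ref, alt


def _planted_event_counts(cfg: SimulationConfig, ann: CellAnnotation) -> dict[str, int]:
    n_by_type = ann.n_cells_by_type()
    counts = {}
    for stage in GERM_STAGES:
        n = n_by_type.get(stage, 0)
        b = _callable_bases(cfg, stage)
        counts[stage] = int(round(cfg.stage_load.get(stage, 0.0) * n * b))
    return counts


def _callable_bases(cfg: SimulationConfig, cell_type: str) -> int:
    if cfg.callable_model == "constant":
        return cfg.callable_bases
    # saturating in stage depth, anchored so the median-depth stage gets cfg.callable_bases
    d = cfg.stage_depth[cell_type]
    d0 = float(np.median(list(cfg.stage_depth.values())))
    return int(round(cfg.callable_bases * (2 * d / (d + d0))))


def generate_variant_truth(
    cfg: SimulationConfig, ann: CellAnnotation, rng: np.random.Generator | None = None
) -> tuple[list[VariantCall], set[VariantKey], set[VariantKey], list[ReadEvidence], dict[str, int], dict]:
    """Simulate candidate calls, site lists, read evidence, coverage and truth.

    True germline events are planted per stage at the configured target load
    (carriers drawn from that stage, multi-UMI ALT support, REF absent or
    below ALT in carriers, REF reads present in somatic cells); a configured
    number of them are clustered 2-3-variant events within the clustering
    window sharing carriers.  Each contaminant class violates exactly one
    filter.  Variant positions are laid on a 50 bp grid so no two unrelated
    variants can fall inside the clustering window.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    df = ann.table
    germ_by_stage = {
        s: df.loc[df["cell_type"] == s, "barcode"].tolist() for s in GERM_STAGES
    }
    somatic_cells = df.loc[df["is_somatic"], "barcode"].tolist()
    germ_cells_all = df.loc[~df["is_somatic"], "barcode"].tolist()

    event_counts = _planted_event_counts(cfg, ann)
    n_true = sum(event_counts.values())
    n_other = (
        cfg.n_somatic_contaminants + cfg.n_transcriptional_errors + cfg.n_editing_sites
        + cfg.n_known_sites + cfg.n_low_quality + cfg.n_low_ref_depth
    )
    grid = np.arange(100, cfg.genome_length - 100, 50)
    slots = np.sort(rng.choice(grid, size=n_true + n_other, replace=False))
    rng.shuffle(slots)
    slot_iter = iter(int(p) for p in slots)

    variants: list[VariantCall] = []
    evidence: list[ReadEvidence] = []
    known_keys: set[VariantKey] = set()
    bulk_keys: set[VariantKey] = set()
    variant_class: dict[VariantKey, str] = {}
    events_truth: list[dict] = []
    umi_counter = [0]

    def next_umi() -> str:
        umi_counter[0] += 1
        return f"U{umi_counter[0]:07d}"

    def add_evidence(key: VariantKey, barcode: str, allele: str, n_umis: int) -> int:
        chrom, pos, ref, alt = key
        for _ in range(n_umis):
            evidence.append(ReadEvidence(chrom, pos, ref, alt, barcode, next_umi(), allele))
        return n_umis

    def somatic_ref_background(key: VariantKey) -> int:
        total = 0
        cells = rng.choice(somatic_cells, size=5, replace=False)
        for bc in cells:
            total += add_evidence(key, str(bc), "REF", int(rng.integers(2, 5)))
        return total

    def make_variant(pos, ref, alt, qual, ref_depth, alt_depth) -> VariantCall:
        return VariantCall(cfg.chrom, pos, ref, alt, qual, ref_depth, alt_depth)

    def plant_carried_variant(pos, carriers, ref=None, alt=None, qual=None):
        """A variant with multi-UMI ALT support in the given carriers."""
        if ref is None:
            ref, alt = _random_substitution(rng)
        key = (cfg.chrom, pos, ref, alt)
        alt_total = 0
        for bc in carriers:
            n_alt = int(rng.integers(cfg.alt_umis_per_carrier[0], cfg.alt_umis_per_carrier[1] + 1))
            alt_total += add_evidence(key, bc, "ALT", n_alt)
            if rng.random() > 0.7:  # heterozygote-like carrier: REF <= ALT
                add_evidence(key, bc, "REF", int(rng.integers(1, n_alt + 1)))
        ref_depth = somatic_ref_background(key)
        q = float(rng.uniform(30, 60)) if qual is None else qual
        v = make_variant(pos, ref, alt, q, ref_depth, alt_total)
        variants.append(v)
        return v

    # --- true germline events, with a stage-graded load ---------------------
    flat_events = [(stage, i) for stage in GERM_STAGES for i in range(event_counts[stage])]
    clustered_idx = set(
        rng.choice(len(flat_events), size=min(cfg.n_clustered_events, len(flat_events)),
                   replace=False).tolist()
    )
    for ev_i, (stage, _) in enumerate(flat_events):
        pool = germ_by_stage[stage]
        k = int(rng.integers(cfg.carriers_per_event[0], cfg.carriers_per_event[1] + 1))
        carriers = [str(b) for b in rng.choice(pool, size=min(k, len(pool)), replace=False)]
        anchor = next(slot_iter)
        if ev_i in clustered_idx:
            n_members = int(rng.integers(2, 4))
            offsets = np.cumsum([0] + [int(rng.integers(3, 6)) for _ in range(n_members - 1)])
        else:
            offsets = np.array([0])
        member_keys = []
        for off in offsets:
            v = plant_carried_variant(anchor + int(off), carriers)
            variant_class[v.key] = "true"
            member_keys.append(v.key)
        events_truth.append({"members": member_keys, "stage": stage, "carriers": carriers})

    # --- somatic contaminants: ALT present in >= 1 somatic cell -------------
    for _ in range(cfg.n_somatic_contaminants):
        n_som = int(rng.integers(1, 3))
        n_germ = int(rng.integers(0, 4))
        carriers = [str(b) for b in rng.choice(somatic_cells, size=n_som, replace=False)]
        carriers += [str(b) for b in rng.choice(germ_cells_all, size=n_germ, replace=False)]
        v = plant_carried_variant(next(slot_iter), carriers)
        variant_class[v.key] = "somatic"

    # --- transcriptional errors: one cell, one ALT molecule, REF > ALT ------
    for _ in range(cfg.n_transcriptional_errors):
        pos = next(slot_iter)
        ref, alt = _random_substitution(rng)
        key = (cfg.chrom, pos, ref, alt)
        carrier = str(rng.choice(germ_cells_all))
        add_evidence(key, carrier, "ALT", 1)
        add_evidence(key, carrier, "REF", int(rng.integers(2, 6)))
        ref_depth = somatic_ref_background(key)
        v = make_variant(pos, ref, alt, float(rng.uniform(30, 60)), ref_depth, 1)
        variants.append(v)
        variant_class[v.key] = "transcriptional_error"

    # --- RNA-editing sites: A>G, recurrent, hence present in bulk calls -----
    for _ in range(cfg.n_editing_sites):
        carriers = [str(b) for b in rng.choice(germ_cells_all, size=int(rng.integers(2, 4)),
                                               replace=False)]
        v = plant_carried_variant(next(slot_iter), carriers, ref="A", alt="G")
        variant_class[v.key] = "editing"
        bulk_keys.add(v.key)

    # --- known population polymorphisms -------------------------------------
    for _ in range(cfg.n_known_sites):
        carriers = [str(b) for b in rng.choice(germ_cells_all, size=int(rng.integers(2, 4)),
                                               replace=False)]
        v = plant_carried_variant(next(slot_iter), carriers)
        variant_class[v.key] = "known"
        known_keys.add(v.key)

    # --- low-quality calls ---------------------------------------------------
    for _ in range(cfg.n_low_quality):
        carriers = [str(b) for b in rng.choice(germ_cells_all, size=2, replace=False)]
        v = plant_carried_variant(next(slot_iter), carriers, qual=float(rng.uniform(5, 24.5)))
        variant_class[v.key] = "low_quality"

    # --- calls with insufficient reference coverage --------------------------
    for _ in range(cfg.n_low_ref_depth):
        pos = next(slot_iter)
        ref, alt = _random_substitution(rng)
        key = (cfg.chrom, pos, ref, alt)
        carriers = [str(b) for b in rng.choice(germ_cells_all, size=2, replace=False)]
        alt_total = 0
        for bc in carriers:
            alt_total += add_evidence(key, bc, "ALT", int(rng.integers(2, 5)))
        ref_depth = int(rng.integers(0, 10))
        if ref_depth:
            add_evidence(key, str(rng.choice(somatic_cells)), "REF", min(ref_depth, 4))
        v = make_variant(pos, ref, alt, float(rng.uniform(30, 60)), ref_depth, alt_total)
        variants.append(v)
        variant_class[v.key] = "low_ref_depth"

    coverage = {t: _callable_bases(cfg, t) for t in list(GERM_STAGES) + list(SOMATIC_TYPES)}
    truth = {
        "variant_class": variant_class,
        "events": events_truth,
        "event_counts_per_stage": event_counts,
        "stage_load": dict(cfg.stage_load),
    }
    return variants, known_keys, bulk_keys, evidence, coverage, truth


# ---------------------------------------------------------------------------
# Bundle assembly and file output
# ---------------------------------------------------------------------------


def generate_bundle(cfg: SimulationConfig | None = None) -> SyntheticBundle:
    """Generate the full input bundle (expression + variants) from one seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    matrix, ann, cell_truth = generate_cells(cfg, rng)
    variants, known, bulk, evidence, coverage, var_truth = generate_variant_truth(cfg, ann, rng)
    truth = {**cell_truth, **var_truth}
    return SyntheticBundle(matrix, ann, variants, known, bulk, evidence, coverage, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as the on-disk formats the pipeline reads.

    Produces ``matrix.mtx``/``barcodes.tsv``/``features.tsv``, ``ann.tsv``,
    ``cand.vcf``, ``known.vcf``, ``bulk.vcf``, ``ev.tsv``, ``cov.tsv`` and a
    ``truth.json`` with the planted classes.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(bundle.matrix, outdir)
    write_annotations(bundle.annotation, outdir / "ann.tsv")
    write_variants_vcf(bundle.variants, outdir / "cand.vcf")
    write_sites_vcf(bundle.known_keys, outdir / "known.vcf")
    write_sites_vcf(bundle.bulk_keys, outdir / "bulk.vcf")
    write_evidence_table(bundle.evidence, outdir / "ev.tsv")
    write_coverage_table(bundle.coverage, outdir / "cov.tsv")
    truth = {
        "variant_class": {"|".join(map(str, k)): c for k, c in bundle.truth["variant_class"].items()},
        "events": [
            {
                "members": ["|".join(map(str, k)) for k in e["members"]],
                "stage": e["stage"],
                "carriers": e["carriers"],
            }
            for e in bundle.truth["events"]
        ],
        "event_counts_per_stage": bundle.truth["event_counts_per_stage"],
        "stage_load": bundle.truth["stage_load"],
        "patterns": bundle.truth["patterns"],
        "gene_sets": {n: sorted(s.members) for n, s in bundle.truth["gene_sets"].items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
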