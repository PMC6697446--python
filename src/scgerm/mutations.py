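"""Inference of de novo germline substitutions from barcoded read evidence.

The cascade mirrors the analysis it re-implements: candidate SNVs from an
external caller are filtered on call quality, known population polymorphisms
and reference-allele coverage; the surviving variants are joined to per-read
(cell barcode, UMI, allele) evidence; variants whose alternate allele appears
in any somatic cell (hub, cyst, epithelial) are discarded as inherited, and
variants present in bulk-tissue calls are discarded as likely RNA editing.
A 2-of-3 criterion screen removes likely transcriptional errors.  Nearby
surviving substitutions sharing carrier cells are merged into single
mutational events, from which per-cell-type load E/(N*B), mutated-cell
proportions with confidence intervals, a Cochran-Armitage trend test over
the ordered germ stages, and the substitution spectrum are computed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io import (
    GERM_STAGES,
    SOMATIC_TYPES,
    CellAnnotation,
    ReadEvidence,
    VariantCall,
    VariantKey,
)

logger = logging.getLogger(__name__)


@dataclass
class MutationPipelineConfig:
    """Thresholds of the filter cascade and downstream statistics.

    All thresholds are inclusive at the stated boundary.  ``min_qual`` is the
    caller quality cutoff; ``min_ref_depth`` the minimum reference-allele
    read coverage; ``cluster_window_bp`` the maximum distance between
    substitutions merged into one event (the conservative stated window;
    co-carried substitutions chain transitively, so wider clusters can
    emerge).  ``error_criteria_required`` is the number of transcriptional
    error criteria a variant must meet.  ``load_numerator`` selects whether
    per-type load counts merged events or raw variants.
    """

    min_qual: float = 25.0
    min_ref_depth: int = 10
    cluster_window_bp: int = 10
    min_cov_callable: int = 10
    somatic_types: frozenset[str] = frozenset(SOMATIC_TYPES)
    min_cells_multi: int = 2
    min_umis_multi: int = 2
    error_criteria_required: int = 2
    ci_method: str = "wilson"
    load_numerator: str = "events"

    def __post_init__(self) -> None:
        if self.error_criteria_required not in (1, 2, 3):
            raise ValueError("error_criteria_required must be 1, 2 or 3")
        if min(self.min_qual, self.min_ref_depth, self.cluster_window_bp,
               self.min_cov_callable, self.min_cells_multi, self.min_umis_multi) <= 0:
            raise ValueError("all thresholds must be > 0")
        if self.ci_method not in ("wilson", "normal"):
            raise ValueError("ci_method must be 'wilson' or 'normal'")
        if self.load_numerator not in ("events", "variants"):
            raise ValueError("load_numerator must be 'events' or 'variants'")


@dataclass
class VariantWithCells:
    """A candidate variant joined to its per-cell UMI evidence.

    ``alt_cells`` maps each barcode carrying the alternate allele to its
    ``(n_alt_umis, n_ref_umis)`` counts; ``ref_cells`` records reference-only
    barcodes (used to confirm the reference allele in somatic cells).
    """

    variant: VariantCall
    alt_cells: dict[str, tuple[int, int]]
    cell_types_touched: set[str] = field(default_factory=set)
    ref_cells: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    @property
    def carrier_cells(self) -> set[str]:
        return set(self.alt_cells)


@dataclass
class MutationalEvent:
    """One or more nearby, co-carried substitutions counted as a single mutation."""

    members: list[VariantKey]
    carrier_cells: set[str]
    cell_types_touched: set[str]


@dataclass
class TrendTestResult:
    """Cochran-Armitage chi-square test for linear trend in proportions (1 df)."""

    chi2: float
    p_value: float
    direction: str  # "decreasing", "increasing" or "none"
    proportions: list[float]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_quality(variants: list[VariantCall], cfg: MutationPipelineConfig) -> list[VariantCall]:
    """Keep variants with call quality >= ``min_qual`` (inclusive)."""
    kept = [v for v in variants if v.qual >= cfg.min_qual]
    logger.info("filter_quality: %d -> %d", len(variants), len(kept))
    return kept


def filter_known(variants: list[VariantCall], known_sites: set[VariantKey]) -> list[VariantCall]:
    """Exclude variants whose exact (chrom, pos, ref, alt) key is a known polymorphism."""
    kept = [v for v in variants if v.key not in known_sites]
    logger.info("filter_known: %d -> %d", len(variants), len(kept))
    return kept


def filter_ref_depth(variants: list[VariantCall], cfg: MutationPipelineConfig) -> list[VariantCall]:
    """Keep variants whose reference-allele read coverage is >= ``min_ref_depth``."""
    kept = [v for v in variants if v.ref_depth >= cfg.min_ref_depth]
    logger.info("filter_ref_depth: %d -> %d", len(variants), len(kept))
    return kept


def attach_cells(
    variants: list[VariantCall],
    evidence: list[ReadEvidence],
    ann: CellAnnotation,
) -> list[VariantWithCells]:
    """Join variants to per-cell UMI evidence; drop variants without annotated alt cells.

    Evidence rows whose barcode is not annotated are dropped (logged).  For
    each variant, every barcode with at least one ALT-allele UMI becomes an
    alt cell with its distinct ALT and REF UMI counts; reference-only
    barcodes are kept separately.
    """
    by_key: dict[VariantKey, dict[str, dict[str, set[str]]]] = defaultdict(
        lambda: defaultdict(lambda: {"ALT": set(), "REF": set()})
    )
    n_unannotated = 0
    for e in evidence:
        if ann.cell_type_of(e.barcode) is None:
            n_unannotated += 1
            continue
        by_key[e.variant_key][e.barcode][e.allele].add(e.umi)
    if n_unannotated:
        logger.info("attach_cells: dropped %d evidence rows from unannotated barcodes", n_unannotated)
    out: list[VariantWithCells] = []
    for v in variants:
        cells = by_key.get(v.key, {})
        alt_cells = {
            bc: (len(umis["ALT"]), len(umis["REF"]))
            for bc, umis in cells.items()
            if umis["ALT"]
        }
        if not alt_cells:
            continue
        ref_cells = {bc: len(u["REF"]) for bc, u in cells.items() if not u["ALT"] and u["REF"]}
        out.append(
            VariantWithCells(
                variant=v,
                alt_cells=alt_cells,
                cell_types_touched=ann.types_of(alt_cells),
                ref_cells=ref_cells,
            )
        )
    logger.info("attach_cells: %d -> %d variants with annotated alt cells", len(variants), len(out))
    return out


def filter_somatic(
    vwcs: list[VariantWithCells], cfg: MutationPipelineConfig
) -> list[VariantWithCells]:
    """Drop variants whose alternate allele appears in any somatic cell.

    Only the ALT allele disqualifies: reference reads in somatic cells are
    expected for genuine de novo germline variants and do not remove them.
    """
    kept = [v for v in vwcs if not (v.cell_types_touched & cfg.somatic_types)]
    logger.info("filter_somatic: %d -> %d", len(vwcs), len(kept))
    return kept


def filter_bulk(vwcs: list[VariantWithCells], bulk_sites: set[VariantKey]) -> list[VariantWithCells]:
    """Drop variants present in bulk-tissue calls (recurrent RNA editing screen)."""
    kept = [v for v in vwcs if v.key not in bulk_sites]
    logger.info("filter_bulk: %d -> %d (removed %d)", len(vwcs), len(kept), len(vwcs) - len(kept))
    return kept


def error_check(
    vwc: VariantWithCells, cfg: MutationPipelineConfig
) -> tuple[bool, set[str]]:
    """Transcriptional-error screen: which of the three criteria does a variant meet?

    C1: the alternate allele is found in multiple (>= ``min_cells_multi``)
    germ cells.  C2: in every alt cell the reference allele is absent or has
    at most as many UMIs as the alternate allele.  C3 (single-cell variants
    only): the alternate allele is on multiple (>= ``min_umis_multi``) UMIs.
    C3 counts as unmet for multi-cell variants.  A variant passes iff it
    meets at least ``error_criteria_required`` criteria.
    """
    met: set[str] = set()
    if len(vwc.alt_cells) >= cfg.min_cells_multi:
        met.add("C1")
    if all(n_ref == 0 or n_ref <= n_alt for n_alt, n_ref in vwc.alt_cells.values()):
        met.add("C2")
    if len(vwc.alt_cells) == 1:
        (n_alt, _), = vwc.alt_cells.values()
        if n_alt >= cfg.min_umis_multi:
            met.add("C3")
    return len(met) >= cfg.error_criteria_required, met


def filter_errors(
    vwcs: list[VariantWithCells], cfg: MutationPipelineConfig
) -> list[VariantWithCells]:
    """Apply :func:`error_check` to a list, keeping the variants that pass."""
    kept = [v for v in vwcs if error_check(v, cfg)[0]]
    logger.info("filter_errors: %d -> %d", len(vwcs), len(kept))
    return kept


# ---------------------------------------------------------------------------
# Event clustering
# ---------------------------------------------------------------------------


def cluster_events(
    vwcs: list[VariantWithCells], cfg: MutationPipelineConfig
) -> list[MutationalEvent]:
    """Merge nearby co-carried substitutions into single mutational events.

    Two variants are linked when they lie on the same chromosome within
    ``cluster_window_bp`` (inclusive) of each other AND share at least one
    carrier cell; events are the connected components of this graph
    (transitive closure, so chained clusters can span more than one window).
    Carrier cells of an event are the union over its members.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(vwcs)))
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, v in enumerate(vwcs):
        by_chrom[v.variant.chrom].append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: vwcs[i].variant.pos)
        for a in range(len(idxs)):
            i = idxs[a]
            for b in range(a + 1, len(idxs)):
                j = idxs[b]
                if vwcs[j].variant.pos - vwcs[i].variant.pos > cfg.cluster_window_bp:
                    break
                if vwcs[i].carrier_cells & vwcs[j].carrier_cells:
                    g.add_edge(i, j)
    events = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda i: (vwcs[i].variant.chrom, vwcs[i].variant.pos))
        carriers = set().union(*(vwcs[i].carrier_cells for i in members))
        types = set().union(*(vwcs[i].cell_types_touched for i in members))
        events.append(
            MutationalEvent(
                members=[vwcs[i].key for i in members],
                carrier_cells=carriers,
                cell_types_touched=types,
            )
        )
    events.sort(key=lambda e: e.members[0])
    logger.info("cluster_events: %d variants -> %d events", len(vwcs), len(events))
    return events


# ---------------------------------------------------------------------------
# Per-cell-type statistics
# ---------------------------------------------------------------------------


def events_per_type(events: list[MutationalEvent], ann: CellAnnotation) -> dict[str, int]:
    """Count events per cell type; an event counts once in every type with a carrier.

    One event may therefore count in several types, and the per-type counts
    can sum to more than the number of events.
    """
    counts: dict[str, int] = defaultdict(int)
    for ev in events:
        for t in ann.types_of(ev.carrier_cells):
            counts[t] += 1
    return dict(counts)


def mutational_load(
    e_by_type: dict[str, int],
    n_by_type: dict[str, int],
    b_by_type: dict[str, int],
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Per-type mutational load L = E / (N * B): events per cell per callable base.

    Types with zero cells or zero callable bases are excluded with a warning.
    """
    cell_types = cell_types or [t for t in GERM_STAGES if t in n_by_type]
    rows = []
    for t in cell_types:
        n, b = n_by_type.get(t, 0), b_by_type.get(t, 0)
        if n <= 0 or b <= 0:
            logger.warning("excluding type %r: N=%d, B=%d", t, n, b)
            continue
        e = e_by_type.get(t, 0)
        rows.append((t, e, n, b, e / (n * b)))
    return pd.DataFrame(rows, columns=["cell_type", "n_events", "n_cells", "callable_bases", "load"])


def mutated_cell_proportions(
    events: list[MutationalEvent],
    ann: CellAnnotation,
    cfg: MutationPipelineConfig,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Per-type count and proportion of cells carrying >= 1 event, with 95% CI."""
    carriers: set[str] = set().union(*(e.carrier_cells for e in events)) if events else set()
    n_by_type = ann.n_cells_by_type()
    cell_types = cell_types or [t for t in GERM_STAGES if t in n_by_type]
    carrier_types = [ann.cell_type_of(b) for b in carriers]
    m_by_type = pd.Series(carrier_types).value_counts().to_dict() if carriers else {}
    rows = []
    for t in cell_types:
        n = n_by_type.get(t, 0)
        if n == 0:
            continue
        m = m_by_type.get(t, 0)
        lo, hi = proportion_confint(m, n, alpha=0.05, method=cfg.ci_method)
        rows.append((t, m, n, m / n, max(float(lo), 0.0), min(float(hi), 1.0)))
    return pd.DataFrame(rows, columns=["cell_type", "n_mutated", "n_cells", "proportion", "ci_lo", "ci_hi"])


def trend_test(
    m: np.ndarray, n: np.ndarray, scores: np.ndarray | None = None
) -> TrendTestResult:
    """Cochran-Armitage chi-square test for linear trend in proportions.

    ``m[i]`` successes out of ``n[i]`` trials in ordered group ``i``; scores
    default to 1..k equally spaced.  The statistic is

        chi2 = (sum_i s_i (m_i - p n_i))^2 /
               [p (1-p) (sum_i n_i s_i^2 - (sum_i n_i s_i)^2 / N)]

    with p the pooled proportion and N the total count; 1 df, two-sided p.
    Degenerate inputs (all successes or none, or zero score variance) give
    chi2 = 0, p = 1.  The statistic is invariant under group-order reversal.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if m.shape != n.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("need >= 2 ordered groups with matching m, n")
    if np.any(m < 0) or np.any(m > n) or np.any(n <= 0):
        raise ValueError("require 0 <= m_i <= n_i and n_i > 0")
    s = np.arange(1, m.size + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    total = n.sum()
    p_bar = m.sum() / total
    props = (m / n).tolist()
    num = float(np.dot(s, m) - p_bar * np.dot(s, n))
    den = float(p_bar * (1 - p_bar) * (np.dot(n, s**2) - np.dot(n, s) ** 2 / total))
    if den <= 0:
        return TrendTestResult(0.0, 1.0, "none", props)
    chi2 = num**2 / den
    p_value = float(stats.chi2.sf(chi2, df=1))
    direction = "none" if num == 0 else ("increasing" if num > 0 else "decreasing")
    return TrendTestResult(float(chi2), p_value, direction, props)


SUBSTITUTION_CLASSES = tuple(f"{r}>{a}" for r, a in product("ACGT", repeat=2) if r != a)


def substitution_spectrum(variants: list[VariantCall]) -> pd.Series:
    """Tally the 12 reference-strand substitution classes (no complementing)."""
    counts = pd.Series(0, index=list(SUBSTITUTION_CLASSES), dtype=int)
    for v in variants:
        counts[f"{v.ref}>{v.alt}"] += 1
    return counts


def a_to_g_fraction(variants: list[VariantCall]) -> float:
    """Fraction of substitutions that are A>G (the RNA-editing signature)."""
    if not variants:
        return 0.0
    return sum(v.ref == "A" and v.alt == "G" for v in variants) / len(variants)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineReport:
    """Everything the cascade produces, including per-step survivor counts."""

    steps: pd.DataFrame
    variants_final: list[VariantWithCells]
    events: list[MutationalEvent]
    load: pd.DataFrame
    proportions: pd.DataFrame
    trend: TrendTestResult | None
    spectrum: pd.Series
    spectrum_prefilter: pd.Series


def run_pipeline(
    variants: list[VariantCall],
    evidence: list[ReadEvidence],
    ann: CellAnnotation,
    known_sites: set[VariantKey],
    bulk_sites: set[VariantKey],
    coverage: dict[str, int],
    cfg: MutationPipelineConfig | None = None,
) -> PipelineReport:
    """Run the full filter cascade and per-cell-type statistics.

    Order: quality -> known polymorphisms -> reference depth -> cell
    attachment -> somatic exclusion -> bulk (RNA editing) -> transcriptional
    error screen -> event clustering -> load / proportions / trend /
    spectrum.  The ``steps`` table records the survivor count after each
    stage.
    """
    cfg = cfg or MutationPipelineConfig()
    steps: list[tuple[str, int]] = [("candidates", len(variants))]

    v = filter_quality(variants, cfg)
    steps.append(("quality", len(v)))
    v = filter_known(v, known_sites)
    steps.append(("known_sites", len(v)))
    v = filter_ref_depth(v, cfg)
    steps.append(("ref_depth", len(v)))
    vwcs = attach_cells(v, evidence, ann)
    steps.append(("attached", len(vwcs)))
    vwcs = filter_somatic(vwcs, cfg)
    steps.append(("somatic", len(vwcs)))
    pre_bulk_variants = [x.variant for x in vwcs]
    vwcs = filter_bulk(vwcs, bulk_sites)
    steps.append(("bulk", len(vwcs)))
    vwcs = filter_errors(vwcs, cfg)
    steps.append(("error_criteria", len(vwcs)))
    events = cluster_events(vwcs, cfg)
    steps.append(("events", len(events)))

    n_by_type = ann.n_cells_by_type()
    if cfg.load_numerator == "events":
        e_by_type = events_per_type(events, ann)
    else:
        singleton = [MutationalEvent([x.key], x.carrier_cells, x.cell_types_touched) for x in vwcs]
        e_by_type = events_per_type(singleton, ann)
    germ_types = [t for t in GERM_STAGES if n_by_type.get(t, 0) > 0]
    load = mutational_load(e_by_type, n_by_type, coverage, germ_types)
    proportions = mutated_cell_proportions(events, ann, cfg, germ_types)
    trend = None
    if len(proportions) >= 2:
        trend = trend_test(
            proportions["n_mutated"].to_numpy(), proportions["n_cells"].to_numpy()
        )
    return PipelineReport(
        steps=pd.DataFrame(steps, columns=["step", "n_surviving"]),
        variants_final=vwcs,
        events=events,
        load=load,
        proportions=proportions,
        trend=trend,
        spectrum=substitution_spectrum([x.variant for x in vwcs]),
        spectrum_prefilter=substitution_spectrum(pre_bulk_variants),
    )
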