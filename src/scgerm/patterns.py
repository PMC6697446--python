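"""Deterministic classification of pseudotime expression profiles.

A gene's scaled expression over pseudotime is binned and loess-smoothed, then
classified as EARLY / MID / LATE / BIMODAL from the positions of the
prominent peaks of the smoothed curve.  The qualitative judgement of where a
profile is "biased" is replaced by an explicit, configurable rule: peaks are
local maxima with min-max-normalized prominence above a threshold; two
well-separated peaks make the profile bimodal, otherwise the dominant-peak
position is assigned to a tercile of the pseudotime axis.

Somatic cells forced onto the trajectory are excluded from all pseudotime
analyses (they carry no pseudotime in the annotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import GeneSet

logger = logging.getLogger(__name__)

PATTERNS = ("EARLY", "MID", "LATE", "BIMODAL")


@dataclass
class PatternCall:
    """Classified pseudotime expression profile of one gene."""

    gene_id: str
    pattern: str
    peak_positions: list[float]
    smoothed_curve: np.ndarray = field(repr=False)
    flat: bool = False


def smooth_over_pseudotime(
    values: np.ndarray,
    pt: np.ndarray,
    n_bins: int = 50,
    span: float = 0.3,
) -> np.ndarray:
    """Bin expression over rescaled pseudotime and loess-smooth the bin means.

    Pseudotime is min-max rescaled to [0, 1] and cells are assigned to
    ``n_bins`` equal-width bins; cells with undefined (NaN) pseudotime --
    e.g. somatic cells -- are dropped.  Empty bins are merged with their
    nearest non-empty neighbor (logged).  The bin means are smoothed with a
    local-linear (lowess) fit using the given span; the returned curve has
    length ``n_bins``.
    """
    values = np.asarray(values, dtype=float)
    pt = np.asarray(pt, dtype=float)
    ok = np.isfinite(pt) & np.isfinite(values)
    values, pt = values[ok], pt[ok]
    if values.size < n_bins:
        raise ValueError(f"need >= {n_bins} cells with defined pseudotime, got {values.size}")
    span_pt = pt.max() - pt.min()
    t = (pt - pt.min()) / span_pt if span_pt > 0 else np.zeros_like(pt)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(t, edges[1:-1]), 0, n_bins - 1)
    sums = np.bincount(which, weights=values, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nonzero = counts > 0
    means[nonzero] = sums[nonzero] / counts[nonzero]
    if not nonzero.all():
        logger.info("merging %d empty pseudotime bins with neighbors", int((~nonzero).sum()))
        idx_nonzero = np.flatnonzero(nonzero)
        for i in np.flatnonzero(~nonzero):
            nearest = idx_nonzero[np.argmin(np.abs(idx_nonzero - i))]
            means[i] = means[nearest]
    centers = (edges[:-1] + edges[1:]) / 2
    smoothed = lowess(means, centers, frac=span, it=0, return_sorted=False)
    return np.asarray(smoothed)


def classify_pattern(
    curve: np.ndarray,
    gene_id: str = "",
    prom_min: float = 0.25,
    min_separation: float = 0.3,
    flat_eps: float = 0.05,
) -> PatternCall:
    """Classify a smoothed pseudotime curve as EARLY / MID / LATE / BIMODAL.

    The curve is min-max normalized to [0, 1]; peaks are local maxima
    (boundaries included) with prominence >= ``prom_min`` on the normalized
    curve.  If the two tallest retained peaks are separated by at least
    ``min_separation`` of the axis the profile is BIMODAL; otherwise the
    dominant peak position p* picks a tercile: EARLY (p* < 1/3),
    MID (1/3 <= p* <= 2/3) or LATE (p* > 2/3).  Curves whose range is below
    ``flat_eps`` times their maximum absolute value are flagged flat and
    returned as MID.

    The rule is invariant to affine transforms ``a * curve + b`` (a > 0)
    away from the near-flat regime, and relabeling pseudotime t -> 1 - t
    swaps EARLY and LATE while fixing MID and BIMODAL.
    """
    curve = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve must be finite")
    n = curve.size
    rng_ = curve.max() - curve.min()
    scale = np.max(np.abs(curve))
    if scale == 0 or rng_ < flat_eps * scale:
        return PatternCall(gene_id, "MID", [float(np.argmax(curve)) / max(n - 1, 1)],
                           curve, flat=True)
    norm = (curve - curve.min()) / rng_
    # pad below the minimum so boundary maxima are detected with full prominence
    padded = np.concatenate(([-1.0], norm, [-1.0]))
    peaks, props = find_peaks(padded, prominence=prom_min)
    peaks = peaks - 1
    order = np.argsort(-norm[peaks]) if peaks.size else np.array([], dtype=int)
    positions = peaks / (n - 1)
    if peaks.size >= 2:
        top2 = np.sort(positions[order[:2]])
        if top2[1] - top2[0] >= min_separation:
            return PatternCall(gene_id, "BIMODAL", [float(top2[0]), float(top2[1])], curve)
    if peaks.size:
        p_star = float(positions[order[0]])
    else:  # no prominent peak survived; fall back to the global maximum
        p_star = float(np.argmax(norm)) / (n - 1)
    if p_star < 1 / 3:
        pattern = "EARLY"
    elif p_star > 2 / 3:
        pattern = "LATE"
    else:
        pattern = "MID"
    return PatternCall(gene_id, pattern, [p_star], curve)


def classify_genes(
    m,
    ann,
    genes: list[str] | None = None,
    n_bins: int = 50,
    span: float = 0.3,
    **classify_kwargs,
) -> dict[str, PatternCall]:
    """Smooth and classify the scaled pseudotime profile of each gene.

    Cells without pseudotime (the somatic branch) are excluded.  Requires a
    ``"scaled"`` layer on the matrix.
    """
    if "scaled" not in m.layers:
        raise ValueError('classify_genes requires a "scaled" layer')
    pt_by_barcode = dict(zip(ann.table["barcode"], ann.table["pseudotime"]))
    pt = np.array([pt_by_barcode.get(b, np.nan) for b in m.barcodes], dtype=float)
    z = np.asarray(m.layers["scaled"])
    genes = list(genes) if genes is not None else list(m.gene_ids)
    idx = m.gene_index(genes)
    calls = {}
    for g, i in zip(genes, idx):
        curve = smooth_over_pseudotime(z[i], pt, n_bins=n_bins, span=span)
        calls[g] = classify_pattern(curve, gene_id=g, **classify_kwargs)
    return calls


def pattern_table(calls: dict[str, PatternCall], groups: list[GeneSet]) -> pd.DataFrame:
    """Per-group fraction of genes in each pattern (unrounded; round for display)."""
    rows = []
    for grp in groups:
        members = [g for g in sorted(grp.members) if g in calls]
        missing = len(grp) - len(members)
        if missing:
            logger.warning("group %s: %d genes lack pattern calls", grp.name, missing)
        n = len(members)
        counts = {p: 0 for p in PATTERNS}
        for g in members:
            counts[calls[g].pattern] += 1
        row = {"group": grp.name, "n_genes": n}
        row.update({p: (counts[p] / n if n else 0.0) for p in PATTERNS})
        rows.append(row)
    return pd.DataFrame(rows)


def parent_child_concordance(
    pairs: list[tuple[str, str]], calls: dict[str, PatternCall]
) -> tuple[int, int]:
    """Count duplicate-gene pairs whose parent and child share a pattern label.

    Pairs with a missing call on either side are skipped (logged).  Returns
    ``(n_match, n_pairs)`` over the scorable pairs.
    """
    n_match = n_pairs = 0
    for parent, child in pairs:
        if parent not in calls or child not in calls:
            logger.warning("skipping pair (%s, %s): missing pattern call", parent, child)
            continue
        n_pairs += 1
        if calls[parent].pattern == calls[child].pattern:
            n_match += 1
    return n_match, n_pairs
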