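"""Expression transforms the downstream statistics are defined on.

Library-size normalization (counts / cell total x scale factor, log1p),
per-gene z-scaling across all cells, and per-cell summary metrics
(genes detected, UMIs, proportion of a gene set expressed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class NormalizationConfig:
    """Parameters of the library-size normalization and z-scaling.

    scale_factor
        Counts are rescaled so every cell totals this value before log1p
        (default 10,000, the standard single-cell convention).
    clip_z
        Optional symmetric clip for the scaled layer at ``+/- clip_z``;
        no clipping by default.
    drop_zero_cells
        Drop cells with zero total counts (with a warning) rather than
        raising.
    """

    scale_factor: float = 10_000.0
    clip_z: float | None = None
    drop_zero_cells: bool = True

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if self.clip_z is not None and self.clip_z <= 0:
            raise ValueError("clip_z must be > 0 when set")


def normalize_counts(
    m: ExpressionMatrix, cfg: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Add a ``"normalized"`` layer: ``ln(1 + scale_factor * c_gc / total_c)``.

    Zeros map to zeros, so the sparsity pattern is preserved.  The transform
    is invariant to rescaling all counts of a cell by a positive factor.
    """
    cfg = cfg or NormalizationConfig()
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        if not cfg.drop_zero_cells:
            raise ValueError("cells with zero total counts present and drop disabled")
        keep = totals > 0
        logger.warning("dropping %d cells with zero total counts", int((~keep).sum()))
        m = m.subset_cells(keep)
        totals = totals[keep]
    x = m.counts.astype(np.float64).tocsc()
    x = x.multiply(cfg.scale_factor / totals)  # broadcast over columns
    x = sp.csr_matrix(x)
    np.log1p(x.data, out=x.data)
    layers = dict(m.layers)
    layers["normalized"] = x
    return ExpressionMatrix(m.gene_ids, m.barcodes, m.counts, layers)


def scale_genes(m: ExpressionMatrix, clip_z: float | None = None) -> ExpressionMatrix:
    """Add a dense ``"scaled"`` layer: per-gene z-score of the normalized layer.

    Mean and sd are taken across all cells; sd uses the n-1 denominator.
    Genes with zero sd map to all-zero rows.  Optional symmetric clipping at
    ``+/- clip_z``.
    """
    if "normalized" not in m.layers:
        raise ValueError('scale_genes requires a "normalized" layer; run normalize_counts first')
    x = m.layers["normalized"]
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    if clip_z is not None:
        np.clip(z, -clip_z, clip_z, out=z)
    layers = dict(m.layers)
    layers["scaled"] = z
    return ExpressionMatrix(m.gene_ids, m.barcodes, m.counts, layers)


def genes_per_cell(m: ExpressionMatrix) -> np.ndarray:
    """Number of genes with non-zero counts in each cell."""
    return np.asarray((m.counts > 0).sum(axis=0)).ravel().astype(int)


def umis_per_cell(m: ExpressionMatrix) -> np.ndarray:
    """Total UMI count per cell (a proxy of cellular RNA content)."""
    return np.asarray(m.counts.sum(axis=0)).ravel().astype(int)


def proportion_expressed(
    m: ExpressionMatrix, s: GeneSet, denominator: str = "intersection"
) -> np.ndarray:
    """Per-cell fraction of a gene set detected (non-zero counts).

    ``denominator="intersection"`` divides by the number of set members
    measured in the matrix (genes absent from the matrix cannot be detected);
    ``"full"`` divides by the full set size.
    """
    if denominator not in ("intersection", "full"):
        raise ValueError("denominator must be 'intersection' or 'full'")
    inter = s.intersect(m.gene_ids)
    idx = m.gene_index(sorted(inter.members))
    detected = np.asarray((m.counts[idx, :] > 0).sum(axis=0)).ravel()
    denom = len(inter) if denominator == "intersection" else len(s)
    return detected / denom
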