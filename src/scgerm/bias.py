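"""Cell-type expression-bias statistics for gene groups on scaled expression.

For every gene the mean scaled (z-scored) expression is computed within each
cell type; a focal gene group is then compared against a comparison group in
each cell type with a two-sided rank test, and the per-cell-type p values
are adjusted by Hochberg's step-up procedure.  Each result carries a
direction (UP / DOWN / NS) from the group medians, mirroring the
arrow-plus-adjusted-p presentation used for gene-group bias tables.

The comparison of two unequal-size gene groups only admits the two-sample
(rank-sum / Mann-Whitney) form of the Wilcoxon test; the paired signed-rank
form is offered for equal-size, explicitly paired groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CellAnnotation, ExpressionMatrix, GeneSet


@dataclass(frozen=True)
class BiasTestResult:
    """Directional bias of a focal gene group in one cell type."""

    focal_set: str
    comparison_set: str
    cell_type: str
    direction: str  # "UP", "DOWN" or "NS"
    p_raw: float
    p_adj: float
    n_focal: int
    n_comparison: int


def mean_scaled_by_type(m: ExpressionMatrix, ann: CellAnnotation) -> pd.DataFrame:
    """Per-gene mean scaled expression within each cell type.

    Returns a genes x cell-types DataFrame.  Every barcode of the matrix
    must be annotated; cell types with zero cells are absent from the result.
    """
    if "scaled" not in m.layers:
        raise ValueError('mean_scaled_by_type requires a "scaled" layer')
    types = [ann.cell_type_of(b) for b in m.barcodes]
    if any(t is None for t in types):
        missing = [b for b, t in zip(m.barcodes, types) if t is None]
        raise ValueError(f"{len(missing)} matrix barcodes lack annotations (e.g. {missing[0]!r})")
    z = np.asarray(m.layers["scaled"])
    out = {}
    types_arr = np.array(types)
    for t in pd.unique(types_arr):
        out[t] = z[:, types_arr == t].mean(axis=1)
    return pd.DataFrame(out, index=m.gene_ids)


def hochberg_adjust(p: np.ndarray) -> np.ndarray:
    """Hochberg step-up adjusted p values, capped at 1.

    ``p_adj_(i) = min over j >= i of (m - j + 1) * p_(j)`` on the sorted
    sequence, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="simes-hochberg")[1]


def bias_test(
    means: pd.DataFrame,
    focal: GeneSet,
    comparison: GeneSet,
    family: list[str] | None = None,
    alpha: float = 0.05,
    test: str = "ranksum",
) -> list[BiasTestResult]:
    """Directional rank test of a focal gene group against a comparison group.

    Parameters
    ----------
    means
        Genes x cell-types mean scaled expression (from
        :func:`mean_scaled_by_type`).
    focal, comparison
        Gene groups; focal members are removed from the comparison group
        ("all other genes" excludes the group itself).
    family
        Cell types forming the multiple-testing family (default: all columns
        of ``means``); Hochberg adjustment is applied across this family for
        this focal/comparison pair.
    alpha
        Significance level; direction is NS iff adjusted p > alpha.
    test
        ``"ranksum"`` (two-sample Mann-Whitney, normal approximation with tie
        and continuity correction) or ``"signed-rank"`` (paired Wilcoxon;
        requires equal-size groups whose order defines the pairing).
    """
    family = list(family) if family is not None else list(means.columns)
    focal_genes = sorted(focal.members & set(means.index))
    comp_genes = sorted((comparison.members - focal.members) & set(means.index))
    if len(focal_genes) < 2 or len(comp_genes) < 2:
        raise ValueError("each group needs >= 2 genes with defined means")
    if test not in ("ranksum", "signed-rank"):
        raise ValueError("test must be 'ranksum' or 'signed-rank'")
    if test == "signed-rank" and len(focal_genes) != len(comp_genes):
        raise ValueError("signed-rank form requires equal-size, paired groups")

    p_raw, med_diff = [], []
    for t in family:
        a = means.loc[focal_genes, t].to_numpy()
        b = means.loc[comp_genes, t].to_numpy()
        if test == "ranksum":
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        else:
            res = stats.wilcoxon(a, b, alternative="two-sided")
        p_raw.append(float(res.pvalue))
        med_diff.append(float(np.median(a) - np.median(b)))
    p_adj = hochberg_adjust(np.clip(p_raw, np.nextafter(0, 1), 1.0))

    results = []
    for t, pr, pa, d in zip(family, p_raw, p_adj, med_diff):
        if pa > alpha or d == 0:
            direction = "NS"
        else:
            direction = "UP" if d > 0 else "DOWN"
        results.append(
            BiasTestResult(
                focal_set=focal.name,
                comparison_set=comparison.name,
                cell_type=t,
                direction=direction,
                p_raw=pr,
                p_adj=float(pa),
                n_focal=len(focal_genes),
                n_comparison=len(comp_genes),
            )
        )
    return results


def bias_table(results: list[BiasTestResult]) -> pd.DataFrame:
    """Tabulate bias-test results (one row per cell type)."""
    return pd.DataFrame(
        [
            (r.focal_set, r.comparison_set, r.cell_type, r.direction, r.p_raw, r.p_adj,
             r.n_focal, r.n_comparison)
            for r in results
        ],
        columns=[
            "focal_set", "comparison_set", "cell_type", "direction",
            "p_raw", "p_adj", "n_focal", "n_comparison",
        ],
    )
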