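"""Readers, writers and domain types for every external file the pipeline touches.

All downstream modules operate on the in-memory types defined here:
:class:`ExpressionMatrix`, :class:`CellAnnotation`, :class:`GeneSet`,
:class:`VariantCall`, :class:`ReadEvidence` and the coverage table.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere (VCF convention).
* Variants are identified by the exact key ``(chrom, pos, ref, alt)``;
  strand is ignored and substitution classes are reference-strand base changes.
* TSV files are tab-separated UTF-8 with a header row; ``#`` comment lines
  are ignored.
* Multiallelic VCF records are skipped (with a logged count), never split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Germ-cell stages in developmental order (index 0..5).
GERM_STAGES: tuple[str, ...] = (
    "GSC/early spermatogonia",
    "late spermatogonia",
    "early spermatocytes",
    "late spermatocytes",
    "early spermatids",
    "late spermatids",
)

#: Somatic cell types of the testis (hub, cyst, terminal epithelial cells).
SOMATIC_TYPES: tuple[str, ...] = ("hub", "cyst", "epithelial")

CELL_TYPE_ONTOLOGY: tuple[str, ...] = GERM_STAGES + SOMATIC_TYPES

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file violated its declared format or an invariant of a domain type."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x cell count matrix with optional derived layers.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers (rows).
    barcodes
        Unique cell barcodes (columns).
    counts
        Sparse non-negative integer matrix of shape ``(n_genes, n_cells)``.
    layers
        Optional real-valued matrices keyed by name (``"normalized"``,
        ``"scaled"``), each with the same shape as ``counts``.
    """

    gene_ids: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix
    layers: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate cell barcodes")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be non-negative integers")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise FormatError(f"layer {name!r} shape mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the cells selected by ``keep`` (bool or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        barcodes = [self.barcodes[i] for i in keep]
        layers = {
            name: (layer.tocsc()[:, keep].tocsr() if sp.issparse(layer) else layer[:, keep])
            for name, layer in self.layers.items()
        }
        return ExpressionMatrix(list(self.gene_ids), barcodes, self.counts[:, keep], layers)

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes, scanpy orientation)."""
        import anndata

        ad = anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=self.barcodes),
            var=pd.DataFrame(index=self.gene_ids),
        )
        for name, layer in self.layers.items():
            ad.layers[name] = layer.T.tocsr() if sp.issparse(layer) else np.asarray(layer).T
        return ad


def read_count_matrix(mtx_path, barcodes_path, features_path) -> ExpressionMatrix:
    """Read a 10X-style Matrix Market triplet (genes in rows, cells in columns)."""
    mat = scipy.io.mmread(str(mtx_path))
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} but features/barcodes "
            f"files declare {len(features)} x {len(barcodes)}"
        )
    return ExpressionMatrix(features, barcodes, sp.csr_matrix(mat))


def write_count_matrix(m: ExpressionMatrix, outdir) -> None:
    """Write the triplet ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), m.counts.astype(np.int64), field="integer")
    (outdir / "barcodes.tsv").write_text("\n".join(m.barcodes) + "\n")
    (outdir / "features.tsv").write_text("\n".join(m.gene_ids) + "\n")


def _read_id_column(path) -> list[str]:
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line.split("\t")[0])
    return ids


# ---------------------------------------------------------------------------
# Cell annotation
# ---------------------------------------------------------------------------


@dataclass
class CellAnnotation:
    """Barcode -> (cell type, pseudotime, somatic flag) table.

    Cell types come from the declared ontology: six germ stages with an
    explicit total order plus three somatic labels.  ``is_somatic`` is true
    iff the cell type is a somatic label; pseudotime may be missing (NaN),
    and is always missing for somatic cells forced onto the trajectory.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = {"barcode", "cell_type", "pseudotime", "is_somatic"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"annotation table missing columns: {sorted(missing)}")
        if df["barcode"].duplicated().any():
            raise FormatError("duplicate barcodes in annotation table")
        bad = set(df["cell_type"]) - set(CELL_TYPE_ONTOLOGY)
        if bad:
            raise FormatError(f"unknown cell types: {sorted(bad)}")
        somatic = df["cell_type"].isin(SOMATIC_TYPES)
        if not (df["is_somatic"].astype(bool) == somatic).all():
            raise FormatError("is_somatic flag inconsistent with cell_type ontology")
        df = df.reset_index(drop=True)
        df["pseudotime"] = pd.to_numeric(df["pseudotime"], errors="coerce")
        self.table = df
        self._type_of = dict(zip(df["barcode"], df["cell_type"]))

    @property
    def barcodes(self) -> pd.Series:
        return self.table["barcode"]

    def cell_type_of(self, barcode: str) -> str | None:
        return self._type_of.get(barcode)

    def n_cells_by_type(self) -> dict[str, int]:
        return self.table["cell_type"].value_counts().to_dict()

    def germ_mask(self) -> np.ndarray:
        return ~self.table["is_somatic"].to_numpy(dtype=bool)

    def types_of(self, barcodes: Iterable[str]) -> set[str]:
        return {self._type_of[b] for b in barcodes if b in self._type_of}


def read_annotations(path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "is_somatic" in df.columns:
        df["is_somatic"] = df["is_somatic"].astype(str).str.lower().isin(
            {"true", "1", "yes"}
        )
    return CellAnnotation(df)


def write_annotations(ann: CellAnnotation, path) -> None:
    df = ann.table.copy()
    df["is_somatic"] = df["is_somatic"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers (e.g. de novo genes, DNA-repair genes)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, gene_ids: Iterable[str]) -> "GeneSet":
        """Intersect with the measured gene universe; the retained size is logged."""
        inter = self.members & set(gene_ids)
        if not inter:
            raise FormatError(
                f"gene set {self.name!r} has no members in the expression matrix"
            )
        logger.info(
            "gene set %s: %d/%d members present in matrix", self.name, len(inter), len(self)
        )
        return GeneSet(self.name, inter)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set from a one-gene-per-line text file."""
    path = Path(path)
    members = {
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return GeneSet(name or path.stem, members)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantCall:
    """A biallelic candidate SNV with call quality and per-allele read depths."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise FormatError(f"{self.chrom}:{self.pos} ref/alt must be single A/C/G/T bases")
        if self.ref == self.alt:
            raise FormatError(f"{self.chrom}:{self.pos} has ref == alt ({self.ref})")
        if self.pos < 1:
            raise FormatError(f"position {self.pos} < 1")
        if self.qual < 0 or self.ref_depth < 0 or self.alt_depth < 0:
            raise FormatError(f"{self.chrom}:{self.pos} negative quality or depth")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_variants(vcf_path, require_depths: bool = True) -> list[VariantCall]:
    """Read biallelic SNVs from a VCF; indels and multiallelic records are skipped.

    Per-allele depths are taken from the first sample's ``AD`` field (or from
    ``INFO/AD``).  A record without depth information raises unless
    ``require_depths`` is false (then depths are 0).
    """
    variants: list[VariantCall] = []
    n_skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pysam warns on headers without contig lines
        vcf = pysam.VariantFile(str(vcf_path))
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            if rec.ref not in _BASES or alts[0] not in _BASES:
                n_skipped += 1
                continue
            ad = _allele_depths(rec)
            if ad is None:
                if require_depths:
                    raise FormatError(
                        f"record {rec.chrom}:{rec.pos} has no AD depth information"
                    )
                ad = (0, 0)
            variants.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alts[0],
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    ref_depth=int(ad[0]),
                    alt_depth=int(ad[1]),
                )
            )
    if n_skipped:
        logger.info("read_variants(%s): skipped %d non-SNV/multiallelic records", vcf_path, n_skipped)
    return variants


def _allele_depths(rec) -> tuple[int, int] | None:
    for sample in rec.samples.values():
        ad = sample.get("AD")
        if ad is not None and ad[0] is not None:
            return int(ad[0]), int(ad[1])
    try:
        ad = rec.info.get("AD")
    except ValueError:  # AD not declared in the header
        ad = None
    if ad is not None:
        ad = (ad,) if np.isscalar(ad) else tuple(ad)
        if len(ad) >= 2:
            return int(ad[0]), int(ad[1])
    return None


def read_site_keys(vcf_path) -> set[VariantKey]:
    """Collect ``(chrom, pos, ref, alt)`` SNV keys from a sites VCF (known / bulk calls)."""
    keys: set[VariantKey] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcf = pysam.VariantFile(str(vcf_path))
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and rec.ref in _BASES and alt in _BASES:
                    keys.add((rec.chrom, rec.pos, rec.ref, alt))
    return keys


def write_variants_vcf(variants: Sequence[VariantCall], path, sample: str = "sample") -> None:
    """Write calls as a minimal VCF 4.2 with a single sample carrying GT:AD."""
    chroms: dict[str, int] = {}
    for v in variants:
        chroms[v.chrom] = max(chroms.get(v.chrom, 0), v.pos + 1000)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in sorted(chroms.items())]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:.12g}\t.\t.\t"
            f"GT:AD\t0/1:{v.ref_depth},{v.alt_depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_vcf(keys: Iterable[VariantKey], path) -> None:
    """Write a sites-only VCF (known-polymorphism or bulk-tissue call lists)."""
    keys = sorted(set(keys))
    chroms: dict[str, int] = {}
    for chrom, pos, _, _ in keys:
        chroms[chrom] = max(chroms.get(chrom, 0), pos + 1000)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in sorted(chroms.items())]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, ref, alt in keys:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Per-read allele evidence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadEvidence:
    """One UMI's allele observation at a variant site in one cell."""

    chrom: str
    pos: int
    ref: str
    alt: str
    barcode: str
    umi: str
    allele: str  # "REF" or "ALT"

    def __post_init__(self) -> None:
        if self.allele not in ("REF", "ALT"):
            raise FormatError(f"allele must be REF or ALT, got {self.allele!r}")

    @property
    def variant_key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


_EVIDENCE_COLUMNS = ["chrom", "pos", "ref", "alt", "barcode", "umi", "allele"]


def read_evidence_table(path) -> list[ReadEvidence]:
    """Read per-read allele evidence; exact duplicate rows are collapsed with a warning."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "barcode": str, "umi": str})
    missing = set(_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"evidence table missing columns: {sorted(missing)}")
    n_raw = len(df)
    df = df.drop_duplicates(subset=_EVIDENCE_COLUMNS)
    if len(df) < n_raw:
        warnings.warn(
            f"evidence table {path}: collapsed {n_raw - len(df)} duplicate rows",
            stacklevel=2,
        )
    bad = set(df["allele"]) - {"REF", "ALT"}
    if bad:
        raise FormatError(f"evidence allele values outside REF/ALT: {sorted(bad)}")
    return [
        ReadEvidence(r.chrom, int(r.pos), r.ref, r.alt, r.barcode, r.umi, r.allele)
        for r in df.itertuples(index=False)
    ]


def write_evidence_table(evidence: Sequence[ReadEvidence], path) -> None:
    df = pd.DataFrame(
        [(e.chrom, e.pos, e.ref, e.alt, e.barcode, e.umi, e.allele) for e in evidence],
        columns=_EVIDENCE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Callable-base coverage
# ---------------------------------------------------------------------------


def read_coverage_table(path) -> dict[str, int]:
    """Read per-cell-type callable-base counts (bases covered by >= min_cov reads)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"cell_type", "callable_bases"} - set(df.columns)
    if missing:
        raise FormatError(f"coverage table missing columns: {sorted(missing)}")
    if df["cell_type"].duplicated().any():
        raise FormatError("coverage table has duplicate cell types")
    if (df["callable_bases"] < 0).any():
        raise FormatError("callable_bases must be >= 0")
    return dict(zip(df["cell_type"], df["callable_bases"].astype(int)))


def write_coverage_table(coverage: Mapping[str, int], path) -> None:
    pd.DataFrame(
        {"cell_type": list(coverage), "callable_bases": list(coverage.values())}
    ).to_csv(path, sep="\t", index=False)
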