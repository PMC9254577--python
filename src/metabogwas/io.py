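"""Genotype, expression, and annotation I/O plus the panel's quality-control filters.

Genotypes are held as an accessions x SNPs additive dosage matrix (alt-allele
counts 0/1/2, ``nan`` for missing). Coordinates are 1-based inclusive
internally; BED export converts to 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "GeneModel",
    "ExpressionMatrix",
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "write_gff3",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_bed",
    "hwe_exact_test",
    "filter_variants",
    "filter_expressed_genes",
]


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNP with its per-panel QC statistics."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float
    missing_rate: float
    hwe_p: float
    vid: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide bi-allelic variants are supported")


@dataclass
class GeneModel:
    """A gene span with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with per-variant metadata.

    ``dosage[i, j]`` is the alt-allele count of sample i at variant j;
    missing genotypes are ``nan`` and left to downstream consumers to impute.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # float, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def maf_from_dosage(self) -> np.ndarray:
        """Recompute minor allele frequencies from the dosage matrix."""
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.dosage, axis=0) / 2.0
        p_alt = np.where(np.isnan(p_alt), 0.0, p_alt)
        return np.minimum(p_alt, 1.0 - p_alt)

    def missing_rate_from_dosage(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def subset_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dosage=self.dosage[:, idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=list(self.variants),
            dosage=self.dosage[idx, :],
        )


@dataclass
class ExpressionMatrix:
    """Accessions x genes abundance matrix (FPKM-like, non-negative)."""

    samples: list[str]
    genes: list[GeneModel]
    values: np.ndarray  # shape (n_samples, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("values shape does not match samples x genes")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in ExpressionMatrix")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subset_genes(self, idx: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            samples=list(self.samples),
            genes=[self.genes[i] for i in idx],
            values=self.values[:, idx],
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _variant_stats(col: np.ndarray) -> tuple[float, float, float]:
    """(maf, missing_rate, hwe_p) for one dosage column."""
    miss = np.isnan(col)
    missing_rate = float(miss.mean()) if col.size else 0.0
    obs = col[~miss]
    if obs.size == 0:
        return 0.0, missing_rate, 1.0
    p_alt = float(obs.mean()) / 2.0
    maf = min(p_alt, 1.0 - p_alt)
    n_aa = int(np.sum(obs == 0))
    n_het = int(np.sum(obs == 1))
    n_AA = int(np.sum(obs == 2))
    return maf, missing_rate, hwe_exact_test(n_AA, n_het, n_aa)


def read_vcf(path: str | Path, strict: bool = False) -> GenotypeMatrix:
    """Read a VCF v4.x into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped (or rejected when ``strict=True``).
    ``./.`` genotypes become ``nan``. Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if strict:
                raise ValueError(
                    f"non-bi-allelic SNP record at {rec.CHROM}:{rec.POS}"
                )
            logger.warning("skipping non-bi-allelic record at %s:%d", rec.CHROM, rec.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        maf, miss, hwe = _variant_stats(col)
        variants.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                maf=maf,
                missing_rate=miss,
                hwe_p=hwe,
                vid=rec.ID or f"{rec.CHROM}:{rec.POS}",
            )
        )
        cols.append(col)
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT fields."""
    path = Path(path)
    chrom_max: dict[str, int] = {}
    for v in g.variants:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, v in enumerate(g.variants):
            gts = [
                _GT_CODE.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosage[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / expression
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, featuretype: str = "gene") -> list[GeneModel]:
    """Read gene models from a GFF3 file (in-memory gffutils database)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    genes = []
    for feat in db.features_of_type(featuretype, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmetabogwas\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a samples x features TSV (first column sample id, header feature ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample_id", float_format="%.10g")


def read_expression_tsv(path: str | Path, genes: Sequence[GeneModel]) -> ExpressionMatrix:
    """Read an expression TSV and attach gene models (order taken from the TSV)."""
    df = read_matrix_tsv(path)
    by_id = {g.gene_id: g for g in genes}
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise ValueError(f"{len(missing)} expression columns lack gene models, e.g. {missing[:3]}")
    return ExpressionMatrix(
        samples=list(df.index.astype(str)),
        genes=[by_id[c] for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_tsv(e: ExpressionMatrix, path: str | Path) -> None:
    write_matrix_tsv(
        pd.DataFrame(e.values, index=e.samples, columns=e.gene_ids), path
    )


def write_bed(
    intervals: Iterable[tuple[str, int, int]],
    path: str | Path,
    extra: Sequence[Sequence] | None = None,
) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED lines."""
    extra = list(extra) if extra is not None else None
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            cols = [chrom, str(start - 1), str(end)]
            if extra is not None:
                cols += [str(x) for x in extra[i]]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test probability.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote configurations no more likely than the observed one
    (Wigginton-style enumeration, no mid-p correction). Monomorphic sites
    return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_alt = 2 * n_AA + n_Aa
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log multinomial probability up to a constant shared by all configurations
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_Aa]
    if p_obs.size == 0:  # parity mismatch cannot happen with consistent counts
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def filter_variants(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.2,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Apply the panel's SNP QC: drop MAF < ``maf_min``, missing rate >
    ``miss_max``, and HWE exact p < ``hwe_p_min``. Order preserved."""
    maf = np.array([v.maf for v in g.variants])
    miss = np.array([v.missing_rate for v in g.variants])
    hwe = np.array([v.hwe_p for v in g.variants])
    keep = (maf >= maf_min) & (miss <= miss_max) & (hwe >= hwe_p_min)
    logger.info(
        "filter_variants: %d/%d retained (removed: %d by MAF, %d by missingness, %d by HWE)",
        int(keep.sum()), g.n_variants,
        int((maf < maf_min).sum()), int((miss > miss_max).sum()), int((hwe < hwe_p_min).sum()),
    )
    if not keep.any():
        logger.warning("filter_variants removed every variant")
    return g.subset_variants(np.flatnonzero(keep))


def filter_expressed_genes(
    e: ExpressionMatrix, fpkm_min: float = 1.0, sample_frac: float = 0.8
) -> ExpressionMatrix:
    """Keep genes with abundance >= ``fpkm_min`` in >= ``sample_frac`` of samples."""
    if not (0 < sample_frac <= 1):
        raise ValueError("sample_frac must lie in (0, 1]")
    frac = (e.values >= fpkm_min).mean(axis=0)
    keep = np.flatnonzero(frac >= sample_frac - 1e-12)
    logger.info("filter_expressed_genes: %d/%d retained", keep.size, len(e.genes))
    return e.subset_genes(keep)
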