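"""Genome-wide eQTL mapping: matrix-form SNP x gene regression, cis/trans
classification at 30 kb from the TSS, per-gene clumping, and trans-eQTL
hotspot detection.

The association model is the additive simple linear regression of
covariate-residualized log2(FPKM+1) on dosage; the slope t statistic is
computed from the residual correlation with n - 2 - q degrees of freedom,
where q is the number of non-intercept covariates removed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneModel, GenotypeMatrix
from .gwas import (
    HotspotWindow,
    impute_dosage,
    permutation_hotspot_threshold,
    tile_windows,
    _window_index,
)

logger = logging.getLogger(__name__)

# The study's printed significance cutoffs (Bonferroni-style constants kept
# verbatim; their denominators are not derivable from the printed test
# counts). bonferroni mode: alpha / (n_genes * n_snps) and alpha / n_cis_pairs.
TRANS_P_THRESHOLD = 1.99e-6
CIS_P_THRESHOLD = 1.99e-3
CIS_WINDOW_BP = 30_000


@dataclass(frozen=True)
class EQTLRecord:
    gene_id: str
    snp_vid: str
    chrom: str
    pos: int
    beta: float
    p: float
    kind: str  # 'cis' | 'trans'
    distance_bp: int


def classify_cis_trans(
    snp_chrom: str, snp_pos: int, gene: GeneModel, cis_window: int = CIS_WINDOW_BP
) -> str:
    """cis iff the SNP lies on the gene's chromosome within ``cis_window``
    of its strand-aware TSS (boundary inclusive); otherwise trans."""
    if snp_chrom == gene.chrom and abs(snp_pos - gene.tss) <= cis_window:
        return "cis"
    return "trans"


def eqtl_scan(
    e: ExpressionMatrix,
    g: GenotypeMatrix,
    X: np.ndarray | None = None,
    p_prefilter: float = 1e-3,
    cis_window: int = CIS_WINDOW_BP,
    log_transform: bool = True,
    chunk: int = 2000,
) -> pd.DataFrame:
    """All-pairs additive scan, streaming records with p <= ``p_prefilter``.

    Expression is log2(x+1)-transformed (unless ``log_transform=False``) and
    both expression and dosage are residualized against the covariates.
    Returns a DataFrame with gene_id, snp_vid, chrom, pos, beta, p, kind,
    distance_bp. Constant-expression genes are skipped with a log message.
    """
    if list(e.samples) != list(g.samples):
        raise ValueError("expression and genotype sample sets are misaligned")
    n = len(e.samples)
    y = np.log2(e.values + 1.0) if log_transform else e.values.copy()
    d = impute_dosage(g.dosage)
    if X is None:
        X = np.ones((n, 1))
    q_extra = X.shape[1] - 1  # df loss beyond the intercept
    q_mat, _ = np.linalg.qr(X)
    y_r = y - q_mat @ (q_mat.T @ y)
    d_r = d - q_mat @ (q_mat.T @ d)

    sd_y = y_r.std(axis=0)
    const = sd_y < 1e-12
    if const.any():
        logger.info("eqtl_scan: skipping %d constant-expression genes", int(const.sum()))
    sd_d = d_r.std(axis=0)
    zero_snp = sd_d < 1e-12

    df = n - 2 - q_extra
    yn = np.where(sd_y > 0, 1.0, 0.0)[None, :] * y_r / np.where(sd_y > 0, sd_y, 1.0)
    dn = np.where(sd_d > 0, 1.0, 0.0)[None, :] * d_r / np.where(sd_d > 0, sd_d, 1.0)

    chroms = g.chroms
    positions = g.positions
    tss = np.array([gm.tss for gm in e.genes])
    gene_chrom = np.array([gm.chrom for gm in e.genes])
    gene_ids = np.array(e.gene_ids)
    vids = np.array([v.vid for v in g.variants])

    rows = []
    for lo in range(0, d.shape[1], chunk):
        hi = min(lo + chunk, d.shape[1])
        r = (yn.T @ dn[:, lo:hi]) / n  # (genes, snps_chunk) correlations
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[const, :] = 1.0
        p[:, zero_snp[lo:hi]] = 1.0
        gi, sj = np.nonzero(p <= p_prefilter)
        for a, b in zip(gi, sj):
            j = lo + b
            # slope on the residualized (unstandardized) scale
            beta = float(r[a, b] * sd_y[a] / sd_d[j]) if sd_d[j] > 0 else 0.0
            same = gene_chrom[a] == chroms[j]
            dist = int(abs(positions[j] - tss[a]))
            rows.append(
                (gene_ids[a], vids[j], chroms[j], int(positions[j]), beta,
                 float(p[a, b]),
                 "cis" if (same and dist <= cis_window) else "trans",
                 dist if same else -1)
            )
    out = pd.DataFrame(
        rows, columns=["gene_id", "snp_vid", "chrom", "pos", "beta", "p", "kind", "distance_bp"]
    )
    return out.sort_values(["gene_id", "chrom", "pos"], kind="mergesort").reset_index(drop=True)


def clump_eqtls(
    records: pd.DataFrame,
    cis_p: float = CIS_P_THRESHOLD,
    trans_p: float = TRANS_P_THRESHOLD,
    clump_radius: int = 30_000,
) -> pd.DataFrame:
    """Per-gene greedy min-p clumping of significant records at a 30-kb radius.

    cis records are kept at ``cis_p``, trans records at ``trans_p``; within a
    gene the most significant remaining SNP is emitted and all significant
    SNPs within ``clump_radius`` on its chromosome are removed.
    """
    if records.empty:
        return records.copy()
    sig = records[
        ((records["kind"] == "cis") & (records["p"] <= cis_p))
        | ((records["kind"] == "trans") & (records["p"] <= trans_p))
    ]
    kept = []
    for gene, sub in sig.groupby("gene_id", sort=True):
        sub = sub.sort_values(["p", "chrom", "pos"], kind="mergesort")
        taken: list[tuple[str, int]] = []
        for _, row in sub.iterrows():
            if any(c == row["chrom"] and abs(pp - row["pos"]) <= clump_radius
                   for c, pp in taken):
                continue
            kept.append(row)
            taken.append((row["chrom"], int(row["pos"])))
    if not kept:
        return records.iloc[0:0].copy()
    return pd.DataFrame(kept).reset_index(drop=True)


def eqtl_hotspots(
    trans_records: pd.DataFrame,
    snp_chroms: np.ndarray,
    snp_positions: np.ndarray,
    chrom_lengths: dict[str, int],
    window_bp: int = 1_000_000,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[HotspotWindow], int]:
    """Trans-eQTL hotspot windows under the same permutation null as the
    mGWAS hotspot caller (uniform re-placement over SNP positions,
    genome-wide max-count statistic)."""
    windows = tile_windows(chrom_lengths, window_bp)
    if trans_records.empty:
        return [], 0
    widx = _window_index(
        trans_records["chrom"].to_numpy(), trans_records["pos"].to_numpy(),
        windows, window_bp,
    )
    observed = np.bincount(widx[widx >= 0], minlength=len(windows))
    rng = np.random.default_rng(seed)
    threshold = permutation_hotspot_threshold(
        len(trans_records), np.asarray(snp_chroms), np.asarray(snp_positions),
        windows, window_bp, n_perm, alpha, rng,
    )
    return [
        HotspotWindow(chrom=c, start=s, end=e, lead_count=int(observed[i]),
                      threshold=threshold, is_hotspot=bool(observed[i] >= threshold))
        for i, (c, s, e) in enumerate(windows)
    ], threshold


def hotspot_overlap(
    a: list[HotspotWindow], b: list[HotspotWindow]
) -> list[tuple[HotspotWindow, HotspotWindow]]:
    """Pairs of flagged windows whose genomic intervals intersect by >= 1 bp."""
    pairs = []
    for wa in a:
        if not wa.is_hotspot:
            continue
        for wb in b:
            if not wb.is_hotspot:
                continue
            if wa.chrom == wb.chrom and wa.start <= wb.end and wb.start <= wa.end:
                pairs.append((wa, wb))
    return pairs
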