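"""Expression-metabolite integration: correlation networks, candidate genes
around lead SNPs, and weighted co-expression module detection.

Modules follow the weighted-network recipe: unsigned adjacency |cor|^beta
(beta = 8 by default), topological overlap dissimilarity, average-linkage
hierarchical clustering with a static tree cut, and first-principal-component
eigengenes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, GeneModel
from .gwas import LeadSNP, bonferroni_threshold

logger = logging.getLogger(__name__)

SOFT_POWER = 8
EDGE_R_MIN = 0.4
# correlation-network cutoff: 0.05 Bonferroni-corrected over 22,374 genes
EDGE_P_MAX = bonferroni_threshold(22_374, 0.05)


@dataclass(frozen=True)
class CorrelationEdge:
    gene_id: str
    metabolite: str
    r: float
    p: float


@dataclass(frozen=True)
class CandidateGene:
    metabolite: str
    lead_vid: str
    gene_id: str
    distance_bp: int
    r: float


@dataclass
class CoexpressionModule:
    module_id: int
    genes: list[str]
    eigengene: np.ndarray


def _corr_with_p(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r between columns of a and b, p from the t transform."""
    n = a.shape[0]
    az = (a - a.mean(axis=0)) / np.where(a.std(axis=0) > 0, a.std(axis=0), np.inf)
    bz = (b - b.mean(axis=0)) / np.where(b.std(axis=0) > 0, b.std(axis=0), np.inf)
    r = np.clip((az.T @ bz) / n, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return r, p


def correlation_network(
    e: ExpressionMatrix,
    metabolites: pd.DataFrame,
    r_min: float = EDGE_R_MIN,
    p_max: float = EDGE_P_MAX,
) -> list[CorrelationEdge]:
    """Gene-metabolite edges with r > ``r_min`` and p < ``p_max``.

    Both matrices are log2(x+1)-transformed; correlations are computed in
    matrix form over the shared samples.
    """
    if list(e.samples) != list(metabolites.index):
        raise ValueError("expression and metabolite samples are misaligned")
    if len(e.samples) < 10:
        raise ValueError("need at least 10 shared samples")
    x = np.log2(e.values + 1.0)
    m = np.log2(metabolites.to_numpy(dtype=float) + 1.0)
    r, p = _corr_with_p(x, m)
    gi, mj = np.nonzero((r > r_min) & (p < p_max))
    gene_ids = e.gene_ids
    mets = list(metabolites.columns)
    return [
        CorrelationEdge(gene_id=gene_ids[i], metabolite=str(mets[j]),
                        r=float(r[i, j]), p=float(p[i, j]))
        for i, j in zip(gi, mj)
    ]


def candidate_genes(
    leads: list[LeadSNP],
    genes: list[GeneModel],
    edges: list[CorrelationEdge],
    flank: int = 25_000,
) -> list[CandidateGene]:
    """Genes whose span, expanded by ``flank``, contains a metabolite's lead
    SNP and which carry a retained expression-metabolite edge to it."""
    edge_by_pair = {(ed.gene_id, ed.metabolite): ed for ed in edges}
    out = []
    for lead in leads:
        for gm in genes:
            if gm.chrom != lead.snp.chrom:
                continue
            if not (gm.start - flank <= lead.snp.pos <= gm.end + flank):
                continue
            ed = edge_by_pair.get((gm.gene_id, lead.trait))
            if ed is None:
                continue
            if gm.start <= lead.snp.pos <= gm.end:
                dist = 0
            else:
                dist = min(abs(lead.snp.pos - gm.start), abs(lead.snp.pos - gm.end))
            out.append(CandidateGene(metabolite=lead.trait, lead_vid=lead.snp.vid,
                                     gene_id=gm.gene_id, distance_bp=dist, r=ed.r))
    return out


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with a
    unit diagonal; values lie in [0, 1] for adjacency in [0, 1]."""
    a = np.array(adj, dtype=float)
    np.fill_diagonal(a, 0.0)
    l_mat = a @ a
    k = a.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    tom = (l_mat + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def coexpression_modules(
    e: ExpressionMatrix,
    beta: int = SOFT_POWER,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> tuple[list[CoexpressionModule], np.ndarray]:
    """Weighted co-expression modules by TOM clustering.

    Adjacency |cor|^beta on log2(x+1) expression; average-linkage clustering
    of 1 - TOM; static tree cut. When ``cut_height`` is None the tree is cut
    in the middle of the largest gap between consecutive merge heights in
    the upper half of the dendrogram (a deterministic static cut that
    separates well-formed branches from the between-branch merges, which
    with a soft power of 8 concentrate just below dissimilarity 1);
    clusters smaller than ``min_module_size`` go to the unassigned pool
    (module 0). Returns the modules (eigengene = first PC of the scaled
    member expression, sign-anchored to the mean member profile) and the
    per-gene module labels aligned with ``e.genes``.
    """
    x = np.log2(e.values + 1.0)
    sd = x.std(axis=0)
    usable = sd > 1e-12
    n_genes = x.shape[1]
    labels = np.zeros(n_genes, dtype=int)
    xu = x[:, usable]
    if xu.shape[1] < 2:
        return [], labels
    corr = np.corrcoef(xu, rowvar=False)
    adj = np.abs(corr) ** beta
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    heights = link[:, 2]
    if cut_height is None:
        order = np.sort(heights)
        upper = order[order >= np.median(order)]
        gaps = np.diff(upper)
        if gaps.size == 0 or gaps.max() <= 1e-12:
            cut = float(order[-1]) + 1.0  # degenerate: one module
        else:
            i = int(np.argmax(gaps))
            cut = float((upper[i] + upper[i + 1]) / 2.0)
    else:
        cut = cut_height
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")

    modules: list[CoexpressionModule] = []
    next_id = 1
    gene_ids = np.asarray(e.gene_ids)
    usable_idx = np.flatnonzero(usable)
    # deterministic module numbering: by lowest member gene index
    clusters = {}
    for local_i, c in enumerate(raw):
        clusters.setdefault(c, []).append(local_i)
    ordered = sorted(clusters.values(), key=lambda idxs: min(idxs))
    for idxs in ordered:
        if len(idxs) < min_module_size:
            continue
        cols = usable_idx[idxs]
        z = (x[:, cols] - x[:, cols].mean(axis=0)) / x[:, cols].std(axis=0)
        u, s, _ = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
        eig = u[:, 0] * s[0]
        if np.corrcoef(eig, z.mean(axis=1))[0, 1] < 0:
            eig = -eig
        modules.append(CoexpressionModule(
            module_id=next_id, genes=[str(gid) for gid in gene_ids[cols]], eigengene=eig,
        ))
        labels[cols] = next_id
        next_id += 1
    return modules, labels


def module_metabolite_association(
    modules: list[CoexpressionModule],
    metabolites: pd.DataFrame,
    p_max: float | None = None,
) -> pd.DataFrame:
    """Pearson r/p between each module eigengene and each metabolite
    (log2(x+1)); ``significant`` flags pairs below ``p_max`` (default
    Bonferroni over modules x metabolites)."""
    m = np.log2(metabolites.to_numpy(dtype=float) + 1.0)
    mets = list(metabolites.columns)
    n_tests = max(len(modules) * len(mets), 1)
    if p_max is None:
        p_max = bonferroni_threshold(n_tests, 0.05)
    rows = []
    for mod in modules:
        eig = mod.eigengene
        if eig.std() < 1e-12:
            logger.warning("module %d has a constant eigengene; skipped", mod.module_id)
            continue
        r, p = _corr_with_p(eig[:, None], m)
        for j, met in enumerate(mets):
            rows.append((mod.module_id, str(met), float(r[0, j]), float(p[0, j]),
                         bool(p[0, j] < p_max)))
    return pd.DataFrame(rows, columns=["module_id", "metabolite", "r", "p", "significant"])
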