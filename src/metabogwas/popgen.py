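"""Windowed Weir-Cockerham F_ST between population pairs, top-5% sweep
calling, overlap of association signals with sweeps, and per-group minor
allele frequencies.

The site estimator is the two-population Weir & Cockerham (1984) analysis of
variance with components a (among populations), b (among individuals within
populations), and c (within individuals); theta = a/(a+b+c). Windows use the
weighted ("ratio of sums") estimator sum(a)/sum(a+b+c) over usable sites.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix
from .gwas import LeadSNP

logger = logging.getLogger(__name__)


@dataclass
class FstComponents:
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0:
            return np.nan
        return self.a / denom


@dataclass
class SweepWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    mean_fst: float
    n_sites: int = 0
    is_sweep: bool = False


def _pop_summary(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n individuals, alt frequency, het frequency) per site for one group."""
    obs = ~np.isnan(dosages)
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * np.where(n > 0, n, np.nan))
        h = np.nansum(dosages == 1, axis=0) / np.where(n > 0, n, np.nan)
    return n, p, h


def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-population Weir-Cockerham (1984) variance components."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
    c = hbar / 2.0
    return a, b, c


def wc_fst_site(
    counts1: tuple[int, int, int], counts2: tuple[int, int, int]
) -> FstComponents:
    """Weir-Cockerham components for one site from genotype counts
    (n_AA, n_Aa, n_aa) in each population. Monomorphic-across-both sites
    return all-zero components (theta undefined)."""
    arrs = []
    for counts in (counts1, counts2):
        nAA, nAa, naa = counts
        if min(nAA, nAa, naa) < 0 or nAA + nAa + naa < 1:
            raise ValueError("each population needs >= 1 genotyped individual")
        n = nAA + nAa + naa
        p = (2 * nAA + nAa) / (2.0 * n)
        h = nAa / float(n)
        arrs.append((np.array([float(n)]), np.array([p]), np.array([h])))
    (n1, p1, h1), (n2, p2, h2) = arrs
    pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
    if pooled[0] in (0.0, 1.0):
        return FstComponents(a=0.0, b=0.0, c=0.0)
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    return FstComponents(a=float(a[0]), b=float(b[0]), c=float(c[0]))


def site_fst_components(
    g: GenotypeMatrix, groupA: list[str], groupB: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (a, a+b+c) arrays for all variants; monomorphic-across-both
    sites are nan (excluded from window sums)."""
    if set(groupA) & set(groupB):
        raise ValueError("group sample lists must be disjoint")
    if not groupA or not groupB:
        raise ValueError("both groups must be non-empty")
    idx = {s: i for i, s in enumerate(g.samples)}
    ia = [idx[s] for s in groupA]
    ib = [idx[s] for s in groupB]
    n1, p1, h1 = _pop_summary(g.dosage[ia, :])
    n2, p2, h2 = _pop_summary(g.dosage[ib, :])
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
    bad = (
        ~np.isfinite(denom) | (n1 < 1) | (n2 < 1)
        | (pooled <= 0.0) | (pooled >= 1.0)
    )
    a = np.where(bad, np.nan, a)
    denom = np.where(bad, np.nan, denom)
    return a, denom


def windowed_fst(
    g: GenotypeMatrix,
    groupA: list[str],
    groupB: list[str],
    window_bp: int = 100_000,
    step_bp: int = 10_000,
) -> list[SweepWindow]:
    """Sliding-window weighted F_ST: sum(a)/sum(a+b+c) over usable sites in
    100-kb windows stepped by 10 kb (1-based inclusive tiling starting at
    position 1). Windows without usable sites are omitted."""
    a, denom = site_fst_components(g, groupA, groupB)
    chroms = g.chroms
    positions = g.positions
    out: list[SweepWindow] = []
    for chrom in sorted(set(chroms.tolist())):
        mask = chroms == chrom
        pos = positions[mask]
        ac = a[mask]
        dc = denom[mask]
        usable = np.isfinite(dc)
        pos, ac, dc = pos[usable], ac[usable], dc[usable]
        if pos.size == 0:
            continue
        order = np.argsort(pos, kind="mergesort")
        pos, ac, dc = pos[order], ac[order], dc[order]
        cum_a = np.concatenate([[0.0], np.cumsum(ac)])
        cum_d = np.concatenate([[0.0], np.cumsum(dc)])
        max_pos = int(pos.max())
        start = 1
        while start <= max_pos:
            end = start + window_bp - 1
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="right"))
            if hi > lo:
                num = cum_a[hi] - cum_a[lo]
                den = cum_d[hi] - cum_d[lo]
                if den > 0:
                    out.append(SweepWindow(chrom=chrom, start=start, end=end,
                                           mean_fst=float(num / den), n_sites=hi - lo))
            start += step_bp
    return out


def call_sweeps(windows: list[SweepWindow], top_q: float = 0.05) -> list[SweepWindow]:
    """Flag windows in the top ``top_q`` of mean F_ST (linear-interpolation
    quantile; ties at the cutoff all included). Returns the full window list
    with ``is_sweep`` set."""
    if len(windows) < 20:
        raise ValueError("need at least 20 windows for a stable top-5% cutoff")
    vals = np.array([w.mean_fst for w in windows])
    cutoff = float(np.quantile(vals, 1.0 - top_q))
    if np.allclose(vals, vals[0]):
        logger.warning("all window F_ST values are equal; every window flagged")
    for w in windows:
        w.is_sweep = bool(w.mean_fst >= cutoff)
    return windows


def merge_sweep_regions(windows: list[SweepWindow]) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent flagged windows into sweep regions."""
    flagged = sorted(
        [(w.chrom, w.start, w.end) for w in windows if w.is_sweep],
        key=lambda t: (t[0], t[1]),
    )
    regions: list[tuple[str, int, int]] = []
    for chrom, start, end in flagged:
        if regions and regions[-1][0] == chrom and start <= regions[-1][2] + 1:
            regions[-1] = (chrom, regions[-1][1], max(regions[-1][2], end))
        else:
            regions.append((chrom, start, end))
    return regions


def overlap_leads_with_sweeps(
    leads: list[LeadSNP], regions: list[tuple[str, int, int]]
) -> dict:
    """Count lead SNPs falling inside any sweep region; report the fraction
    of the total and the distinct metabolites involved."""
    inside = [
        l for l in leads
        if any(c == l.snp.chrom and s <= l.snp.pos <= e for c, s, e in regions)
    ]
    total = len(leads)
    return {
        "n_leads": total,
        "n_in_sweeps": len(inside),
        "fraction": len(inside) / total if total else 0.0,
        "metabolites": sorted({l.trait for l in inside}),
    }


def maf_by_group(
    dosage_column: np.ndarray, groups: dict[str, list[int]]
) -> dict[str, float]:
    """Frequency of the pooled-sample minor allele within each group (may
    exceed 0.5 inside a group). Groups with no genotyped individuals map to
    nan."""
    col = np.asarray(dosage_column, dtype=float)
    obs = ~np.isnan(col)
    if not obs.any():
        raise ValueError("no genotyped individuals at this site")
    p_alt = np.nansum(col) / (2.0 * obs.sum())
    minor_is_alt = p_alt <= 0.5
    out = {}
    for name, idx in groups.items():
        sub = col[np.asarray(idx, dtype=int)]
        m = ~np.isnan(sub)
        if not m.any():
            logger.warning("group %s has no genotyped individuals at this site", name)
            out[name] = float("nan")
            continue
        freq_alt = np.nansum(sub) / (2.0 * m.sum())
        out[name] = float(freq_alt if minor_is_alt else 1.0 - freq_alt)
    return out
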