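"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates the derived matrices of a structured peach germplasm panel: ~252
accessions in four groups (wild W, landrace L, eastern improved EI, western
improved WI), a bi-allelic SNP panel over 8 chromosomes with Balding-Nichols
population structure, seasonally replicated metabolite abundances with
controlled broad-sense heritability and planted mQTLs, and an expression
matrix with cis/trans genetic control, a shared trans-regulator hotspot, and
latent co-expression modules. Every output is a pure function of the config
and its seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .gwas import kinship, impute_dosage

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_population",
    "simulate_metabolome",
    "simulate_expression",
    "emit_cohort",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Group sizes total 252 accessions; eight chromosomes of 28 Mb mimic a
    ~224-Mb genome. SNP and gene counts default to desk-scale densities;
    structural parameters (F_ST, heritability, cis window, thresholds) carry
    the analysis defaults.
    """

    seed: int = 0
    n_samples: dict = field(
        default_factory=lambda: {"W": 40, "L": 90, "EI": 60, "WI": 62}
    )
    n_chrom: int = 8
    chrom_length_bp: int = 28_000_000
    n_snps: int = 8_000
    fst_background: float = 0.1
    maf_min: float = 0.05  # post-filter realism: reject rare sites
    geno_missing_rate: float = 0.0

    # metabolome
    n_metabolites: int = 400
    n_mqtl: int = 20  # metabolites carrying one planted causal SNP each
    mqtl_pve: float = 0.2
    h2_target: float = 0.5
    season_effect_sd: float = 0.3
    mqtl_hotspot_window: tuple | None = None  # (chrom, start, end)
    mqtl_hotspot_n_traits: int = 0  # causal SNPs forced into the window

    # expression
    n_genes: int = 600
    cis_window_bp: int = 30_000
    n_cis_genes: int = 60
    cis_pve: float = 0.4
    trans_hotspot_size: int = 50
    trans_pve: float = 0.2
    trans_hotspot_window: tuple | None = None
    n_modules: int = 3
    module_size: int = 50
    module_loading: float = 0.8
    expr_h2_poly: float = 0.0  # optional polygenic share of log-expression

    # selection sweeps
    sweep_windows: list = field(default_factory=list)  # [(chrom, start, end), ...]
    sweep_gap: float = 0.8  # allele-frequency gap forced between contrast groups
    sweep_contrast: tuple = ("W", "L")

    # landrace environment levels
    env_levels: tuple = (1, 2, 3, 4, 5)

    def validate(self) -> None:
        if not (0.0 < self.fst_background < 1.0):
            raise ValueError("fst_background must lie in (0, 1)")
        if self.n_mqtl > self.n_metabolites:
            raise ValueError("n_mqtl cannot exceed n_metabolites")
        if self.mqtl_pve * 1 + 0.0 > self.h2_target + 1e-12:
            raise ValueError("mqtl_pve must not exceed h2_target")
        if self.season_effect_sd**2 > 1.0 - self.h2_target + 1e-12:
            raise ValueError("season_effect_sd^2 must not exceed 1 - h2_target")
        if self.trans_hotspot_size > self.n_genes:
            raise ValueError("trans_hotspot_size cannot exceed n_genes")
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError("h2_target must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    causal_snps: dict = field(default_factory=dict)      # metabolite -> [vid, effect]
    hotspot_truth: list = field(default_factory=list)    # [(chrom, start, end), ...]
    cis_truth: dict = field(default_factory=dict)        # gene -> [vid, effect]
    trans_truth: dict = field(default_factory=dict)      # gene -> [vid, effect]
    module_truth: dict = field(default_factory=dict)     # gene -> module id
    sweep_truth: list = field(default_factory=list)      # [(chrom, start, end), ...]
    h2_truth: dict = field(default_factory=dict)         # metabolite -> H2

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: d.get(k, {}) for k in
                      ("causal_snps", "cis_truth", "trans_truth", "module_truth", "h2_truth")}
                   | {k: [tuple(w) for w in d.get(k, [])] for k in ("hotspot_truth", "sweep_truth")})


def _group_labels(cfg: SimulationConfig) -> list[str]:
    labels: list[str] = []
    for grp, n in cfg.n_samples.items():
        labels += [grp] * n
    return labels


def _in_window(chrom: str, pos: int, window: tuple) -> bool:
    wc, ws, we = window
    return str(chrom) == str(wc) and ws <= pos <= we


def simulate_population(cfg: SimulationConfig) -> gio.GenotypeMatrix:
    """Balding-Nichols structured genotype panel.

    Ancestral frequencies p0 ~ U(0.05, 0.95); each group's frequency is Beta
    distributed around p0 with divergence F = ``fst_background``; genotypes
    are Binomial(2, p_group). Sites inside ``sweep_windows`` get the contrast
    groups' frequencies pushed to opposite extremes (gap ``sweep_gap``).
    Sites with realized pooled MAF below ``maf_min`` are redrawn, mimicking a
    post-QC panel.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    groups = _group_labels(cfg)
    n_total = len(groups)
    group_names = list(cfg.n_samples)
    gidx = {g: np.array([i for i, lab in enumerate(groups) if lab == g]) for g in group_names}

    # positions: uniform over chromosomes, sorted within chromosome
    n_per_chrom = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    n_per_chrom[: cfg.n_snps % cfg.n_chrom] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for c in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=n_per_chrom[c], replace=False)) + 1
        chroms += [f"Pp0{c + 1}"] * n_per_chrom[c]
        positions += pos.tolist()

    F = cfg.fst_background
    a_scale = (1.0 - F) / F
    dosage = np.empty((n_total, cfg.n_snps))
    p_group = np.empty((len(group_names), cfg.n_snps))
    contrast_a, contrast_b = cfg.sweep_contrast

    for j in range(cfg.n_snps):
        in_sweep = any(_in_window(chroms[j], positions[j], w) for w in cfg.sweep_windows)
        for _attempt in range(50):
            p0 = rng.uniform(0.05, 0.95)
            pg = rng.beta(p0 * a_scale, (1.0 - p0) * a_scale, size=len(group_names))
            if in_sweep:
                lo = np.clip(0.5 - cfg.sweep_gap / 2.0, 0.01, 0.99)
                hi = np.clip(0.5 + cfg.sweep_gap / 2.0, 0.01, 0.99)
                for gi, gname in enumerate(group_names):
                    if gname == contrast_a:
                        pg[gi] = lo
                    elif gname == contrast_b:
                        pg[gi] = hi
            col = np.empty(n_total)
            for gi, gname in enumerate(group_names):
                col[gidx[gname]] = rng.binomial(2, pg[gi], size=gidx[gname].size)
            p_alt = col.mean() / 2.0
            if min(p_alt, 1 - p_alt) >= cfg.maf_min:
                break
        dosage[:, j] = col
        p_group[:, j] = pg

    if cfg.geno_missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.geno_missing_rate
        dosage[mask] = np.nan

    variants = []
    for j in range(cfg.n_snps):
        maf, miss, hwe = gio._variant_stats(dosage[:, j])
        variants.append(
            gio.VariantRecord(
                chrom=chroms[j], pos=positions[j], ref="A", alt="G",
                maf=maf, missing_rate=miss, hwe_p=hwe,
                vid=f"{chroms[j]}_{positions[j]}",
            )
        )
    sample_ids = [f"acc{i + 1:03d}" for i in range(n_total)]
    return gio.GenotypeMatrix(samples=sample_ids, variants=variants, dosage=dosage)


def _kinship_chol(g: gio.GenotypeMatrix) -> np.ndarray:
    K = kinship(g).values
    return np.linalg.cholesky(K + 1e-6 * np.eye(K.shape[0]))


def _scaled(v: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a vector to an exact realized sample variance."""
    sd = v.std()
    if sd < 1e-12 or target_var <= 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd * np.sqrt(target_var)


def simulate_metabolome(
    g: gio.GenotypeMatrix, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two seasons of metabolite abundances with planted mQTLs.

    Per metabolite the latent (log) trait has unit variance per season:
    a planted causal-SNP component (variance ``mqtl_pve``, first ``n_mqtl``
    metabolites), a polygenic component drawn from N(0, K) filling the
    genetic share to ``h2_target``, a season-wide additive shift
    (sd ``season_effect_sd``), and residual noise. Abundances are
    exp(latent), giving positively skewed, high-CV intensities. Returns the
    two seasonal sample x metabolite tables and the planted truth.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = g.n_samples
    L = _kinship_chol(g)
    truth = GroundTruth()

    mafs = g.maf_from_dosage()
    candidates = np.flatnonzero(mafs >= max(cfg.maf_min, 0.05))
    if cfg.mqtl_hotspot_window is not None and cfg.mqtl_hotspot_n_traits > 0:
        chroms, positions = g.chroms, g.positions
        in_hot = np.array([
            _in_window(chroms[j], positions[j], cfg.mqtl_hotspot_window) for j in candidates
        ])
        hot_candidates = candidates[in_hot]
        if hot_candidates.size == 0:
            raise ValueError("mqtl_hotspot_window contains no eligible SNPs")
        truth.hotspot_truth.append(tuple(cfg.mqtl_hotspot_window))

    names = [f"met{k + 1:04d}" for k in range(cfg.n_metabolites)]
    dosage = impute_dosage(g.dosage)
    h2 = cfg.h2_target
    sigma_s2 = cfg.season_effect_sd**2
    sigma_e2 = max(1.0 - h2 - sigma_s2, 0.0)

    latents = {1: np.empty((n, cfg.n_metabolites)), 2: np.empty((n, cfg.n_metabolites))}
    for k in range(cfg.n_metabolites):
        pve = cfg.mqtl_pve if k < cfg.n_mqtl else 0.0
        genetic = np.zeros(n)
        if pve > 0:
            if (cfg.mqtl_hotspot_window is not None
                    and k < cfg.mqtl_hotspot_n_traits):
                j = int(rng.choice(hot_candidates))
            else:
                j = int(rng.choice(candidates))
            sign = rng.choice([-1.0, 1.0])
            qtl = _scaled(dosage[:, j], pve) * sign
            genetic = genetic + qtl
            truth.causal_snps[names[k]] = [g.variants[j].vid, float(sign * np.sqrt(pve))]
        poly_var = max(h2 - pve, 0.0)
        if poly_var > 0:
            genetic = genetic + _scaled(L @ rng.standard_normal(n), poly_var)
        truth.h2_truth[names[k]] = h2
        for season in (1, 2):
            shift = rng.normal(0.0, cfg.season_effect_sd)
            noise = rng.standard_normal(n) * np.sqrt(sigma_e2)
            latents[season][:, k] = genetic + shift + noise

    frames = {
        season: pd.DataFrame(np.exp(latents[season]), index=g.samples, columns=names)
        for season in (1, 2)
    }
    return frames[1], frames[2], truth


def simulate_expression(
    g: gio.GenotypeMatrix, cfg: SimulationConfig
) -> tuple[gio.ExpressionMatrix, GroundTruth]:
    """Expression matrix with cis/trans genetic control and latent modules.

    Gene models are placed uniformly over the chromosomes. The first
    ``n_cis_genes`` genes get a cis SNP (nearest SNP within ``cis_window_bp``
    of the TSS, variance share ``cis_pve``); ``trans_hotspot_size`` genes
    share one trans-regulator SNP (variance share ``trans_pve``);
    ``n_modules`` disjoint blocks of ``module_size`` genes load a latent
    factor with loading ``module_loading``. FPKM-like values are
    exp(log-expression) rescaled to median 5.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = g.n_samples
    chroms, positions = g.chroms, g.positions
    truth = GroundTruth()

    genes: list[gio.GeneModel] = []
    for k in range(cfg.n_genes):
        c = f"Pp0{int(rng.integers(cfg.n_chrom)) + 1}"
        start = int(rng.integers(1, cfg.chrom_length_bp - 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(gio.GeneModel(
            gene_id=f"gene{k + 1:05d}", chrom=c, start=start, end=start + 2999,
            strand=strand,
        ))

    dosage = impute_dosage(g.dosage)
    mafs = g.maf_from_dosage()

    # trans regulator: one common SNP, optionally inside a named window
    eligible = np.flatnonzero(mafs >= max(cfg.maf_min, 0.05))
    if cfg.trans_hotspot_window is not None:
        in_win = np.array([
            _in_window(chroms[j], positions[j], cfg.trans_hotspot_window) for j in eligible
        ])
        pool = eligible[in_win]
        if pool.size == 0:
            raise ValueError("trans_hotspot_window contains no eligible SNPs")
        reg = int(rng.choice(pool))
    else:
        reg = int(rng.choice(eligible))
    reg_v = g.variants[reg]
    win = 1_000_000
    w_start = ((reg_v.pos - 1) // win) * win + 1
    truth.hotspot_truth.append((reg_v.chrom, w_start, w_start + win - 1))
    trans_genes = rng.choice(cfg.n_genes, size=cfg.trans_hotspot_size, replace=False)

    # module blocks: assigned to genes after the cis genes to keep them disjoint
    factors = rng.standard_normal((n, cfg.n_modules))
    module_of = np.zeros(cfg.n_genes, dtype=int)  # 0 = unassigned
    start_block = cfg.n_cis_genes
    for m in range(cfg.n_modules):
        lo = start_block + m * cfg.module_size
        hi = lo + cfg.module_size
        if hi > cfg.n_genes:
            break
        module_of[lo:hi] = m + 1

    log_expr = np.empty((n, cfg.n_genes))
    for k in range(cfg.n_genes):
        gmodel = genes[k]
        var_used = 0.0
        comp = np.zeros(n)
        if k < cfg.n_cis_genes:
            on_chrom = np.flatnonzero(
                (chroms == gmodel.chrom) & (np.abs(positions - gmodel.tss) <= cfg.cis_window_bp)
                & (mafs >= 0.05)
            )
            if on_chrom.size:
                j = int(on_chrom[np.argmin(np.abs(positions[on_chrom] - gmodel.tss))])
                sign = rng.choice([-1.0, 1.0])
                comp = comp + _scaled(dosage[:, j], cfg.cis_pve) * sign
                var_used += cfg.cis_pve
                truth.cis_truth[gmodel.gene_id] = [g.variants[j].vid,
                                                   float(sign * np.sqrt(cfg.cis_pve))]
        if k in trans_genes:
            sign = rng.choice([-1.0, 1.0])
            comp = comp + _scaled(dosage[:, reg], cfg.trans_pve) * sign
            var_used += cfg.trans_pve
            truth.trans_truth[gmodel.gene_id] = [reg_v.vid, float(sign * np.sqrt(cfg.trans_pve))]
        m = module_of[k]
        if m > 0:
            lam2 = cfg.module_loading**2 * (1.0 - var_used)
            comp = comp + _scaled(factors[:, m - 1], lam2)
            var_used += lam2
            truth.module_truth[gmodel.gene_id] = int(m)
        noise_var = max(1.0 - var_used, 1e-6)
        comp = comp + rng.standard_normal(n) * np.sqrt(noise_var)
        log_expr[:, k] = comp

    raw = np.exp(log_expr)
    raw *= 5.0 / np.median(raw)
    return gio.ExpressionMatrix(samples=list(g.samples), genes=genes, values=raw), truth


def sample_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample table: group, geographic group, and landrace environment levels."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    groups = _group_labels(cfg)
    sample_ids = [f"acc{i + 1:03d}" for i in range(len(groups))]
    geo = []
    rain = []
    temp = []
    geo_pool = ["NW", "NC", "SC", "SE", "TP"]
    for grp in groups:
        if grp == "L":
            geo.append(geo_pool[int(rng.integers(len(geo_pool)))])
            rain.append(int(rng.choice(cfg.env_levels)))
            temp.append(int(rng.choice(cfg.env_levels)))
        else:
            geo.append({"W": "wild", "EI": "east", "WI": "west"}.get(grp, "NA"))
            rain.append(0)
            temp.append(0)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "geo_group": geo,
            "rainfall_level": rain,
            "temperature_level": temp,
        }
    ).set_index("sample_id")


def emit_cohort(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full cohort (VCF, metabolite/expression TSVs, GFF3,
    metadata, ground-truth JSON) and return the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = simulate_population(cfg)
    met1, met2, truth_m = simulate_metabolome(g, cfg)
    expr, truth_e = simulate_expression(g, cfg)
    truth = GroundTruth(
        causal_snps=truth_m.causal_snps,
        hotspot_truth=truth_m.hotspot_truth + truth_e.hotspot_truth,
        cis_truth=truth_e.cis_truth,
        trans_truth=truth_e.trans_truth,
        module_truth=truth_e.module_truth,
        sweep_truth=[tuple(w) for w in cfg.sweep_windows],
        h2_truth=truth_m.h2_truth,
    )
    files = {
        "vcf": outdir / "genotypes.vcf",
        "met1": outdir / "metabolites_season1.tsv",
        "met2": outdir / "metabolites_season2.tsv",
        "expression": outdir / "expression.tsv",
        "gff3": outdir / "genes.gff3",
        "metadata": outdir / "samples.tsv",
        "truth": outdir / "ground_truth.json",
    }
    gio.write_vcf(g, files["vcf"])
    gio.write_matrix_tsv(met1, files["met1"])
    gio.write_matrix_tsv(met2, files["met2"])
    gio.write_expression_tsv(expr, files["expression"])
    gio.write_gff3(expr.genes, files["gff3"])
    sample_metadata(cfg).to_csv(files["metadata"], sep="\t")
    truth.to_json(files["truth"])
    return files
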