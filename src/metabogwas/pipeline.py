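"""End-to-end orchestration: simulate (or load) a cohort, run QC, metabolome
statistics, mGWAS, eQTL mapping, integration, and selection scans, and write
a reproducibility manifest with parameter values and output hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import eqtl as eq
from . import gwas
from . import integrate as integ
from . import io as gio
from . import metabolome as met
from . import popgen
from .simulate import SimulationConfig, GroundTruth, emit_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, with the analysis defaults as printed constants."""

    outdir: str = "pipeline_out"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    stages: list = field(default_factory=lambda: [
        "simulate", "filter", "stats", "mgwas", "eqtl", "integrate", "fst", "report",
    ])
    # QC
    maf_min: float = 0.05
    miss_max: float = 0.2
    hwe_p_min: float = 1e-6
    fpkm_min: float = 1.0
    expressed_frac: float = 0.8
    # mGWAS
    n_pcs: int = 3
    mgwas_p: float = gwas.MGWAS_P_THRESHOLD
    clump_radius: int = 100_000
    hotspot_window: int = 1_000_000
    n_perm: int = 1000
    hotspot_alpha: float = 0.05
    mgwas_max_traits: int | None = None  # scan the first k metabolites only
    # eQTL
    cis_window: int = eq.CIS_WINDOW_BP
    cis_p: float = eq.CIS_P_THRESHOLD
    trans_p: float = eq.TRANS_P_THRESHOLD
    eqtl_prefilter: float = 1e-3
    # integration
    edge_r_min: float = integ.EDGE_R_MIN
    edge_p_max: float = integ.EDGE_P_MAX
    candidate_flank: int = 25_000
    soft_power: int = integ.SOFT_POWER
    min_module_size: int = 30
    # differential metabolites
    fc_high: float = 1.5
    fc_low: float = 0.67
    vip_min: float = 1.0
    # selection
    fst_window: int = 100_000
    fst_step: int = 10_000
    sweep_top_q: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulate", {}))
        cfg = cls(**raw)
        cfg.simulate = sim
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    stages = list(cfg.stages)

    if "simulate" in stages:
        cohort = emit_cohort(cfg.simulate, out / "cohort")
        files.update({f"cohort_{k}": v for k, v in cohort.items()})
        vcf, met1_p, met2_p = cohort["vcf"], cohort["met1"], cohort["met2"]
        expr_p, gff_p = cohort["expression"], cohort["gff3"]
        meta_p, truth_p = cohort["metadata"], cohort["truth"]
    else:
        vcf = out / "cohort" / "genotypes.vcf"
        met1_p = out / "cohort" / "metabolites_season1.tsv"
        met2_p = out / "cohort" / "metabolites_season2.tsv"
        expr_p = out / "cohort" / "expression.tsv"
        gff_p = out / "cohort" / "genes.gff3"
        meta_p = out / "cohort" / "samples.tsv"
        truth_p = out / "cohort" / "ground_truth.json"
    for p in (vcf, met1_p, met2_p, expr_p, gff_p, meta_p):
        if not Path(p).exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")

    g = gio.read_vcf(vcf)
    met1 = gio.read_matrix_tsv(met1_p)
    met2 = gio.read_matrix_tsv(met2_p)
    genes = gio.read_gff3(gff_p)
    expr = gio.read_expression_tsv(expr_p, genes)
    metadata = pd.read_csv(meta_p, sep="\t", index_col=0)
    seed = cfg.simulate.seed

    if "filter" in stages:
        g = gio.filter_variants(g, cfg.maf_min, cfg.miss_max, cfg.hwe_p_min)
        expr = gio.filter_expressed_genes(expr, cfg.fpkm_min, cfg.expressed_frac)
        logger.info("post-QC: %d SNPs, %d expressed genes", g.n_variants, len(expr.genes))

    chrom_lengths = {c: cfg.simulate.chrom_length_bp for c in sorted(set(g.chroms.tolist()))}
    K = gwas.kinship(g)
    X = gwas.pc_covariates(g, k=cfg.n_pcs)

    if "stats" in stages:
        rows = []
        log1 = np.log(met1.to_numpy(dtype=float))
        log2_ = np.log(met2.to_numpy(dtype=float))
        for j, m in enumerate(met1.columns):
            cv = met.coefficient_of_variation(met1.iloc[:, j].to_numpy())
            vd = met.broad_sense_heritability(log1[:, j], log2_[:, j])
            r, p = met.season_correlation(log1[:, j], log2_[:, j])
            rows.append((m, cv, vd.var_G, vd.var_E, vd.H2, r, p))
        stats_df = pd.DataFrame(
            rows, columns=["metabolite", "cv", "var_G", "var_E", "H2", "season_r", "season_p"]
        )
        files["stats"] = out / "metabolite_stats.tsv"
        stats_df.to_csv(files["stats"], sep="\t", index=False, float_format="%.8g")

        wl = metadata[metadata["group"].isin(["W", "L"])]
        mw = met1.loc[wl.index[wl["group"] == "W"]]
        ml = met1.loc[wl.index[wl["group"] == "L"]]
        diff = met.differential_metabolites(mw, ml, cfg.fc_high, cfg.fc_low, cfg.vip_min)
        files["differential"] = out / "differential_W_vs_L.tsv"
        pd.DataFrame([asdict(d) for d in diff]).to_csv(
            files["differential"], sep="\t", index=False, float_format="%.8g"
        )

    leads_all: list[gwas.LeadSNP] = []
    if "mgwas" in stages:
        n_traits = len(met1.columns)
        if cfg.mgwas_max_traits is not None:
            n_traits = min(n_traits, cfg.mgwas_max_traits)
        assoc_rows = []
        for j in range(n_traits):
            name = str(met1.columns[j])
            y = np.log(met1.iloc[:, j].to_numpy(dtype=float))
            res = gwas.lmm_scan(y, g, X, K, trait=name)
            leads = gwas.extract_lead_snps(res, cfg.mgwas_p, cfg.clump_radius)
            leads_all.extend(leads)
            for r in res:
                if r.p <= 1e-3:
                    assoc_rows.append((name, r.snp.chrom, r.snp.pos, r.beta, r.se, r.p, r.r2))
        assoc = pd.DataFrame(
            assoc_rows, columns=["trait", "chrom", "pos", "beta", "se", "p", "r2"]
        )
        files["associations"] = out / "mgwas_associations.tsv"
        assoc.to_csv(files["associations"], sep="\t", index=False, float_format="%.8g")
        files["leads"] = out / "mgwas_leads.tsv"
        pd.DataFrame(
            [(l.trait, l.snp.chrom, l.snp.pos, l.snp.vid, l.p) for l in leads_all],
            columns=["trait", "chrom", "pos", "vid", "p"],
        ).to_csv(files["leads"], sep="\t", index=False, float_format="%.8g")
        hw, thr = gwas.detect_hotspots(
            leads_all, g.chroms, g.positions, chrom_lengths,
            cfg.hotspot_window, cfg.n_perm, cfg.hotspot_alpha, seed=seed,
        )
        files["hotspots"] = out / "mgwas_hotspots.bed"
        gio.write_bed(
            [(w.chrom, w.start, w.end) for w in hw], files["hotspots"],
            extra=[(w.lead_count, w.threshold, int(w.is_hotspot)) for w in hw],
        )

    eqtl_clumped = pd.DataFrame()
    if "eqtl" in stages:
        recs = eq.eqtl_scan(expr, g, X, cfg.eqtl_prefilter, cfg.cis_window)
        eqtl_clumped = eq.clump_eqtls(recs, cfg.cis_p, cfg.trans_p, cfg.cis_window)
        files["eqtls"] = out / "eqtls.tsv"
        eqtl_clumped.to_csv(files["eqtls"], sep="\t", index=False, float_format="%.8g")
        trans = eqtl_clumped[eqtl_clumped["kind"] == "trans"] if not eqtl_clumped.empty \
            else eqtl_clumped
        ehw, ethr = eq.eqtl_hotspots(
            trans, g.chroms, g.positions, chrom_lengths,
            cfg.hotspot_window, cfg.n_perm, cfg.hotspot_alpha, seed=seed,
        )
        files["eqtl_hotspots"] = out / "eqtl_hotspots.bed"
        gio.write_bed(
            [(w.chrom, w.start, w.end) for w in ehw], files["eqtl_hotspots"],
            extra=[(w.lead_count, w.threshold, int(w.is_hotspot)) for w in ehw],
        )

    if "integrate" in stages:
        met1_aligned = met1.loc[expr.samples]
        edges = integ.correlation_network(expr, met1_aligned, cfg.edge_r_min, cfg.edge_p_max)
        files["edges"] = out / "correlation_edges.tsv"
        pd.DataFrame([asdict(e_) for e_ in edges]).to_csv(
            files["edges"], sep="\t", index=False, float_format="%.8g"
        )
        cands = integ.candidate_genes(leads_all, expr.genes, edges, cfg.candidate_flank)
        files["candidates"] = out / "candidate_genes.tsv"
        pd.DataFrame([asdict(c) for c in cands]).to_csv(
            files["candidates"], sep="\t", index=False, float_format="%.8g"
        )
        modules, labels = integ.coexpression_modules(
            expr, cfg.soft_power, cfg.min_module_size
        )
        files["modules"] = out / "modules.tsv"
        pd.DataFrame({"gene_id": expr.gene_ids, "module_id": labels}).to_csv(
            files["modules"], sep="\t", index=False
        )
        assoc_mm = integ.module_metabolite_association(modules, met1_aligned)
        files["module_metabolite"] = out / "module_metabolite.tsv"
        assoc_mm.to_csv(files["module_metabolite"], sep="\t", index=False, float_format="%.8g")

    if "fst" in stages:
        grp = metadata["group"]
        contrasts = {
            "domestication": (list(grp.index[grp == "W"]), list(grp.index[grp == "L"])),
            "improvement": (list(grp.index[grp == "L"]),
                            list(grp.index[grp.isin(["EI", "WI"])])),
            "differentiation": (list(grp.index[grp == "EI"]), list(grp.index[grp == "WI"])),
        }
        for name, (ga, gb) in contrasts.items():
            wins = popgen.windowed_fst(g, ga, gb, cfg.fst_window, cfg.fst_step)
            wins = popgen.call_sweeps(wins, cfg.sweep_top_q)
            files[f"fst_{name}"] = out / f"fst_{name}.bed"
            gio.write_bed(
                [(w.chrom, w.start, w.end) for w in wins], files[f"fst_{name}"],
                extra=[(f"{w.mean_fst:.6g}", w.n_sites, int(w.is_sweep)) for w in wins],
            )
            if name == "domestication" and leads_all:
                regions = popgen.merge_sweep_regions(wins)
                rep = popgen.overlap_leads_with_sweeps(leads_all, regions)
                files["sweep_overlap"] = out / "lead_sweep_overlap.json"
                with open(files["sweep_overlap"], "w") as fh:
                    json.dump(rep, fh, indent=1)

    manifest = {
        "parameters": {**{k: v for k, v in asdict(cfg).items() if k != "simulate"},
                       "simulate": asdict(cfg.simulate)},
        "outputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in files.items()},
    }
    manifest["parameters"]["simulate"]["n_samples"] = dict(
        manifest["parameters"]["simulate"]["n_samples"]
    )
    files_manifest = out / "manifest.json"
    with open(files_manifest, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def recovery_report(outdir: str | Path, truth: GroundTruth) -> dict:
    """Precision/recall of planted signals from a completed pipeline run."""
    out = Path(outdir)
    report: dict = {}

    leads_p = out / "mgwas_leads.tsv"
    if leads_p.exists() and truth.causal_snps:
        leads = pd.read_csv(leads_p, sep="\t")
        causal = {
            m: tuple(v[0].rsplit("_", 1)) for m, v in truth.causal_snps.items()
        }
        hits, n_traits_hit = 0, 0
        traits_with_lead = set(leads["trait"]) & set(causal)
        for _, row in leads.iterrows():
            c = causal.get(row["trait"])
            if c and row["chrom"] == c[0] and abs(int(row["pos"]) - int(c[1])) <= 100_000:
                hits += 1
        for t in traits_with_lead:
            sub = leads[leads["trait"] == t]
            c = causal[t]
            if any((sub["chrom"] == c[0]) & ((sub["pos"] - int(c[1])).abs() <= 100_000)):
                n_traits_hit += 1
        report["lead_snp_precision"] = hits / len(leads) if len(leads) else float("nan")
        report["lead_snp_trait_recall"] = (
            n_traits_hit / len(causal) if causal else float("nan")
        )

    for stem, key in (("mgwas_hotspots", "mgwas_hotspot_recall"),
                      ("eqtl_hotspots", "eqtl_hotspot_recall")):
        bed = out / f"{stem}.bed"
        if bed.exists() and truth.hotspot_truth:
            rows = pd.read_csv(bed, sep="\t", header=None,
                               names=["chrom", "start0", "end", "count", "thr", "flag"])
            flagged = rows[rows["flag"] == 1]
            found = 0
            for chrom, s, e in truth.hotspot_truth:
                hit = flagged[(flagged["chrom"] == chrom)
                              & (flagged["start0"] < e) & (flagged["end"] >= s)]
                if len(hit):
                    found += 1
            report[key] = found / len(truth.hotspot_truth)

    eqtl_p = out / "eqtls.tsv"
    if eqtl_p.exists() and truth.cis_truth:
        recs = pd.read_csv(eqtl_p, sep="\t")
        cis = recs[recs["kind"] == "cis"] if not recs.empty else recs
        genes_with_cis = set(cis["gene_id"]) if not cis.empty else set()
        report["cis_eqtl_recall"] = (
            len(genes_with_cis & set(truth.cis_truth)) / len(truth.cis_truth)
        )

    mod_p = out / "modules.tsv"
    if mod_p.exists() and truth.module_truth:
        from sklearn.metrics import adjusted_rand_score

        mods = pd.read_csv(mod_p, sep="\t").set_index("gene_id")["module_id"]
        genes = [gid for gid in truth.module_truth if gid in mods.index]
        report["module_ari"] = float(adjusted_rand_score(
            [truth.module_truth[gid] for gid in genes],
            [mods[gid] for gid in genes],
        ))

    sweep_beds = list(out.glob("fst_*.bed"))
    if sweep_beds and truth.sweep_truth:
        found = 0
        for chrom, s, e in truth.sweep_truth:
            hit = False
            for bed in sweep_beds:
                rows = pd.read_csv(bed, sep="\t", header=None,
                                   names=["chrom", "start0", "end", "fst", "n", "flag"])
                flagged = rows[rows["flag"] == 1]
                if len(flagged[(flagged["chrom"] == chrom)
                               & (flagged["start0"] < e) & (flagged["end"] >= s)]):
                    hit = True
            found += int(hit)
        report["sweep_recall"] = found / len(truth.sweep_truth)

    stats_p = out / "metabolite_stats.tsv"
    if stats_p.exists() and truth.h2_truth:
        st = pd.read_csv(stats_p, sep="\t").set_index("metabolite")
        common = [m for m in truth.h2_truth if m in st.index]
        if common:
            est = st.loc[common, "H2"].to_numpy(dtype=float)
            tru = np.array([truth.h2_truth[m] for m in common])
            report["h2_bias"] = float(np.mean(est - tru))
    return report
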