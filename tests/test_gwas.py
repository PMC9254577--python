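"""Mixed-model GWAS machinery: kinship, REML, clumping, hotspots."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

from metabogwas import gwas
from metabogwas.io import GenotypeMatrix, VariantRecord
from conftest import small_config
from metabogwas.simulate import simulate_population


def _toy_genotypes(dosage, positions=None, chrom="Pp01"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions if positions is not None else [100 * (j + 1) for j in range(m)]
    variants = []
    for j in range(m):
        col = dosage[:, j]
        p = np.nanmean(col) / 2
        variants.append(VariantRecord(chrom, positions[j], "A", "G",
                                      min(p, 1 - p), 0.0, 1.0, vid=f"v{j}"))
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosage)


class TestKinship:
    def test_duplicated_sample_matches_diagonal(self, rng):
        d = rng.binomial(2, 0.4, (20, 300)).astype(float)
        d[1] = d[0]
        K = gwas.kinship(_toy_genotypes(d)).values
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-10)
        assert K[0, 1] == pytest.approx(K[1, 1], abs=1e-10)

    def test_grm_normalization(self, rng):
        # HWE panel: mean diagonal ~ 1; mean off-diagonal ~ -1/(n-1) ~ 0
        # (sample-frequency centering forces zero row sums)
        p = rng.uniform(0.1, 0.9, 5000)
        d = rng.binomial(2, p, (200, 5000)).astype(float)
        K = gwas.kinship(_toy_genotypes(d)).values
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.1)
        off = K[np.triu_indices_from(K, k=1)]
        assert abs(off.mean()) < 0.02

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            gwas.kinship(_toy_genotypes(np.zeros((5, 3))))


def _dense_reml_oracle(y, X, K):
    """Brute-force dense REML over delta (no spectral shortcut)."""
    n, q = X.shape
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    def negll(log_delta):
        H = K + np.exp(log_delta) * np.eye(n)
        Hinv = np.linalg.inv(H)
        XtHX = X.T @ Hinv @ X
        beta = np.linalg.solve(XtHX, X.T @ Hinv @ y)
        r = y - X @ beta
        sigma_g2 = float(r @ Hinv @ r) / (n - q)
        _, logdet_H = np.linalg.slogdet(H)
        _, logdet_XtHX = np.linalg.slogdet(XtHX)
        return 0.5 * (
            (n - q) * (np.log(2 * np.pi * sigma_g2) + 1)
            + logdet_H + logdet_XtHX - logdet_xtx
        )

    res = optimize.minimize_scalar(negll, bounds=(np.log(1e-5), np.log(1e5)),
                                   method="bounded", options={"xatol": 1e-12})
    return float(np.exp(res.x)), -float(res.fun)


class TestNullLMM:
    def test_brute_force_likelihood_agreement(self):
        cfg = small_config(seed=21, n_snps=400,
                           n_samples={"A": 25, "B": 25})
        g = simulate_population(cfg)
        K = gwas.kinship(g)
        rng = np.random.default_rng(3)
        u = np.linalg.cholesky(K.values + 1e-6 * np.eye(50)) @ rng.normal(size=50)
        y = u + rng.normal(size=50)
        X = np.ones((50, 1))
        vc = gwas.fit_null_lmm(y, X, K)
        delta_o, ll_o = _dense_reml_oracle(y, X, K.values)
        assert vc.log_likelihood == pytest.approx(ll_o, abs=1e-6)
        assert vc.delta == pytest.approx(delta_o, rel=1e-3)

    def test_h2_recovery_on_average(self):
        cfg = small_config(seed=22, n_snps=800, n_samples={"A": 150, "B": 150})
        g = simulate_population(cfg)
        K = gwas.kinship(g)
        L = np.linalg.cholesky(K.values + 1e-6 * np.eye(300))
        X = np.ones((300, 1))
        h2s = []
        rng = np.random.default_rng(4)
        for _ in range(25):
            y = np.sqrt(0.5) * (L @ rng.normal(size=300)) + np.sqrt(0.5) * rng.normal(size=300)
            vc = gwas.fit_null_lmm(y, X, K)
            h2s.append(vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2))
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.1)

    def test_pure_noise_low_heritability(self):
        cfg = small_config(seed=23, n_snps=800, n_samples={"A": 150, "B": 150})
        g = simulate_population(cfg)
        K = gwas.kinship(g)
        X = np.ones((300, 1))
        rng = np.random.default_rng(5)
        low = sum(
            (lambda vc: vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2) <= 0.1)(
                gwas.fit_null_lmm(rng.normal(size=300), X, K)
            )
            for _ in range(40)
        )
        assert low >= 36

    def test_nonfinite_trait_rejected(self, small_cohort):
        K = gwas.kinship(small_cohort["g"])
        y = np.full(small_cohort["g"].n_samples, np.nan)
        with pytest.raises(ValueError):
            gwas.fit_null_lmm(y, np.ones((len(y), 1)), K)


class TestScan:
    def test_identity_kinship_equals_ols(self, rng):
        n, m = 60, 30
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        g = _toy_genotypes(d)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        K = gwas.KinshipMatrix(g.samples, np.eye(n))
        res = gwas.lmm_scan(y, g, X, K)
        for j in rng.choice(m, 5, replace=False):
            Xj = np.column_stack([X, d[:, j]])
            beta = np.linalg.lstsq(Xj, y, rcond=None)[0]
            r = y - Xj @ beta
            s2 = float(r @ r) / (n - Xj.shape[1])
            cov = s2 * np.linalg.inv(Xj.T @ Xj)
            t = beta[-1] / np.sqrt(cov[-1, -1])
            p_ols = 2 * stats.t.sf(abs(t), n - Xj.shape[1])
            assert res[j].p == pytest.approx(p_ols, rel=1e-10)

    def test_zero_variance_snp_flagged(self, rng):
        d = rng.binomial(2, 0.4, (30, 5)).astype(float)
        d[:, 2] = 1.0
        g = _toy_genotypes(d)
        K = gwas.KinshipMatrix(g.samples, np.eye(30))
        res = gwas.lmm_scan(rng.normal(size=30), g, np.ones((30, 1)), K)
        assert res[2].flagged and res[2].p == 1.0

    def test_planted_qtl_power(self):
        cfg = small_config(seed=24, n_snps=2000, n_mqtl=3, mqtl_pve=0.2,
                           n_samples={"W": 75, "L": 75, "EI": 75, "WI": 75})
        g = simulate_population(cfg)
        from metabogwas.simulate import simulate_metabolome

        m1, _, truth = simulate_metabolome(g, cfg)
        K = gwas.kinship(g)
        X = gwas.pc_covariates(g, 3)
        thr = gwas.bonferroni_threshold(2000)
        vid_to_idx = {v.vid: j for j, v in enumerate(g.variants)}
        hits = 0
        for met_name, (vid, _eff) in truth.causal_snps.items():
            res = gwas.lmm_scan(np.log(m1[met_name].to_numpy()), g, X, K)
            assert res[vid_to_idx[vid]].p <= thr
            hits += 1
        assert hits == 3


class TestBonferroni:
    def test_values(self):
        assert gwas.bonferroni_threshold(10) == pytest.approx(5e-3)
        assert gwas.bonferroni_threshold(22_374) == pytest.approx(2.23e-6, rel=5e-3)
        # the printed genome-wide cutoff is a constant, not this division
        assert gwas.bonferroni_threshold(486_009) == pytest.approx(1.03e-7, rel=5e-3)
        assert gwas.bonferroni_threshold(486_009) != pytest.approx(
            gwas.MGWAS_P_THRESHOLD, rel=0.5
        )

    def test_invalid(self):
        with pytest.raises(ValueError):
            gwas.bonferroni_threshold(0)


def _assoc(chrom, pos, p, trait="t"):
    v = VariantRecord(chrom, pos, "A", "G", 0.2, 0.0, 1.0, vid=f"{chrom}:{pos}")
    return gwas.AssociationResult(trait, v, 1.0, 0.1, p, 0.1)


class TestClumping:
    def test_empty_when_nothing_significant(self):
        assert gwas.extract_lead_snps([_assoc("Pp01", 100, 0.5)], 1e-6) == []

    def test_nearby_pair_one_lead(self):
        res = [_assoc("Pp01", 1_000_000, 1e-9), _assoc("Pp01", 1_050_000, 1e-8)]
        leads = gwas.extract_lead_snps(res, 1e-6, clump_radius=100_000)
        assert [(l.snp.pos, l.p) for l in leads] == [(1_000_000, 1e-9)]

    def test_distant_pair_two_leads(self):
        res = [_assoc("Pp01", 1_000_000, 1e-9), _assoc("Pp01", 1_200_000, 1e-8)]
        leads = gwas.extract_lead_snps(res, 1e-6, clump_radius=100_000)
        assert len(leads) == 2

    @given(st.permutations(range(6)))
    def test_order_invariance(self, perm):
        base = [
            _assoc("Pp01", 500_000, 1e-9),
            _assoc("Pp01", 560_000, 1e-8),
            _assoc("Pp01", 900_000, 1e-7),
            _assoc("Pp02", 500_000, 1e-10),
            _assoc("Pp02", 540_000, 1e-7),
            _assoc("Pp02", 2_000_000, 0.5),
        ]
        shuffled = [base[i] for i in perm]
        ref = gwas.extract_lead_snps(base, 1e-6)
        got = gwas.extract_lead_snps(shuffled, 1e-6)
        assert [(l.snp.chrom, l.snp.pos) for l in got] == [
            (l.snp.chrom, l.snp.pos) for l in ref
        ]


class TestHotspots:
    def test_single_loaded_window_flagged(self, rng):
        pos = np.sort(rng.choice(10_000_000, 2000, replace=False)) + 1
        chroms = np.array(["Pp01"] * 2000)
        in_first = pos[pos <= 1_000_000]
        leads = [
            gwas.LeadSNP("t", VariantRecord("Pp01", int(p), "A", "G", 0.2, 0, 1.0), 1e-9)
            for p in rng.choice(in_first, 60)
        ]
        wins, thr = gwas.detect_hotspots(
            leads, chroms, pos, {"Pp01": 10_000_000}, n_perm=300, seed=1
        )
        flagged = [w for w in wins if w.is_hotspot]
        assert len(flagged) == 1
        assert flagged[0].start == 1
        assert all(w.is_hotspot == (w.lead_count >= w.threshold) for w in wins)

    def test_poisson_max_oracle(self, rng):
        n_chrom, clen = 8, 28_125_000
        chroms = np.repeat([f"Pp0{i+1}" for i in range(n_chrom)], 2500)
        pos = np.concatenate(
            [np.sort(rng.choice(clen, 2500, replace=False)) + 1 for _ in range(n_chrom)]
        )
        windows = gwas.tile_windows({f"Pp0{i+1}": clen for i in range(n_chrom)})
        thr = gwas.permutation_hotspot_threshold(
            8685, chroms, pos, windows, 1_000_000, 1000, 0.05,
            np.random.default_rng(2),
        )
        mu = 8685 / len(windows)
        c = 1
        while 1 - stats.poisson.cdf(c - 1, mu) ** len(windows) >= 0.05:
            c += 1
        assert abs(thr - c) <= 0.15 * c


class TestPCCovariates:
    def test_group_separation(self):
        cfg = small_config(seed=25, n_snps=1000, fst_background=0.25,
                           n_samples={"A": 40, "B": 40})
        g = simulate_population(cfg)
        X = gwas.pc_covariates(g, 2)
        pc1 = X[:, 1]
        labels = np.array([0] * 40 + [1] * 40)
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(labels, pc1)
        assert max(auc, 1 - auc) >= 0.95

    def test_k_zero_intercept_only(self, small_cohort):
        X = gwas.pc_covariates(small_cohort["g"], 0)
        np.testing.assert_array_equal(X, np.ones((small_cohort["g"].n_samples, 1)))

    def test_orthonormal(self, small_cohort):
        X = gwas.pc_covariates(small_cohort["g"], 4)
        gram = X[:, 1:].T @ X[:, 1:]
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_k_too_large(self, small_cohort):
        with pytest.raises(ValueError):
            gwas.pc_covariates(small_cohort["g"], small_cohort["g"].n_samples)
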