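"""Metabolome statistics: CV, heritability, PCA, PLS-DA/VIP, differential
calling, group-specific features, environmental levels."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from metabogwas import metabolome as met


class TestCV:
    def test_constant_vector(self):
        assert met.coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_pair(self):
        # sd([2,4]) = sqrt(2), mean = 3
        assert met.coefficient_of_variation([2.0, 4.0]) == pytest.approx(
            np.sqrt(2) / 3
        )

    def test_lognormal_closed_form(self, rng):
        # CV of LogNormal(mu, sigma) is sqrt(exp(sigma^2) - 1)
        x = rng.lognormal(0.0, 0.5, 2000)
        assert met.coefficient_of_variation(x) == pytest.approx(
            np.sqrt(np.exp(0.25) - 1.0), abs=0.05
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            met.coefficient_of_variation([-1.0, 1.0])


def _anova_h2_oracle(y1, y2):
    """Brute-force one-way random-effects ANOVA via explicit sums of squares."""
    y = np.stack([y1, y2])  # 2 reps x n accessions
    n = y.shape[1]
    grand = y.mean()
    acc_means = y.mean(axis=0)
    ss_between = 2 * np.sum((acc_means - grand) ** 2)
    ss_within = np.sum((y - acc_means) ** 2)
    ms_b = ss_between / (n - 1)
    ms_w = ss_within / n  # n*(2-1) within degrees of freedom
    var_g = max((ms_b - ms_w) / 2, 0.0)
    return var_g / (var_g + ms_w) if var_g + ms_w > 0 else 0.0


class TestHeritability:
    def test_identical_seasons_h2_one(self):
        v = met.broad_sense_heritability([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert v.H2 == 1.0

    def test_no_accession_variance_h2_zero(self):
        v = met.broad_sense_heritability([1.0, 1, 1, 1], [2.0, 2, 2, 2])
        assert v.var_G == 0.0
        assert v.H2 == 0.0

    def test_anova_oracle_worked_table(self):
        y1 = np.array([3.1, 5.0, 2.2, 7.5])
        y2 = np.array([2.9, 5.6, 1.8, 6.9])
        v = met.broad_sense_heritability(y1, y2)
        assert v.H2 == pytest.approx(_anova_h2_oracle(y1, y2), abs=1e-10)

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=12),
           st.integers(0, 2**31 - 1))
    def test_h2_in_unit_interval(self, base, seed):
        rng = np.random.default_rng(seed)
        y1 = np.array(base) + rng.normal(0, 1, len(base))
        y2 = np.array(base) + rng.normal(0, 1, len(base))
        v = met.broad_sense_heritability(y1, y2)
        assert 0.0 <= v.H2 <= 1.0
        assert v.H2 == pytest.approx(_anova_h2_oracle(y1, y2), abs=1e-10)

    def test_too_few_accessions(self):
        with pytest.raises(ValueError):
            met.broad_sense_heritability([1.0], [2.0])


class TestSeasonCorrelation:
    def test_perfect_correlation(self):
        r, p = met.season_correlation([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_matches_formula(self, rng):
        x = rng.normal(0, 1, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        r, _ = met.season_correlation(x, y)
        rx = (x - x.mean()) / x.std()
        ry = (y - y.mean()) / y.std()
        assert r == pytest.approx(float((rx * ry).mean()), abs=1e-12)

    def test_null_calibration(self):
        # |r| > 0.18 at n = 200 corresponds to p ~ 0.01 two-sided
        rng = np.random.default_rng(123)
        count = sum(
            abs(np.corrcoef(rng.normal(size=200), rng.normal(size=200))[0, 1]) > 0.18
            for _ in range(1000)
        )
        assert 0 < count < 35  # ~1% expected

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            met.season_correlation([1.0, 1, 1], [1.0, 2, 3])


class TestPCA:
    def test_duplicated_samples_identical_scores(self, rng):
        x = rng.lognormal(0, 0.4, (6, 30))
        x[1] = x[0]
        scores, _ = met.pca_scores(x, 3)
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-8)

    def test_variance_ratio_monotone_and_bounded(self, rng):
        x = rng.lognormal(0, 0.4, (20, 15))
        _, ratio = met.pca_scores(x, 5)
        assert np.all(np.diff(ratio) <= 1e-12)
        assert ratio.sum() <= 1.0 + 1e-9

    def test_sample_order_invariance_up_to_sign(self, rng):
        x = rng.lognormal(0, 0.4, (15, 20))
        perm = rng.permutation(15)
        s1, _ = met.pca_scores(x, 2)
        s2, _ = met.pca_scores(x[perm], 2)
        for k in range(2):
            agree = np.allclose(s1[perm, k], s2[:, k], atol=1e-8)
            flipped = np.allclose(s1[perm, k], -s2[:, k], atol=1e-8)
            assert agree or flipped

    def test_group_separation(self, rng):
        from sklearn.metrics import silhouette_score

        groups = np.repeat([0, 1, 2, 3], 15)
        shift = np.zeros((60, 40))
        for k in range(4):
            shift[groups == k, 10 * k: 10 * (k + 1)] = 2.5
        x = np.exp(rng.normal(0, 0.3, (60, 40)) + shift)
        scores, _ = met.pca_scores(x, 2)
        assert silhouette_score(scores, groups) > 0.3


class TestPLSDA:
    def test_symmetric_two_features(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(0, 0.3, 40)
        x = np.column_stack([base, base])
        y = ["A"] * 20 + ["B"] * 20
        model = met.plsda_fit(x, y, n_components=1)
        np.testing.assert_allclose(model.vip, [1.0, 1.0], atol=1e-8)

    def test_vip_normalization_and_informative_feature(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 0.4, (60, 10))
        x[:30, 0] *= 5.0
        y = ["A"] * 30 + ["B"] * 30
        model = met.plsda_fit(x, y)
        assert np.nanmean(model.vip**2) == pytest.approx(1.0, abs=1e-8)
        assert model.vip[0] > 1.0

    def test_matches_sklearn_components(self):
        """NIPALS scores/weights agree with the reference PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 0.4, (50, 8))
        y = np.array([0] * 25 + [1] * 25)
        model = met.plsda_fit(x, y, n_components=2)
        z = (np.log2(x + 1) - np.log2(x + 1).mean(0)) / np.log2(x + 1).std(0, ddof=1)
        ref = PLSRegression(n_components=2, scale=False).fit(z, y - y.mean())
        for a in range(2):
            # same subspace up to sign
            c = np.corrcoef(model.scores[:, a], ref.x_scores_[:, a])[0, 1]
            assert abs(c) > 1 - 1e-8

    def test_random_labels_permutation_rate(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(0, 0.4, (40, 30))
        fracs = []
        for _ in range(30):
            y = rng.permutation([0] * 20 + [1] * 20)
            m = met.plsda_fit(x, y)
            fracs.append(np.nanmean(m.vip >= 1.0))
        # under exchangeability roughly a third to a half of features reach
        # VIP >= 1 (mean VIP^2 is pinned at 1); the rate must be stable
        assert 0.2 < np.mean(fracs) < 0.6

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            met.plsda_fit(np.ones((4, 2)), ["A"] * 4)


class TestDifferential:
    @staticmethod
    def _frames(rng, n_per=30, n_feat=25, planted=(0, 1, 2)):
        a = rng.lognormal(0, 0.3, (n_per, n_feat))
        b = rng.lognormal(0, 0.3, (n_per, n_feat))
        for j in planted:
            a[:, j] *= 20.0
        cols = [f"m{j}" for j in range(n_feat)]
        return (pd.DataFrame(a, columns=cols), pd.DataFrame(b, columns=cols))

    def test_rule_application(self):
        rng = np.random.default_rng(9)
        ma, mb = self._frames(rng)
        res = {r.metabolite: r for r in met.differential_metabolites(ma, mb)}
        for r in res.values():
            expected = (r.fold_change >= 1.5 or r.fold_change <= 0.67) and r.vip >= 1.0
            assert r.is_differential == expected

    def test_planted_recovery(self):
        rng = np.random.default_rng(10)
        ma, mb = self._frames(rng, n_per=100, n_feat=40, planted=tuple(range(8)))
        res = met.differential_metabolites(ma, mb)
        planted = [r for r in res if r.metabolite in {f"m{j}" for j in range(8)}]
        nulls = [r for r in res if r.metabolite not in {f"m{j}" for j in range(8)}]
        assert np.mean([r.is_differential for r in planted]) >= 0.9
        assert np.mean([r.is_differential for r in nulls]) <= 0.1

    def test_direction_symmetry_with_reciprocal_rule(self):
        rng = np.random.default_rng(11)
        ma, mb = self._frames(rng)
        fwd = met.differential_metabolites(ma, mb, fc_high=1.5, fc_low=1 / 1.5)
        rev = met.differential_metabolites(mb, ma, fc_high=1.5, fc_low=1 / 1.5)
        assert {r.metabolite for r in fwd if r.is_differential} == {
            r.metabolite for r in rev if r.is_differential
        }

    def test_mismatched_columns_rejected(self):
        a = pd.DataFrame(np.ones((3, 2)), columns=["x", "y"])
        b = pd.DataFrame(np.ones((3, 2)), columns=["x", "z"])
        with pytest.raises(ValueError):
            met.differential_metabolites(a, b)


class TestGroupSpecific:
    def test_exclusive_feature(self):
        cols = ["m1", "m2"]
        mats = {
            "W": pd.DataFrame([[5.0, 5.0]] * 10, columns=cols),
            "L": pd.DataFrame([[0.0, 5.0]] * 10, columns=cols),
        }
        out = met.group_specific_metabolites(mats, detect_min=1.0)
        assert out["W"] == ["m1"]
        assert out["L"] == []

    def test_brute_force_oracle(self, rng):
        cols = [f"m{j}" for j in range(15)]
        mats = {
            g: pd.DataFrame((rng.random((12, 15)) < 0.5).astype(float) * 3.0,
                            columns=cols)
            for g in ("W", "L", "EI")
        }
        out = met.group_specific_metabolites(mats, detect_min=1.0,
                                             presence_frac=0.8, other_max_frac=0.05)
        for g in mats:
            expected = []
            for j, m in enumerate(cols):
                frac = {h: (mats[h].iloc[:, j] >= 1.0).mean() for h in mats}
                if frac[g] >= 0.8 and all(frac[h] <= 0.05 for h in mats if h != g):
                    expected.append(m)
            assert out[g] == expected


class TestEnvLevel:
    @pytest.mark.parametrize(
        "value,kind,level",
        [
            (800, "rainfall", 3),
            (370, "rainfall", 2),   # half-open boundary
            (1, "rainfall", 1),
            (1850, "rainfall", 5),
            (21, "temperature", 5),
            (7, "temperature", 1),
            (13, "temperature", 3),
        ],
    )
    def test_binning(self, value, kind, level):
        assert met.env_level(value, kind) == level

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            met.env_level(2000, "rainfall")
        with pytest.raises(ValueError):
            met.env_level(5, "temperature")
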