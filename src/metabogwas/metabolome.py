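"""Descriptive and multivariate metabolome statistics.

Coefficient of variation (s/m), broad-sense heritability from seasonal
replicates (H2 = var(G)/(var(G)+var(E)) via one-way random-effects ANOVA),
between-season trait correlation, PCA, two-group PLS-DA with VIP scores,
differential-metabolite calling (fold change + VIP rule), group-specific
features, and the 5-level environmental classification.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class VarianceDecomposition:
    var_G: float
    var_E: float
    H2: float


@dataclass
class PLSDAModel:
    n_components: int
    weights: np.ndarray        # (p, A), each column unit norm
    scores: np.ndarray         # (n, A)
    explained_y_ss: np.ndarray  # SS_a per component
    vip: np.ndarray            # (p,)


@dataclass(frozen=True)
class DifferentialResult:
    metabolite: str
    fold_change: float
    vip: float
    is_differential: bool


def coefficient_of_variation(values: np.ndarray) -> float:
    """CV = s/m with the sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("CV needs at least 2 observed values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m)


def broad_sense_heritability(
    season1: np.ndarray, season2: np.ndarray
) -> VarianceDecomposition:
    """H2 from two seasonal replicates per accession.

    One-way random-effects ANOVA with accession as the grouping factor and
    season as the replicate: var_E = MS_within, var_G = (MS_between -
    MS_within)/2 clipped at zero, H2 = var_G/(var_G + var_E).
    """
    y1 = np.asarray(season1, dtype=float)
    y2 = np.asarray(season2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("need one value per accession per season")
    n = y1.size
    if n < 2:
        raise ValueError("need at least 2 accessions")
    means = (y1 + y2) / 2.0
    grand = means.mean()
    ms_between = 2.0 * np.sum((means - grand) ** 2) / (n - 1)
    ms_within = np.sum((y1 - means) ** 2 + (y2 - means) ** 2) / n
    var_e = ms_within
    var_g = max((ms_between - ms_within) / 2.0, 0.0)
    total = var_g + var_e
    h2 = var_g / total if total > 0 else 0.0
    return VarianceDecomposition(var_G=var_g, var_E=var_e, H2=h2)


def season_correlation(
    season1: np.ndarray, season2: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between seasons with a two-sided t-test p-value."""
    y1 = np.asarray(season1, dtype=float)
    y2 = np.asarray(season2, dtype=float)
    if y1.size < 3:
        raise ValueError("need at least 3 paired values")
    if y1.std() == 0 or y2.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(y1, y2)
    return float(r), float(p)


def _log_scale(x: np.ndarray, drop_constant: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """log2(x+1), feature-centered and unit-variance scaled.

    Returns the scaled matrix and the boolean mask of retained (non-constant)
    features.
    """
    z = np.log2(np.asarray(x, dtype=float) + 1.0)
    sd = z.std(axis=0, ddof=1)
    keep = sd > 1e-12
    if not keep.all():
        logger.warning("dropping %d constant features", int((~keep).sum()))
    z = (z[:, keep] - z[:, keep].mean(axis=0)) / sd[keep]
    return z, keep


def pca_scores(
    abundances: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of the log2(x+1)-scaled metabolite table.

    Returns (scores, explained variance ratio), components ordered by
    decreasing variance explained.
    """
    x = np.asarray(abundances, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    z, _ = _log_scale(x)
    u, s, _vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    k = min(n_components, s.size)
    var = s**2
    return u[:, :k] * s[:k], var[:k] / var.sum()


def plsda_fit(
    X: np.ndarray, y: Sequence, n_components: int = 2
) -> PLSDAModel:
    """Two-group PLS-DA via NIPALS (PLS1 on the centered group indicator).

    Features are log2(x+1)-scaled to unit variance. Components maximize
    covariance with the class indicator; VIP_j = sqrt(p * sum_a SS_a
    (w_ja/||w_a||)^2 / sum_a SS_a) where SS_a is the y sum of squares
    explained by component a.
    """
    labels = np.asarray(y)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("plsda_fit requires exactly 2 groups")
    if min((labels == c).sum() for c in classes) == 0:
        raise ValueError("both groups must be non-empty")
    z, keep = _log_scale(np.asarray(X, dtype=float))
    n, p_kept = z.shape
    yv = (labels == classes[1]).astype(float)
    yv = yv - yv.mean()

    rank = min(n - 1, p_kept)
    if n_components > rank:
        logger.warning("n_components truncated from %d to rank %d", n_components, rank)
        n_components = rank
    E = z.copy()
    f = yv.copy()
    W = np.zeros((p_kept, n_components))
    T = np.zeros((n, n_components))
    ss = np.zeros(n_components)
    A = 0
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = (E.T @ t) / tt
        q = float(f @ t) / tt
        W[:, a] = w
        T[:, a] = t
        ss[a] = q * q * tt  # y sum of squares explained by component a
        E = E - np.outer(t, p_load)
        f = f - q * t
        A += 1
    W, T, ss = W[:, :A], T[:, :A], ss[:A]
    ss_total = ss.sum()
    if ss_total <= 0:
        vip_kept = np.ones(p_kept)
    else:
        vip_kept = np.sqrt(p_kept * (W**2 @ ss) / ss_total)
    vip = np.full(np.asarray(X).shape[1], np.nan)
    vip[keep] = vip_kept
    return PLSDAModel(n_components=A, weights=W, scores=T, explained_y_ss=ss, vip=vip)


def differential_metabolites(
    mA: pd.DataFrame,
    mB: pd.DataFrame,
    fc_high: float = 1.5,
    fc_low: float = 0.67,
    vip_min: float = 1.0,
    n_components: int = 2,
) -> list[DifferentialResult]:
    """Differential features between two groups: FC = mean(A)/mean(B) on raw
    abundances, VIP from a two-group PLS-DA on the pooled samples; a feature
    is differential iff (FC >= fc_high or FC <= fc_low) and VIP >= vip_min.
    """
    if list(mA.columns) != list(mB.columns):
        raise ValueError("groups must share the metabolite set")
    mean_a = mA.to_numpy(dtype=float).mean(axis=0)
    mean_b = mB.to_numpy(dtype=float).mean(axis=0)
    X = np.vstack([mA.to_numpy(dtype=float), mB.to_numpy(dtype=float)])
    y = ["A"] * len(mA) + ["B"] * len(mB)
    model = plsda_fit(X, y, n_components=n_components)
    out = []
    for j, met in enumerate(mA.columns):
        if mean_b[j] == 0:
            raise ValueError(f"zero group mean for {met}: fold change undefined")
        fc = mean_a[j] / mean_b[j]
        vip = model.vip[j]
        flag = bool(
            np.isfinite(vip)
            and vip >= vip_min
            and (fc >= fc_high or fc <= fc_low)
        )
        out.append(DifferentialResult(metabolite=str(met), fold_change=float(fc),
                                      vip=float(vip), is_differential=flag))
    return out


def group_specific_metabolites(
    matrices: dict[str, pd.DataFrame],
    detect_min: float,
    presence_frac: float = 0.8,
    other_max_frac: float = 0.05,
) -> dict[str, list[str]]:
    """Features detected (>= detect_min) in >= presence_frac of one group's
    samples and in <= other_max_frac of every other group's samples."""
    groups = list(matrices)
    cols = list(matrices[groups[0]].columns)
    for g in groups[1:]:
        if list(matrices[g].columns) != cols:
            raise ValueError("groups must share the metabolite set")
    det = {
        g: (matrices[g].to_numpy(dtype=float) >= detect_min).mean(axis=0) for g in groups
    }
    out: dict[str, list[str]] = {g: [] for g in groups}
    for j, met in enumerate(cols):
        for g in groups:
            if det[g][j] >= presence_frac and all(
                det[h][j] <= other_max_frac for h in groups if h != g
            ):
                out[g].append(str(met))
    return out


_RAIN_EDGES = (1.0, 370.0, 740.0, 1110.0, 1480.0, 1850.0)
_TEMP_EDGES = (7.0, 10.0, 13.0, 16.0, 19.0, 23.0)


def env_level(value: float, kind: str) -> int:
    """5-level environmental classification.

    Rainfall bins (mm): 1-370, 370-740, 740-1110, 1110-1480, 1480-1850.
    Temperature bins (C): 7-10, 10-13, 13-16, 16-19, 19-23. Interior
    boundaries are half-open [lower, upper); the outermost upper bound is
    inclusive.
    """
    edges = {"rainfall": _RAIN_EDGES, "temperature": _TEMP_EDGES}.get(kind)
    if edges is None:
        raise ValueError("kind must be 'rainfall' or 'temperature'")
    if not (edges[0] <= value <= edges[-1]):
        raise ValueError(f"{kind} value {value} outside [{edges[0]}, {edges[-1]}]")
    if value == edges[-1]:
        return 5
    return int(np.searchsorted(edges, value, side="right"))
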