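"""Group-level inference: HC-anchored confounder adjustment, permutation
t-tests with BH-FDR, Hedges' g with bootstrap CIs, one-way ANOVA with Tukey
post hoc, and the clinical dichotomies (EDSS >= 4; SDMT z < -1.5)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .layers import NuisanceZScorer

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustedScores",
    "GroupComparison",
    "adjust_confounders",
    "permutation_ttest",
    "nodal_comparison",
    "hedges_g",
    "anova_tukey",
    "dichotomize_clinical",
]

EXHAUSTIVE_LIMIT = 20_000


@dataclass
class AdjustedScores:
    """Confounder-adjusted, HC-standardized values.

    ``z = (corrected - mean of HC corrected) / SD of HC corrected`` where
    ``corrected = observed - prediction`` from the age/sex model fit on HC.
    """

    z: np.ndarray
    scaler: NuisanceZScorer
    hc_mean: np.ndarray
    hc_sd: np.ndarray


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    n1: int
    n2: int
    hedges_g: float | None = None
    g_ci_low: float | None = None
    g_ci_high: float | None = None
    fdr_significant: bool | None = None


def adjust_confounders(values, covariates, hc_mask, *, min_hc: int = 10) -> AdjustedScores:
    """Remove age/sex effects with weights estimated in the HC group only.

    Fitting nuisance weights in HC avoids absorbing disease-related variance
    into the confounder model.  Over the HC sample the returned z-scores
    have mean 0 and SD 1 (ddof=1).
    """
    hc_mask = np.asarray(hc_mask, dtype=bool)
    if hc_mask.sum() < min_hc:
        raise ValueError(f"need at least {min_hc} HC subjects, got {int(hc_mask.sum())}")
    scaler = NuisanceZScorer(ddof=1)
    scaler.fit(values, covariates=covariates, reference_mask=hc_mask)
    z = scaler.transform(values, covariates=covariates)
    if np.asarray(values).ndim == 1:
        z = z.ravel()
    return AdjustedScores(
        z=z, scaler=scaler, hc_mean=scaler.resid_mean_, hc_sd=scaler.resid_sd_
    )


def _pooled_t(s1, q1, S, Q, n1, n2):
    """Pooled-variance two-sample t from group-1 sums; vectorized over axis 0."""
    m1 = s1 / n1
    m2 = (S - s1) / n2
    ss1 = q1 - s1 ** 2 / n1
    ss2 = (Q - q1) - (S - s1) ** 2 / n2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def _perm_indices(n, n1, n_perm, rng, exhaustive_if_small=True):
    """Group-1 index sets: exhaustive if few arrangements, else sampled."""
    total = comb(n, n1)
    if exhaustive_if_small and total <= EXHAUSTIVE_LIMIT:
        idx = np.array(list(combinations(range(n), n1)), dtype=int)
        return idx, True
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    return idx, False


def permutation_ttest(x, y, n_perm: int = 10_000, seed=None,
                      exhaustive_if_small: bool = True):
    """Two-sided permutation test with the pooled-variance t statistic.

    When the number of distinct group assignments is at most 20,000 the
    null is enumerated exhaustively and ``p = #{|t_perm| >= |t_obs|} / B``
    (the identity assignment guarantees p > 0); otherwise ``B = n_perm``
    random assignments are drawn and ``p = (#{|t_perm| >= |t_obs|} + 1) /
    (B + 1)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if not exhaustive_if_small and n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    pooled = np.concatenate([x, y])
    S, Q = pooled.sum(), (pooled ** 2).sum()
    t_obs = float(_pooled_t(x.sum(), (x ** 2).sum(), S, Q, n1, n2))
    rng = np.random.default_rng(seed)
    idx, exhaustive = _perm_indices(n1 + n2, n1, n_perm, rng, exhaustive_if_small)
    s1 = pooled[idx].sum(axis=1)
    q1 = (pooled[idx] ** 2).sum(axis=1)
    t_perm = _pooled_t(s1, q1, S, Q, n1, n2)
    hits = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    if exhaustive:
        p = hits / idx.shape[0]
    else:
        p = (hits + 1) / (idx.shape[0] + 1)
    return t_obs, float(p)


def nodal_comparison(values, groups, n_perm: int = 10_000, q: float = 0.05,
                     seed=None, effect_sizes: bool = True) -> pd.DataFrame:
    """Per-node permutation t-tests with Benjamini-Hochberg FDR control.

    ``values`` is subjects x nodes (already confounder-adjusted); ``groups``
    is a binary label vector.  The same permutation set is shared across
    nodes (standard practice; nodes are tested marginally).  BH is applied
    across the full set of nodes at level ``q``.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    g1 = groups == labels[0]
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    order = np.concatenate([np.where(g1)[0], np.where(~g1)[0]])
    V = X[order]  # group 1 rows first
    S, Q = V.sum(axis=0), (V ** 2).sum(axis=0)
    t_obs = _pooled_t(V[:n1].sum(axis=0), (V[:n1] ** 2).sum(axis=0), S, Q, n1, n2)

    rng = np.random.default_rng(seed)
    idx, exhaustive = _perm_indices(n1 + n2, n1, n_perm, rng)
    B = idx.shape[0]
    sel = np.zeros((B, n1 + n2))
    sel[np.arange(B)[:, None], idx] = 1.0
    s1 = sel @ V
    q1 = sel @ (V ** 2)
    t_perm = _pooled_t(s1, q1, S, Q, n1, n2)
    hits = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    p = hits / B if exhaustive else (hits + 1) / (B + 1)

    reject, p_bh, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    out = pd.DataFrame({"t": t_obs, "p": p, "p_bh": p_bh, "significant": reject})
    if effect_sizes:
        gvals = [
            _hedges_g_value(X[g1, j], X[~g1, j]) for j in range(X.shape[1])
        ]
        out["hedges_g"] = gvals
    return out


def _hedges_g_value(x, y):
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return np.nan
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return d * J


def hedges_g(x, y, n_boot: int = 5000, seed=None):
    """Bias-corrected standardized mean difference with a percentile
    bootstrap CI (per-group resampling, default 5000 resamples).

    ``g = d * J`` with pooled-SD Cohen's d (denominator n1+n2-2) and the
    small-sample correction ``J = 1 - 3 / (4(n1+n2) - 9)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    g = _hedges_g_value(x, y)
    if np.isnan(g):
        raise ValueError("zero pooled SD: effect size undefined")
    if n_boot <= 0:
        return float(g), (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    bx = x[rng.integers(0, x.size, size=(n_boot, x.size))]
    by = y[rng.integers(0, y.size, size=(n_boot, y.size))]
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * bx.var(axis=1, ddof=1) + (n2 - 1) * by.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gb = (bx.mean(axis=1) - by.mean(axis=1)) / np.sqrt(sp2) * J
    gb = gb[np.isfinite(gb)]
    lo, hi = np.percentile(gb, [2.5, 97.5])
    return float(g), (float(lo), float(hi))


def anova_tukey(values, group_labels):
    """One-way fixed-effects ANOVA with Tukey HSD post hoc comparisons.

    Returns ``(F, p, pairwise)`` where ``pairwise`` is a DataFrame with one
    row per group pair and Tukey-adjusted p-values (studentized range).
    """
    values = np.asarray(values, dtype=float).ravel()
    group_labels = np.asarray(group_labels)
    names = [str(g) for g in pd.unique(group_labels)]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for name in names:
        grp = values[group_labels.astype(str) == name]
        if grp.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        samples.append(grp)
    F, p = sps.f_oneway(*samples)
    if not np.isfinite(F):  # all groups identical -> zero between+within variance
        F, p = 0.0, 1.0
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_diff": samples[i].mean() - samples[j].mean(),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return float(F), float(p), pd.DataFrame(rows)


def dichotomize_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Clinical dichotomies: EDSS >= 4 (high disability, cutoff inclusive)
    and SDMT z < -1.5 (impaired information processing speed, strict).

    Subjects missing the relevant score get NA in that column and are
    excluded from the corresponding comparison (counts logged).
    """
    out = pd.DataFrame(index=records.index)
    edss = pd.to_numeric(records["edss"], errors="coerce")
    sdmt = pd.to_numeric(records["sdmt_z"], errors="coerce")
    out["high_disability"] = pd.array(
        np.where(edss.isna(), pd.NA, edss >= 4.0), dtype="boolean"
    )
    out["ips_impaired"] = pd.array(
        np.where(sdmt.isna(), pd.NA, sdmt < -1.5), dtype="boolean"
    )
    n_edss = int(edss.isna().sum())
    n_sdmt = int(sdmt.isna().sum())
    if n_edss or n_sdmt:
        logger.info(
            "dichotomize_clinical: excluded %d subject(s) without EDSS, "
            "%d without SDMT", n_edss, n_sdmt,
        )
    return out
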