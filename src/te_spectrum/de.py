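"""Negative-binomial pairwise differential expression.

The engine is shared by gene-level and TE-family-level testing.  For a
contrast (A, B) it

1. normalizes counts by median-of-ratios size factors,
2. estimates a per-feature NB dispersion by method of moments from the
   pooled within-group variance, shrinks it 50/50 toward a trended
   mean-dispersion fit ``a0 + a1 / mean``,
3. performs a Wald test on the log2 fold change with a t reference
   distribution on the within-group residual degrees of freedom, and
4. adjusts p-values with Benjamini-Hochberg across features.

A t rather than normal reference is used because with the small replicate
numbers typical of these designs (2-3 per condition) the moment dispersion
estimate is noisy and a normal reference is anti-conservative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import DesignTable

log = logging.getLogger(__name__)

_LN2 = np.log(2.0)
_MIN_DISP = 1e-8
_MAX_DISP = 20.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x samples input).

    Each sample's factor is the median over features of the ratio of its
    count to the feature's geometric mean, using only features with
    strictly positive counts in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(mat).mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        log.warning("no feature positive in all samples; size factors set to 1")
        return pd.Series(1.0, index=counts.columns)
    ratios = np.log(mat[usable]) - loggeo[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def estimate_dispersions(
    normed: pd.DataFrame,
    groups: list[list[str]],
    inv_sf: pd.Series,
    common_dispersion: float = 0.1,
) -> np.ndarray:
    """Per-feature NB dispersion: method-of-moments pooled within groups,
    shrunk 50/50 toward a trended ``a0 + a1/mean`` fit.

    The moment estimator subtracts the Poisson (shot-noise) term, corrected
    for size-factor scaling: on normalized counts ``K/s`` the technical
    variance is ``mean * E[1/s]`` within the group.
    """
    n_feat = normed.shape[0]
    total_df = sum(max(len(g) - 1, 0) for g in groups)
    if total_df < 1:
        log.warning(
            "fewer than 2 samples per condition; using common dispersion %.3g",
            common_dispersion,
        )
        return np.full(n_feat, common_dispersion)

    ss = np.zeros(n_feat)
    shot = np.zeros(n_feat)
    grand = np.zeros(n_feat)
    n_samples = 0
    for g in groups:
        sub = normed[g].to_numpy()
        m = sub.mean(axis=1)
        grand += m * len(g)
        n_samples += len(g)
        if len(g) >= 2:
            ss += sub.var(axis=1, ddof=1) * (len(g) - 1)
            shot += m * float(inv_sf[g].mean()) * (len(g) - 1)
    grand /= n_samples
    s2 = ss / total_df
    shot /= total_df

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - shot) / grand**2
    raw[~np.isfinite(raw)] = np.nan

    trend = _fit_dispersion_trend(grand, raw)
    shrunk = 0.5 * np.clip(np.nan_to_num(raw, nan=0.0), 0.0, _MAX_DISP) + 0.5 * trend
    return np.clip(shrunk, _MIN_DISP, _MAX_DISP)


def _fit_dispersion_trend(mean: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Least-squares fit of raw dispersions to ``a0 + a1/mean``."""
    ok = np.isfinite(raw) & (mean > 0)
    if ok.sum() < 10:
        fallback = float(np.nanmedian(np.clip(raw, 0, _MAX_DISP))) if ok.any() else 0.1
        return np.full_like(mean, max(fallback, _MIN_DISP))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(x, raw[ok], rcond=None)
    with np.errstate(divide="ignore"):
        pred = coef[0] + coef[1] / np.where(mean > 0, mean, np.nan)
    pred = np.nan_to_num(pred, nan=_MIN_DISP)
    return np.clip(pred, _MIN_DISP, _MAX_DISP)


def differential_expression(
    counts: pd.DataFrame,
    design: DesignTable,
    contrast: tuple[str, str],
    alpha: float = 0.01,
    lfc_threshold: float = 2.0,
    pseudocount: float = 0.5,
    size_factors_override: pd.Series | None = None,
    common_dispersion: float = 0.1,
) -> pd.DataFrame:
    """NB Wald test of condition A vs condition B.

    Parameters
    ----------
    counts
        Raw counts, features x samples; columns must cover both conditions'
        samples.
    size_factors_override
        Pre-computed size factors (e.g. from gene counts when testing TE
        families, so repeat activation cannot distort normalization).

    Returns
    -------
    DataFrame with one row per feature: ``feature_id, condition_A,
    condition_B, mean_A, mean_B, log2fc, se, p, padj, significant``.
    """
    cond_a, cond_b = contrast
    samples_a = [s for s in design.samples_of(cond_a) if s in counts.columns]
    samples_b = [s for s in design.samples_of(cond_b) if s in counts.columns]
    if not samples_a or not samples_b:
        raise ValueError(f"contrast {contrast}: condition with zero samples in matrix")

    used = samples_a + samples_b
    sub = counts[used]
    if size_factors_override is not None:
        sf = size_factors_override[used]
    else:
        sf = size_factors(sub)
    if (sf <= 0).any():
        raise ValueError("non-positive size factor; check library sizes")
    inv_sf = 1.0 / sf
    normed = sub / sf

    disp = estimate_dispersions(
        normed, [samples_a, samples_b], inv_sf, common_dispersion=common_dispersion
    )

    mean_a = normed[samples_a].mean(axis=1).to_numpy()
    mean_b = normed[samples_b].mean(axis=1).to_numpy()
    n_a, n_b = len(samples_a), len(samples_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    # delta-method variance of log2(group mean + pc); shot noise term uses
    # the group-average 1/s of the raw-scale Poisson variance
    var_a = (mean_a * float(inv_sf[samples_a].mean()) + disp * mean_a**2) / n_a
    var_b = (mean_b * float(inv_sf[samples_b].mean()) + disp * mean_b**2) / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            var_a / ((mean_a + pseudocount) ** 2) + var_b / ((mean_b + pseudocount) ** 2)
        ) / _LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~np.isfinite(z)] = 1.0  # all-zero or degenerate features are not evidence
    p = np.clip(p, 0.0, 1.0)

    padj = multipletests(p, method="fdr_bh")[1]
    significant = (np.abs(lfc) > lfc_threshold) & (padj < alpha)

    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "condition_A": cond_a,
            "condition_B": cond_b,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": lfc,
            "se": se,
            "p": p,
            "padj": padj,
            "significant": significant,
        }
    ).reset_index(drop=True)


def all_pairs_de(
    counts: pd.DataFrame,
    design: DesignTable,
    alpha: float = 0.01,
    lfc_threshold: float = 2.0,
    **kwargs,
) -> tuple[pd.DataFrame, set[str]]:
    """Run every pairwise contrast; return the stacked table and the union
    set of features significant in at least one pair (BH within contrast)."""
    conditions = design.conditions
    tables = []
    union: set[str] = set()
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            res = differential_expression(
                counts, design, (a, b), alpha=alpha, lfc_threshold=lfc_threshold, **kwargs
            )
            tables.append(res)
            union |= set(res.loc[res["significant"], "feature_id"])
    stacked = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return stacked, union
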