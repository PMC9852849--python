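"""Stress ratios, significance-annotated correlations and PCA of trait variation.

Cold/control ratios (trait_cold / trait_control, on genotype entry means)
put traits with very different units on a common dimensionless response
scale; the correlation matrix among ratios and the PCA of the
genotype x trait table summarise which physiological responses travel
together under cold stress.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .variance import entry_means

__all__ = [
    "stress_ratios",
    "CorrelationResult",
    "correlation_with_stars",
    "PCAResult",
    "pca_traits",
    "stars_for_p",
]

log = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    """Map a p-value to its significance annotation (*** / ** / * / '')."""
    if not np.isfinite(p):
        return ""
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return ""


def stress_ratios(panel: pd.DataFrame, epsilon: float = 1e-9) -> pd.DataFrame:
    """Genotype x trait table of cold/control entry-mean ratios.

    Replicates (and trials) are averaged within treatment first.  A ratio
    whose control mean is <= ``epsilon`` is flagged missing (NaN) with a
    logged warning rather than raising.
    """
    cold = entry_means(panel, "cold")
    control = entry_means(panel, "control")
    common = [t for t in cold.columns if t in control.columns]
    cold, control = cold[common], control[common].reindex(cold.index)
    bad = control <= epsilon
    if bad.any().any():
        n_bad = int(bad.to_numpy().sum())
        log.warning("%d cold/control ratios dropped: control mean <= %.3g", n_bad, epsilon)
    ratios = cold / control.where(~bad)
    ratios.columns = [f"{t}_ratio" for t in common]
    return ratios


@dataclass
class CorrelationResult:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame
    long: pd.DataFrame  # pairwise rows: trait_x, trait_y, n, r, p, stars, p_holm


def correlation_with_stars(table: pd.DataFrame, min_n: int = 3) -> CorrelationResult:
    """Pairwise-complete Pearson correlations with significance stars.

    p-values come from the exact t transform t = r sqrt((n-2)/(1-r^2))
    with n-2 degrees of freedom (two-sided).  Constant columns and pairs
    with fewer than ``min_n`` complete rows are reported missing.  A
    Holm-adjusted p-value column is included in the long-format output.
    """
    cols = list(table.columns)
    k = len(cols)
    r_m = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p_m = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    n_m = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    rows = []
    for ta, tb in combinations(cols, 2):
        pair = table[[ta, tb]].dropna()
        n = len(pair)
        n_m.loc[ta, tb] = n_m.loc[tb, ta] = n
        if n < min_n or pair[ta].nunique() < 2 or pair[tb].nunique() < 2:
            r_val, p_val = np.nan, np.nan
        else:
            r_val, p_val = stats.pearsonr(pair[ta], pair[tb])
            r_val, p_val = float(r_val), float(p_val)
        r_m.loc[ta, tb] = r_m.loc[tb, ta] = r_val
        p_m.loc[ta, tb] = p_m.loc[tb, ta] = p_val
        rows.append({"trait_x": ta, "trait_y": tb, "n": n, "r": r_val, "p": p_val})
    long = pd.DataFrame(rows)
    if len(long):
        valid = long["p"].notna()
        p_holm = np.full(len(long), np.nan)
        if valid.any():
            p_holm[valid.to_numpy()] = multipletests(long.loc[valid, "p"], method="holm")[1]
        long["p_holm"] = p_holm
        long["stars"] = long["p"].map(stars_for_p)
    stars = p_m.map(stars_for_p)
    for c in cols:
        stars.loc[c, c] = ""
    return CorrelationResult(traits=cols, r=r_m, p=p_m, stars=stars, n=n_m, long=long)


@dataclass
class PCAResult:
    component_variance_percent: np.ndarray
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame   # trait x component
    scores: pd.DataFrame     # genotype x component


def pca_traits(table: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of a genotype x trait table.

    Columns are centred and (by default) scaled to unit variance, so the
    decomposition acts on the correlation matrix — appropriate when traits
    span wildly different scales.  Rows with any missing value are dropped
    (listwise).  Component signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    data = table.dropna()
    if data.shape[0] < 3:
        raise ValueError("PCA needs at least 3 complete genotype rows")
    if data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 traits")
    X = data.to_numpy(float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            const = [c for c, s in zip(data.columns, sd) if s == 0]
            raise ValueError(f"constant traits cannot be standardized: {const}")
        X = X / sd

    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # trait x component

    # deterministic orientation: dominant loading of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    var_pct = 100.0 * pca.explained_variance_ratio_
    pcs = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        component_variance_percent=var_pct,
        cumulative_percent=np.cumsum(var_pct),
        loadings=pd.DataFrame(loadings, index=data.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=data.index, columns=pcs),
    )
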