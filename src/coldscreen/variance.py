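"""Variance components, heritability and index matrices from replicated panels.

All estimators are the classical balanced one-way random-effects ANOVA
moment estimators: with g genotypes and r replicates per genotype,

    MSG = r * sum_g (ybar_g - ybar)^2 / (g - 1)
    MSE = sum_{g,j} (y_gj - ybar_g)^2 / (g (r - 1))
    sigma2_g = max(0, (MSG - MSE) / r)          E[MSG] = r sigma2_g + sigma2_e

Heritability is reported on the entry-mean (genotype-mean) basis by
default, H2 = sigma2_g / (sigma2_g + sigma2_e / r), the basis on which a
selection index over genotype means operates.  The genotypic covariance
between two traits is the analysis-of-cross-products mirror of the same
decomposition, and the phenotypic matrix P is the sample covariance of
genotype entry means, so the identity P = G + E/r holds exactly on
balanced data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitStats",
    "IndexMatrices",
    "entry_means",
    "descriptive_stats",
    "anova_one_way",
    "heritability",
    "genetic_advance",
    "genotypic_covariance",
    "build_index_matrices",
    "trait_stats",
    "trait_stats_table",
]

#: selection intensity for the top 5% of a normal population
DEFAULT_SELECTION_INTENSITY = 2.06

#: condition number above which P is flagged unusable for the index
CONDITION_THRESHOLD = 1e8


@dataclass
class TraitStats:
    """Descriptive statistics and variance components for one trait/treatment."""

    trait: str
    treatment: str
    n_genotypes: int
    n_reps_effective: int
    min: float
    max: float
    mean: float
    sd: float
    MSG: float
    MSE: float
    F: float
    p_value: float
    sigma2_g: float
    sigma2_e: float
    H2_percent: float
    GA: float
    CVb_percent: float
    CVp_percent: float


@dataclass
class IndexMatrices:
    """Phenotypic (entry-mean) and genotypic covariance matrices over index traits."""

    traits: list[str]
    P: np.ndarray
    G: np.ndarray
    r: int
    condition_number: float = np.nan
    ill_conditioned: bool = False

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.P.shape != (len(self.traits),) * 2 or self.G.shape != self.P.shape:
            raise ValueError("P and G must be square with dimension len(traits)")


def _replicate_matrix(panel: pd.DataFrame, trait: str, treatment: str,
                      trials: str = "average") -> pd.DataFrame:
    """Genotype x replicate-unit wide matrix for one trait under one treatment.

    trials="average": replicates are averaged within each trial and the trial
    means become the replicate units (one column per trial).  trials="pool":
    every trial x replicate observation is its own unit.  With a single trial
    the two coincide... except that "average" with one trial would collapse
    to a single column, so a lone trial always keeps its raw replicates.
    """
    sub = panel[(panel["trait"] == trait) & (panel["treatment"] == treatment)]
    if sub.empty:
        raise KeyError(f"trait {trait!r} absent under treatment {treatment!r}")
    n_trials = sub["trial"].nunique()
    if trials == "average" and n_trials > 1:
        unit = sub.groupby(["genotype", "trial"], observed=True)["value"].mean().unstack("trial")
    else:
        sub = sub.assign(unit=sub["trial"].astype(str) + "/" + sub["replicate"].astype(str))
        unit = sub.pivot_table(index="genotype", columns="unit", values="value",
                               aggfunc="mean", observed=True)
    if unit.isna().any().any():
        raise ValueError(
            f"unbalanced design for trait {trait!r} / {treatment!r}: "
            "some genotype cells are missing replicate units"
        )
    return unit


def entry_means(panel: pd.DataFrame, treatment: str,
                traits: list[str] | None = None) -> pd.DataFrame:
    """Genotype x trait matrix of entry means (replicates and trials averaged)."""
    sub = panel[panel["treatment"] == treatment]
    if traits is not None:
        sub = sub[sub["trait"].isin(traits)]
    wide = sub.groupby(["genotype", "trait"], observed=True)["value"].mean().unstack("trait")
    if traits is not None:
        missing = [t for t in traits if t not in wide.columns]
        if missing:
            raise KeyError(f"traits absent under {treatment!r}: {missing}")
        wide = wide[traits]
    return wide


def descriptive_stats(panel: pd.DataFrame, trait: str, treatment: str) -> dict:
    """min / max / mean / sd over genotype entry means (sample sd, n-1)."""
    m = entry_means(panel, treatment, [trait])[trait]
    return {
        "min": float(m.min()),
        "max": float(m.max()),
        "mean": float(m.mean()),
        "sd": float(m.std(ddof=1)) if len(m) > 1 else 0.0,
    }


def anova_one_way(panel: pd.DataFrame, trait: str, treatment: str,
                  trials: str = "average") -> dict:
    """Balanced one-way random-effects ANOVA with genotype as the factor.

    Returns MSG, MSE, F = MSG/MSE and the p-value from F(g-1, g(r-1)).
    A panel with zero variance yields F = NaN with a warning.
    """
    unit = _replicate_matrix(panel, trait, treatment, trials)
    y = unit.to_numpy(float)
    g, r = y.shape
    if g < 2:
        raise ValueError("ANOVA needs at least 2 genotypes")
    if r < 2:
        raise ValueError("ANOVA needs at least 2 replicate units (MSE undefined)")
    gm = y.mean()
    row_means = y.mean(axis=1)
    ss_between = r * float(((row_means - gm) ** 2).sum())
    ss_within = float(((y - row_means[:, None]) ** 2).sum())
    msg = ss_between / (g - 1)
    mse = ss_within / (g * (r - 1))
    if mse == 0.0 and msg == 0.0:
        warnings.warn(f"all observations identical for {trait}/{treatment}; F undefined")
        f_val, p = np.nan, np.nan
    elif mse == 0.0:
        f_val, p = np.inf, 0.0
    else:
        f_val = msg / mse
        p = float(stats.f.sf(f_val, g - 1, g * (r - 1)))
    return {"MSG": msg, "MSE": mse, "F": f_val, "p_value": p,
            "n_genotypes": g, "r": r}


def heritability(MSG: float, MSE: float, r: int, basis: str = "entry-mean") -> float:
    """Broad-sense heritability in percent, floored into [0, 100].

    entry-mean basis: H2 = sigma2_g / (sigma2_g + MSE/r); plot basis:
    H2 = sigma2_g / (sigma2_g + MSE); sigma2_g = max(0, (MSG - MSE)/r).
    """
    if r < 2:
        raise ValueError("heritability needs r >= 2")
    if MSE < 0 or MSG < 0:
        raise ValueError("mean squares must be non-negative")
    sigma2_g = max(0.0, (MSG - MSE) / r)
    if sigma2_g == 0.0:
        return 0.0
    denom = sigma2_g + (MSE / r if basis == "entry-mean" else MSE)
    if denom == 0.0:
        return 100.0
    return 100.0 * sigma2_g / denom


def genetic_advance(H2_percent: float, sigma_p_entrymean: float,
                    k: float = DEFAULT_SELECTION_INTENSITY) -> float:
    """Expected gain from selecting the top fraction: GA = k * H2 * sigma_p.

    sigma_p is the phenotypic standard deviation among entry means,
    sqrt(sigma2_g + MSE/r); k = 2.06 corresponds to 5% selection.
    """
    if k <= 0:
        raise ValueError("selection intensity k must be positive")
    if sigma_p_entrymean < 0:
        raise ValueError("sigma_p must be non-negative")
    return k * (H2_percent / 100.0) * sigma_p_entrymean


def genotypic_covariance(panel: pd.DataFrame, trait_x: str, trait_y: str,
                         treatment: str, trials: str = "average") -> float:
    """Genotypic covariance from the analysis of cross-products.

    cov_g = (MPG - MPE) / r with MPG/MPE the genotype and error mean
    cross-products; the diagonal case reproduces sigma2_g (floored at 0).
    """
    ux = _replicate_matrix(panel, trait_x, treatment, trials)
    uy = _replicate_matrix(panel, trait_y, treatment, trials)
    if not ux.index.equals(uy.index) or ux.shape != uy.shape:
        uy = uy.reindex(index=ux.index)
        if uy.isna().any().any() or ux.shape != uy.shape:
            raise ValueError(
                f"traits {trait_x!r}/{trait_y!r} measured on different replicate sets"
            )
    x, y = ux.to_numpy(float), uy.to_numpy(float)
    g, r = x.shape
    xm, ym = x.mean(axis=1), y.mean(axis=1)
    mpg = r * float(((xm - xm.mean()) * (ym - ym.mean())).sum()) / (g - 1)
    mpe = float(((x - xm[:, None]) * (y - ym[:, None])).sum()) / (g * (r - 1))
    cov_g = (mpg - mpe) / r
    if trait_x == trait_y:
        cov_g = max(0.0, cov_g)
    return cov_g


DEFAULT_INDEX_TRAITS = ["LI", "qL", "FvFm"]


def build_index_matrices(panel: pd.DataFrame, traits: list[str] | None = None,
                         treatment: str = "cold",
                         trials: str = "average") -> IndexMatrices:
    """Assemble P (entry-mean phenotypic) and G (genotypic) covariance matrices.

    P is the sample covariance matrix of genotype entry means; G is built
    from pairwise analysis-of-cross-products estimates with the diagonal
    floored at zero.  When P's condition number exceeds
    ``CONDITION_THRESHOLD`` the result is flagged and downstream index
    computation refuses it.
    """
    traits = list(traits) if traits is not None else list(DEFAULT_INDEX_TRAITS)
    k = len(traits)
    units = {t: _replicate_matrix(panel, t, treatment, trials) for t in traits}
    r = units[traits[0]].shape[1]
    means = np.column_stack([units[t].mean(axis=1).to_numpy() for t in traits])
    P = np.cov(means, rowvar=False, ddof=1).reshape(k, k)

    G = np.empty((k, k))
    for i, ti in enumerate(traits):
        for j in range(i, k):
            cov = genotypic_covariance(panel, ti, traits[j], treatment, trials)
            G[i, j] = G[j, i] = cov
    G = (G + G.T) / 2.0

    cond = float(np.linalg.cond(P)) if np.isfinite(P).all() else np.inf
    flagged = (not np.isfinite(cond)) or cond > CONDITION_THRESHOLD
    if flagged:
        warnings.warn(
            f"phenotypic matrix is numerically singular (condition number {cond:.3g}); "
            "index computation will refuse it"
        )
    return IndexMatrices(traits=traits, P=P, G=G, r=r,
                         condition_number=cond, ill_conditioned=flagged)


def trait_stats(panel: pd.DataFrame, trait: str, treatment: str,
                k: float = DEFAULT_SELECTION_INTENSITY, basis: str = "entry-mean",
                trials: str = "average") -> TraitStats:
    """Full per-trait summary: descriptives, ANOVA, H2, GA, CVs."""
    desc = descriptive_stats(panel, trait, treatment)
    av = anova_one_way(panel, trait, treatment, trials)
    msg, mse, r = av["MSG"], av["MSE"], av["r"]
    sigma2_g = max(0.0, (msg - mse) / r)
    h2 = heritability(msg, mse, r, basis)
    sigma_p = np.sqrt(sigma2_g + mse / r)
    ga = genetic_advance(h2, sigma_p, k)
    mean = desc["mean"]
    cvb = 100.0 * np.sqrt(sigma2_g) / mean if mean != 0 else np.nan
    cvp = 100.0 * sigma_p / mean if mean != 0 else np.nan
    return TraitStats(
        trait=trait, treatment=treatment,
        n_genotypes=av["n_genotypes"], n_reps_effective=r,
        min=desc["min"], max=desc["max"], mean=mean, sd=desc["sd"],
        MSG=msg, MSE=mse, F=av["F"], p_value=av["p_value"],
        sigma2_g=sigma2_g, sigma2_e=mse, H2_percent=h2, GA=ga,
        CVb_percent=cvb, CVp_percent=cvp,
    )


def trait_stats_table(panel: pd.DataFrame, treatment: str = "cold",
                      traits: list[str] | None = None,
                      **kwargs) -> pd.DataFrame:
    """One TraitStats row per trait, as a DataFrame."""
    if traits is None:
        traits = sorted(panel.loc[panel["treatment"] == treatment, "trait"].unique())
    rows = [vars(trait_stats(panel, t, treatment, **kwargs)) for t in traits]
    return pd.DataFrame(rows)
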