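"""Smith-Hazel selection index: coefficients, CTI scores, ranking, categories.

The index weights solve P b = G a, where P and G are the phenotypic and
genotypic covariance matrices over the index traits and a the economic
weights (all ones by default).  The cold tolerance index of a genotype is
the plain dot product CTI = b1 X1 + b2 X2 + b3 X3 over its index-trait
entry means under cold; low CTI = tolerant.  Genotypes are ranked
ascending and binned into the five standard tolerance classes
T / MT / MS / S / SS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .variance import CONDITION_THRESHOLD, IndexMatrices, entry_means

__all__ = [
    "IndexCoefficients",
    "IndexError_",
    "smith_hazel_coefficients",
    "compute_cti",
    "rank_and_categorize",
    "cti_table",
    "CATEGORIES",
]

CATEGORIES = ("T", "MT", "MS", "S", "SS")

#: maximum allowed |P b - G a| after the solve
SOLVE_RESIDUAL_TOL = 1e-8


class IndexError_(ValueError):
    """Raised when index coefficients cannot be computed."""


@dataclass
class IndexCoefficients:
    traits: list[str]
    b: np.ndarray
    a: np.ndarray
    solve_residual: float = 0.0

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if not (len(self.traits) == self.b.size == self.a.size):
            raise ValueError("traits, b and a must have equal length")


def smith_hazel_coefficients(M: IndexMatrices, a=None,
                             residual_tol: float = SOLVE_RESIDUAL_TOL) -> IndexCoefficients:
    """Solve P b = G a for the index weight vector b.

    The system is solved directly (LU with partial pivoting), never via an
    explicit inverse; the achieved residual max|P b - G a| is recorded and
    must fall below ``residual_tol``.
    """
    k = len(M.traits)
    a = np.ones(k) if a is None else np.asarray(a, dtype=float)
    if a.size != k:
        raise IndexError_(f"economic weights have length {a.size}, expected {k}")
    if M.ill_conditioned:
        pair = _most_collinear_pair(M)
        raise IndexError_(
            f"phenotypic matrix is singular or ill-conditioned "
            f"(condition number {M.condition_number:.3g}); "
            f"most collinear trait pair: {pair}"
        )
    rhs = M.G @ a
    cond = np.linalg.cond(M.P)
    if not np.isfinite(cond) or cond > CONDITION_THRESHOLD:
        pair = _most_collinear_pair(M)
        raise IndexError_(
            f"phenotypic matrix is singular or ill-conditioned "
            f"(condition number {cond:.3g}); most collinear trait pair: {pair}"
        )
    b = linalg.solve(M.P, rhs, assume_a="sym")
    residual = float(np.max(np.abs(M.P @ b - rhs)))
    if residual > residual_tol:
        raise IndexError_(f"solve residual {residual:.3g} exceeds tolerance {residual_tol:.3g}")
    return IndexCoefficients(traits=list(M.traits), b=b, a=a, solve_residual=residual)


def _most_collinear_pair(M: IndexMatrices) -> tuple[str, str]:
    """Trait pair with the highest absolute phenotypic correlation."""
    d = np.sqrt(np.clip(np.diag(M.P), 1e-300, None))
    corr = M.P / np.outer(d, d)
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    return (M.traits[i], M.traits[j])


def compute_cti(coeffs: IndexCoefficients, X, standardize: bool = False) -> np.ndarray | float:
    """CTI = sum_i b_i X_i, an exact dot product.

    ``X`` is a vector in the coefficients' trait order, or a DataFrame /
    2-D array of per-genotype rows; missing values raise, naming the
    offending genotype and trait.  With ``standardize`` (DataFrame input
    only) trait columns are z-scored across genotypes before weighting.
    """
    if standardize:
        if not isinstance(X, pd.DataFrame):
            raise ValueError("standardize requires a per-genotype DataFrame")
        vals = X[coeffs.traits]
        X = (vals - vals.mean()) / vals.std(ddof=1)
    if isinstance(X, pd.DataFrame):
        missing_cols = [t for t in coeffs.traits if t not in X.columns]
        if missing_cols:
            raise KeyError(f"index traits missing from table: {missing_cols}")
        vals = X[coeffs.traits]
        if vals.isna().any().any():
            bad = vals[vals.isna().any(axis=1)]
            culprit = [(idx, [t for t in coeffs.traits if pd.isna(row[t])])
                       for idx, row in bad.head(5).iterrows()]
            raise ValueError(f"missing index-trait values, e.g. {culprit}")
        return pd.Series(vals.to_numpy(float) @ coeffs.b, index=X.index, name="CTI")
    arr = np.asarray(X, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("X contains non-finite values")
    if arr.ndim == 1:
        if arr.size != coeffs.b.size:
            raise ValueError(f"X has length {arr.size}, expected {coeffs.b.size}")
        return float(arr @ coeffs.b)
    return arr @ coeffs.b


def rank_and_categorize(scores: pd.Series, scheme: str = "equal-width",
                        breakpoints=None) -> pd.DataFrame:
    """Rank genotypes ascending by CTI and assign tolerance categories.

    Rank 1 = lowest CTI = most tolerant; ties broken by genotype id
    (lexicographic), so the result is deterministic.  Category schemes:

    - "equal-width" (default): five equal-width bins over [min, max];
    - "quantile": five equal-count quantile bins;
    - "manual": four ascending interior ``breakpoints`` delimiting T..SS.

    If every score is identical all genotypes land in the middle class MS
    with a warning.
    """
    if not np.isfinite(scores.to_numpy(float)).all():
        raise ValueError("CTI scores must be finite")
    scores = scores.astype(float)
    # mergesort is stable; pre-sorting by genotype id makes ties resolve by id
    order = (pd.DataFrame({"genotype": scores.index.astype(str), "CTI": scores.to_numpy()})
             .sort_values("genotype", kind="mergesort")
             .sort_values("CTI", kind="mergesort")
             .reset_index(drop=True))
    order["rank"] = np.arange(1, len(order) + 1)

    lo, hi = order["CTI"].min(), order["CTI"].max()
    if lo == hi:
        warnings.warn("all CTI scores identical; assigning every genotype to MS")
        order["category"] = "MS"
    elif scheme == "equal-width":
        edges = np.linspace(lo, hi, 6)
        idx = np.clip(np.searchsorted(edges, order["CTI"], side="right") - 1, 0, 4)
        order["category"] = [CATEGORIES[i] for i in idx]
    elif scheme == "quantile":
        cats = pd.qcut(order["CTI"], 5, labels=CATEGORIES, duplicates="drop")
        order["category"] = cats.astype(str)
    elif scheme == "manual":
        if breakpoints is None or len(breakpoints) != 4:
            raise ValueError("manual scheme needs 4 ascending breakpoints")
        bp = sorted(float(x) for x in breakpoints)
        idx = np.searchsorted(bp, order["CTI"], side="right")
        order["category"] = [CATEGORIES[i] for i in idx]
    else:
        raise ValueError(f"unknown categorization scheme {scheme!r}")
    order["category"] = pd.Categorical(order["category"], categories=list(CATEGORIES))
    return order


def cti_table(panel: pd.DataFrame, coeffs: IndexCoefficients,
              treatment: str = "cold", scheme: str = "equal-width",
              breakpoints=None) -> pd.DataFrame:
    """Score every genotype: index-trait entry means, CTI, rank, category.

    Columns: genotype, X1..Xk (entry means under ``treatment`` in the
    coefficients' trait order), CTI, rank, category.
    """
    X = entry_means(panel, treatment, coeffs.traits)
    scores = compute_cti(coeffs, X)
    table = rank_and_categorize(scores, scheme=scheme, breakpoints=breakpoints)
    xcols = X.rename(columns={t: f"X{i + 1}_{t}" for i, t in enumerate(coeffs.traits)})
    table = table.merge(xcols.reset_index(), on="genotype", how="left")
    cols = (["genotype"] + [c for c in table.columns if c.startswith("X")]
            + ["CTI", "rank", "category"])
    return table[cols]
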