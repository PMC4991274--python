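"""Phylogenetic generalized least squares.

Closed-form GLS with a tree-derived residual covariance: under Brownian
motion the residual covariance of species-level observations is
proportional to the shared-branch-length matrix C, so regression
coefficients are beta = (X' V^-1 X)^-1 X' V^-1 y with V = C.  The
module also provides phylogenetically corrected (optionally
biomass-weighted) group means, the tree-aware analogue of the
community-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve

from .phylo import PhyloCovariance, safe_cho_factor


@dataclass
class GlsFit:
    coefficients: dict[str, tuple[float, float]]  # term -> (estimate, SE)
    sigma2: float
    loglik: float
    correlation: str  # e.g. "brownian" or "lambda(0.5)"
    n_obs: int

    def coef(self, term: str) -> float:
        return self.coefficients[term][0]


def gls_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    V: np.ndarray | PhyloCovariance,
    term_names: Sequence[str] | None = None,
    correlation: str = "brownian",
) -> GlsFit:
    """Closed-form GLS: beta = (X'V^-1X)^-1 X'V^-1 y.

    sigma2 is the REML-style estimate resid'V^-1 resid / (n - p) and
    standard errors come from sigma2 (X'V^-1X)^-1; the reported
    log-likelihood is the ML Gaussian log-likelihood at beta-hat.
    Raises for singular X (V singularity is handled by the shared
    jittered Cholesky).
    """
    if isinstance(X, pd.DataFrame):
        term_names = term_names or list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, float)
    n, p = X.shape
    term_names = list(term_names or [f"x{i}" for i in range(p)])
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is singular")
    Vm = V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V, float)
    cf = safe_cho_factor(Vm)
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    resid = y - X @ beta
    quad = float(resid @ cho_solve(cf, resid))
    sigma2 = quad / (n - p) if n > p else 0.0
    cov = sigma2 * np.linalg.inv(XtViX) if n > p else np.zeros((p, p))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    logdet = 2.0 * np.sum(np.log(np.diagonal(cf[0])))
    s2_ml = quad / n
    loglik = (
        -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
        if s2_ml > 0
        else np.inf
    )
    return GlsFit(
        coefficients={t: (float(b), float(s)) for t, b, s in zip(term_names, beta, se)},
        sigma2=sigma2,
        loglik=float(loglik),
        correlation=correlation,
        n_obs=n,
    )


def pgls_species_mean(
    trait: np.ndarray,
    C: PhyloCovariance | np.ndarray,
    group_indicators: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Phylogenetically corrected per-group means of a species trait.

    GLS of the trait on the group indicator columns (cell-means coding,
    V = C, Brownian); groups must partition the tips.  On a star tree
    the corrected means reduce to arithmetic group means.
    """
    names = list(group_indicators)
    cols = [np.asarray(group_indicators[g], float) for g in names]
    total = np.sum(cols, axis=0)
    if not np.allclose(total, 1.0):
        raise ValueError("group indicators must partition the tips")
    for g, c in zip(names, cols):
        if c.sum() == 0:
            raise ValueError(f"empty group: {g!r}")
    X = np.column_stack(cols)
    fit = gls_fit(X, trait, C, term_names=names)
    rows = [
        {"group": g, "corrected_mean": fit.coefficients[g][0], "se": fit.coefficients[g][1]}
        for g in names
    ]
    return pd.DataFrame(rows)


def pgls_weighted_mean(
    trait: np.ndarray,
    C: PhyloCovariance | np.ndarray,
    weights: np.ndarray,
) -> tuple[float, float]:
    """Biomass-weighted phylogenetic mean of a species trait.

    GLS intercept with V = D^-1/2 C D^-1/2, D = diag(w / mean(w)): a
    species with more biomass carries a proportionally smaller residual
    variance.  With C = I this is exactly the ordinary weighted mean;
    with equal weights it is the phylogenetic (GLS) mean.  Returns
    (estimate, SE).  This weighting is one documented interpretation of
    a "phylogenetic community-weighted mean"; the plain CWM remains the
    primary descriptive statistic.
    """
    w = np.asarray(weights, float)
    if (w <= 0).any():
        raise ValueError("weights must be positive (drop absent species first)")
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    scale = np.sqrt(w / w.mean())
    V = Cm / np.outer(scale, scale)
    fit = gls_fit(np.ones((len(w), 1)), trait, V, term_names=["mean"])
    return fit.coefficients["mean"]


def pgls_treatment_means(
    species_trait: Mapping[str, float],
    C: PhyloCovariance,
    biomass_by_treatment: pd.DataFrame,
) -> pd.DataFrame:
    """Corrected biomass-weighted trait means per nutrient treatment.

    ``biomass_by_treatment`` has species rows and treatment columns of
    summed biomass; species absent from a treatment are dropped for
    that column.
    """
    rows = []
    for treatment in biomass_by_treatment.columns:
        col = biomass_by_treatment[treatment]
        present = [sp for sp in col.index if col[sp] > 0]
        if not present:
            continue
        sub = C.subset(present)
        y = np.array([species_trait[sp] for sp in present])
        est, se = pgls_weighted_mean(y, sub, col[present].to_numpy(float))
        rows.append(
            {"treatment": treatment, "corrected_mean": est, "se": se, "n_species": len(present)}
        )
    return pd.DataFrame(rows)
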