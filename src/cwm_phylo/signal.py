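"""Phylogenetic signal statistics: Blomberg's K and Pagel's lambda.

K compares the observed ratio of trait variance to
phylogenetically-corrected variance against its Brownian-motion
expectation; K = 1 under Brownian motion on the given tree, K > 1 means
close relatives are even more similar than Brownian motion predicts.
Significance comes from a tip-shuffling permutation test on the
phylogenetically corrected mean squared error.

Pagel's lambda rescales the off-diagonal entries of the Brownian
covariance; it is estimated by maximum likelihood over [0, lambda_max]
where lambda_max keeps the rescaled matrix positive definite (values
slightly above 1 are admissible), with a likelihood-ratio test against
lambda = 0 (no signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_solve

from .phylo import PhyloCovariance, lambda_transform, lambda_upper_bound, safe_cho_factor

logger = logging.getLogger("cwm_phylo")


@dataclass
class SignalResult:
    k_stat: float
    k_pvalue: float
    lambda_hat: float
    lambda_loglik: float
    lambda_lr_pvalue: float


def _as_cov(C: PhyloCovariance | np.ndarray) -> np.ndarray:
    return C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)


def _phylo_mse(trait: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """(MSE0, MSE, a_hat): ordinary and C^-1-weighted mean squared error
    about the phylogenetically corrected mean a_hat."""
    n = trait.shape[0]
    cf = safe_cho_factor(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    a_hat = float(Ci1 @ trait) / float(Ci1 @ ones)
    dev = trait - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ cho_solve(cf, dev)) / (n - 1)
    return mse0, mse, a_hat


def blomberg_k(trait: np.ndarray, C: PhyloCovariance | np.ndarray) -> float:
    """Blomberg's K for a tip trait.

    K = (MSE0 / MSE) / [(tr(C) - n / (1' C^-1 1)) / (n - 1)], with the
    phylogenetic mean a_hat = (1' C^-1 y) / (1' C^-1 1).  Returns NaN
    (with a warning) for a constant trait, for which signal is
    undefined.
    """
    C = _as_cov(C)
    y = np.asarray(trait, float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips for Blomberg's K")
    if np.ptp(y) == 0:
        logger.warning("constant trait: Blomberg's K undefined")
        return float("nan")
    cf = safe_cho_factor(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    mse0, mse, _ = _phylo_mse(y, C)
    expected = (float(np.trace(C)) - n / float(ones @ Ci1)) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k_test(
    trait: np.ndarray,
    C: PhyloCovariance | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for phylogenetic signal via Blomberg's MSE.

    Tip values are shuffled across the tree; the p-value is the
    add-one-corrected fraction of permutations whose corrected MSE is
    at most the observed one (small MSE = strong signal).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    C = _as_cov(C)
    y = np.asarray(trait, float)
    _, mse_obs, _ = _phylo_mse(y, C)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, mse_perm, _ = _phylo_mse(rng.permutation(y), C)
        if mse_perm <= mse_obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _lambda_loglik(lam: float, y: np.ndarray, C: np.ndarray) -> float:
    """Profile log-likelihood of lambda (mean and sigma^2 profiled out)."""
    n = y.shape[0]
    Cl = lambda_transform(C, lam)
    try:
        cf = safe_cho_factor(Cl)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diagonal(cf[0])))
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    a_hat = float(Ci1 @ y) / float(Ci1 @ ones)
    dev = y - a_hat
    quad = float(dev @ cho_solve(cf, dev))
    if quad <= 0:
        return -np.inf
    s2 = quad / n
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagel_lambda_ml(
    trait: np.ndarray, C: PhyloCovariance | np.ndarray
) -> tuple[float, float, float]:
    """Maximum-likelihood Pagel's lambda with an LR test against zero.

    Returns (lambda_hat, log-likelihood at the optimum, LR p-value).
    The search interval is [0, lambda_max] where lambda_max (capped at
    1.2) keeps the transformed covariance positive definite.
    """
    C = _as_cov(C)
    y = np.asarray(trait, float)
    if y.shape[0] < 4:
        raise ValueError("need at least 4 tips to estimate lambda")
    if np.ptp(y) == 0:
        logger.warning("constant trait: lambda undefined")
        return float("nan"), float("nan"), float("nan")
    lam_max = lambda_upper_bound(C)
    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, y, C),
        bounds=(0.0, lam_max),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(f"lambda optimisation did not converge: {res}")
    candidates = [(float(res.x), -float(res.fun))]
    for lam in (0.0, min(1.0, lam_max), lam_max):
        candidates.append((lam, _lambda_loglik(lam, y, C)))
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = _lambda_loglik(0.0, y, C)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, 1))
    return lam_hat, ll_hat, p


def phylo_signal(
    trait: np.ndarray,
    C: PhyloCovariance | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Blomberg's K with permutation test plus ML Pagel's lambda."""
    k = blomberg_k(trait, C)
    if np.isnan(k):
        return SignalResult(k, float("nan"), float("nan"), float("nan"), float("nan"))
    kp = blomberg_k_test(trait, C, n_perm=n_perm, seed=seed)
    lam, ll, lrp = pagel_lambda_ml(trait, C)
    return SignalResult(k, kp, lam, ll, lrp)
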