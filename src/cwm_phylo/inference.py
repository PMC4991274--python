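"""Non-phylogenetic inference: factorial ANOVA and linear mixed models.

Sums of squares are sequential (Type I) in the stated formula order;
the experiment's design is unbalanced (12/11/16/25 subplots per
treatment cell), where sequential and marginal decompositions differ.
Mixed models are Gaussian random-intercept models estimated by
profiling the variance ratio out of the (restricted) likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .community import classify_treatment
from .records import SubplotRecord

logger = logging.getLogger("cwm_phylo")


@dataclass
class AnovaResult:
    term: str
    df_num: int
    df_den: int
    ss: float
    F: float  # NaN when the denominator mean square is 0 (degenerate)
    p: float

    def as_dict(self) -> dict:
        return dict(
            term=self.term, df_num=self.df_num, df_den=self.df_den,
            ss=self.ss, F=self.F, p=self.p,
        )


@dataclass
class LmmFit:
    """Random-intercept Gaussian mixed model fit."""

    fixed_effects: dict[str, tuple[float, float]]  # term -> (estimate, SE)
    variance_components: dict[str, float]  # grouping name -> sigma^2
    log_likelihood: float
    method: str  # "ML" or "REML"
    n_obs: int
    n_params: int  # fixed coefficients + variance components

    def coef(self, term: str) -> float:
        return self.fixed_effects[term][0]


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns linearly dependent on earlier ones (QR pivot test)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diagonal(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def sequential_anova(
    blocks: list[tuple[str, np.ndarray]],
    y: np.ndarray,
    df_den: int | None = None,
) -> list[AnovaResult]:
    """Type-I ANOVA over ordered design blocks.

    ``blocks`` is an ordered list of (term name, column matrix); the
    first block is typically the intercept (reported only through the
    residual).  Each term's SS is the drop in residual SS when its
    columns join the design.  F statistics use the residual mean square
    of the full model unless ``df_den``/caller overrides are applied
    afterwards.
    """
    X_parts: list[np.ndarray] = []
    rss_prev = float(y @ y)
    rows = []
    for name, cols in blocks:
        X_parts.append(np.atleast_2d(cols.T).T if cols.ndim == 1 else cols)
        X = np.hstack(X_parts)
        rss_cur = _rss(X, y)
        df_num = np.linalg.matrix_rank(X) - (
            np.linalg.matrix_rank(np.hstack(X_parts[:-1])) if len(X_parts) > 1 else 0
        )
        rows.append((name, df_num, rss_prev - rss_cur))
        rss_prev = rss_cur
    X_full = np.hstack(X_parts)
    n = y.shape[0]
    rank_full = np.linalg.matrix_rank(X_full)
    resid_df = n - rank_full if df_den is None else df_den
    resid_ss = rss_prev
    ms_resid = resid_ss / resid_df if resid_df > 0 else np.nan
    # guard against 0/0: a residual mean square at float-noise level
    # (relative to the response scale) is degenerate, not evidence
    scale = float(y @ y) / max(n, 1) + 1e-300
    if np.isfinite(ms_resid) and ms_resid <= 1e-12 * scale:
        ms_resid = 0.0
    out = []
    for name, df_num, ss in rows:
        if name == "intercept":
            continue
        if df_num == 0:
            out.append(AnovaResult(name, 0, resid_df, ss, np.nan, np.nan))
            continue
        if ms_resid is np.nan or ms_resid <= 0 or not np.isfinite(ms_resid):
            logger.warning("degenerate ANOVA: residual mean square is 0 for %s", name)
            out.append(AnovaResult(name, df_num, resid_df, ss, np.nan, np.nan))
            continue
        F = (ss / df_num) / ms_resid
        p = float(stats.f.sf(F, df_num, resid_df))
        out.append(AnovaResult(name, df_num, resid_df, ss, float(F), p))
    out.append(AnovaResult("residual", resid_df, resid_df, resid_ss, np.nan, np.nan))
    return out


def _np_indicators(treatment: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    n = treatment.isin(["N", "N+P"]).to_numpy(float)
    p = treatment.isin(["P", "N+P"]).to_numpy(float)
    return n, p


def two_way_anova(
    cwm: pd.DataFrame, response: str = "cwm_1c_pg"
) -> tuple[list[AnovaResult], pd.DataFrame]:
    """Two-way factorial ANOVA of a per-subplot response on N and P.

    Fits ``response ~ N + P + N:P`` with sequential sums of squares in
    that order (residual df = n - 4), plus treatment contrasts against
    the control cell.  Raises if any factorial cell is empty.
    """
    y = cwm[response].to_numpy(float)
    treatment = cwm["treatment"]
    counts = treatment.value_counts()
    for cell in ("control", "N", "P", "N+P"):
        if counts.get(cell, 0) == 0:
            raise ValueError(f"empty factorial cell: {cell!r}")
    n_ind, p_ind = _np_indicators(treatment)
    nrow = len(y)
    blocks = [
        ("intercept", np.ones((nrow, 1))),
        ("N", n_ind.reshape(-1, 1)),
        ("P", p_ind.reshape(-1, 1)),
        ("N:P", (n_ind * p_ind).reshape(-1, 1)),
    ]
    table = sequential_anova(blocks, y)

    # Treatment contrasts: cell-means coding vs the control reference.
    X = np.column_stack(
        [
            np.ones(nrow),
            (treatment == "N").to_numpy(float),
            (treatment == "P").to_numpy(float),
            (treatment == "N+P").to_numpy(float),
        ]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = nrow - 4
    s2 = float(resid @ resid) / df_resid
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    contrasts = pd.DataFrame(
        {
            "term": ["intercept(control)", "N", "P", "N+P"],
            "estimate": beta,
            "se": se,
            "t": tvals,
            "p": 2 * stats.t.sf(np.abs(tvals), df_resid),
        }
    )
    return table, contrasts


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model, profiled (restricted) likelihood.
# ---------------------------------------------------------------------------


def _lmm_profile(
    theta: float,
    y: np.ndarray,
    X: np.ndarray,
    group_slices: list[np.ndarray],
    reml: bool,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled negative log-likelihood at variance ratio theta.

    With V = I + theta * sum_g J_g (block one-matrices), applies the
    Woodbury identity per group so the cost is linear in n.  Returns
    (nll, beta_hat, XtViX, sigma2_hat).
    """
    n, p = X.shape
    ViX = X.copy()
    Viy = y.copy()
    logdet = 0.0
    for idx in group_slices:
        ng = idx.size
        shrink = theta / (1.0 + ng * theta)
        ViX[idx] -= shrink * X[idx].sum(axis=0)
        Viy[idx] -= shrink * y[idx].sum()
        logdet += np.log1p(ng * theta)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    quad = float(y @ Viy - beta @ XtViy)
    quad = max(quad, 1e-300)
    if reml:
        dof = n - p
        s2 = quad / dof
        _, ld2 = np.linalg.slogdet(XtViX)
        nll = 0.5 * (dof * np.log(2 * np.pi * s2) + logdet + ld2 + dof)
    else:
        s2 = quad / n
        nll = 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return nll, beta, XtViX, s2


def lmm_fit(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    groups: Sequence,
    method: str = "REML",
    term_names: Sequence[str] | None = None,
    group_name: str = "group",
) -> LmmFit:
    """Fit a Gaussian random-intercept mixed model.

    The between-group variance enters through the ratio
    theta = sigma2_group / sigma2_resid, profiled out of the (restricted)
    likelihood and optimised on [0, inf); theta = 0 recovers ordinary
    least squares.  Raises for a rank-deficient fixed design, listing
    the aliased terms.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if isinstance(X, pd.DataFrame):
        term_names = term_names or list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, float)
    term_names = list(term_names or [f"x{i}" for i in range(X.shape[1])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, term_names)
        raise ValueError(f"fixed design is rank deficient; aliased terms: {aliased}")
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValueError("grouping factor must have >= 2 levels")
    group_slices = [np.flatnonzero(codes == g) for g in range(n_groups)]
    reml = method == "REML"

    def nll(log_theta: float) -> float:
        return _lmm_profile(np.exp(log_theta), y, X, group_slices, reml)[0]

    # Coarse bracket on log-theta, then local refinement; theta = 0 is
    # always evaluated as the boundary candidate.
    grid = np.linspace(-12.0, 8.0, 41)
    vals = [nll(g) for g in grid]
    i_best = int(np.argmin(vals))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    theta_hat = float(np.exp(res.x))
    nll_hat = float(res.fun)
    nll_zero, *_ = _lmm_profile(0.0, y, X, group_slices, reml)
    if nll_zero <= nll_hat:
        theta_hat, nll_hat = 0.0, nll_zero
    _, beta, XtViX, s2 = _lmm_profile(theta_hat, y, X, group_slices, reml)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtViX)))
    return LmmFit(
        fixed_effects={t: (float(b), float(s)) for t, b, s in zip(term_names, beta, se)},
        variance_components={group_name: theta_hat * s2, "residual": s2},
        log_likelihood=-nll_hat,
        method=method,
        n_obs=len(y),
        n_params=X.shape[1] + 2,
    )


def lrt_reduce(full: LmmFit, reduced: LmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Both fits must use ML: REML likelihoods are not comparable across
    fixed-effect structures.
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("lrt_reduce requires ML fits (REML not comparable)")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are not on identical data (different n)")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


NUTRIENT_COLUMNS = ("dose_nitrate", "dose_ammonium", "p_applied", "k_applied", "na_applied", "si_applied")


def per_nutrient_lme(
    cwm: pd.DataFrame,
    design: Sequence[SubplotRecord],
    response: str = "cwm_1c_pg",
    alpha: float = 0.05,
) -> tuple[LmmFit, pd.DataFrame]:
    """Per-nutrient mixed model with backward likelihood-ratio elimination.

    Response ~ nitrate dose + ammonium dose + P + K + Na + Si with a
    plot-level random intercept.  Starting from the full ML fit, the
    least-significant nutrient (largest LRT p-value above ``alpha``) is
    removed and the procedure repeats; the final model is refitted by
    REML.  Nutrient columns that are constant over the data (never
    applied, or always applied) are unidentifiable and dropped up
    front.  Returns the REML fit and a significance table giving each
    term's LRT against the model without it.
    """
    dmap = {d.subplot_id: d for d in design}
    rows = []
    for _, rec in cwm.iterrows():
        d = dmap[rec["subplot_id"]]
        rows.append(
            {
                "y": rec[response],
                "plot_id": d.plot_id,
                "dose_nitrate": d.dose_nitrate,
                "dose_ammonium": d.dose_ammonium,
                "p_applied": float(d.p_applied),
                "k_applied": float(d.k_applied),
                "na_applied": float(d.na_applied),
                "si_applied": float(d.si_applied),
            }
        )
    df = pd.DataFrame(rows)
    y = df["y"].to_numpy(float)
    groups = df["plot_id"].to_numpy()

    active = []
    for col in NUTRIENT_COLUMNS:
        if df[col].nunique() > 1:
            active.append(col)
        else:
            logger.warning("nutrient %s constant over subplots; not estimable", col)

    def fit(terms: list[str], method: str) -> LmmFit:
        X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy(float) for t in terms])
        return lmm_fit(
            y, X, groups, method=method,
            term_names=["intercept"] + terms, group_name="plot",
        )

    while active:
        full = fit(active, "ML")
        tests = []
        for term in active:
            reduced = fit([t for t in active if t != term], "ML")
            chi2, dfree, p = lrt_reduce(full, reduced)
            tests.append((term, chi2, dfree, p))
        worst = max(tests, key=lambda t: t[3])
        if worst[3] > alpha:
            active.remove(worst[0])
        else:
            break

    final_ml = fit(active, "ML")
    sig_rows = []
    for term in active:
        reduced = fit([t for t in active if t != term], "ML")
        chi2, dfree, p = lrt_reduce(final_ml, reduced)
        sig_rows.append({"term": term, "chi2": chi2, "df": dfree, "p": p, "retained": True})
    dropped = [c for c in NUTRIENT_COLUMNS if c not in active]
    for term in dropped:
        sig_rows.append({"term": term, "chi2": np.nan, "df": np.nan, "p": np.nan, "retained": False})
    final = fit(active, "REML")
    return final, pd.DataFrame(sig_rows)


# ---------------------------------------------------------------------------
# Four-way split-plot ANOVA for genomic-group responses.
# ---------------------------------------------------------------------------

_WITHIN_ORDER = (
    "GS",
    "Ploidy",
    "GS:N",
    "GS:P",
    "GS:Ploidy",
    "N:Ploidy",
    "P:Ploidy",
    "GS:N:P",
    "GS:N:Ploidy",
    "GS:P:Ploidy",
    "N:P:Ploidy",
    "GS:N:P:Ploidy",
)


def four_way_anova(
    group_df: pd.DataFrame, response: str = "sqrt_biomass"
) -> list[AnovaResult]:
    """Factorial ANOVA of a group-level response with a subplot stratum.

    The data are one row per subplot x genomic group; N, P and N:P vary
    only between subplots and are tested against the subplot stratum
    (df = n_subplots - 4), while terms involving genome-size class or
    ploidy vary within subplots and are tested against the residual
    stratum.  With 64 subplots and 4 groups the residual has
    256 - 64 - 12 = 180 degrees of freedom.

    The default response is square-root biomass; pass
    ``response="sqrt_n_species"`` for richness.
    """
    y = group_df[response].to_numpy(float)
    treatment = group_df["treatment"]
    for cell in ("control", "N", "P", "N+P"):
        if (treatment == cell).sum() == 0:
            raise ValueError(f"empty factorial cell: {cell!r}")
    n_ind, p_ind = _np_indicators(treatment)
    gs_large = group_df["group"].str.endswith("large").to_numpy(float)
    poly = group_df["group"].str.startswith("polyploid").to_numpy(float)
    sub_dummies = pd.get_dummies(group_df["subplot_id"]).to_numpy(float)
    n_subplots = sub_dummies.shape[1]
    nrow = len(y)

    within_cols = {
        "GS": gs_large,
        "Ploidy": poly,
        "GS:N": gs_large * n_ind,
        "GS:P": gs_large * p_ind,
        "GS:Ploidy": gs_large * poly,
        "N:Ploidy": n_ind * poly,
        "P:Ploidy": p_ind * poly,
        "GS:N:P": gs_large * n_ind * p_ind,
        "GS:N:Ploidy": gs_large * n_ind * poly,
        "GS:P:Ploidy": gs_large * p_ind * poly,
        "N:P:Ploidy": n_ind * p_ind * poly,
        "GS:N:P:Ploidy": gs_large * n_ind * p_ind * poly,
    }
    blocks = [
        ("intercept", np.ones((nrow, 1))),
        ("N", n_ind.reshape(-1, 1)),
        ("P", p_ind.reshape(-1, 1)),
        ("N:P", (n_ind * p_ind).reshape(-1, 1)),
        ("subplot", sub_dummies),
    ] + [(name, within_cols[name].reshape(-1, 1)) for name in _WITHIN_ORDER]
    raw = sequential_anova(blocks, y)
    by_term = {r.term: r for r in raw}

    resid = by_term["residual"]
    whole = by_term["subplot"]
    ms_whole = whole.ss / whole.df_num if whole.df_num > 0 else np.nan
    out = []
    for name in ("N", "P", "N:P"):
        r = by_term[name]
        if ms_whole and np.isfinite(ms_whole) and ms_whole > 0:
            F = (r.ss / r.df_num) / ms_whole
            p = float(stats.f.sf(F, r.df_num, whole.df_num))
        else:
            F, p = np.nan, np.nan
        out.append(AnovaResult(name, r.df_num, whole.df_num, r.ss, F, p))
    out.append(
        AnovaResult("subplot(stratum)", whole.df_num, whole.df_num, whole.ss, np.nan, np.nan)
    )
    for name in _WITHIN_ORDER:
        out.append(by_term[name])
    out.append(resid)
    return out


def anova_to_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
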