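"""Bayesian phylogenetic mixed model ("animal model") by Gibbs sampling.

Log biomass of each occupied (species, subplot) pair is modelled as

    y = X beta + Z_plot u_plot + Z_sp u_species + Z_sp a + e

with fixed effects for log genome size, N, P, ploidy, soil pH and all
their interactions; independent random intercepts for plot and species;
a second species-level effect a ~ MVN(0, sigma2_phylo * C) whose
covariance is the tree's shared-branch-length matrix (scaled to unit
height); and Gaussian residuals.  All full conditionals are conjugate
(multivariate normal for the joint location block, scaled-inverse-
chi-square for each variance component), so the sampler is a plain
Gibbs scheme, deterministic under its seed.

Variance priors are scaled-inverse-chi-square parameterised as (V, nu):
shape nu/2, scale nu*V/2.  nu = 0 is the improper flat limit, accepted
with a warning.  pMCMC is the two-sided sign probability
2 * min(#{theta > 0}, #{theta < 0}) / M, floored at 1/M and reported as
"< 1/M" when one sign never occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .community import classify_treatment
from .phylo import PhyloCovariance, phylo_covariance, safe_cho_factor
from .records import (
    BiomassTable,
    McmcSchedule,
    SpeciesRecord,
    SubplotRecord,
    VariancePrior,
    design_map,
    species_map,
)
from .simulate import FIXED_TERMS, fixed_design_row

logger = logging.getLogger("cwm_phylo")

VARIANCE_COMPONENTS = ("var_plot", "var_phylo", "var_species", "var_residual")

#: Near-flat Gaussian prior precision on fixed effects.
_BETA_PRIOR_PRECISION = 1e-8


@dataclass
class MixedModelSpec:
    """Model structure: fixed-term order, random terms, priors."""

    fixed_terms: tuple[str, ...] = FIXED_TERMS
    random_terms: tuple[str, ...] = ("plot", "phylogeny", "species")
    prior: VariancePrior = field(default_factory=VariancePrior)
    response: str = "log biomass (g)"

    def __post_init__(self) -> None:
        if tuple(self.fixed_terms) != FIXED_TERMS:
            raise ValueError("fixed_terms must match the canonical term order")


@dataclass
class PglmmDesign:
    y: np.ndarray
    X: np.ndarray
    term_names: list[str]
    plot_codes: np.ndarray
    plot_levels: list[str]
    species_codes: np.ndarray
    species_levels: list[str]
    C: np.ndarray  # normalized phylogenetic covariance over species_levels
    meta: pd.DataFrame

    @property
    def n_obs(self) -> int:
        return int(self.y.shape[0])


def build_design(
    biomass: BiomassTable,
    species: Sequence[SpeciesRecord],
    design: Sequence[SubplotRecord],
    tree,
    spec: MixedModelSpec | None = None,
) -> PglmmDesign:
    """Assemble response, fixed design and random-effect structure.

    Only occupied rows (biomass > 0) enter; the number of excluded
    zero cells is logged.  y = ln(biomass g); the GS column is
    ln(1C pg); N, P and ploidy are 0/1; pH enters uncentred.  The
    phylogenetic covariance is subset to the species present and scaled
    so its maximum diagonal entry is 1.
    """
    spec = spec or MixedModelSpec()
    smap = species_map(species)
    dmap = design_map(design)
    cov = phylo_covariance(tree)

    rows = []
    n_zero = 0
    for sub_id in biomass.subplot_ids:
        sub = dmap[sub_id]
        treatment = classify_treatment(sub)
        n_ind = 1.0 if treatment in ("N", "N+P") else 0.0
        p_ind = 1.0 if treatment in ("P", "N+P") else 0.0
        col = biomass.column(sub_id)
        for sp_id, b in col.items():
            if b <= 0:
                n_zero += 1
                continue
            rec = smap[sp_id]
            rows.append(
                {
                    "species_id": sp_id,
                    "subplot_id": sub_id,
                    "plot_id": sub.plot_id,
                    "y": float(np.log(b)),
                    "log_gs": float(np.log(rec.one_c_pg)),
                    "n": n_ind,
                    "p": p_ind,
                    "ploidy": 1.0 if rec.ploidy_class == "polyploid" else 0.0,
                    "ph": sub.ph,
                }
            )
    logger.info("build_design: %d occupied rows, %d zero cells excluded", len(rows), n_zero)
    if not rows:
        raise ValueError("no occupied (biomass > 0) rows")
    meta = pd.DataFrame(rows)
    X = np.vstack(
        [
            fixed_design_row(r.log_gs, r.n, r.p, r.ploidy, r.ph)
            for r in meta.itertuples(index=False)
        ]
    )
    plot_codes, plot_levels = pd.factorize(meta["plot_id"])
    species_codes, species_levels = pd.factorize(meta["species_id"])
    C = cov.subset(list(species_levels)).normalized().matrix
    return PglmmDesign(
        y=meta["y"].to_numpy(float),
        X=X,
        term_names=list(FIXED_TERMS),
        plot_codes=np.asarray(plot_codes),
        plot_levels=list(plot_levels),
        species_codes=np.asarray(species_codes),
        species_levels=list(species_levels),
        C=C,
        meta=meta,
    )


def _draw_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale_sum: float
) -> float:
    """One draw from scaled-inv-chi2: scale_sum / chi2(df)."""
    if df <= 0 or scale_sum <= 0:
        raise ValueError("improper posterior: no data and a flat (nu = 0) prior")
    return scale_sum / rng.chisquare(df)


def gibbs_sampler(
    design: PglmmDesign | None,
    prior: VariancePrior | Mapping[str, VariancePrior] | None = None,
    schedule: McmcSchedule | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the Gibbs sampler; returns thinned post-burn-in chains.

    One column per fixed effect plus the four variance components.
    ``prior`` is a single (V, nu) applied to every variance component,
    or a mapping keyed by component name.  With ``design=None`` (no
    data) the variance components are sampled from their priors, which
    is the standard prior-recovery check for the sampler's
    scaled-inverse-chi-square machinery.
    """
    schedule = schedule or McmcSchedule()
    priors = _expand_priors(prior)
    rng = np.random.default_rng(seed)

    if design is None:
        return _sample_prior_only(priors, schedule, rng)

    y, X = design.y, design.X
    n, p = X.shape
    q_plot = len(design.plot_levels)
    q_sp = len(design.species_levels)

    Zp = np.zeros((n, q_plot))
    Zp[np.arange(n), design.plot_codes] = 1.0
    Zs = np.zeros((n, q_sp))
    Zs[np.arange(n), design.species_codes] = 1.0
    W = np.hstack([X, Zp, Zs, Zs])
    d = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    cf = safe_cho_factor(design.C)
    Cinv = cho_solve(cf, np.eye(q_sp))
    Cinv = (Cinv + Cinv.T) / 2.0

    sl_beta = slice(0, p)
    sl_plot = slice(p, p + q_plot)
    sl_sp = slice(p + q_plot, p + q_plot + q_sp)
    sl_phy = slice(p + q_plot + q_sp, d)

    s2 = {k: priors[k].v for k in VARIANCE_COMPONENTS}
    if any(priors[k].improper for k in VARIANCE_COMPONENTS):
        logger.warning("flat (nu = 0) prior in use: posterior may be improper")

    names = design.term_names + list(VARIANCE_COMPONENTS)
    samples = np.empty((schedule.n_samples, len(names)))
    k_out = 0
    idx = np.arange(d)
    P = np.empty_like(WtW)
    for it in range(schedule.iterations):
        # --- joint location block ---
        np.multiply(WtW, 1.0 / s2["var_residual"], out=P)
        P[idx[sl_beta], idx[sl_beta]] += _BETA_PRIOR_PRECISION
        P[idx[sl_plot], idx[sl_plot]] += 1.0 / s2["var_plot"]
        P[idx[sl_sp], idx[sl_sp]] += 1.0 / s2["var_species"]
        P[sl_phy, sl_phy] += Cinv / s2["var_phylo"]
        L = cholesky(P, lower=True, check_finite=False, overwrite_a=True)
        rhs = Wty / s2["var_residual"]
        mu = cho_solve((L, True), rhs, check_finite=False)
        theta = mu + solve_triangular(
            L, rng.standard_normal(d), lower=True, trans="T", check_finite=False
        )

        # --- variance components ---
        sse = yty - 2.0 * float(theta @ Wty) + float(theta @ (WtW @ theta))
        sse = max(sse, 1e-300)
        pr = priors["var_residual"]
        s2["var_residual"] = _draw_scaled_inv_chi2(rng, pr.nu + n, pr.nu * pr.v + sse)
        u_plot = theta[sl_plot]
        pr = priors["var_plot"]
        s2["var_plot"] = _draw_scaled_inv_chi2(
            rng, pr.nu + q_plot, pr.nu * pr.v + float(u_plot @ u_plot)
        )
        u_sp = theta[sl_sp]
        pr = priors["var_species"]
        s2["var_species"] = _draw_scaled_inv_chi2(
            rng, pr.nu + q_sp, pr.nu * pr.v + float(u_sp @ u_sp)
        )
        a = theta[sl_phy]
        pr = priors["var_phylo"]
        s2["var_phylo"] = _draw_scaled_inv_chi2(
            rng, pr.nu + q_sp, pr.nu * pr.v + float(a @ (Cinv @ a))
        )

        if it >= schedule.burn_in and (it - schedule.burn_in) % schedule.thinning == 0:
            if k_out < samples.shape[0]:
                samples[k_out, :p] = theta[sl_beta]
                samples[k_out, p:] = [s2[k] for k in VARIANCE_COMPONENTS]
                k_out += 1
    return pd.DataFrame(samples[:k_out], columns=names)


def _expand_priors(
    prior: VariancePrior | Mapping[str, VariancePrior] | None,
) -> dict[str, VariancePrior]:
    if prior is None:
        prior = VariancePrior()
    if isinstance(prior, VariancePrior):
        return {k: prior for k in VARIANCE_COMPONENTS}
    missing = set(VARIANCE_COMPONENTS) - set(prior)
    if missing:
        raise ValueError(f"missing priors for: {sorted(missing)}")
    return dict(prior)


def _sample_prior_only(
    priors: dict[str, VariancePrior], schedule: McmcSchedule, rng: np.random.Generator
) -> pd.DataFrame:
    out = {}
    m = schedule.n_samples
    for name in VARIANCE_COMPONENTS:
        pr = priors[name]
        if pr.improper:
            raise ValueError(
                f"improper posterior for {name}: flat (nu = 0) prior with no data"
            )
        out[name] = pr.nu * pr.v / rng.chisquare(pr.nu, size=m)
    return pd.DataFrame(out)


def effective_sample_size(chain: np.ndarray | pd.Series) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator.

    M / (1 + 2 sum rho_t), truncating at the first non-positive sum of
    adjacent autocorrelation pairs (Geyer's initial positive sequence),
    capped at M.  Returns NaN (flagged) for a constant chain.
    """
    x = np.asarray(chain, float)
    M = x.shape[0]
    if M < 10:
        raise ValueError("chain too short for an ESS estimate (need >= 10)")
    x = x - x.mean()
    var = float(x @ x) / M
    if var == 0:
        logger.warning("constant chain: ESS undefined")
        return float("nan")
    nfft = 1 << (2 * M - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:M].real / M
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < M:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(M, M / tau))


def pmcmc(chain: np.ndarray | pd.Series) -> tuple[float, str]:
    """Two-sided MCMC sign probability with the 1/M floor.

    Returns (value, label); when one sign never occurs the value is the
    floor 1/M and the label reads "< 1/M".
    """
    x = np.asarray(chain, float)
    M = x.shape[0]
    lo = min(int((x > 0).sum()), int((x < 0).sum()))
    if lo == 0:
        return 1.0 / M, f"< {1.0 / M:.4g}"
    val = min(1.0, 2.0 * lo / M)
    return val, f"{val:.4g}"


def summarize(chains: pd.DataFrame) -> pd.DataFrame:
    """Posterior mean, central 95% CI, ESS and pMCMC per parameter."""
    if chains.empty:
        raise ValueError("empty chains")
    rows = []
    for name in chains.columns:
        x = chains[name].to_numpy(float)
        lo, hi = np.percentile(x, [2.5, 97.5])
        val, label = pmcmc(x)
        rows.append(
            {
                "parameter": name,
                "posterior_mean": float(x.mean()),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "ess": effective_sample_size(x),
                "pmcmc": val,
                "pmcmc_label": label,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_scan(
    design: PglmmDesign,
    priors_list: Sequence[VariancePrior],
    schedule: McmcSchedule | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior means of the fixed effects under each candidate prior.

    Runs the sampler once per prior (typically at a reduced schedule)
    and appends a ``max_abs_change`` column giving each prior's largest
    fixed-effect deviation from the first prior's posterior means.
    """
    if len(priors_list) < 2:
        raise ValueError("need at least 2 priors to scan")
    schedule = schedule or McmcSchedule(iterations=6000, burn_in=1000, thinning=5)
    rows = []
    base = None
    for i, prior in enumerate(priors_list):
        chains = gibbs_sampler(design, prior, schedule, seed=seed)
        means = chains[list(design.term_names)].mean()
        if base is None:
            base = means
        rows.append(
            {
                "prior_v": prior.v,
                "prior_nu": prior.nu,
                **{t: float(means[t]) for t in design.term_names},
                "max_abs_change": float((means - base).abs().max()),
            }
        )
    return pd.DataFrame(rows)
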