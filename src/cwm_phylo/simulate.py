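"""Synthetic-community generator.

Produces complete datasets — a pure-birth phylogeny, genome sizes
evolved on it, ploidy / C-S-R assignments, a 2x2 factorial
nitrogen/phosphorus design with replicate subplots, and a log-scale
biomass matrix — with exactly the statistical structure the downstream
analyses assume.  Every stage is deterministic under its seed.

The default parameter values mirror the long-term grassland experiment
the pipeline targets: 60 species on 16 plots of 4 subplots (64
subplots), genome sizes spanning roughly two orders of magnitude with
strong phylogenetic signal, about half the species polyploid, and
fixed-effect / variance-component magnitudes set to the published
phylogenetic-mixed-model estimates for that system.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .community import classify_treatment
from .io import write_biomass_table, write_design_table, write_newick, write_species_table
from .phylo import lambda_transform, phylo_covariance, safe_cholesky_lower
from .records import BiomassTable, SpeciesRecord, SubplotRecord

#: Fixed-effect terms of the biomass model, in canonical order.
FIXED_TERMS = (
    "intercept",
    "GS",
    "N",
    "P",
    "ploidy",
    "pH",
    "GS:N",
    "GS:P",
    "N:P",
    "GS:ploidy",
    "N:ploidy",
    "P:ploidy",
    "GS:N:P",
    "GS:N:ploidy",
    "GS:P:ploidy",
    "N:P:ploidy",
    "GS:N:P:ploidy",
)

#: Published posterior means for the biomass model on the target system,
#: used as the generator's default fixed effects.  The pH slope is per
#: uncentred pH unit; because the simulator centres pH at 5.75 the
#: matching intercept is -4.573 + 0.256 * 5.75.
DEFAULT_BETA: dict[str, float] = {
    "intercept": -4.573 + 0.256 * 5.75,
    "GS": 0.186,
    "N": -0.034,
    "P": 0.907,
    "ploidy": 0.452,
    "pH": 0.256,
    "GS:N": 0.04,
    "GS:P": -0.536,
    "N:P": -0.605,
    "GS:ploidy": 0.053,
    "N:ploidy": -0.722,
    "P:ploidy": -1.411,
    "GS:N:P": 0.71,
    "GS:N:ploidy": 0.503,
    "GS:P:ploidy": 1.225,
    "N:P:ploidy": -0.872,
    "GS:N:P:ploidy": 0.043,
}

PH_CENTER = 5.75  # midpoint of the included soil-pH range [4.5, 7.0]


def fixed_design_row(
    log_gs: float, n: float, p: float, ploidy: float, ph: float
) -> np.ndarray:
    """One row of the 17-column fixed-effect design, in FIXED_TERMS order."""
    g, i_n, i_p, pl = log_gs, n, p, ploidy
    return np.array(
        [
            1.0,
            g,
            i_n,
            i_p,
            pl,
            ph,
            g * i_n,
            g * i_p,
            i_n * i_p,
            g * pl,
            i_n * pl,
            i_p * pl,
            g * i_n * i_p,
            g * i_n * pl,
            g * i_p * pl,
            i_n * i_p * pl,
            g * i_n * i_p * pl,
        ]
    )


@dataclass
class SimulationParams:
    """Tunable knobs of the synthetic-community generator."""

    n_species: int = 60
    birth_rate: float = 1.0
    sigma2_bm: float = 0.25  # Brownian rate of log 1C per unit branch length
    lambda_true: float = 1.0
    root_log1c: float = float(np.log(2.5))
    p_polyploid: float = 0.5
    polyploid_gs_multiplier: float = 2.0
    csr_concentration: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_plots: int = 16
    subplots_per_plot: int = 4
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma2_plot: float = 0.102
    sigma2_species: float = 2.806
    sigma2_phylo: float = 0.818
    sigma2_resid: float = 3.022
    occupancy: float = 0.5
    #: Optional hook: (SpeciesRecord, SubplotRecord, treatment) -> occupancy
    #: probability, enabling treatment-dependent species richness.
    occupancy_fn: Callable[[SpeciesRecord, SubplotRecord, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_bm", "sigma2_plot", "sigma2_species", "sigma2_phylo", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_polyploid", "occupancy"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.lambda_true <= 1:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.polyploid_gs_multiplier < 1:
            raise ValueError("polyploid_gs_multiplier must be >= 1")
        unknown = set(self.beta) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed-effect terms: {sorted(unknown)}")
        missing = set(FIXED_TERMS) - set(self.beta)
        if missing:
            raise ValueError(f"missing fixed-effect coefficients: {sorted(missing)}")


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth tree with tips relabelled sp001, sp002, ...

    Tip labels follow the Newick leaf order, so the same seed always
    yields the identical Newick string.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=float(birth_rate),
        death_rate=0.0,
        num_extant_tips=int(n_species),
        rng=rng,
    )
    tree.is_rooted = True
    # The simulation stops at the n-th speciation, leaving a zero-length
    # cherry (and a singular covariance matrix).  Extend every terminal
    # branch by the waiting time to the next speciation event, which
    # keeps the tree ultrametric and the process exact.
    extra = rng.expovariate(n_species * float(birth_rate))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
    return tree


def simulate_gs(
    tree: dendropy.Tree,
    sigma2_bm: float,
    lambda_true: float,
    root_log1c: float,
    seed: int = 0,
) -> dict[str, float]:
    """Genome sizes from Brownian motion with Pagel-lambda signal.

    log 1C ~ MVN(root_log1c, sigma2_bm * C(lambda)) where C(lambda)
    scales the off-diagonal shared-branch-length entries by lambda;
    lambda = 0 gives independent tips, lambda = 1 plain Brownian motion.
    Returns 1C-values in picograms (exponentiated).
    """
    if not 0 <= lambda_true <= 1:
        raise ValueError("lambda_true must be in [0, 1]")
    if sigma2_bm <= 0:
        raise ValueError("sigma2_bm must be > 0")
    cov = phylo_covariance(tree)
    C = lambda_transform(cov.matrix, lambda_true) * sigma2_bm
    rng = np.random.default_rng(seed)
    L = safe_cholesky_lower(C)
    log_vals = root_log1c + L @ rng.standard_normal(cov.n)
    return {lab: float(np.exp(v)) for lab, v in zip(cov.tip_labels, log_vals)}


def assign_ploidy_csr(
    gs_map: Mapping[str, float],
    p_polyploid: float = 0.5,
    multiplier: float = 2.0,
    csr_concentration: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> list[SpeciesRecord]:
    """Flag polyploids, inflate their genome size, draw C-S-R triples.

    Multiplying polyploid 1C-values by ``multiplier`` creates the
    genome-size / ploidy association; ``multiplier = 1`` leaves the two
    ploidy classes identically distributed.  C-S-R proportions are
    Dirichlet draws, so every triple sums to one by construction.
    """
    rng = np.random.default_rng(seed)
    records = []
    for sp in sorted(gs_map):
        poly = rng.random() < p_polyploid
        one_c = gs_map[sp] * (multiplier if poly else 1.0)
        csr = rng.dirichlet(csr_concentration)
        csr = csr / csr.sum()  # guard against float drift
        records.append(
            SpeciesRecord(
                species_id=sp,
                one_c_pg=float(one_c),
                ploidy_class="polyploid" if poly else "diploid",
                csr=(float(csr[0]), float(csr[1]), float(csr[2])),
            )
        )
    return records


_N_FORMS = (
    ("nitrate", 48.0),
    ("nitrate", 96.0),
    ("ammonium", 48.0),
    ("ammonium", 96.0),
    ("ammonium", 144.0),
)


def simulate_design(
    n_plots: int = 16, subplots_per_plot: int = 4, seed: int = 0
) -> list[SubplotRecord]:
    """Factorial N/P design with replicate subplots.

    Treatment cells (control, N, P, N+P) are cycled across subplots so
    the design is as balanced as the subplot count allows; nitrogen
    form/dose is drawn among the experiment's dose levels, the minor
    nutrients are random booleans, and soil pH is uniform on the
    inclusion range [4.5, 7.0].
    """
    if n_plots < 4:
        raise ValueError("n_plots must be >= 4 for a full factorial")
    rng = np.random.default_rng(seed)
    cells = ("control", "N", "P", "N+P")
    records = []
    k = 0
    for ip in range(n_plots):
        plot_id = f"plot{ip + 1:02d}"
        for isub in range(subplots_per_plot):
            cell = cells[k % 4]
            k += 1
            dose_nitrate = dose_ammonium = 0.0
            if "N" in cell and cell != "control":
                form, dose = _N_FORMS[rng.integers(len(_N_FORMS))]
                if form == "nitrate":
                    dose_nitrate = dose
                else:
                    dose_ammonium = dose
            p_applied = cell in ("P", "N+P")
            fertilized = cell != "control"
            records.append(
                SubplotRecord(
                    plot_id=plot_id,
                    subplot_id=f"{plot_id}{'abcdefgh'[isub % 8]}",
                    dose_nitrate=dose_nitrate,
                    dose_ammonium=dose_ammonium,
                    p_applied=p_applied,
                    k_applied=bool(fertilized and rng.random() < 0.5),
                    na_applied=bool(fertilized and rng.random() < 0.3),
                    mg_applied=bool(fertilized and rng.random() < 0.3),
                    si_applied=bool(fertilized and rng.random() < 0.05),
                    ph=float(rng.uniform(4.5, 7.0)),
                )
            )
    return records


def simulate_biomass(
    species: Sequence[SpeciesRecord],
    design: Sequence[SubplotRecord],
    tree: dendropy.Tree,
    params: SimulationParams,
) -> BiomassTable:
    """Log-normal biomass from the fixed/random structure of the model.

    For each occupied (species, subplot) pair,

        log biomass = x'beta + u_plot + u_species + a_species + e

    with GS entering as log 1C, N/P/ploidy as 0-1 indicators, pH centred
    at 5.75; u_plot ~ N(0, sigma2_plot), u_species ~ N(0,
    sigma2_species), a ~ MVN(0, sigma2_phylo * C) with C the tree
    covariance scaled to unit height (drawn once per species, shared
    across subplots), e ~ N(0, sigma2_resid).  Unoccupied pairs are 0.
    """
    rng = np.random.default_rng(params.seed + 1_000_003)
    cov = phylo_covariance(tree).normalized()
    beta = np.array([params.beta[t] for t in FIXED_TERMS])

    plots = sorted({d.plot_id for d in design})
    u_plot = dict(zip(plots, rng.normal(0.0, np.sqrt(params.sigma2_plot), len(plots))))
    sp_ids = [s.species_id for s in species]
    u_species = dict(
        zip(sp_ids, rng.normal(0.0, np.sqrt(params.sigma2_species), len(sp_ids)))
    )
    L = safe_cholesky_lower(params.sigma2_phylo * cov.matrix + 1e-12 * np.eye(cov.n))
    a_vals = L @ rng.standard_normal(cov.n)
    a_phylo = dict(zip(cov.tip_labels, a_vals))

    data = pd.DataFrame(
        0.0, index=sp_ids, columns=[d.subplot_id for d in design], dtype=float
    )
    for sub in design:
        treatment = classify_treatment(sub)
        n_ind = 1.0 if "N" in treatment and treatment != "control" else 0.0
        p_ind = 1.0 if treatment in ("P", "N+P") else 0.0
        ph_c = sub.ph - PH_CENTER
        for rec in species:
            prob = (
                params.occupancy_fn(rec, sub, treatment)
                if params.occupancy_fn is not None
                else params.occupancy
            )
            if rng.random() >= prob:
                continue
            x = fixed_design_row(
                float(np.log(rec.one_c_pg)),
                n_ind,
                p_ind,
                1.0 if rec.ploidy_class == "polyploid" else 0.0,
                ph_c,
            )
            log_b = (
                float(x @ beta)
                + u_plot[sub.plot_id]
                + u_species[rec.species_id]
                + a_phylo.get(rec.species_id, 0.0)
                + rng.normal(0.0, np.sqrt(params.sigma2_resid))
            )
            data.loc[rec.species_id, sub.subplot_id] = float(np.exp(log_b))
    return BiomassTable(data)


@dataclass
class SyntheticDataset:
    tree: dendropy.Tree
    species: list[SpeciesRecord]
    design: list[SubplotRecord]
    biomass: BiomassTable
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        """Write the four standard input files plus true parameter values."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_newick(self.tree, out / "tree.nwk")
        write_species_table(self.species, out / "species.csv")
        write_design_table(self.design, out / "design.csv")
        write_biomass_table(self.biomass, out / "biomass.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def simulate_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """Generate tree, traits, design and biomass in one deterministic call."""
    params = params or SimulationParams()
    ss = np.random.SeedSequence(params.seed)
    s_tree, s_gs, s_traits, s_design = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    tree = simulate_tree(params.n_species, params.birth_rate, seed=s_tree)
    gs = simulate_gs(
        tree, params.sigma2_bm, params.lambda_true, params.root_log1c, seed=s_gs
    )
    species = assign_ploidy_csr(
        gs,
        params.p_polyploid,
        params.polyploid_gs_multiplier,
        params.csr_concentration,
        seed=s_traits,
    )
    design = simulate_design(params.n_plots, params.subplots_per_plot, seed=s_design)
    biomass = simulate_biomass(species, design, tree, params)
    truth = {
        "beta": dict(params.beta),
        "sigma2_plot": params.sigma2_plot,
        "sigma2_species": params.sigma2_species,
        "sigma2_phylo": params.sigma2_phylo,
        "sigma2_resid": params.sigma2_resid,
        "lambda_true": params.lambda_true,
        "sigma2_bm": params.sigma2_bm,
        "p_polyploid": params.p_polyploid,
        "polyploid_gs_multiplier": params.polyploid_gs_multiplier,
        "occupancy": params.occupancy,
        "seed": params.seed,
    }
    return SyntheticDataset(tree, species, design, biomass, truth)
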