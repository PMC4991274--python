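"""Core record types shared across the pipeline.

The analysis revolves around four artifacts: a species trait table
(genome size as 1C-value in picograms, ploidy class, Grime C-S-R
strategy proportions), a subplot design table (nutrient doses and soil
pH for a long-term factorial fertilisation experiment), a species-by-
subplot biomass matrix (10-year mean dry weights, grams), and an
ultrametric phylogeny.  The record classes here validate the invariants
every downstream stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CSR_TOL = 1e-9

PLOIDY_CLASSES = ("diploid", "polyploid")

#: The four cells of the nitrogen x phosphorus factorial.
TREATMENTS = ("control", "N", "P", "N+P")

#: The four genomic groups: ploidy class crossed with a genome-size threshold.
GENOMIC_GROUPS = (
    "diploid-small",
    "diploid-large",
    "polyploid-small",
    "polyploid-large",
)


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' genome size, ploidy class and C-S-R strategy.

    Parameters
    ----------
    species_id
        Unique species label (tip label in the phylogeny).
    one_c_pg
        1C-value: DNA amount of the unreplicated gametic nucleus, in
        picograms (1 pg = 978 Mbp).  Species with an intraspecific GS
        range are stored as a single mean value; the optional
        ``one_c_min_pg`` / ``one_c_max_pg`` pair records the range but
        all downstream computation uses the mean.
    ploidy_class
        ``"diploid"`` or ``"polyploid"``.
    csr
        Grime competitor / stress-tolerator / ruderal proportions; must
        sum to one.
    """

    species_id: str
    one_c_pg: float
    ploidy_class: str
    csr: tuple[float, float, float]
    one_c_min_pg: float | None = None
    one_c_max_pg: float | None = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not (self.one_c_pg > 0):
            raise ValueError(
                f"{self.species_id}: 1C-value must be positive, got {self.one_c_pg}"
            )
        if self.ploidy_class not in PLOIDY_CLASSES:
            raise ValueError(
                f"{self.species_id}: ploidy_class must be one of {PLOIDY_CLASSES}, "
                f"got {self.ploidy_class!r}"
            )
        c, s, r = self.csr
        if min(c, s, r) < 0:
            raise ValueError(f"{self.species_id}: C-S-R components must be >= 0")
        if abs(c + s + r - 1.0) > CSR_TOL:
            raise ValueError(
                f"{self.species_id}: C-S-R triple {self.csr} sums to {c + s + r}, "
                "expected 1"
            )


@dataclass(frozen=True)
class SubplotRecord:
    """One subplot's nutrient regime and soil pH.

    Nitrogen arrives as nitrate (doses 0/48/96 kg N ha^-1 yr^-1) or as
    ammonium (0/48/96/144); phosphorus and the minor nutrients are
    recorded as applied / not applied.
    """

    plot_id: str
    subplot_id: str
    dose_nitrate: float
    dose_ammonium: float
    p_applied: bool
    k_applied: bool = False
    na_applied: bool = False
    mg_applied: bool = False
    si_applied: bool = False
    ph: float = 7.0

    def __post_init__(self) -> None:
        if self.dose_nitrate < 0 or self.dose_ammonium < 0:
            raise ValueError(f"{self.subplot_id}: nitrogen doses must be >= 0")


@dataclass
class BiomassTable:
    """Species-by-subplot dry-weight matrix (grams); zero means absent."""

    data: pd.DataFrame  # index: species_id, columns: subplot_id

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if (self.data.to_numpy() < 0).any():
            bad = self.data.index[(self.data < 0).any(axis=1)].tolist()
            raise ValueError(f"negative biomass for species: {bad}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate species_id rows in biomass table")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate subplot_id columns in biomass table")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subplot_ids(self) -> list[str]:
        return list(self.data.columns)

    def column(self, subplot_id: str) -> pd.Series:
        return self.data[subplot_id]

    def validate_against(
        self,
        species: Sequence[SpeciesRecord],
        design: Sequence[SubplotRecord],
    ) -> list[str]:
        """Cross-reference the matrix against species and design tables.

        Returns a list of human-readable warnings (species present in
        the biomass table with no trait record, subplots with no design
        row); raises nothing so callers can decide how strict to be.
        """
        known_species = {s.species_id for s in species}
        known_subplots = {d.subplot_id for d in design}
        warnings = []
        for sp in self.species_ids:
            if sp not in known_species:
                warnings.append(f"species {sp!r} in biomass table has no trait record")
        for sub in self.subplot_ids:
            if sub not in known_subplots:
                warnings.append(f"subplot {sub!r} in biomass table has no design row")
        return warnings


@dataclass
class McmcSchedule:
    """Gibbs-sampler schedule: total iterations, burn-in, thinning."""

    iterations: int = 60_000
    burn_in: int = 10_000
    thinning: int = 10

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class VariancePrior:
    """Scaled-inverse-chi-square prior on a variance component.

    ``(V, nu)`` maps to shape ``nu/2`` and scale ``nu*V/2``.  ``nu = 0``
    is the improper flat limit; it is accepted but flagged.
    """

    v: float = 1.0
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("prior V must be > 0")
        if self.nu < 0:
            raise ValueError("prior nu must be >= 0")

    @property
    def improper(self) -> bool:
        return self.nu == 0


ALLOWED_GS_THRESHOLDS = (2.5, 3.0, 5.0, 6.0)


@dataclass
class RunConfig:
    """Pipeline configuration: threshold, MCMC schedule, priors, seed."""

    gs_threshold_pg: float = 5.0
    mcmc: McmcSchedule = field(default_factory=McmcSchedule)
    prior: VariancePrior = field(default_factory=VariancePrior)
    n_permutations: int = 999
    seed: int = 0
    drop_missing_gs: bool = False  # drop-and-renormalise species without GS
    signal_log_scale: bool = True  # test phylogenetic signal on log 1C

    def __post_init__(self) -> None:
        if self.gs_threshold_pg <= 0:
            raise ValueError("gs_threshold_pg must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def species_map(species: Sequence[SpeciesRecord]) -> dict[str, SpeciesRecord]:
    out: dict[str, SpeciesRecord] = {}
    for rec in species:
        if rec.species_id in out:
            raise ValueError(f"duplicate species_id {rec.species_id!r}")
        out[rec.species_id] = rec
    return out


def design_map(design: Sequence[SubplotRecord]) -> dict[str, SubplotRecord]:
    out: dict[str, SubplotRecord] = {}
    for rec in design:
        if rec.subplot_id in out:
            raise ValueError(f"duplicate subplot_id {rec.subplot_id!r}")
        out[rec.subplot_id] = rec
    return out
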