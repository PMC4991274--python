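"""Community descriptive statistics.

Biomass-weighted community mean genome size per subplot, the 2x2
nitrogen/phosphorus treatment classification, partition of species into
genomic groups (ploidy class crossed with a genome-size threshold), and
per-group biomass / richness summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    BiomassTable,
    GENOMIC_GROUPS,
    SpeciesRecord,
    SubplotRecord,
    design_map,
    species_map,
)


@dataclass
class CWMResult:
    subplot_id: str
    cwm_1c_pg: float  # NaN when the subplot has no biomass
    total_biomass_g: float
    n_species: int
    treatment: str


def classify_treatment(subplot: SubplotRecord) -> str:
    """2x2 factorial cell: N+ iff any nitrogen dose > 0, P+ iff P applied.

    The minor nutrients (K, Na, Mg, Si) do not enter the four-cell
    factor; their effects are assessed separately with per-nutrient
    mixed models.
    """
    n_plus = (subplot.dose_nitrate + subplot.dose_ammonium) > 0
    p_plus = subplot.p_applied
    if n_plus and p_plus:
        return "N+P"
    if n_plus:
        return "N"
    if p_plus:
        return "P"
    return "control"


def biomass_weighted_mean_gs(
    biomass_column: Mapping[str, float] | pd.Series,
    species: Sequence[SpeciesRecord] | Mapping[str, SpeciesRecord],
    drop_missing_gs: bool = False,
) -> float:
    """Community-weighted mean 1C-value for one subplot.

    Sum over present species of 1C times the species' biomass fraction
    (species biomass / total subplot biomass).  Returns NaN when total
    biomass is zero.  A present species without a trait record raises,
    unless ``drop_missing_gs`` asks for drop-and-renormalise.
    """
    smap = species if isinstance(species, Mapping) else species_map(species)
    items = (
        biomass_column.items()
        if isinstance(biomass_column, (dict, pd.Series))
        else biomass_column
    )
    weights: list[tuple[float, float]] = []
    for sp, b in items:
        b = float(b)
        if b < 0:
            raise ValueError(f"negative biomass for {sp!r}")
        if b == 0:
            continue
        rec = smap.get(sp)
        if rec is None:
            if drop_missing_gs:
                continue
            raise KeyError(f"species {sp!r} present with biomass but no 1C-value")
        weights.append((rec.one_c_pg, b))
    total = sum(b for _, b in weights)
    if total == 0:
        return math.nan
    return sum(gs * b for gs, b in weights) / total


def partition_genomic_groups(
    species: Sequence[SpeciesRecord] | Mapping[str, SpeciesRecord],
    threshold_pg: float,
) -> dict[str, str]:
    """Assign each species to a genomic group at a genome-size threshold.

    "Large" is boundary-inclusive: 1C >= threshold.
    """
    if threshold_pg <= 0:
        raise ValueError("threshold_pg must be > 0")
    smap = species if isinstance(species, Mapping) else species_map(species)
    out = {}
    for sp, rec in smap.items():
        size = "large" if rec.one_c_pg >= threshold_pg else "small"
        out[sp] = f"{rec.ploidy_class}-{size}"
    return out


def cwm_table(
    biomass: BiomassTable,
    species: Sequence[SpeciesRecord],
    design: Sequence[SubplotRecord],
    drop_missing_gs: bool = False,
) -> pd.DataFrame:
    """Per-subplot CWM results as a DataFrame (one row per subplot)."""
    smap = species_map(species)
    dmap = design_map(design)
    rows = []
    for sub in biomass.subplot_ids:
        col = biomass.column(sub)
        present = col[col > 0]
        cwm = biomass_weighted_mean_gs(col, smap, drop_missing_gs=drop_missing_gs)
        rows.append(
            CWMResult(
                subplot_id=sub,
                cwm_1c_pg=cwm,
                total_biomass_g=float(col.sum()),
                n_species=int((present > 0).sum()),
                treatment=classify_treatment(dmap[sub]),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df


def treatment_summary(cwm: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level n, mean and SD of biomass, richness and CWM."""
    agg = cwm.groupby("treatment").agg(
        n=("subplot_id", "size"),
        total_biomass_mean=("total_biomass_g", "mean"),
        total_biomass_sd=("total_biomass_g", "std"),
        n_species_mean=("n_species", "mean"),
        n_species_sd=("n_species", "std"),
        cwm_mean=("cwm_1c_pg", "mean"),
        cwm_sd=("cwm_1c_pg", "std"),
    )
    order = [t for t in ("control", "N", "P", "N+P") if t in agg.index]
    return agg.loc[order].reset_index()


def group_summaries(
    biomass: BiomassTable,
    species: Sequence[SpeciesRecord],
    design: Sequence[SubplotRecord],
    threshold_pg: float = 5.0,
) -> pd.DataFrame:
    """Per subplot x genomic group: biomass, biomass ratio, species count.

    Species with recorded-but-zero biomass do not count towards
    richness.  The ``sqrt_biomass`` / ``sqrt_n_species`` columns carry
    the square-root transform used for the factorial ANOVAs.
    """
    groups = partition_genomic_groups(species, threshold_pg)
    dmap = design_map(design)
    rows = []
    for sub in biomass.subplot_ids:
        col = biomass.column(sub)
        total = float(col.sum())
        treatment = classify_treatment(dmap[sub])
        for group in GENOMIC_GROUPS:
            members = [sp for sp in biomass.species_ids if groups.get(sp) == group]
            gb = float(col[members].sum()) if members else 0.0
            n_sp = int((col[members] > 0).sum()) if members else 0
            rows.append(
                {
                    "subplot_id": sub,
                    "treatment": treatment,
                    "group": group,
                    "threshold_pg": threshold_pg,
                    "biomass_g": gb,
                    "biomass_ratio": gb / total if total > 0 else np.nan,
                    "n_species": n_sp,
                    "sqrt_biomass": math.sqrt(gb),
                    "sqrt_n_species": math.sqrt(n_sp),
                }
            )
    return pd.DataFrame(rows)


def group_treatment_summary(group_df: pd.DataFrame) -> pd.DataFrame:
    """Treatment x group means and SDs of biomass, ratio and richness."""
    agg = (
        group_df.groupby(["treatment", "group"])
        .agg(
            biomass_mean=("biomass_g", "mean"),
            biomass_sd=("biomass_g", "std"),
            ratio_mean=("biomass_ratio", "mean"),
            ratio_sd=("biomass_ratio", "std"),
            n_species_mean=("n_species", "mean"),
        )
        .reset_index()
    )
    return agg


def gs_distribution_summary(species: Sequence[SpeciesRecord]) -> dict[str, float]:
    """Median, mean, min and max 1C across the species pool (pg)."""
    vals = np.array([rec.one_c_pg for rec in species])
    return {
        "n_species": int(vals.size),
        "median_pg": float(np.median(vals)),
        "mean_pg": float(vals.mean()),
        "min_pg": float(vals.min()),
        "max_pg": float(vals.max()),
    }
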