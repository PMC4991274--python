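"""Grime C-S-R strategy partitioning of biomass.

Each species carries a competitor : stress-tolerator : ruderal
proportion triple summing to one; a species' biomass on a subplot is
split among the three strategies in those proportions (e.g. 10 g at
0.5 : 0.25 : 0.25 gives 5 g to C and 2.5 g to each of S and R).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .community import classify_treatment, partition_genomic_groups
from .records import (
    BiomassTable,
    GENOMIC_GROUPS,
    SpeciesRecord,
    SubplotRecord,
    design_map,
    species_map,
)

_BASE_CODES = {
    "C": (1.0, 0.0, 0.0),
    "S": (0.0, 1.0, 0.0),
    "R": (0.0, 0.0, 1.0),
    "CS": (0.5, 0.5, 0.0),
    "CR": (0.5, 0.0, 0.5),
    "SR": (0.0, 0.5, 0.5),
    "CSR": (1 / 3, 1 / 3, 1 / 3),
}


def csr_code_to_triple(code: str) -> tuple[float, float, float]:
    """Translate a Grime letter code to a proportion triple.

    Pure and intermediate types map to the obvious allocations
    ("C" -> (1,0,0), "CSR" -> (1/3,1/3,1/3)); a slashed code such as
    "C/CSR" averages its two parts, following the convention of numeric
    strategy allocations.
    """
    key = code.strip().upper().replace("-", "/")
    if "/" in key:
        parts = key.split("/")
        triples = [csr_code_to_triple(p) for p in parts]
        n = len(triples)
        return tuple(sum(t[i] for t in triples) / n for i in range(3))  # type: ignore[return-value]
    if key not in _BASE_CODES:
        raise KeyError(f"unknown C-S-R code {code!r}")
    return _BASE_CODES[key]


def partition_biomass_csr(
    biomass_g: float, csr_triple: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Split one biomass value into (C, S, R) grams, conserving mass."""
    if biomass_g < 0:
        raise ValueError("biomass must be >= 0")
    c, s, r = csr_triple
    if min(c, s, r) < 0 or abs(c + s + r - 1.0) > 1e-9:
        raise ValueError(f"C-S-R triple {csr_triple} does not sum to 1")
    return (biomass_g * c, biomass_g * s, biomass_g * r)


def csr_group_table(
    biomass: BiomassTable,
    species: Sequence[SpeciesRecord],
    design: Sequence[SubplotRecord],
    threshold_pg: float = 5.0,
) -> pd.DataFrame:
    """Strategy-partitioned biomass per subplot x genomic group.

    Columns ``c_g``, ``s_g``, ``r_g`` sum to the group's biomass
    exactly; ``c_ratio`` etc. divide by the subplot total so the twelve
    (group x strategy) ratios of a subplot sum to one.
    """
    smap = species_map(species)
    dmap = design_map(design)
    groups = partition_genomic_groups(smap, threshold_pg)
    rows = []
    for sub in biomass.subplot_ids:
        col = biomass.column(sub)
        total = float(col.sum())
        treatment = classify_treatment(dmap[sub])
        sums = {g: [0.0, 0.0, 0.0] for g in GENOMIC_GROUPS}
        for sp, b in col.items():
            if b <= 0:
                continue
            rec = smap.get(sp)
            if rec is None:
                raise KeyError(f"species {sp!r} has biomass but no trait record")
            cg, sg, rg = partition_biomass_csr(float(b), rec.csr)
            acc = sums[groups[sp]]
            acc[0] += cg
            acc[1] += sg
            acc[2] += rg
        for group in GENOMIC_GROUPS:
            cg, sg, rg = sums[group]
            rows.append(
                {
                    "subplot_id": sub,
                    "treatment": treatment,
                    "group": group,
                    "threshold_pg": threshold_pg,
                    "c_g": cg,
                    "s_g": sg,
                    "r_g": rg,
                    "c_ratio": cg / total if total > 0 else float("nan"),
                    "s_ratio": sg / total if total > 0 else float("nan"),
                    "r_ratio": rg / total if total > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def csr_treatment_summary(csr_df: pd.DataFrame) -> pd.DataFrame:
    """Treatment x group mean and SD of the strategy biomass ratios."""
    return (
        csr_df.groupby(["treatment", "group"])
        .agg(
            c_ratio_mean=("c_ratio", "mean"),
            c_ratio_sd=("c_ratio", "std"),
            s_ratio_mean=("s_ratio", "mean"),
            s_ratio_sd=("s_ratio", "std"),
            r_ratio_mean=("r_ratio", "mean"),
            r_ratio_sd=("r_ratio", "std"),
        )
        .reset_index()
    )
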