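"""Readers and writers for the four input artifacts plus run configuration.

All tables are comma-separated UTF-8 with a mandatory header row and a
decimal point.  The phylogeny is a single rooted Newick tree with branch
lengths.  Layouts:

``species.csv``
    species_id, one_c_pg, ploidy_class, csr_c, csr_s, csr_r
    [, one_c_min_pg, one_c_max_pg]
``design.csv``
    plot_id, subplot_id, dose_nitrate, dose_ammonium, p_applied,
    k_applied, na_applied, mg_applied, si_applied, ph
``biomass.csv``
    wide matrix: first column species_id, remaining columns one per
    subplot_id, entries dry weight in grams (0 = absent).
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import dendropy
import pandas as pd
import yaml

from .records import (
    BiomassTable,
    McmcSchedule,
    RunConfig,
    SpeciesRecord,
    SubplotRecord,
    VariancePrior,
)

logger = logging.getLogger("cwm_phylo")

_BOOL_COLS = ("p_applied", "k_applied", "na_applied", "mg_applied", "si_applied")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Raises ``ValueError`` for a missing branch length (naming the edge),
    duplicate tip labels, or fewer than two tips.  Zero-length terminal
    branches are accepted but logged: the phylogenetic covariance matrix
    then has repeated rows and downstream solvers add a diagonal jitter.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises its own parse-error hierarchy
        if "Duplicate taxon" in str(exc):
            raise ValueError(f"duplicate tip labels in {path}: {exc}") from exc
        raise ValueError(f"could not parse Newick tree {path}: {exc}") from exc
    tree.is_rooted = True
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError(f"tree in {path} has {len(leaves)} tips; need >= 2")
    labels = [lf.taxon.label for lf in leaves]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate tip label {lab!r} in {path}")
        seen.add(lab)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            tips = [lf.taxon.label for lf in node.leaf_iter()]
            raise ValueError(
                f"missing branch length on edge above clade containing {tips[:3]}"
            )
        if node.edge.length < 0:
            raise ValueError("negative branch length in tree")
        if node.is_leaf() and node.edge.length == 0:
            logger.warning("zero-length terminal branch at tip %s", node.taxon.label)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    df = pd.read_csv(path)
    required = {"species_id", "one_c_pg", "ploidy_class", "csr_c", "csr_s", "csr_r"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table {path} missing columns: {sorted(missing)}")
    records = []
    bad_csr = []
    for row in df.itertuples(index=False):
        triple = (float(row.csr_c), float(row.csr_s), float(row.csr_r))
        if abs(sum(triple) - 1.0) > 1e-9:
            bad_csr.append(f"{row.species_id} (sums to {sum(triple):g})")
            continue
        records.append(
            SpeciesRecord(
                species_id=str(row.species_id),
                one_c_pg=float(row.one_c_pg),
                ploidy_class=str(row.ploidy_class),
                csr=triple,
                one_c_min_pg=_opt(getattr(row, "one_c_min_pg", None)),
                one_c_max_pg=_opt(getattr(row, "one_c_max_pg", None)),
            )
        )
    if bad_csr:
        raise ValueError(f"C-S-R triples not summing to 1 for: {', '.join(bad_csr)}")
    return records


def _opt(x) -> float | None:
    if x is None or pd.isna(x):
        return None
    return float(x)


def read_design_table(path: str | Path) -> list[SubplotRecord]:
    df = pd.read_csv(path)
    required = {"plot_id", "subplot_id", "dose_nitrate", "dose_ammonium", "p_applied", "ph"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        kwargs = {
            "plot_id": str(row.plot_id),
            "subplot_id": str(row.subplot_id),
            "dose_nitrate": float(row.dose_nitrate),
            "dose_ammonium": float(row.dose_ammonium),
            "ph": float(row.ph),
        }
        for col in _BOOL_COLS:
            if hasattr(row, col):
                kwargs[col] = _parse_bool(getattr(row, col))
        records.append(SubplotRecord(**kwargs))
    return records


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes", "t"}
    return bool(x)


def read_biomass_table(path: str | Path) -> BiomassTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BiomassTable(df)


def read_tables(
    species_path: str | Path,
    design_path: str | Path,
    biomass_path: str | Path,
) -> tuple[list[SpeciesRecord], list[SubplotRecord], BiomassTable]:
    """Read and cross-validate the three CSV inputs.

    Validation warnings (biomass species without trait records, subplots
    without design rows) are logged; hard invariant violations raise.
    """
    species = read_species_table(species_path)
    design = read_design_table(design_path)
    biomass = read_biomass_table(biomass_path)
    for warning in biomass.validate_against(species, design):
        logger.warning(warning)
    return species, design, biomass


def write_species_table(species: Sequence[SpeciesRecord], path: str | Path) -> None:
    rows = []
    for rec in species:
        rows.append(
            {
                "species_id": rec.species_id,
                "one_c_pg": rec.one_c_pg,
                "ploidy_class": rec.ploidy_class,
                "csr_c": rec.csr[0],
                "csr_s": rec.csr[1],
                "csr_r": rec.csr[2],
                "one_c_min_pg": rec.one_c_min_pg,
                "one_c_max_pg": rec.one_c_max_pg,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_design_table(design: Sequence[SubplotRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(rec) for rec in design]).to_csv(path, index=False)


def write_biomass_table(biomass: BiomassTable, path: str | Path) -> None:
    out = biomass.data.copy()
    out.index.name = "species_id"
    out.to_csv(path)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mcmc = McmcSchedule(**raw.pop("mcmc", {}))
    prior = VariancePrior(**raw.pop("prior", {}))
    return RunConfig(mcmc=mcmc, prior=prior, **raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    payload = {
        "gs_threshold_pg": config.gs_threshold_pg,
        "mcmc": asdict(config.mcmc),
        "prior": asdict(config.prior),
        "n_permutations": config.n_permutations,
        "seed": config.seed,
        "drop_missing_gs": config.drop_missing_gs,
        "signal_log_scale": config.signal_log_scale,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
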