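import dendropy
import numpy as np
import pandas as pd
import pytest

from cwm_phylo import (
    BiomassTable,
    SimulationParams,
    SpeciesRecord,
    SubplotRecord,
    simulate_dataset,
)


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def star_tree(n: int, height: float = 1.0) -> dendropy.Tree:
    tips = ",".join(f"t{i}:{height}" for i in range(n))
    return tree_from_newick(f"({tips});")


@pytest.fixture
def toy_species() -> list[SpeciesRecord]:
    return [
        SpeciesRecord("grass_small", 1.0, "diploid", (0.5, 0.25, 0.25)),
        SpeciesRecord("herb_mid", 4.0, "diploid", (0.0, 1.0, 0.0)),
        SpeciesRecord("poly_large", 8.0, "polyploid", (1.0, 0.0, 0.0)),
    ]


@pytest.fixture
def toy_design() -> list[SubplotRecord]:
    return [
        SubplotRecord("p1", "p1a", 0.0, 0.0, False, ph=5.5),
        SubplotRecord("p1", "p1b", 96.0, 0.0, False, ph=5.9),
        SubplotRecord("p2", "p2a", 0.0, 0.0, True, ph=6.2),
        SubplotRecord("p2", "p2b", 0.0, 144.0, True, k_applied=True, ph=6.8),
    ]


@pytest.fixture
def toy_biomass() -> BiomassTable:
    data = pd.DataFrame(
        {
            "p1a": [10.0, 10.0, 0.0],
            "p1b": [4.0, 0.0, 6.0],
            "p2a": [0.0, 5.0, 5.0],
            "p2b": [1.0, 1.0, 8.0],
        },
        index=["grass_small", "herb_mid", "poly_large"],
    )
    return BiomassTable(data)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic community reused by read-only tests."""
    params = SimulationParams(
        n_species=30, n_plots=8, subplots_per_plot=2, occupancy=0.6, seed=42
    )
    return simulate_dataset(params)
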