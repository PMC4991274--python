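"""Partition biomass by genomic group and Grime C-S-R strategy.

Species are cross-classified as diploid/polyploid x small/large genome
(large: 1C >= 5 pg by default) and each species' biomass is split among
competitor / stress-tolerator / ruderal strategies by its C:S:R ratio
(e.g. 10 g at 0.5:0.25:0.25 -> 5 g C, 2.5 g S, 2.5 g R).
"""

from cwm_phylo import (
    SimulationParams,
    csr_treatment_summary,
    group_summaries,
    group_treatment_summary,
    partition_biomass_csr,
    simulate_dataset,
)
from cwm_phylo.csr import csr_group_table

print("worked example:", partition_biomass_csr(10.0, (0.5, 0.25, 0.25)), "g to (C, S, R)")
print()

ds = simulate_dataset(SimulationParams(seed=1))
groups = group_summaries(ds.biomass, ds.species, ds.design, threshold_pg=5.0)
print(group_treatment_summary(groups).to_string(index=False))
print()
csr = csr_group_table(ds.biomass, ds.species, ds.design, threshold_pg=5.0)
print(csr_treatment_summary(csr).head(8).to_string(index=False))

# ratio_mean is each group's average share of subplot biomass within a
# treatment; c_ratio_mean is the share flowing through the competitor
# strategy, the channel through which fertilised plots are expected to
# favour large-genomed polyploids.
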