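"""Biomass yield vs heterogeneity across aggregate sizes (batch culture).

Grows a culture from single cells with the population balance model, then at
48 h measures each size group's biomass production over a 1 h window: the
mean (yield) and the relative standard deviation (heterogeneity) per Poisson
variance decomposition.
"""

import numpy as np

from biosos.assembly import SimulationConfig
from biosos.fixtures import point_mass_density
from biosos.heterogeneity import size_sweep
from biosos.pbm import GrowthParams, KernelParams, evolve_pbm
from biosos.smn import FluxModel, default_network

network = default_network()
flux_model = FluxModel(network)

init = point_mass_density(7.5, 2e5 / 0.73)  # 2e5 cells/mL seeded as singles
snaps, _ = evolve_pbm(init, KernelParams(), GrowthParams(), dt=0.1,
                      horizon=48.0, save_every=1)

radii = np.array([75.0, 90.0, 105.0, 120.0, 135.0])
bounds = np.concatenate([[radii[0] - 7.5], radii + 7.5])
tab = size_sweep(network, flux_model, radii, np.ones_like(radii), times=[48.0],
                 cfg=SimulationConfig(horizon=48.0, save_every=10),
                 pbm_snapshots=snaps, group_boundaries=bounds,
                 n_replicates=100, master_seed=11)
print(tab[["radius_um", "biomass_mean_mM", "biomass_per_cell", "rsd"]]
      .to_string(index=False))
print("\nLarger size groups are rarer and their cores less productive, so the")
print("group biomass mean falls while its relative standard deviation rises:")
print("the yield-heterogeneity trade-off that motivates controlling aggregate")
print("size in stirred iPSC cultures.")
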