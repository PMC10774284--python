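"""Inner-vs-outer metabolic heterogeneity as a function of aggregate size.

Runs a reduced version of the constant-bulk in-silico study (glucose 25,
lactate 5, alanine 0.1 mM held; 5 replicates instead of 30) and prints the
summed |inner - outer| flux index per aggregate radius at 24 h.
"""

from biosos.assembly import SimulationConfig
from biosos.fixtures import CONSTANT_BULK_PRESET, held_bulk_vector
from biosos.heterogeneity import heterogeneity_index_study
from biosos.smn import FluxModel, default_network

network = default_network()
flux_model = FluxModel(network)
cfg = SimulationConfig(bulk_mode="batch", held_species=("GLC", "LAC", "ALA"),
                       seed=3)
u0 = held_bulk_vector(network, CONSTANT_BULK_PRESET)

df = heterogeneity_index_study(network, flux_model, [60.0, 120.0, 240.0],
                               [24.0], cfg, background_X=1e6, n_replicates=5,
                               master_seed=3, u0=u0)
print(df[["radius_um", "time_h", "hetero_index"]].to_string(index=False))
ratio = (df.loc[df.radius_um == 240.0, "hetero_index"].item()
         / df.loc[df.radius_um == 60.0, "hetero_index"].item())
print(f"\n240:60 um index ratio at 24 h: {ratio:.1f}x")
print("Cells at the core of a large aggregate see depleted nutrients and")
print("accumulated waste, so their fluxes deviate strongly from surface cells;")
print("the index grows roughly with the square of the radius.")
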