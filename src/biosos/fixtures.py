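"""Synthetic fixtures: toy networks, initial densities and study presets.

Everything a simulation needs can be generated here, so no external data is
required. The toy networks have closed-form mean dynamics and are the
workhorses of the stochastic/deterministic consistency checks; the presets
mirror the packaged in-silico study conditions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .pbm import AggregateSizeDensity
from .smn import (FluxModel, MetaboliteSpec, MetabolicNetwork, ReactionSpec,
                  default_network, write_network)
from .units import SINGLE_CELL_RADIUS_UM

#: constant-bulk sweep preset: glucose / lactate / alanine pinned (mM)
CONSTANT_BULK_PRESET = {"GLC": 25.0, "LAC": 5.0, "ALA": 0.1}


def toy_decay_network(k: float = 200.0, a0: float = 10.0) -> MetabolicNetwork:
    """Single extracellular conversion A -> B with mass-action rate k * [A].

    For a homogeneous culture of density X the mean follows the closed form
    ``A(t) = a0 exp(-k X 1e-9 t)`` (exponential decay), making this the
    canonical oracle fixture for the stochastic/deterministic comparison.
    """
    mets = [MetaboliteSpec("A", "extracellular", a0, "toy substrate"),
            MetaboliteSpec("B", "extracellular", 0.0, "toy product")]
    rxns = [ReactionSpec("J1", {"A": 1}, {"B": 1}, "mass_action", {"k": k},
                         description="toy first-order conversion")]
    return MetabolicNetwork(mets, rxns)


def toy_chain_network(k1: float = 200.0, k2: float = 100.0) -> MetabolicNetwork:
    """Two-step chain A -> B -> C (extracellular) with mass-action kinetics.

    Linear system with an analytic ODE solution; total A + B + C is
    conserved along every sample path (the stoichiometric columns sum to 0
    for the pooled species).
    """
    mets = [MetaboliteSpec("A", "extracellular", 10.0, "toy substrate"),
            MetaboliteSpec("B", "extracellular", 0.0, "toy intermediate"),
            MetaboliteSpec("C", "extracellular", 0.0, "toy product")]
    rxns = [ReactionSpec("J1", {"A": 1}, {"B": 1}, "mass_action", {"k": k1}),
            ReactionSpec("J2", {"B": 1}, {"C": 1}, "mass_action", {"k": k2})]
    return MetabolicNetwork(mets, rxns)


def toy_cell_network(k: float = 1.0) -> MetabolicNetwork:
    """Intracellular two-pool toy P -> Q for single-cell tau-leap tests."""
    mets = [MetaboliteSpec("P", "intracellular", 10.0, "toy pool"),
            MetaboliteSpec("Q", "intracellular", 0.0, "toy product pool")]
    rxns = [ReactionSpec("J1", {"P": 1}, {"Q": 1}, "mass_action", {"k": k})]
    return MetabolicNetwork(mets, rxns)


def point_mass_density(radius_um: float, count: float,
                       r_min: float = SINGLE_CELL_RADIUS_UM, r_max: float = 600.0,
                       dr: float = 1.0) -> AggregateSizeDensity:
    """All aggregates at one radius: count aggregates per volume in one bin."""
    dens = AggregateSizeDensity.on_radius_grid(r_min, r_max, dr)
    idx = int(np.argmin(np.abs(dens.radius_grid - radius_um)))
    widths = dens.bin_widths()
    vals = dens.values.copy()
    vals[idx] = count / widths[idx]
    return AggregateSizeDensity(size_grid=dens.size_grid, values=vals, time=0.0)


def lognormal_radius_density(median_um: float = 80.0, sigma: float = 0.45,
                             n_aggregates: float = 1e4,
                             r_min: float = SINGLE_CELL_RADIUS_UM,
                             r_max: float = 600.0, dr: float = 1.0) -> AggregateSizeDensity:
    """Lognormal radius distribution scaled to a requested aggregate count.

    Returns the size-domain density phi(x) with int phi dx = n_aggregates
    (the lognormal shape over R converted through the x = R^3 Jacobian).
    """
    dens = AggregateSizeDensity.on_radius_grid(r_min, r_max, dr)
    R = dens.radius_grid
    pdf_R = (1.0 / (R * sigma * np.sqrt(2 * np.pi))
             * np.exp(-((np.log(R) - np.log(median_um)) ** 2) / (2 * sigma**2)))
    phi_x = pdf_R / (3.0 * R**2)
    vals = phi_x / np.sum(phi_x * dens.bin_widths()) * n_aggregates
    return AggregateSizeDensity(size_grid=dens.size_grid, values=vals, time=0.0)


def monolayer_preset() -> dict:
    """Monolayer validation setting: all radii at the single-cell 7.5 um."""
    return {"radii": [SINGLE_CELL_RADIUS_UM], "bulk_mode": "batch",
            "shell_width": SINGLE_CELL_RADIUS_UM}


def generate_fixtures(out_dir) -> dict:
    """Write the packaged fixture set to ``out_dir`` and return the paths.

    Emits the toy decay network, the default-scale network, a lognormal
    initial aggregate density, and YAML presets for the constant-bulk,
    health and size sweeps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    toy = toy_decay_network()
    paths["toy_metabolites"] = out_dir / "toy_metabolites.csv"
    paths["toy_reactions"] = out_dir / "toy_reactions.csv"
    write_network(toy, paths["toy_metabolites"], paths["toy_reactions"])

    full = default_network()
    paths["metabolites"] = out_dir / "metabolites.csv"
    paths["reactions"] = out_dir / "reactions.csv"
    write_network(full, paths["metabolites"], paths["reactions"])

    dens = lognormal_radius_density()
    import pandas as pd
    paths["initial_density"] = out_dir / "initial_density.csv"
    pd.DataFrame({"time_h": 0.0, "radius_um": dens.radius_grid,
                  "density": dens.values}).to_csv(paths["initial_density"], index=False)

    presets = {
        "constant_bulk_sweep": {"held_species": sorted(CONSTANT_BULK_PRESET),
                                "bulk_mM": CONSTANT_BULK_PRESET,
                                "radii_um": [30, 60, 120, 240, 360, 600]},
        "monolayer": monolayer_preset(),
        "health_sweep": {"radii_um": [30, 150, 300, 600],
                         "glucose_mM": [1.0, 2.0, 5.0, 10.0, 20.0],
                         "lactate_mM": 0.0},
        "size_sweep": {"radii_um": list(range(30, 301, 15)),
                       "times_h": [24, 48, 72], "replicates": 100},
    }
    paths["presets"] = out_dir / "presets.yaml"
    paths["presets"].write_text(yaml.safe_dump(presets, sort_keys=True))
    return paths


def held_bulk_vector(network: MetabolicNetwork, overrides: dict) -> np.ndarray:
    """Bulk concentration vector: packaged medium defaults with overrides."""
    ext_ids = [network.metabolite_ids[i] for i in network.ext_index]
    u = network.initial_state()[network.ext_index].copy()
    for sp, val in overrides.items():
        u[ext_ids.index(sp)] = val
    return u
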