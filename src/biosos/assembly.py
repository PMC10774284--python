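"""Culture-scale assembly of the aggregation, diffusion and reaction modules.

The simulator advances the culture in fixed intervals ``dt`` (default 0.1 h):

1. the aggregate population (either static radius groups or a population
   balance run sampled at each interval) fixes the per-group shell cell
   densities ``G_l^(n)``;
2. per group, the quasi-steady shell profiles equilibrate the extracellular
   micro-environment against the current per-shell fluxes;
3. each (group, shell, reaction) channel fires a Poisson count with
   intensity ``G_l^(n) v_j dt`` (volume-scaled tau-leap, rates frozen per
   substep) that updates the bulk concentrations (batch mode), while the
   shell's representative cell advances its intracellular pools with a
   tau-leap at the single-cell system size.

Cells within a shell are treated as homogeneous; both updates share the
same rate function, so the expectation of either matches the deterministic
dynamic flux-balance ODE exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pbm import AggregateSizeDensity, SizeGroups, group_aggregates, to_radius_density
from .rdm import (DEFAULT_POROSITY, DEFAULT_SHELL_WIDTH_UM, DEFAULT_TORTUOSITY,
                  DiffusionParams, MicroEnvProfile, ShellDecomposition, solve_quasi_steady)
from .smn import DEFAULT_OMEGA, FluxModel, MetabolicNetwork
from .units import (CELL_FLUX_TO_MM, FLUX_TO_MM_PER_CELL_PER_ML,
                    SINGLE_CELL_RADIUS_UM, SINGLE_CELL_VOLUME_UM3)

logger = logging.getLogger(__name__)

#: system size of the bulk update: Poisson events per mM of culture volume;
#: a 0.2 mM/h nominal glucose drawdown then yields 2e4 events per 0.1 h step.
DEFAULT_OMEGA_BULK = 1e6

#: single-cell volume expressed in mL, linking population and per-cell updates
_CELL_VOLUME_ML = SINGLE_CELL_VOLUME_UM3 * 1e-12


def shell_cell_density(M_l: float, porosity: float, shells: ShellDecomposition,
                       R0: float = SINGLE_CELL_RADIUS_UM) -> np.ndarray:
    """Cells per unit culture volume in each shell of a group of aggregates.

    ``G_l^(n) = M_l (1 - eps) ((R^(n))^3 - (R^(n-1))^3) / R0^3`` — the group
    aggregate density times the number of cells packed (at solid fraction
    1 - eps) in the shell.
    """
    b = shells.boundaries
    return M_l * (1.0 - porosity) * np.diff(b**3) / R0**3


@dataclass
class AggregatePopulation:
    """Static aggregate population: representative radius and density per group."""

    radii: np.ndarray       # R_l, um
    densities: np.ndarray   # M_l, aggregates per mL

    def __post_init__(self) -> None:
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        self.densities = np.atleast_1d(np.asarray(self.densities, float))
        if self.radii.shape != self.densities.shape:
            raise ValueError("radii and densities must have matching shapes")
        if np.any(self.radii < SINGLE_CELL_RADIUS_UM):
            raise ValueError("aggregate radii cannot be below the single-cell radius")

    @classmethod
    def from_size_groups(cls, groups: SizeGroups) -> "AggregatePopulation":
        return cls(radii=groups.group_mid_radii(), densities=groups.group_density)

    @classmethod
    def monolayer(cls, X: float, porosity: float = DEFAULT_POROSITY) -> "AggregatePopulation":
        """All aggregates are single cells of radius 7.5 um.

        The density is chosen so the shell cell density equals X exactly
        (the (1 - eps) packing factor cancels against the aggregate count).
        """
        return cls(radii=[SINGLE_CELL_RADIUS_UM], densities=[X / (1.0 - porosity)])

    @classmethod
    def single_aggregate(cls, radius: float) -> "AggregatePopulation":
        """One aggregate per mL of the given radius (in-silico single-aggregate study)."""
        return cls(radii=[radius], densities=[1.0])

    def total_cells(self, porosity: float = DEFAULT_POROSITY) -> float:
        return float(np.sum(self.densities * (1.0 - porosity)
                            * (self.radii / SINGLE_CELL_RADIUS_UM) ** 3))


@dataclass
class SimulationConfig:
    """Knobs of the coupled culture simulation."""

    dt: float = 0.1                      # h
    horizon: float = 72.0                # h
    shell_width: float = DEFAULT_SHELL_WIDTH_UM
    porosity: float = DEFAULT_POROSITY
    tortuosity: float = DEFAULT_TORTUOSITY
    omega_bulk: float = DEFAULT_OMEGA_BULK
    omega_cell: float = DEFAULT_OMEGA
    bulk_mode: str = "batch"             # "batch" | "held"
    held_species: tuple = ()             # species ids pinned in batch mode
    seed: int = 0
    save_every: int = 1
    qss_tol: float = 1e-6
    qss_damping: float = 0.6
    n_substeps: int = 10                 # intracellular tau-leap substeps per dt

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.bulk_mode not in ("batch", "held"):
            raise ValueError("bulk_mode must be 'batch' or 'held'")


@dataclass
class CultureState:
    """Snapshot of the coupled culture at one time point."""

    time: float
    u: np.ndarray                        # bulk extracellular concentrations (mM)
    s: list                              # per group: (n_shells, n_int) intracellular mM
    G: list                              # per group: (n_shells,) cells per mL
    v: list                              # per group: (n_shells, k) per-cell fluxes
    c: list                              # per group: (n_shells, n_ext) local conc (mM)
    X: float = 0.0
    delta_u: np.ndarray | None = None


@dataclass
class Trajectory:
    """Time course of a coupled simulation."""

    network: MetabolicNetwork
    states: list
    config: SimulationConfig
    population: AggregatePopulation
    clamp_events: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.array([st.time for st in self.states])

    def bulk(self, species: str) -> np.ndarray:
        i = list(np.asarray(self.network.metabolite_ids)[self.network.ext_index]).index(species)
        return np.array([st.u[i] for st in self.states])

    def bulk_frame(self) -> pd.DataFrame:
        ext_ids = [self.network.metabolite_ids[i] for i in self.network.ext_index]
        rows = []
        for st in self.states:
            for i, sp in enumerate(ext_ids):
                rows.append({"time_h": st.time, "species": sp, "conc_mM": st.u[i]})
        return pd.DataFrame(rows)

    def flux_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.states:
            for l, v_l in enumerate(st.v):
                for n in range(v_l.shape[0]):
                    for j, rid in enumerate(self.network.reaction_ids):
                        rows.append({"time_h": st.time, "group": l, "shell": n,
                                     "reaction": rid, "v": v_l[n, j],
                                     "v_bar": v_l[n, j] * st.G[l][n]})
        return pd.DataFrame(rows)


def _load_diffusion_for(network: MetabolicNetwork, porosity: float,
                        tortuosity: float) -> DiffusionParams:
    """Diffusion parameters for the network's extracellular species, from the
    packaged aqueous-diffusivity table (unknown species fall back to the
    glucose value)."""
    from pathlib import Path
    table = pd.read_csv(Path(__file__).parent / "data" / "diffusion.csv")
    lookup = dict(zip(table["species"], table["D_aqueous_um2_per_h"]))
    ext_ids = [network.metabolite_ids[i] for i in network.ext_index]
    fallback = lookup.get("GLC", 2.4e6)
    D = np.array([lookup.get(sp, fallback) for sp in ext_ids])
    return DiffusionParams(D_aqueous=D, porosity=porosity, tortuosity=tortuosity)


def solve_group_profile(network: MetabolicNetwork, flux_model: FluxModel,
                        radius: float, u_bulk: np.ndarray, s_shells: np.ndarray,
                        cfg: SimulationConfig,
                        diffusion: DiffusionParams | None = None) -> MicroEnvProfile:
    """Quasi-steady micro-environment of one aggregate group.

    Monolayer-sized aggregates (R <= one cell radius) short-circuit to a flat
    profile equal to the bulk.
    """
    shells = ShellDecomposition.equal_width(radius, cfg.shell_width)
    if diffusion is None:
        diffusion = _load_diffusion_for(network, cfg.porosity, cfg.tortuosity)
    if radius <= SINGLE_CELL_RADIUS_UM + 1e-9:
        n_sh = shells.n_shells
        prof = MicroEnvProfile(
            shells=shells, u_bulk=np.asarray(u_bulk, float),
            u_shell=np.tile(u_bulk, (n_sh, 1)).astype(float),
            c_mid=np.tile(u_bulk, (n_sh, 1)).astype(float),
            c_center=np.asarray(u_bulk, float).copy(),
            rho=np.zeros((n_sh, len(u_bulk))),
            depleted=np.zeros((n_sh, len(u_bulk)), dtype=bool))
        prof.s = s_shells
        return prof
    return solve_quasi_steady(flux_model, shells, u_bulk, s_shells, network,
                              diffusion, network.ext_index, damping=cfg.qss_damping,
                              tol=cfg.qss_tol)


def step_population(u: np.ndarray, s_groups: list, population: AggregatePopulation,
                    network: MetabolicNetwork, flux_model: FluxModel,
                    cfg: SimulationConfig, rng: np.random.Generator,
                    diffusion: DiffusionParams) -> tuple:
    """One dt interval of the coupled update. Returns (u_new, s_new, state_record).

    For each group and shell, the channel intensity is the volume-scaled flux
    ``G_l^(n) v_j`` converted to mM/h of culture volume; one Poisson draw per
    channel feeds both the bulk increment and the shell's per-cell
    intracellular increment (linked through the cell volume).
    """
    ext_ids = [network.metabolite_ids[i] for i in network.ext_index]
    N_ext = network.N[network.ext_index, :]
    N_int = network.N[network.int_index, :]
    from .rdm import _assemble_state

    held_idx = [ext_ids.index(sp) for sp in cfg.held_species if sp in ext_ids]
    n_sub = max(1, int(cfg.n_substeps))
    h = cfg.dt / n_sub
    u_start = u.copy()
    du = np.zeros_like(u)
    s_new = [s.copy() for s in s_groups]
    v_rec, c_rec, G_rec = [], [], []
    clamps = 0

    # shell profiles are refreshed once per interval, against the bulk at the
    # interval start; the faster intracellular pools are advanced on substeps
    groups = []
    for l, (R_l, M_l) in enumerate(zip(population.radii, population.densities)):
        shells = ShellDecomposition.equal_width(R_l, cfg.shell_width)
        G = shell_cell_density(M_l, cfg.porosity, shells)
        prof = solve_group_profile(network, flux_model, R_l, u_start, s_new[l], cfg,
                                   diffusion)
        groups.append((G, prof.c_mid.copy()))
        v_rec.append(np.zeros((shells.n_shells, network.n_reactions)))
        c_rec.append(prof.c_mid.copy())
        G_rec.append(G)

    u_cur = u.copy()
    for _ in range(n_sub):
        du_sub = np.zeros_like(u)
        for l, (G, c_mid) in enumerate(groups):
            U = _assemble_state(network, network.ext_index, c_mid, s_new[l])
            v = flux_model.rates(U)                  # (n_shells, k) per-cell fluxes
            v_rec[l] += v / n_sub
            rate_mM = v * G[:, None] * FLUX_TO_MM_PER_CELL_PER_ML  # mM/h of culture
            lam = np.maximum(rate_mM * h * cfg.omega_bulk, 0.0)
            counts = rng.poisson(lam)                # (n_shells, k) events
            du_sub += ((counts / cfg.omega_bulk) @ N_ext.T).sum(axis=0)
            # representative-cell intracellular update at the single-cell
            # system size (noise independent of how rare the group is)
            lam_cell = np.maximum(v * h * cfg.omega_cell, 0.0)
            counts_cell = rng.poisson(lam_cell)
            s_new[l] = s_new[l] + (counts_cell * (CELL_FLUX_TO_MM / cfg.omega_cell)) @ N_int.T
            neg = s_new[l] < 0
            if np.any(neg):
                clamps += int(np.sum(neg))
                s_new[l][neg] = 0.0
        if cfg.bulk_mode == "held":
            du_sub[:] = 0.0
        else:
            du_sub[held_idx] = 0.0
        u_cur = u_cur + du_sub
        neg = u_cur < 0
        if np.any(neg):
            clamps += int(np.sum(neg))
            logger.warning("bulk species %s driven negative; clamped to 0",
                           [ext_ids[i] for i in np.where(neg)[0]])
            u_cur[neg] = 0.0
        du += du_sub
    return u_cur, s_new, (du, v_rec, c_rec, G_rec, clamps)


def simulate(cfg: SimulationConfig, network: MetabolicNetwork, flux_model: FluxModel,
             population: AggregatePopulation, u0: np.ndarray | None = None,
             s0: np.ndarray | None = None,
             rng: np.random.Generator | None = None,
             pbm_snapshots: list | None = None,
             group_boundaries: np.ndarray | None = None,
             X0: float | None = None) -> Trajectory:
    """Run the coupled culture simulation for one replicate.

    With ``pbm_snapshots`` (output of :func:`biosos.pbm.evolve_pbm` on an
    absolute aggregate density, one snapshot per dt interval) the aggregate
    population is re-derived each interval by grouping the evolving density
    over ``group_boundaries``; otherwise ``population`` is static
    (one-way coupling: metabolite state never feeds back into aggregation).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    init = network.initial_state()
    u = init[network.ext_index].copy() if u0 is None else np.asarray(u0, float).copy()
    diffusion = _load_diffusion_for(network, cfg.porosity, cfg.tortuosity)

    def population_at(step: int) -> AggregatePopulation:
        if pbm_snapshots is None:
            return population
        snap = pbm_snapshots[min(step, len(pbm_snapshots) - 1)]
        phi_R = to_radius_density(snap)
        z_density = snap.total_count()
        with warnings.catch_warnings():
            # sweeping a sub-range of the distribution is intentional here
            warnings.simplefilter("ignore", UserWarning)
            groups = group_aggregates(phi_R, group_boundaries, z_density)
        return AggregatePopulation.from_size_groups(groups)

    pop = population_at(0)
    s_int0 = init[network.int_index]
    s_groups = []
    for R_l in pop.radii:
        n_sh = ShellDecomposition.equal_width(R_l, cfg.shell_width).n_shells
        s_groups.append(np.tile(s_int0 if s0 is None else np.asarray(s0, float), (n_sh, 1)))

    n_steps = int(round(cfg.horizon / cfg.dt))
    states = [CultureState(time=0.0, u=u.copy(), s=[s.copy() for s in s_groups],
                           G=[shell_cell_density(M, cfg.porosity,
                                                 ShellDecomposition.equal_width(R, cfg.shell_width))
                              for R, M in zip(pop.radii, pop.densities)],
                           v=[np.zeros((s.shape[0], network.n_reactions)) for s in s_groups],
                           c=[np.tile(u, (s.shape[0], 1)) for s in s_groups],
                           X=pop.total_cells(cfg.porosity))]
    total_clamps = 0
    t = 0.0
    for step in range(n_steps):
        new_pop = population_at(step)
        if pbm_snapshots is not None and len(new_pop.radii) == len(pop.radii):
            pop = new_pop  # shell counts per group are fixed by the boundaries
        u, s_groups, (du, v_rec, c_rec, G_rec, clamps) = step_population(
            u, s_groups, pop, network, flux_model, cfg, rng, diffusion)
        total_clamps += clamps
        t += cfg.dt
        if (step + 1) % cfg.save_every == 0 or step == n_steps - 1:
            states.append(CultureState(time=t, u=u.copy(),
                                       s=[s.copy() for s in s_groups],
                                       G=G_rec, v=v_rec, c=c_rec,
                                       X=pop.total_cells(cfg.porosity), delta_u=du))
    return Trajectory(network=network, states=states, config=cfg,
                      population=pop, clamp_events=total_clamps)


def simulate_monolayer(cfg: SimulationConfig, network: MetabolicNetwork,
                       flux_model: FluxModel, X: float,
                       u0: np.ndarray | None = None,
                       rng: np.random.Generator | None = None) -> Trajectory:
    """Degenerate configuration: every aggregate is a single 7.5 um cell.

    One group, one shell, no diffusion gradient — the shell concentration is
    the bulk itself, so the replicate mean reproduces the deterministic
    flux-balance ODE (homogeneous population limit).
    """
    return simulate(cfg, network, flux_model,
                    AggregatePopulation.monolayer(X, cfg.porosity), u0=u0, rng=rng)


def simulate_replicates(cfg: SimulationConfig, network: MetabolicNetwork,
                        flux_model: FluxModel, population: AggregatePopulation,
                        n_replicates: int = 30, master_seed: int | None = None,
                        **kwargs) -> list:
    """Independent replicate runs with seeds derived from a master seed.

    Seeds are spawned from ``numpy.random.SeedSequence(master_seed)`` so the
    replicate set is reproducible and independent of execution order.
    """
    if master_seed is None:
        master_seed = cfg.seed
    seqs = np.random.SeedSequence(master_seed).spawn(n_replicates)
    return [simulate(cfg, network, flux_model, population,
                     rng=np.random.default_rng(seq), **kwargs) for seq in seqs]


def deterministic_ode_trajectory(network: MetabolicNetwork, flux_model: FluxModel,
                                 X: float, horizon: float, dt: float = 0.1,
                                 u0: np.ndarray | None = None,
                                 n_substeps: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic dynamic flux-balance trajectory for a homogeneous culture.

    Integrates du/dt = N v(u) with exactly the stochastic simulator's
    discretization: the extracellular state seen by the rate laws is frozen
    over each dt interval (the quasi-steady profile is refreshed once per
    interval) while intracellular pools advance on substeps. Bulk species are
    scaled by the cell density X and intracellular species by the cell
    volume. This is the infinite-system-size limit of the monolayer run.
    """
    from .units import CELL_FLUX_TO_MM
    init = network.initial_state()
    if u0 is not None:
        init = init.copy()
        init[network.ext_index] = u0
    n_steps = int(round(horizon / dt))
    n_sub = max(1, n_substeps)
    h = dt / n_sub
    out = np.empty((n_steps + 1, init.size))
    out[0] = init
    state = init.copy()
    scale = np.empty(init.size)
    scale[network.ext_index] = X * FLUX_TO_MM_PER_CELL_PER_ML
    scale[network.int_index] = CELL_FLUX_TO_MM
    for g in range(n_steps):
        frozen_ext = state[network.ext_index].copy()
        for _ in range(n_sub):
            probe = state.copy()
            probe[network.ext_index] = frozen_ext
            v = flux_model.rates(probe)
            state = np.maximum(state + (network.N @ v) * scale * h, 0.0)
        out[g + 1] = state
    times = np.arange(n_steps + 1) * dt
    return times, out
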