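"""Variance decomposition and heterogeneity metrics for aggregate cultures.

All second-moment formulas follow from the Poisson channel model: the
concentration change of species i contributed by shell n of group l over an
interval dt is a sum of independent Poisson counts scaled by stoichiometry,

    mu_{i,l}      = sum_n sum_j vbar_j^(l,n) dt N_ij
    sigma2_{i,l}  = sum_n sum_j vbar_j^(l,n) dt N_ij^2 / omega

(mean independent of the system size omega, variance shrinking as 1/omega),
and group contributions add because aggregates are modeled as independent.
RSD = sigma / mu quantifies the relative heterogeneity; for a single unit
channel it reduces to 1/sqrt(vbar dt omega).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rdm import MicroEnvProfile, ShellDecomposition
from .units import FLUX_TO_MM_PER_CELL_PER_ML


@dataclass(frozen=True)
class HealthCriteria:
    """Micro-environment viability thresholds (media concentrations, mM)."""

    glucose_min: float = 2.5
    lactate_max: float = 40.0

    def __post_init__(self) -> None:
        if self.glucose_min <= 0 or self.lactate_max <= 0:
            raise ValueError("health thresholds must be positive")


def group_variance(v_bar: np.ndarray, N_row: np.ndarray, dt: float,
                   omega: float = 1.0, mode: str = "analytic",
                   rng: np.random.Generator | None = None,
                   n_replicates: int = 10000) -> tuple[float, float]:
    """Mean and variance of one species' increment from a group's shell fluxes.

    ``v_bar`` is (n_shells, k) volume-scaled rates (any consistent rate unit),
    ``N_row`` the species' row of the stoichiometric matrix. ``analytic``
    mode applies the Poisson identity; ``empirical`` mode draws
    ``n_replicates`` realizations of the channel counts. Returns
    (sigma2, mu).
    """
    v_bar = np.atleast_2d(np.asarray(v_bar, float))
    N_row = np.asarray(N_row, float)
    lam = v_bar * dt * omega
    mu = float(np.sum(lam / omega * N_row[None, :]))
    if mode == "analytic":
        sigma2 = float(np.sum(lam * (N_row[None, :] / omega) ** 2))
        return sigma2, mu
    if mode != "empirical":
        raise ValueError("mode must be 'analytic' or 'empirical'")
    if n_replicates < 2:
        raise ValueError("empirical mode needs at least 2 replicates")
    if rng is None:
        rng = np.random.default_rng(0)
    draws = rng.poisson(lam, size=(n_replicates,) + lam.shape) / omega
    increments = np.tensordot(draws, N_row, axes=([2], [0])).sum(axis=1)
    return float(np.var(increments, ddof=1)), mu


def rsd(sigma2: float, mu: float) -> float:
    """Relative standard deviation sigma / mu; undefined (NaN) when mu = 0."""
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    if mu == 0:
        warnings.warn("RSD undefined for zero mean; reporting NaN", stacklevel=2)
        return float("nan")
    return float(np.sqrt(sigma2) / mu)


def decompose_population_variance(sigma2_groups) -> tuple[float, np.ndarray]:
    """Total variance and per-group shares under aggregate independence.

    sigma2_total = sum_l sigma2_l; shares sum to 1.
    """
    sigma2_groups = np.asarray(sigma2_groups, float)
    if np.any(sigma2_groups < 0):
        raise ValueError("group variances must be non-negative")
    total = float(np.sum(sigma2_groups))
    shares = sigma2_groups / total if total > 0 else np.full_like(sigma2_groups, np.nan)
    return total, shares


def standardize_fluxes(group_mean_fluxes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score per-reaction group-average fluxes across aggregate groups.

    ``group_mean_fluxes`` is (L, k): the shell-average flux of each reaction
    in each of L >= 2 size groups. Returns (z, flat_flag) where z uses the
    sample standard deviation over groups (denominator L - 1) and
    ``flat_flag`` marks reactions with zero spread (z reported as 0).
    """
    V = np.atleast_2d(np.asarray(group_mean_fluxes, float))
    if V.shape[0] < 2:
        raise ValueError("standardization requires at least two groups")
    mean = V.mean(axis=0, keepdims=True)
    sd = V.std(axis=0, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (V - mean) / sd_safe
    z[:, flat] = 0.0
    return z, flat


def classify_health(profile: MicroEnvProfile, species_ids: list,
                    criteria: HealthCriteria = HealthCriteria(),
                    glucose: str = "GLC", lactate: str = "LAC",
                    cell_weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Per-shell health flags and the cell-count-weighted unhealthy fraction.

    A shell is unhealthy iff its local extracellular glucose falls below
    ``glucose_min`` or its lactate exceeds ``lactate_max``. Weights default
    to the shell cell counts (proportional to shell volume for uniform
    packing).
    """
    for sp in (glucose, lactate):
        if sp not in species_ids:
            raise ValueError(f"profile lacks required species {sp}")
    g = profile.c_mid[:, species_ids.index(glucose)]
    l = profile.c_mid[:, species_ids.index(lactate)]
    unhealthy = (g < criteria.glucose_min) | (l > criteria.lactate_max)
    if cell_weights is None:
        cell_weights = np.diff(profile.shells.boundaries**3)
    fraction = float(np.sum(cell_weights * unhealthy) / np.sum(cell_weights))
    return unhealthy, fraction


def inner_outer_heterogeneity(v_shells: np.ndarray,
                              reaction_ids: list | None = None) -> dict:
    """Inner-vs-outer flux comparison for one aggregate at one time.

    ``v_shells`` is (n_shells, k) per-cell fluxes, shell 0 innermost. The
    inner cell is sampled at the innermost shell midpoint and the outer cell
    at the outermost shell midpoint. Returns the per-reaction inner/outer
    ratios (NaN where the outer flux is zero, excluded from the index with a
    flag) and the summed absolute deviation index sum_j |v_inner - v_outer|.
    """
    v_shells = np.atleast_2d(np.asarray(v_shells, float))
    inner, outer = v_shells[0], v_shells[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(outer > 0, inner / np.where(outer > 0, outer, 1.0), np.nan)
    index = float(np.sum(np.abs(inner - outer)))
    out = {"ratios": ratios, "index": index,
           "excluded": np.asarray(outer == 0)}
    if reaction_ids is not None:
        out["table"] = pd.DataFrame({"reaction": reaction_ids, "v_inner": inner,
                                     "v_outer": outer, "ratio": ratios})
    return out


def heterogeneity_index_study(network, flux_model, radii, times, cfg,
                              background_X: float = 1e6,
                              n_replicates: int = 30,
                              master_seed: int | None = None,
                              u0: np.ndarray | None = None,
                              window_h: float = 1.0) -> pd.DataFrame:
    """Replicate-averaged inner/outer heterogeneity index per radius and time.

    Each radius is simulated as a culture of identical aggregates at a
    density giving ``background_X`` cells per mL, so the non-held bulk
    species evolve on a realistic culture timescale while (in the default
    sweep configuration) glucose/lactate/alanine are held constant. The
    per-cell fluxes "at" a measurement time are estimated over the trailing
    ``window_h`` hours of trajectory and averaged over replicates before the
    inner-minus-outer difference is taken, so the index measures the
    systematic spatial gradient rather than sampling noise.
    """
    from .assembly import AggregatePopulation, simulate_replicates

    rows = []
    for radius in np.atleast_1d(radii):
        n_agg = background_X / (AggregatePopulation.single_aggregate(radius)
                                .total_cells(cfg.porosity))
        pop = AggregatePopulation(radii=[radius], densities=[n_agg])
        horizon = max(times)
        run_cfg = cfg
        if cfg.horizon != horizon:
            from dataclasses import replace
            run_cfg = replace(cfg, horizon=horizon)
        trajs = simulate_replicates(run_cfg, network, flux_model, pop,
                                    n_replicates=n_replicates,
                                    master_seed=master_seed, u0=u0)
        for t_query in np.atleast_1d(times):
            v_stack, indices = [], []
            for traj in trajs:
                t_arr = traj.times
                sel = np.where((t_arr > t_query - window_h - 1e-9)
                               & (t_arr <= t_query + 1e-9))[0]
                if sel.size == 0:
                    sel = np.array([int(np.argmin(np.abs(t_arr - t_query)))])
                v_window = np.mean([traj.states[k].v[0] for k in sel], axis=0)
                v_stack.append(v_window)
                indices.append(inner_outer_heterogeneity(v_window)["index"])
            # fluxes are averaged over replicates first, so the index reflects
            # the systematic spatial gradient rather than single-cell noise
            res = inner_outer_heterogeneity(np.mean(v_stack, axis=0))
            rows.append({"radius_um": float(radius), "time_h": float(t_query),
                         "hetero_index": res["index"],
                         "index_replicate_mean": float(np.mean(indices)),
                         "index_replicate_sd": (float(np.std(indices, ddof=1))
                                                if len(indices) > 1 else 0.0),
                         "n_replicates": len(indices)})
    return pd.DataFrame(rows)


def unhealthy_fraction_sweep(network, flux_model, radii, bulk_overrides: dict,
                             cfg, criteria: HealthCriteria = HealthCriteria()) -> pd.DataFrame:
    """Steady-profile unhealthy-cell fraction across aggregate radii.

    ``bulk_overrides`` maps species ids to bulk concentrations (mM); other
    species keep the packaged medium defaults. Deterministic given the
    quasi-steady profile (initial intracellular pools, no sampling).
    """
    from .assembly import SimulationConfig, solve_group_profile

    ext_ids = [network.metabolite_ids[i] for i in network.ext_index]
    u = network.initial_state()[network.ext_index].copy()
    for sp, val in bulk_overrides.items():
        u[ext_ids.index(sp)] = val
    s0 = network.initial_state()[network.int_index]
    rows = []
    for radius in np.atleast_1d(radii):
        shells = ShellDecomposition.equal_width(radius, cfg.shell_width)
        s_shells = np.tile(s0, (shells.n_shells, 1))
        prof = solve_group_profile(network, flux_model, radius, u, s_shells, cfg)
        _, frac = classify_health(prof, ext_ids, criteria)
        rows.append({"radius_um": float(radius), "unhealthy_fraction": frac,
                     "unhealthy_percent": 100.0 * frac})
    return pd.DataFrame(rows)


def size_sweep(network, flux_model, radii, group_densities, times, cfg,
               window_h: float = 1.0, biomass: str = "BIOM",
               master_seed: int = 0, n_replicates: int = 100,
               pbm_snapshots: list | None = None,
               group_boundaries: np.ndarray | None = None) -> pd.DataFrame:
    """Biomass yield and RSD per aggregate size group (yield-heterogeneity trade-off).

    Runs one batch culture containing all the size groups, then at each
    requested time measures the biomass increment over a ``window_h`` window
    per group: analytically (Poisson identity on the volume-scaled biomass
    flux) and empirically over ``n_replicates`` sampled windows. The RSD is
    computed on the biomass-species increment of each group. With
    ``pbm_snapshots``/``group_boundaries`` the group densities track the
    evolving population balance solution instead of staying static, so the
    rarity of large aggregates enters the group variance as it does in the
    full model.
    """
    from .assembly import AggregatePopulation, simulate

    pop = AggregatePopulation(radii=radii, densities=group_densities)
    from dataclasses import replace
    run_cfg = replace(cfg, horizon=float(max(times)))
    traj = simulate(run_cfg, network, flux_model, pop,
                    rng=np.random.default_rng(master_seed),
                    pbm_snapshots=pbm_snapshots, group_boundaries=group_boundaries)
    bio_row = network.N[network.species(biomass), :]
    t_arr = traj.times
    rng = np.random.default_rng(master_seed + 1)
    rows = []
    for t_query in np.atleast_1d(times):
        k = int(np.argmin(np.abs(t_arr - t_query)))
        st = traj.states[k]
        for l, radius in enumerate(np.atleast_1d(radii)):
            v_bar = st.v[l] * st.G[l][:, None] * FLUX_TO_MM_PER_CELL_PER_ML
            sigma2, mu = group_variance(v_bar, bio_row, window_h, omega=cfg.omega_bulk)
            sig2_emp, _ = group_variance(v_bar, bio_row, window_h, omega=cfg.omega_bulk,
                                         mode="empirical", rng=rng,
                                         n_replicates=n_replicates)
            cells = float(np.sum(st.G[l]))
            rows.append({"time_h": float(t_query), "radius_um": float(radius),
                         "biomass_mean_mM": mu,
                         "biomass_per_cell": mu / cells if cells > 0 else np.nan,
                         "rsd": rsd(sigma2, mu) if mu > 0 else np.nan,
                         "rsd_empirical": rsd(sig2_emp, mu) if mu > 0 else np.nan})
    return pd.DataFrame(rows)
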