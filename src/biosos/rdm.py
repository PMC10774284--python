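"""Quasi-steady reaction-diffusion micro-environments inside aggregates.

An aggregate of radius R is partitioned into concentric spherical shells of
equal thickness. Within each shell the volumetric reaction rate ``rho``
(mM/h, negative for net consumption) is constant, so the steady diffusion
equation ``D (1/r^2) d/dr (r^2 dc/dr) + rho = 0`` has the closed form

    c(r) = u + rho (R_outer^2 - r^2) / (6 D)

per shell, chained inward by interface continuity: the outermost shell's
outer boundary is the bulk concentration, and each inner shell's outer
boundary equals the adjacent shell's concentration at the shared radius.
For a spatially uniform rho the chain telescopes to the exact whole-sphere
solution; for piecewise-constant rho it is the quasi-steady approximation
used throughout the simulator and validated against a finite-difference
solve of the full spherical problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .units import GAMMA_TO_MM_PER_H, unit_gamma

DEFAULT_POROSITY = 0.27
DEFAULT_TORTUOSITY = 1.5
DEFAULT_SHELL_WIDTH_UM = 15.0  # about two cell diameters


@dataclass(frozen=True)
class DiffusionParams:
    """Aqueous diffusivities (um^2/h) plus aggregate porosity and tortuosity."""

    D_aqueous: np.ndarray
    porosity: float = DEFAULT_POROSITY
    tortuosity: float = DEFAULT_TORTUOSITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "D_aqueous", np.atleast_1d(np.asarray(self.D_aqueous, float)))
        if np.any(self.D_aqueous <= 0):
            raise ValueError("aqueous diffusivities must be positive")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")
        if self.tortuosity < 1.0:
            raise ValueError("tortuosity must be >= 1")


def effective_diffusivity(params: DiffusionParams) -> np.ndarray:
    """Effective diffusivity D = (eps / tau) * D_aqueous inside the aggregate."""
    return (params.porosity / params.tortuosity) * params.D_aqueous


@dataclass
class ShellDecomposition:
    """Concentric spherical shells [R^(n-1), R^(n)] covering an aggregate."""

    aggregate_radius: float
    boundaries: np.ndarray  # R^(0)=0 < R^(1) < ... < R^(N) = aggregate_radius

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries[0] != 0.0 or not np.isclose(self.boundaries[-1], self.aggregate_radius):
            raise ValueError("shell boundaries must run from 0 to the aggregate radius")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("shell boundaries must be strictly increasing")

    @classmethod
    def equal_width(cls, aggregate_radius: float,
                    shell_width: float = DEFAULT_SHELL_WIDTH_UM) -> "ShellDecomposition":
        """N = ceil(R / width) equally sized shells (the packaged default rule)."""
        n = max(1, int(np.ceil(aggregate_radius / shell_width)))
        return cls(aggregate_radius=aggregate_radius,
                   boundaries=np.linspace(0.0, aggregate_radius, n + 1))

    @property
    def n_shells(self) -> int:
        return self.boundaries.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    @property
    def volumes(self) -> np.ndarray:
        """Shell volumes (4 pi / 3)(R^(n)^3 - R^(n-1)^3), um^3."""
        return (4.0 * np.pi / 3.0) * np.diff(self.boundaries**3)


@dataclass
class MicroEnvProfile:
    """Per-shell extracellular concentrations of the diffusing species.

    ``c_mid`` holds the concentration at each shell midpoint (the value the
    shell's cells experience), ``u_shell`` the boundary value at each shell's
    outer radius, and ``depleted`` flags (shell, species) pairs clamped at 0.
    """

    shells: ShellDecomposition
    u_bulk: np.ndarray                  # (n_species,)
    u_shell: np.ndarray                 # (n_shells, n_species)
    c_mid: np.ndarray                   # (n_shells, n_species)
    c_center: np.ndarray                # (n_species,)
    rho: np.ndarray                     # (n_shells, n_species), mM/h
    depleted: np.ndarray                # bool (n_shells, n_species)
    s: np.ndarray | None = None         # intracellular state per shell, if tracked
    n_iterations: int = 0
    residuals: list = field(default_factory=list)

    def concentration_at(self, r: float) -> np.ndarray:
        """Evaluate the piecewise profile at radius r (um)."""
        n = min(np.searchsorted(self.shells.boundaries[1:], r, side="left"),
                self.shells.n_shells - 1)
        u = self.u_shell[n]
        R_out = self.shells.boundaries[n + 1]
        # D is folded into rho_over_6D at construction; recompute from stored pieces
        c = u + self._rho_over_6D[n] * (R_out**2 - r**2)
        return np.maximum(c, 0.0)


def volumetric_rates(flux: np.ndarray, N: np.ndarray, gamma: float) -> np.ndarray:
    """Per-species volumetric rates rho = N @ v * gamma.

    ``flux`` may be a vector (k,) or a stack (n_shells, k); the result is in
    the gamma-scaled units (multiply by ``GAMMA_TO_MM_PER_H`` for mM/h).
    Negative entries are net consumption, positive net production.
    """
    flux = np.asarray(flux, dtype=float)
    N = np.asarray(N, dtype=float)
    if flux.ndim == 1:
        if N.shape[1] != flux.shape[0]:
            raise ValueError("stoichiometric matrix and flux vector do not conform")
        return (N @ flux) * gamma
    if N.shape[1] != flux.shape[1]:
        raise ValueError("stoichiometric matrix and flux stack do not conform")
    return (flux @ N.T) * gamma


def shell_profile(rho: np.ndarray, D_eff: np.ndarray, shells: ShellDecomposition,
                  u_bulk: np.ndarray, literal_eq5: bool = False) -> MicroEnvProfile:
    """Chained analytic quasi-steady concentration profile (mM).

    ``rho`` is (n_shells, n_species) in mM/h, signed; ``D_eff`` (n_species,)
    in um^2/h; ``u_bulk`` (n_species,) in mM. With ``literal_eq5=True`` the
    profile multiplies rho by D instead of dividing (the printed form, for
    audit only — dimensionally inconsistent).
    """
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    D_eff = np.atleast_1d(np.asarray(D_eff, dtype=float))
    u_bulk = np.atleast_1d(np.asarray(u_bulk, dtype=float))
    n_sh = shells.n_shells
    if rho.shape != (n_sh, u_bulk.size):
        raise ValueError(f"rho must have shape ({n_sh}, {u_bulk.size}), got {rho.shape}")
    factor = rho * D_eff[None, :] / 6.0 if literal_eq5 else rho / (6.0 * D_eff[None, :])

    bounds = shells.boundaries
    mids = shells.midpoints
    u_shell = np.empty_like(rho)
    c_mid = np.empty_like(rho)
    depleted = np.zeros(rho.shape, dtype=bool)
    u = np.maximum(u_bulk.astype(float), 0.0)
    for n in range(n_sh - 1, -1, -1):
        R_out = bounds[n + 1]
        u_shell[n] = u
        c = u + factor[n] * (R_out**2 - mids[n] ** 2)
        neg = c < 0
        depleted[n] |= neg
        c_mid[n] = np.where(neg, 0.0, c)
        u_inner = u + factor[n] * (R_out**2 - bounds[n] ** 2)
        neg_b = u_inner < 0
        depleted[n] |= neg_b
        u = np.where(neg_b, 0.0, u_inner)
    c_center = u  # after the loop, u is the value at r = 0
    prof = MicroEnvProfile(shells=shells, u_bulk=u_bulk, u_shell=u_shell, c_mid=c_mid,
                           c_center=c_center, rho=rho, depleted=depleted)
    prof._rho_over_6D = factor
    return prof


def solve_quasi_steady(flux_model, shells: ShellDecomposition, u_bulk: np.ndarray,
                       s_init: np.ndarray, network, diffusion: DiffusionParams,
                       ext_index: np.ndarray, damping: float = 0.5, tol: float = 1e-6,
                       max_iter: int = 100) -> MicroEnvProfile:
    """Fixed point of rho = N v(c, s) gamma and c = shell_profile(rho).

    ``flux_model.rates(U)`` must map a (n_shells, n_metabolites) state stack
    to per-shell per-reaction fluxes (n_shells, k). ``ext_index`` selects the
    extracellular (diffusing) rows of the network's metabolite vector;
    intracellular pools ``s_init`` (n_shells, n_int) are held fixed during
    the solve (they evolve on the slower simulation clock). Damped Picard
    iteration until the max relative change drops below ``tol``.
    """
    n_sh = shells.n_shells
    u_bulk = np.atleast_1d(np.asarray(u_bulk, dtype=float))
    D_eff = effective_diffusivity(diffusion)
    if D_eff.size == 1 and u_bulk.size > 1:
        D_eff = np.full(u_bulk.size, float(D_eff[0]))
    gamma = unit_gamma(diffusion.porosity).gamma
    N_ext = network.N[ext_index, :]

    c = np.tile(u_bulk, (n_sh, 1)).astype(float)
    residuals: list[float] = []
    scale = np.maximum(np.abs(u_bulk), 1.0)
    prof = None
    for it in range(max_iter):
        U = _assemble_state(network, ext_index, c, s_init)
        v = flux_model.rates(U)
        rho = volumetric_rates(v, N_ext, gamma) * GAMMA_TO_MM_PER_H
        prof = shell_profile(rho, D_eff, shells, u_bulk)
        c_new = prof.c_mid
        resid = float(np.max(np.abs(c_new - c) / scale))
        residuals.append(resid)
        c = (1.0 - damping) * c + damping * c_new
        if resid < tol:
            prof.n_iterations = it + 1
            prof.residuals = residuals
            prof.s = s_init
            # shells whose local level is effectively zero relative to the
            # bulk are flagged depleted even when the smooth kinetics keep the
            # clamped closed form marginally positive
            prof.depleted |= prof.c_mid < 1e-3 * np.maximum(np.abs(u_bulk), 1e-12)
            return prof
    raise RuntimeError(
        f"quasi-steady shell solve did not converge in {max_iter} iterations; "
        f"residual history tail: {residuals[-5:]}")


def _assemble_state(network, ext_index, c: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Interleave extracellular shell concentrations and intracellular pools."""
    n_sh = c.shape[0]
    U = np.zeros((n_sh, network.n_metabolites))
    U[:, ext_index] = c
    int_index = np.setdiff1d(np.arange(network.n_metabolites), ext_index)
    U[:, int_index] = s
    return U


def steady_state_fd(rho_shells: np.ndarray, D: float, shells: ShellDecomposition,
                    u_bulk: float, n_r: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference steady solve of the spherical reaction-diffusion problem.

    Independent validation oracle for :func:`shell_profile` (one species):
    solves ``D (1/r^2)(r^2 c')' + rho(r) = 0`` with ``c(R) = u_bulk`` and a
    zero-gradient center, with ``rho`` piecewise constant per shell.
    Returns (r, c) on a uniform grid. Not used on the production path.
    """
    rho_shells = np.atleast_1d(np.asarray(rho_shells, dtype=float))
    R = shells.aggregate_radius
    r = np.linspace(0.0, R, n_r)
    h = r[1] - r[0]
    idx = np.minimum(np.searchsorted(shells.boundaries[1:], r, side="left"),
                     shells.n_shells - 1)
    rho = rho_shells[idx]

    ab = np.zeros((3, n_r))
    b = np.zeros(n_r)
    # center node: spherical Laplacian at the origin ~ 6 (c1 - c0) / h^2
    ab[1, 0] = -6.0 / h**2
    ab[0, 1] = 6.0 / h**2
    b[0] = -rho[0] / D
    for i in range(1, n_r - 1):
        rp = 0.5 * (r[i] + r[i + 1])
        rm = 0.5 * (r[i] + r[i - 1])
        ab[0, i + 1] = rp**2 / (r[i] ** 2 * h**2)
        ab[2, i - 1] = rm**2 / (r[i] ** 2 * h**2)
        ab[1, i] = -(rp**2 + rm**2) / (r[i] ** 2 * h**2)
        b[i] = -rho[i] / D
    ab[1, -1] = 1.0
    b[-1] = u_bulk
    c = solve_banded((1, 1), ab, b)
    return r, c
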