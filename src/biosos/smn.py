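"""Single-cell stochastic metabolic reaction network.

A cell's metabolic state is the vector of metabolite concentrations
``u_tilde = (s, c)`` (intracellular pools plus the local extracellular
micro-environment). Each of the k reactions fires as a nonhomogeneous
Poisson process with intensity equal to its flux rate ``v_j(u_tilde)``
(nmol per 10^6 cells per hour); over a short interval the reaction count is

    R_j ~ Poisson(v_j * dt * omega)

with the system size ``omega`` setting the event granularity (tau-leaping
with rates frozen at the interval start). The mass balance is
``u(t + dt) = u(t) + N @ R`` scaled back to concentration units, so the
expected trajectory follows the deterministic flux-balance ODE
``du/dt = N @ v(u)`` and the variance shrinks as 1/omega.

Rate laws are a pluggable interface; the packaged default family is
irreversible Michaelis-Menten with optional product inhibition (reversible
reactions are split into forward/reverse components), with parameters
carried in the network table.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .units import CELL_FLUX_TO_MM

#: default system size: events per (flux unit x hour); a nominal flux of
#: 200 nmol/10^6 cells/h over a 0.1 h step then yields 10^4 expected events.
DEFAULT_OMEGA = 500.0

_PATHWAY_MAP = {
    "glycolysis": ["HK", "PGI", "PFK", "ALD", "GAPDH", "ENO", "PK", "LDHf", "LDHr"],
    "ppp": ["PPPox", "PPPnonox"],
    "tca": ["PDH", "CS", "IDH", "AKGDH", "SDH", "FUMase", "MDH"],
    "anaplerosis": ["PC", "ME"],
    "amino_acid": ["GLNSf", "GLNSr", "GLDHf", "GLDHr", "ASTA", "ALATAf", "ALATAr",
                   "SERS", "SAL", "SHMT"],
    "transport": ["GlnT", "LacTf", "LacTr", "AlaTf", "SerT", "GluT", "NH4T"],
    "biomass": ["biomass"],
}


@dataclass(frozen=True)
class MetaboliteSpec:
    id: str
    compartment: str  # "intracellular" | "extracellular"
    initial_conc: float  # mM
    description: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in ("intracellular", "extracellular"):
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.id}")


@dataclass(frozen=True)
class ReactionSpec:
    id: str
    consumed: dict       # metabolite id -> eta_ij (non-negative integer)
    produced: dict       # metabolite id -> eta'_ij
    rate_law: str
    params: dict
    reversible: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        for coeffs in (self.consumed, self.produced):
            for met, c in coeffs.items():
                if int(c) != c or c < 0:
                    raise ValueError(f"stoichiometric coefficient {c} for {met} in "
                                     f"{self.id} must be a non-negative integer")
        if not self.consumed and not self.produced:
            raise ValueError(f"reaction {self.id} has no nonzero coefficients")

    def equation(self) -> str:
        lhs = " + ".join(f"{int(c)} {m}" for m, c in self.consumed.items())
        rhs = " + ".join(f"{int(c)} {m}" for m, c in self.produced.items())
        return f"{lhs} -> {rhs}"


class MetabolicNetwork:
    """Stoichiometry container: n metabolites x k reactions, N = eta' - eta."""

    def __init__(self, metabolites: list[MetaboliteSpec], reactions: list[ReactionSpec]):
        ids = [m.id for m in metabolites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.index = {m.id: i for i, m in enumerate(self.metabolites)}
        for r in reactions:
            for met in list(r.consumed) + list(r.produced):
                if met not in self.index:
                    raise ValueError(f"reaction {r.id} references undeclared metabolite {met}")
        self.eta = np.zeros((self.n_metabolites, self.n_reactions))
        self.eta_prime = np.zeros_like(self.eta)
        for j, r in enumerate(reactions):
            for met, c in r.consumed.items():
                self.eta[self.index[met], j] = c
            for met, c in r.produced.items():
                self.eta_prime[self.index[met], j] = c
        self.N = self.eta_prime - self.eta

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def ext_index(self) -> np.ndarray:
        """Indices of extracellular (diffusing) metabolites."""
        return np.array([i for i, m in enumerate(self.metabolites)
                         if m.compartment == "extracellular"], dtype=int)

    @property
    def int_index(self) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.metabolites)
                         if m.compartment == "intracellular"], dtype=int)

    def initial_state(self) -> np.ndarray:
        return np.array([m.initial_conc for m in self.metabolites], dtype=float)

    def species(self, met_id: str) -> int:
        return self.index[met_id]

    def pathway_coverage(self) -> dict:
        """Which canonical central-carbon pathways the network covers."""
        have = set(self.reaction_ids)
        return {pw: sorted(have.intersection(rxns)) for pw, rxns in _PATHWAY_MAP.items()}

    def glossary(self) -> pd.DataFrame:
        """Abbreviation glossary for metabolites and reactions."""
        rows = [{"kind": "metabolite", "id": m.id, "description": m.description,
                 "detail": m.compartment} for m in self.metabolites]
        rows += [{"kind": "reaction", "id": r.id, "description": r.description,
                  "detail": r.equation()} for r in self.reactions]
        return pd.DataFrame(rows)


_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?(\S+)\s*$")


def parse_equation(eq: str) -> tuple[dict, dict]:
    """Parse '1 GLC + 1 ATP -> 1 G6P' into (consumed, produced) coefficient dicts."""
    if "->" not in eq:
        raise ValueError(f"equation {eq!r} lacks '->'")
    lhs, rhs = eq.split("->")

    def side(s: str) -> dict:
        out: dict = {}
        s = s.strip()
        if not s:
            return out
        for term in s.split("+"):
            m = _TERM_RE.match(term)
            if not m:
                raise ValueError(f"cannot parse term {term!r} in equation {eq!r}")
            coeff = int(m.group(1) or 1)
            out[m.group(2)] = out.get(m.group(2), 0) + coeff
        return out

    return side(lhs), side(rhs)


def load_network(metabolite_file, reaction_file) -> MetabolicNetwork:
    """Load a metabolic network from the metabolite and reaction tables.

    Metabolite CSV columns: id, compartment, initial_mM[, description].
    Reaction CSV columns: reaction_id, equation, reversible, rate_law,
    params_json[, description].
    """
    mdf = pd.read_csv(metabolite_file)
    rdf = pd.read_csv(reaction_file)
    metabolites = [MetaboliteSpec(id=row["id"], compartment=row["compartment"],
                                  initial_conc=float(row["initial_mM"]),
                                  description=str(row.get("description", "") or ""))
                   for _, row in mdf.iterrows()]
    reactions = []
    for _, row in rdf.iterrows():
        consumed, produced = parse_equation(row["equation"])
        reactions.append(ReactionSpec(
            id=row["reaction_id"], consumed=consumed, produced=produced,
            rate_law=row["rate_law"], params=json.loads(row["params_json"]),
            reversible=str(row["reversible"]).strip().lower() in ("true", "1", "yes"),
            description=str(row.get("description", "") or "")))
    return MetabolicNetwork(metabolites, reactions)


def write_network(network: MetabolicNetwork, metabolite_file, reaction_file) -> None:
    """Write the network back to CSV; round-trips exactly with load_network."""
    pd.DataFrame([{"id": m.id, "compartment": m.compartment, "initial_mM": m.initial_conc,
                   "description": m.description} for m in network.metabolites]
                 ).to_csv(metabolite_file, index=False)
    pd.DataFrame([{"reaction_id": r.id, "equation": r.equation(),
                   "reversible": r.reversible, "rate_law": r.rate_law,
                   "params_json": json.dumps(r.params, sort_keys=True),
                   "description": r.description} for r in network.reactions]
                 ).to_csv(reaction_file, index=False)


def default_network() -> MetabolicNetwork:
    """The packaged 32-metabolite / 38-reaction central-carbon network."""
    data_dir = Path(__file__).parent / "data"
    return load_network(data_dir / "metabolites.csv", data_dir / "reactions.csv")


class FluxModel:
    """Pluggable single-cell flux-rate function v(u_tilde) >= 0.

    The packaged rate-law family:

    * ``mm`` — irreversible Michaelis-Menten in every consumed substrate,
      ``v = vmax * prod_s c_s / (km_s + c_s)``, optionally damped by product
      inhibition terms ``ki / (ki + c_p)`` (params: ``vmax``, ``km`` mapping,
      optional ``inhibitors`` mapping).
    * ``mass_action`` — ``v = k * prod_s c_s^eta_s`` (params: ``k``).
    * ``constant`` — ``v = value`` (params: ``value``).

    Fluxes are in nmol per 10^6 cells per hour; the uptake of an absent
    substrate is zero by construction of the saturating forms.
    """

    def __init__(self, network: MetabolicNetwork):
        self.network = network
        self._compiled = []
        for j, r in enumerate(network.reactions):
            subs = [(network.index[m], float(c)) for m, c in r.consumed.items()]
            if r.rate_law == "mm":
                km = {network.index[m]: float(v) for m, v in r.params["km"].items()}
                missing = [m for m in r.consumed if network.index[m] not in km]
                if missing:
                    raise ValueError(f"reaction {r.id}: km missing for substrates {missing}")
                inhib = {network.index[m]: float(v)
                         for m, v in r.params.get("inhibitors", {}).items()}
                self._compiled.append(("mm", float(r.params["vmax"]), km, inhib))
            elif r.rate_law == "mass_action":
                self._compiled.append(("mass_action", float(r.params["k"]), subs, None))
            elif r.rate_law == "constant":
                self._compiled.append(("constant", float(r.params["value"]), None, None))
            else:
                raise ValueError(f"unknown rate law {r.rate_law!r} in reaction {r.id}")

    def rates(self, U: np.ndarray) -> np.ndarray:
        """Per-reaction fluxes for a state vector (n,) or stack (m, n) of states."""
        U = np.asarray(U, dtype=float)
        single = U.ndim == 1
        U = np.atleast_2d(np.maximum(U, 0.0))
        v = np.empty((U.shape[0], self.network.n_reactions))
        for j, (law, p0, p1, p2) in enumerate(self._compiled):
            if law == "mm":
                col = np.full(U.shape[0], p0)
                for idx, km in p1.items():
                    col = col * U[:, idx] / (km + U[:, idx])
                for idx, ki in p2.items():
                    col = col * ki / (ki + U[:, idx])
            elif law == "mass_action":
                col = np.full(U.shape[0], p0)
                for idx, order in p1:
                    col = col * U[:, idx] ** order
            else:  # constant
                col = np.full(U.shape[0], p0)
            v[:, j] = col
        v = np.maximum(v, 0.0)
        return v[0] if single else v


@dataclass
class CellState:
    """Metabolite concentrations (mM) of one cell and its local environment."""

    u_tilde: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.u_tilde = np.asarray(self.u_tilde, dtype=float)
        if np.any(self.u_tilde < 0):
            raise ValueError("metabolite amounts must be non-negative")


@dataclass
class ReactionCounts:
    """Poisson reaction counts over an interval and their cumulative intensity."""

    counts: np.ndarray
    cumulative_intensity: np.ndarray  # Lambda_j = v_j * dt * omega


def sample_counts(v: np.ndarray, dt: float, omega: float,
                  rng: np.random.Generator) -> ReactionCounts:
    """Draw R_j ~ Poisson(v_j dt omega) independently for each reaction."""
    v = np.asarray(v, dtype=float)
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if np.any(v < 0):
        raise ValueError("flux rates must be non-negative")
    lam = v * dt * omega
    return ReactionCounts(counts=rng.poisson(lam), cumulative_intensity=lam)


def step_cell(state: CellState, flux_model: FluxModel, dt: float, omega: float,
              rng: np.random.Generator, max_substeps: int = 12) -> CellState:
    """One tau-leap step of the single-cell network.

    Rates are frozen at the interval start; if the sampled update would drive
    any species negative the interval is recursively halved (rates re-frozen
    at each substep start) up to ``max_substeps`` levels.
    """
    network = flux_model.network
    scale = CELL_FLUX_TO_MM / omega

    def leap(u: np.ndarray, h: float, depth: int) -> np.ndarray:
        v = flux_model.rates(u)
        delta = network.N @ rng.poisson(v * h * omega) * scale
        u_new = u + delta
        if np.all(u_new >= 0):
            return u_new
        if depth >= max_substeps:
            bad = [network.metabolite_ids[i] for i in np.where(u_new < 0)[0]]
            raise RuntimeError(f"species {bad} persistently negative after "
                               f"{max_substeps} substep halvings")
        u = leap(u, h / 2.0, depth + 1)
        return leap(u, h / 2.0, depth + 1)

    return CellState(u_tilde=leap(state.u_tilde, dt, 0), time=state.time + dt)
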