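"""Run configuration: YAML/JSON loading with validation and provenance."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .assembly import SimulationConfig
from .pbm import GrowthParams, KernelParams

_PBM_KEYS = {"k", "k1", "a", "M", "alpha_G", "r_min", "r_max", "dr", "dt", "horizon"}
_DIFFUSION_KEYS = {"table", "porosity", "tortuosity"}
_NETWORK_KEYS = {"metabolites", "reactions"}
_SIMULATION_KEYS = {"dt", "horizon", "shell_width", "porosity", "tortuosity",
                    "omega_bulk", "omega_cell", "bulk_mode", "held_species",
                    "seed", "save_every", "replicates"}
_OUTPUT_KEYS = {"directory", "log_level"}
_SECTIONS = {"pbm": _PBM_KEYS, "diffusion": _DIFFUSION_KEYS, "network": _NETWORK_KEYS,
             "simulation": _SIMULATION_KEYS, "outputs": _OUTPUT_KEYS}


@dataclass
class RunConfig:
    """Validated run configuration with per-key provenance (default vs user)."""

    kernel: KernelParams = field(default_factory=KernelParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    pbm_grid: dict = field(default_factory=lambda: {"r_min": 7.5, "r_max": 600.0,
                                                    "dr": 1.0, "dt": 0.1, "horizon": 72.0})
    network_files: dict = field(default_factory=dict)   # empty -> packaged default
    diffusion_table: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    replicates: int = 30
    output_dir: str = "biosos_out"
    log_level: str = "INFO"
    provenance: dict = field(default_factory=dict)
    master_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "pbm": {"k": self.kernel.k, "k1": self.kernel.k1, "a": self.kernel.a,
                    "M": self.growth.M, "alpha_G": self.growth.alpha_G,
                    **self.pbm_grid},
            "diffusion": {"table": self.diffusion_table,
                          "porosity": self.simulation.porosity,
                          "tortuosity": self.simulation.tortuosity},
            "network": dict(self.network_files),
            "simulation": {"dt": self.simulation.dt, "horizon": self.simulation.horizon,
                           "shell_width": self.simulation.shell_width,
                           "porosity": self.simulation.porosity,
                           "tortuosity": self.simulation.tortuosity,
                           "omega_bulk": self.simulation.omega_bulk,
                           "omega_cell": self.simulation.omega_cell,
                           "bulk_mode": self.simulation.bulk_mode,
                           "held_species": list(self.simulation.held_species),
                           "seed": self.master_seed, "save_every": self.simulation.save_every,
                           "replicates": self.replicates},
            "outputs": {"directory": self.output_dir, "log_level": self.log_level},
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown sections or keys are collected and reported all at once; every
    key absent from the file keeps the packaged default and is recorded as
    such in ``provenance``.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    errors: list[str] = []
    for section, content in raw.items():
        if section not in _SECTIONS:
            errors.append(f"unknown section {section!r}")
            continue
        if content is None:
            continue
        if not isinstance(content, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key in content:
            if key not in _SECTIONS[section]:
                errors.append(f"unknown key {section}.{key}")
    if errors:
        raise ValueError("configuration schema violations:\n  " + "\n  ".join(errors))

    cfg = RunConfig()
    prov: dict[str, str] = {sec + "." + k: "default" for sec, keys in _SECTIONS.items()
                            for k in keys}

    def pick(section: str, key: str, default):
        val = raw.get(section, {}) or {}
        if key in val:
            prov[f"{section}.{key}"] = "user"
            return val[key]
        return default

    cfg.kernel = KernelParams(k=pick("pbm", "k", cfg.kernel.k),
                              k1=pick("pbm", "k1", cfg.kernel.k1),
                              a=pick("pbm", "a", cfg.kernel.a))
    cfg.growth = GrowthParams(M=pick("pbm", "M", cfg.growth.M),
                              alpha_G=pick("pbm", "alpha_G", cfg.growth.alpha_G))
    for key in ("r_min", "r_max", "dr", "dt", "horizon"):
        cfg.pbm_grid[key] = pick("pbm", key, cfg.pbm_grid[key])
    cfg.diffusion_table = pick("diffusion", "table", None)
    for key in ("metabolites", "reactions"):
        val = pick("network", key, None)
        if val is not None:
            cfg.network_files[key] = val
    sim = SimulationConfig(
        dt=pick("simulation", "dt", 0.1),
        horizon=pick("simulation", "horizon", 72.0),
        shell_width=pick("simulation", "shell_width", 15.0),
        porosity=pick("diffusion", "porosity", pick("simulation", "porosity", 0.27)),
        tortuosity=pick("diffusion", "tortuosity", pick("simulation", "tortuosity", 1.5)),
        omega_bulk=pick("simulation", "omega_bulk", 1e6),
        omega_cell=pick("simulation", "omega_cell", 500.0),
        bulk_mode=pick("simulation", "bulk_mode", "batch"),
        held_species=tuple(pick("simulation", "held_species", ())),
        seed=int(pick("simulation", "seed", 0)),
        save_every=int(pick("simulation", "save_every", 1)))
    cfg.simulation = sim
    cfg.master_seed = sim.seed
    cfg.replicates = int(pick("simulation", "replicates", 30))
    cfg.output_dir = pick("outputs", "directory", "biosos_out")
    cfg.log_level = pick("outputs", "log_level", "INFO")
    cfg.provenance = prov
    # referenced files must exist
    missing = [f for f in [cfg.diffusion_table, *cfg.network_files.values()]
               if f and not Path(f).exists()]
    if missing:
        raise FileNotFoundError(f"configured files not found: {missing}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig to YAML; load_config(save_config(cfg)) is identity."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
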