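"""Trajectory and table I/O: headered CSV round-tripping.

Every file written carries a ``#``-prefixed header block with the config
hash, master seed and software version, so replicate sets can be audited
and reassembled. Floats are written with 12 significant digits, making
write -> read -> write byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__

_FLOAT_FMT = "%.12g"


def _config_hash(meta: dict) -> str:
    payload = repr(sorted((k, str(v)) for k, v in meta.items() if k != "config_hash"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, meta: dict) -> None:
    """Write a DataFrame as CSV under a '#'-prefixed metadata header."""
    meta = dict(meta)
    meta.setdefault("version", __version__)
    meta["config_hash"] = _config_hash(meta)
    buf = _io.StringIO()
    for k in sorted(meta):
        buf.write(f"# {k}: {meta[k]}\n")
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a headered CSV; warns if the recorded config hash does not match."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            try:
                key, val = line[1:].split(":", 1)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed header at line {i + 1}") from exc
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    if body_start >= len(lines):
        raise ValueError(f"{path}: no data rows after header (file truncated at "
                         f"line {len(lines)})")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: parse error in data block starting at line "
                         f"{body_start + 1}: {exc}") from exc
    if "config_hash" in meta:
        expect = _config_hash({k: v for k, v in meta.items()})
        if meta["config_hash"] != expect:
            warnings.warn(f"{path}: config hash mismatch (file {meta['config_hash']}, "
                          f"recomputed {expect})", stacklevel=2)
    return df, meta


@dataclass
class TrajectoryFiles:
    """On-disk form of a trajectory: tidy frames plus shared metadata."""

    bulk: pd.DataFrame
    flux: pd.DataFrame
    shells: pd.DataFrame
    meta: dict


def write_trajectory(traj, out_dir, seed: int | None = None,
                     replicate: int | None = None) -> TrajectoryFiles:
    """Write a simulated trajectory (or a TrajectoryFiles) to CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(traj, TrajectoryFiles):
        files = traj
    else:
        ext_ids = [traj.network.metabolite_ids[i] for i in traj.network.ext_index]
        shells_rows = []
        for st in traj.states:
            for l, c_l in enumerate(st.c):
                for n in range(c_l.shape[0]):
                    for i, sp in enumerate(ext_ids):
                        shells_rows.append({"time_h": st.time, "group": l, "shell": n,
                                            "species": sp, "conc_mM": c_l[n, i]})
        meta = {"seed": traj.config.seed if seed is None else seed,
                "dt_h": traj.config.dt, "horizon_h": traj.config.horizon,
                "bulk_mode": traj.config.bulk_mode}
        if replicate is not None:
            meta["replicate"] = replicate
        files = TrajectoryFiles(bulk=traj.bulk_frame(), flux=traj.flux_frame(),
                                shells=pd.DataFrame(shells_rows), meta=meta)
    write_table(files.bulk, out_dir / "bulk.csv", files.meta)
    write_table(files.flux, out_dir / "flux.csv", files.meta)
    write_table(files.shells, out_dir / "shells.csv", files.meta)
    return files


def read_trajectory(out_dir) -> TrajectoryFiles:
    """Read back a trajectory directory written by :func:`write_trajectory`."""
    out_dir = Path(out_dir)
    bulk, meta = read_table(out_dir / "bulk.csv")
    flux, _ = read_table(out_dir / "flux.csv")
    shells, _ = read_table(out_dir / "shells.csv")
    meta.pop("config_hash", None)
    meta.pop("version", None)
    return TrajectoryFiles(bulk=bulk, flux=flux, shells=shells, meta=meta)
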