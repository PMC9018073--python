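"""Configuration, serialization and seed management.

Run configuration is a TOML file whose ``[simulation]`` table mirrors
the :class:`~spindlesim.params.SimParams` field names; omitted keys fall
back to the wild-type defaults, and ``preset = "ase1_delta"`` switches
the uniform-rescue variant together with its rescue budget and
catastrophe parameters. Event logs and trajectory series round-trip
through CSV; every output directory gets a manifest recording the
resolved configuration, master seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SimParams, ase1_delta_params, wild_type_params
from .simulation import EventRecord, Trajectory

__all__ = ["RunConfig", "load_config", "events_to_frame", "frame_to_events",
           "write_event_log", "read_event_log", "write_trajectory_series",
           "write_manifest", "child_seed"]

EVENT_COLUMNS = ["kind", "t_min", "mt_id", "pos_signed_um", "spindle_length_um"]
SERIES_COLUMNS = ["t_min", "spindle_length_um", "polymer_um",
                  "n_mts_left", "n_mts_right"]


@dataclasses.dataclass
class RunConfig:
    params: SimParams
    seed: int = 0
    n_runs: int = 1
    out_dir: Path = Path("spindlesim_out")
    scan_name: str | None = None
    scan_points: int = 10
    log_level: str = "INFO"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.pop("_beta_norm", None)
        return {"simulation": d, "seed": self.seed, "n_runs": self.n_runs,
                "out_dir": str(self.out_dir), "scan_name": self.scan_name,
                "scan_points": self.scan_points, "log_level": self.log_level}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Unknown keys raise a ``ValueError`` naming the key; an empty file
    yields the wild-type defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = dict(raw.pop("simulation", {}))
    preset = sim.pop("preset", raw.pop("preset", "wild_type"))
    if preset == "wild_type":
        base = wild_type_params
    elif preset == "ase1_delta":
        base = ase1_delta_params
    else:
        raise ValueError(f"unknown preset {preset!r}")
    # a bare `variant = "uniform"` implies the crosslinker-deletion preset
    if sim.get("variant") == "uniform" and preset == "wild_type":
        base = ase1_delta_params
        sim.pop("variant")
    valid = set(SimParams.field_names())
    for key in sim:
        if key not in valid:
            raise ValueError(f"unknown simulation key {key!r}; "
                             f"valid keys: {sorted(valid)}")
    try:
        params = base(**sim)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid simulation configuration: {exc}") from exc

    cfg = RunConfig(params=params)
    for key, value in raw.items():
        if key == "seed":
            cfg.seed = int(value)
        elif key == "n_runs":
            cfg.n_runs = int(value)
        elif key == "out_dir":
            cfg.out_dir = Path(value)
        elif key == "scan_name":
            cfg.scan_name = str(value)
        elif key == "scan_points":
            cfg.scan_points = int(value)
        elif key == "log_level":
            cfg.log_level = str(value)
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return cfg


def child_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Counter-based derivation of per-stage seeds from the master seed,
    independent of execution order. Stable across runs and platforms."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.kind, e.t, e.mt_id, e.pos_signed, e.S_at_event) for e in events],
        columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[EventRecord]:
    return [EventRecord(kind=row.kind, t=float(row.t_min),
                        mt_id=int(row.mt_id),
                        pos_signed=float(row.pos_signed_um),
                        S_at_event=float(row.spindle_length_um))
            for row in df.itertuples(index=False)]


def write_event_log(events: list[EventRecord], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False, float_format="%.17g")


def read_event_log(path: str | Path) -> list[EventRecord]:
    return frame_to_events(pd.read_csv(path, float_precision="round_trip"))


def write_trajectory_series(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({
        "t_min": traj.times,
        "spindle_length_um": traj.spindle_length,
        "polymer_um": traj.polymer,
        "n_mts_left": traj.n_left,
        "n_mts_right": traj.n_right,
    }).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(config: RunConfig, out_dir: str | Path) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    blob = json.dumps(resolved, sort_keys=True).encode()
    manifest = {
        "config": resolved,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {"spindlesim": __version__, "numpy": np.__version__},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
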