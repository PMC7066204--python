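"""Reading and writing: scenario configs, trajectories, snapshots, manifests.

Scenario specs round-trip through YAML with unknown keys rejected.
Trajectories are tidy CSV tables (one row per cell per recorded tick) with
a versioned schema line so stale files fail loudly.  Writers use fixed
float formatting, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from .engine import TRAJECTORY_COLUMNS
from .scenario import ScenarioSpec

__all__ = [
    "load_spec",
    "save_spec",
    "write_trajectories",
    "read_trajectories",
    "write_snapshot_csv",
    "write_snapshots_npz",
    "RunManifest",
    "SchemaError",
]

TRAJECTORY_SCHEMA = "sggrad-trajectory-v1"
_VERSION = "0.1.0"


class SchemaError(ValueError):
    """A persisted file does not match the expected schema version."""


# ----------------------------------------------------------------------
# scenario specs
# ----------------------------------------------------------------------
def load_spec(path) -> ScenarioSpec:
    """Load and validate a scenario config (YAML/JSON mapping).

    Unknown keys, missing required fields and out-of-range values raise a
    validation error naming the offending fields.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    try:
        return ScenarioSpec.model_validate(data)
    except ValidationError as err:
        raise ValueError(f"invalid scenario config {path}:\n{err}") from err


def save_spec(spec: ScenarioSpec, path) -> None:
    """Write a fully resolved spec (defaults included) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.model_dump(mode="json"), fh, sort_keys=True)


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------
def write_trajectories(traj: pd.DataFrame, path) -> None:
    """Write the tidy trajectory table as CSV with a schema header line."""
    missing = [c for c in TRAJECTORY_COLUMNS if c not in traj.columns]
    if missing:
        raise SchemaError(f"trajectory table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"# {TRAJECTORY_SCHEMA}\n")
        traj.to_csv(fh, index=False, float_format="%.6g", columns=TRAJECTORY_COLUMNS)


def read_trajectories(path) -> pd.DataFrame:
    """Read a trajectory CSV, enforcing the schema version and columns."""
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {TRAJECTORY_SCHEMA}":
            raise SchemaError(
                f"{path}: expected schema '{TRAJECTORY_SCHEMA}', got {header!r}"
            )
        traj = pd.read_csv(fh, dtype={"event": str})
    if list(traj.columns) != TRAJECTORY_COLUMNS:
        raise SchemaError(
            f"{path}: column mismatch: {list(traj.columns)} != {TRAJECTORY_COLUMNS}"
        )
    traj["cell_id"] = traj["cell_id"].astype(np.int64)
    return traj


# ----------------------------------------------------------------------
# field snapshots
# ----------------------------------------------------------------------
def write_snapshot_csv(array: np.ndarray, path, spacing_um: float, time_s: float) -> None:
    """Plain CSV matrix of one field snapshot with metadata comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# sggrad-field-v1 time_s={time_s:.6g} spacing_um={spacing_um:.6g} units=nM\n")
        np.savetxt(fh, array, fmt="%.6g", delimiter=",")


def write_snapshots_npz(snapshots, path, spacing_um: float) -> None:
    """Compact container for a snapshot series keyed by time."""
    arrays = {f"t_{t:.3f}": arr for t, arr in snapshots}
    np.savez_compressed(path, spacing_um=np.asarray(spacing_um), **arrays)


# ----------------------------------------------------------------------
# manifest
# ----------------------------------------------------------------------
def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one run: resolved spec, seed, software version, outputs."""

    spec: dict
    seed: int
    software_version: str = _VERSION
    start_time: str = ""
    end_time: str = ""
    outputs: dict = dc_field(default_factory=dict)

    @classmethod
    def begin(cls, spec: ScenarioSpec) -> "RunManifest":
        return cls(
            spec=spec.model_dump(mode="json"),
            seed=spec.seed,
            start_time=datetime.datetime.now().isoformat(timespec="seconds"),
        )

    def finish(self, output_paths) -> None:
        self.end_time = datetime.datetime.now().isoformat(timespec="seconds")
        self.outputs = {
            str(Path(p).name): _sha256(p) for p in output_paths
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
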