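"""File formats: HDF5 frame stacks and masks, versioned CSV, JSON sidecars.

Frame stacks live in HDF5 under ``/entry_1/data_1/data`` (frames × slow ×
fast, unsigned integer ADU) with ``/entry_1/event_id`` and
``/entry_1/timestamp_s``; masks under ``/entry_1/mask``. CSV artifacts
carry a schema-version header line and readers reject unknown major
versions. Every artifact gets a JSON sidecar recording the configuration
hash and seed so outputs are traceable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import BeamlineGeometry
from .simulate import FrameStack

CSV_SCHEMA_MAJOR = 1
CSV_SCHEMA_MINOR = 0
_HEADER_PREFIX = "# dropsfx-csv"


class SchemaVersionError(ValueError):
    """CSV schema major version not understood by this reader."""


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def write_frame_stack(path: str | Path, stack: FrameStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("/entry_1/data_1/data", data=stack.frames,
                         dtype=stack.frames.dtype)
        f.create_dataset("/entry_1/event_id", data=stack.event_ids)
        f.create_dataset("/entry_1/timestamp_s", data=stack.timestamps)
        f["/entry_1"].attrs["geometry_json"] = json.dumps(stack.geometry.to_dict())


def read_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame stack not found: {path}")
    with h5py.File(path, "r") as f:
        frames = f["/entry_1/data_1/data"][...]
        event_ids = f["/entry_1/event_id"][...]
        timestamps = f["/entry_1/timestamp_s"][...]
        geom = BeamlineGeometry.from_dict(
            json.loads(f["/entry_1"].attrs["geometry_json"]))
    return FrameStack(frames=frames, event_ids=event_ids,
                      timestamps=timestamps, geometry=geom)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("/entry_1/mask", data=mask.astype(bool))


def read_mask(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["/entry_1/mask"][...].astype(bool)


# ---------------------------------------------------------------------------
# versioned CSV
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a CSV with a schema-version header line.

    Floats use a fixed repr-style format so identical inputs give
    byte-identical files.
    """
    path = Path(path)
    header = f"{_HEADER_PREFIX} {CSV_SCHEMA_MAJOR}.{CSV_SCHEMA_MINOR} {kind}\n"
    body = df.to_csv(index=False, float_format="%.10g", lineterminator="\n")
    path.write_text(header + body)


def read_csv(path: str | Path, expected_kind: str | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as f:
        first = f.readline()
        if not first.startswith(_HEADER_PREFIX):
            raise SchemaVersionError(f"{path}: missing dropsfx-csv header")
        parts = first.strip().split()
        version = parts[2]
        kind = parts[3] if len(parts) > 3 else ""
        major = int(version.split(".")[0])
        if major != CSV_SCHEMA_MAJOR:
            raise SchemaVersionError(
                f"{path}: schema major version {major} not supported "
                f"(reader speaks {CSV_SCHEMA_MAJOR}.x)")
        if expected_kind is not None and kind != expected_kind:
            raise SchemaVersionError(
                f"{path}: expected kind {expected_kind!r}, found {kind!r}")
        return pd.read_csv(f)


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def config_hash(config_doc: dict) -> str:
    """Stable SHA-256 of a JSON-serializable configuration document."""
    canonical = json.dumps(config_doc, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_sidecar(artifact_path: str | Path, config_doc: dict,
                  seed: int) -> Path:
    """Write ``<artifact>.meta.json`` with config hash, seed, and config."""
    artifact_path = Path(artifact_path)
    sidecar = artifact_path.with_name(artifact_path.name + ".meta.json")
    doc = {
        "artifact": artifact_path.name,
        "config_sha256": config_hash(config_doc),
        "seed": seed,
        "config": config_doc,
    }
    sidecar.write_text(json.dumps(doc, indent=2, sort_keys=True,
                                  default=str) + "\n")
    return sidecar
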