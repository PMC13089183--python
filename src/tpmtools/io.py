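"""Readers and writers for the package's delimited-text formats.

Formats:

* kinetic CSV — columns substrate_uM, rate_nmol_min_mg, replicate, condition;
* PIE TSV, wide — one row per conformation id, one column per fragment label;
* PIE table, long — columns conformation_id, fragment_label, pie_kj_mol;
* multi-frame XYZ — per frame an atom-count line, a comment line carrying the
  frame index, then one "name x y z" line per atom (coordinates in A);
* result envelope JSON — stage name, package version, input digests,
  parameters, and payload, with floats rounded to 12 significant digits and
  fixed key order so reruns diff cleanly.

Floats are written with 17 significant digits in the delimited formats so a
write/read round trip reproduces the binary values exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .conformers import PIEMatrix
from .kinetics import KineticDataset
from .synth import TrajectoryFrames

__all__ = [
    "read_kinetic_csv",
    "write_kinetic_csv",
    "read_pie_tsv",
    "write_pie_tsv",
    "read_pie_long",
    "write_pie_long",
    "read_xyz",
    "write_xyz",
    "sha256_digest",
    "ResultEnvelope",
    "write_envelope",
]

FLOAT_FMT = "%.17g"


def write_kinetic_csv(data: KineticDataset, path) -> None:
    data.table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_kinetic_csv(path) -> KineticDataset:
    table = pd.read_csv(path, float_precision="round_trip")
    try:
        return KineticDataset(table)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_pie_tsv(m: PIEMatrix, path) -> None:
    m.table.to_csv(path, sep="\t", index_label="conformation_id", float_format=FLOAT_FMT)


def read_pie_tsv(path) -> PIEMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return PIEMatrix(table)


def write_pie_long(m: PIEMatrix, path) -> None:
    long = m.table.reset_index(names="conformation_id").melt(
        id_vars="conformation_id", var_name="fragment_label", value_name="pie_kj_mol"
    )
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_pie_long(path) -> PIEMatrix:
    long = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"conformation_id", "fragment_label", "pie_kj_mol"}
    if not required.issubset(long.columns):
        raise ValueError(f"{path}: long-format PIE table needs columns {sorted(required)}")
    wide = long.pivot(index="conformation_id", columns="fragment_label", values="pie_kj_mol")
    if wide.isna().any().any():
        raise ValueError(f"{path}: long-format PIE table is not rectangular")
    # preserve first-appearance order of conformations and fragments
    wide = wide.loc[
        long["conformation_id"].drop_duplicates(), long["fragment_label"].drop_duplicates()
    ]
    wide.index.name = None
    wide.columns.name = None
    return PIEMatrix(wide)


def write_xyz(frames: TrajectoryFrames, path) -> None:
    n_atoms = len(frames.atom_names)
    with open(path, "w") as fh:
        for i in range(frames.n_frames):
            fh.write(f"{n_atoms}\nframe {i}\n")
            for name, (x, y, z) in zip(frames.atom_names, frames.coords[i]):
                fh.write(f"{name} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path) -> TrajectoryFrames:
    """Read a multi-frame XYZ file; all frames must share the same atoms."""
    names: list[str] | None = None
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: frame {frame_no}: bad atom-count line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: frame {frame_no}: truncated at line {i + 1}")
        cur_names, coords = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: frame {frame_no}: malformed atom line {i + 3 + j}")
            cur_names.append(parts[0])
            coords.append([float(p) for p in parts[1:]])
        if names is None:
            names = cur_names
        elif cur_names != names:
            raise ValueError(
                f"{path}: frame {frame_no}: atom names/count differ from frame 0"
            )
        frames.append(np.asarray(coords))
        i += 2 + n
        frame_no += 1
    if names is None:
        raise ValueError(f"{path}: no frames found")
    return TrajectoryFrames(atom_names=tuple(names), coords=np.stack(frames))


def sha256_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def _jsonable(obj, sig: int = 12):
    """Recursively convert to JSON-serializable form with rounded floats."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj), sig)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v, sig) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v, sig) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"), sig)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return _round_sig(v, sig) if math.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


@dataclass
class ResultEnvelope:
    """Provenance wrapper written next to every stage's results."""

    stage: str
    version: str
    input_digests: dict[str, str]
    parameters: dict
    payload: dict
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )


def write_envelope(env: ResultEnvelope, path) -> None:
    doc = {
        "stage": env.stage,
        "version": env.version,
        "input_digests": env.input_digests,
        "parameters": _jsonable(env.parameters),
        "payload": _jsonable(env.payload),
        "timestamp": env.timestamp,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
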