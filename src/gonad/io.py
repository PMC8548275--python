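"""File formats: provenance-stamped CSVs, two-channel TIFF velocity fields,
JSON/YAML parameter files.

All CSVs are UTF-8, dot-decimal, header row mandatory, numbers written with
6 significant digits; a ``# key=value`` comment block at the top carries
provenance (seed, config hash) and is ignored on read.  Write -> read ->
write round-trips are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .doublet import DoubletParams
from .hydromodel import ModelParams
from .types import CELL_COLUMNS, EVENT_COLUMNS, VelocityField

__all__ = [
    "FormatError",
    "write_table",
    "read_table",
    "write_cell_table",
    "read_cell_table",
    "write_events",
    "read_events",
    "write_profile",
    "read_profile",
    "write_velocity_field",
    "read_velocity_field",
    "write_model_params",
    "read_model_params",
    "write_doublet_params",
    "read_doublet_params",
]

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Raised for malformed input files; names the offending column."""


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in sorted(provenance.items()))


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_provenance(path) -> dict:
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                out[k.strip()] = v.strip()
    return out


# -- typed wrappers ---------------------------------------------------------

def write_cell_table(cells: pd.DataFrame, path, provenance=None) -> None:
    write_table(cells[CELL_COLUMNS], path, provenance)


def read_cell_table(path) -> pd.DataFrame:
    df = read_table(path, required=["gonad_id", "x", "volume_fl"])
    if "alive" not in df.columns:
        df["alive"] = True
    if (df["volume_fl"] <= 0).any():
        raise FormatError(f"{Path(path).name}: column volume_fl must be strictly positive")
    if ((df["x"] < 0) | (df["x"] > 1)).any():
        raise FormatError(f"{Path(path).name}: column x must lie in [0, 1]")
    return df


def write_events(events: pd.DataFrame, path, provenance=None) -> None:
    write_table(events[EVENT_COLUMNS], path, provenance)


def read_events(path) -> pd.DataFrame:
    return read_table(path, required=EVENT_COLUMNS)


def write_profile(profile: pd.DataFrame, path, provenance=None) -> None:
    if "x" not in profile.columns:
        raise FormatError("axial profile must carry an x column")
    write_table(profile, path, provenance)


def read_profile(path) -> pd.DataFrame:
    return read_table(path, required=["x"])


# -- velocity fields --------------------------------------------------------

def write_velocity_field(field: VelocityField, tiff_path, centreline_path, provenance=None) -> None:
    """Two-channel float32 TIFF (u, v) plus mask channel and centreline CSV."""
    stack = np.stack(
        [field.u.astype(np.float32), field.v.astype(np.float32), field.mask.astype(np.float32)]
    )
    tifffile.imwrite(
        tiff_path,
        stack,
        photometric="minisblack",
        metadata={
            "pixel_size_um": field.pixel_size,
            "origin_um": list(field.origin_um) if field.origin_um else None,
        },
    )
    cl = pd.DataFrame(field.centreline, columns=["axial_um", "transverse_um"])
    write_table(cl, centreline_path, provenance)


def read_velocity_field(tiff_path, centreline_path) -> VelocityField:
    with tifffile.TiffFile(tiff_path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise FormatError("velocity TIFF must have channels (u, v, mask)")
    cl = read_table(centreline_path, required=["axial_um", "transverse_um"])
    origin = meta.get("origin_um")
    return VelocityField(
        u=stack[0],
        v=stack[1],
        mask=stack[2] > 0.5,
        centreline=cl.to_numpy(dtype=float),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        origin_um=tuple(origin) if origin else None,
    )


def write_frames(frame_a: np.ndarray, frame_b: np.ndarray, path) -> None:
    tifffile.imwrite(
        path, np.stack([frame_a, frame_b]).astype(np.float32), photometric="minisblack"
    )


def read_frames(path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise FormatError("frame TIFF must contain exactly 2 planes")
    return stack[0], stack[1]


# -- parameters -------------------------------------------------------------

def write_model_params(params: ModelParams, path, extra: dict | None = None) -> None:
    d = dataclasses.asdict(params)
    if isinstance(d["rhoV"], np.ndarray):
        d["rhoV"] = d["rhoV"].tolist()
    if extra:
        d["_meta"] = extra
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_params(path) -> ModelParams:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    d.pop("_meta", None)
    if isinstance(d.get("rhoV"), list):
        d["rhoV"] = np.asarray(d["rhoV"], dtype=float)
    return ModelParams(**d)


def write_doublet_params(params: DoubletParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=True)


def read_doublet_params(path) -> DoubletParams:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    return DoubletParams(**d)
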