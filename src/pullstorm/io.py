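"""File formats: multi-page TIFF stacks, localization CSV, result CSVs, YAML.

The localization CSV dialect uses the interchange header

    frame,x [nm],y [nm],sigma [nm],intensity [photon],uncertainty [nm]

mapped one-to-one onto the internal column names ``frame, x, y, sigma,
intensity, uncertainty``; frames are integers, all other columns floats.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import LOC_COLUMNS, FrameStack

__all__ = [
    "LOC_CSV_HEADER",
    "write_stack",
    "read_stack",
    "write_localizations",
    "read_localizations",
    "write_counts",
    "read_counts",
    "write_morphology",
    "read_morphology",
    "write_yaml",
    "read_yaml",
]

#: CSV header of the localization-table interchange dialect
LOC_CSV_HEADER = [
    "frame",
    "x [nm]",
    "y [nm]",
    "sigma [nm]",
    "intensity [photon]",
    "uncertainty [nm]",
]

_TO_INTERNAL = dict(zip(LOC_CSV_HEADER, LOC_COLUMNS))
_TO_DIALECT = dict(zip(LOC_COLUMNS, LOC_CSV_HEADER))

COUNTS_COLUMNS = ["participant", "target", "fov", "count"]
MORPH_COLUMNS = ["participant", "target", "fov", "label",
                 "area_um2", "circularity", "n_locs"]


def write_stack(path: str | Path, stack: FrameStack,
                dtype: np.dtype | str = np.float32) -> Path:
    """Write a frame stack as a multi-page TIFF, pixel size in the metadata.

    ``dtype=np.uint16`` quantizes to camera ADU (rounded, clipped at the type
    range) which halves the file size of raw camera data.
    """
    path = Path(path)
    data = np.asarray(stack.data)
    dtype = np.dtype(dtype)
    if dtype.kind == "u":
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    else:
        data = data.astype(dtype)
    resolution = 1e3 / stack.pixel_size  # pixels per µm
    tifffile.imwrite(
        path,
        data,
        resolution=(resolution, resolution),
        photometric="minisblack",
        metadata={"axes": "TYX", "pixel_size_nm": float(stack.pixel_size)},
    )
    return path


def read_stack(path: str | Path, pixel_size: float | None = None) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    ``pixel_size`` (nm) overrides the value stored in the TIFF metadata; if
    neither is available a ``ValueError`` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size=")
    return FrameStack(data=np.asarray(data, dtype=float), pixel_size=float(px))


def write_localizations(path: str | Path, table: pd.DataFrame) -> Path:
    """Write a localization table in the interchange CSV dialect."""
    missing = [c for c in LOC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"localization table missing columns {missing}")
    out = table[LOC_COLUMNS].rename(columns=_TO_DIALECT).copy()
    out["frame"] = out["frame"].astype(int)
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.4f")
    return path


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read an interchange-dialect localization CSV into internal columns."""
    df = pd.read_csv(path)
    missing = [c for c in LOC_CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing localization columns {missing}")
    df = df[LOC_CSV_HEADER].rename(columns=_TO_INTERNAL)
    df["frame"] = df["frame"].astype(int)
    for c in LOC_COLUMNS[1:]:
        df[c] = df[c].astype(float)
    return df


def _write_table(path: str | Path, df: pd.DataFrame, columns: list[str]) -> Path:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    path = Path(path)
    df[columns].to_csv(path, index=False)
    return path


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[columns]


def write_counts(path: str | Path, df: pd.DataFrame) -> Path:
    """Per-FoV counts CSV: ``participant,target,fov,count``."""
    return _write_table(path, df, COUNTS_COLUMNS)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, COUNTS_COLUMNS)
    df["fov"] = df["fov"].astype(int)
    df["count"] = df["count"].astype(int)
    return df


def write_morphology(path: str | Path, df: pd.DataFrame) -> Path:
    """Morphology CSV: ``participant,target,fov,label,area_um2,circularity,n_locs``."""
    return _write_table(path, df, MORPH_COLUMNS)


def read_morphology(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, MORPH_COLUMNS)
    for c in ("fov", "label", "n_locs"):
        df[c] = df[c].astype(int)
    for c in ("area_um2", "circularity"):
        df[c] = df[c].astype(float)
    return df


def write_yaml(path: str | Path, obj: dict) -> Path:
    """Write a mapping as YAML with stable key order."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return obj
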