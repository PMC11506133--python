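"""Read/write height maps, measurement tables and configs in bit-stable formats.

Conventions used throughout the package:

* heights are in nanometres, everywhere; no other length unit appears
  internally,
* grids are row-major with the origin at the top-left pixel;
  ``x = column * pixel_size_nm`` and ``y = row * pixel_size_nm`` refer to
  pixel centres,
* height maps are stored as single-channel 32-bit float TIFF plus a JSON
  metadata sidecar (same stem, ``.json`` suffix).  Proprietary instrument
  formats are rejected, not guessed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

SCHEMA_VERSION = 1

#: fixed column order of the measurement CSV
MEASUREMENT_COLUMNS = [
    "frame_id",
    "time_min",
    "object_id",
    "class",
    "diameter_nm",
    "length_nm",
    "rq_nm",
    "site",
    "activity",
    "host_id",
]

#: columns that must never contain NaN
MANDATORY_COLUMNS = ["frame_id", "object_id", "class"]

MIN_GRID = 16


class FormatError(ValueError):
    """Raised on contract violations of the on-disk formats."""


@dataclasses.dataclass
class HeightMap:
    """Calibrated 2-D height field in nm — the pipeline's universal currency.

    Parameters
    ----------
    heights:
        ``(rows, cols)`` float array of heights in nm.
    pixel_size_nm:
        physical size of one pixel (nm / pixel), identical in x and y.
    time_min:
        minutes since secondary-oligomer deposition, if applicable.
    frame_id:
        identifier of the frame; used as the CSV key.
    """

    heights: np.ndarray
    pixel_size_nm: float
    time_min: float | None = None
    frame_id: str = "frame"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise FormatError("heights must be a 2-D grid")
        if self.heights.shape[0] < MIN_GRID or self.heights.shape[1] < MIN_GRID:
            raise FormatError(f"grid must be at least {MIN_GRID}x{MIN_GRID}")
        if not np.all(np.isfinite(self.heights)):
            raise FormatError("heights must be finite")
        if not (float(self.pixel_size_nm) > 0):
            raise FormatError("pixel_size_nm must be > 0")
        self.pixel_size_nm = float(self.pixel_size_nm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(height, width) of the field in nm."""
        r, c = self.heights.shape
        return r * self.pixel_size_nm, c * self.pixel_size_nm

    def copy_with(self, heights: np.ndarray) -> "HeightMap":
        return HeightMap(
            heights=np.asarray(heights, dtype=float),
            pixel_size_nm=self.pixel_size_nm,
            time_min=self.time_min,
            frame_id=self.frame_id,
        )


@dataclasses.dataclass
class SidecarMeta:
    """JSON sidecar metadata; round-trips losslessly with HeightMap."""

    pixel_size_nm: float
    time_min: float | None = None
    frame_id: str = "frame"
    generator_seed: int | None = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SidecarMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_heightmap(
    hm: HeightMap, path: str | Path, generator_seed: int | None = None
) -> Path:
    """Write ``hm`` as float32 TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, hm.heights.astype(np.float32))
    meta = SidecarMeta(
        pixel_size_nm=hm.pixel_size_nm,
        time_min=hm.time_min,
        frame_id=hm.frame_id,
        generator_seed=generator_seed,
    )
    _sidecar_path(path).write_text(json.dumps(meta.to_dict(), indent=1, sort_keys=True))
    return path


def read_heightmap(path: str | Path) -> HeightMap:
    """Read a float TIFF + sidecar pair written by :func:`write_heightmap`.

    The sidecar is mandatory: pixel size is never silently defaulted.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar: {side}")
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise FormatError(
            f"expected a single-channel 2-D TIFF, got shape {data.shape}"
        )
    if not np.issubdtype(data.dtype, np.floating):
        raise FormatError(
            f"expected a floating-point TIFF, got dtype {data.dtype}"
        )
    meta = SidecarMeta.from_dict(json.loads(side.read_text()))
    return HeightMap(
        heights=np.asarray(data, dtype=float),
        pixel_size_nm=meta.pixel_size_nm,
        time_min=meta.time_min,
        frame_id=meta.frame_id,
    )


def write_measurements(records: Iterable[Mapping], path: str | Path) -> Path:
    """Write measurement records as CSV with a fixed, documented column order.

    Rows are sorted by (frame_id, object_id) so output is deterministic
    regardless of insertion order.  NaN in a mandatory column is an error.
    """
    path = Path(path)
    rows = [dict(r) for r in records]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if len(df):
        for col in MANDATORY_COLUMNS:
            if df[col].isna().any():
                raise FormatError(f"NaN in mandatory column {col!r}")
        df = df.sort_values(["frame_id", "object_id"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.8g", lineterminator="\n")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"frame_id": str, "object_id": str, "host_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurement CSV missing columns {missing}")
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise FormatError(f"expected a mapping at the top of {path}")
    return out


def write_yaml(obj: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)
    return path
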