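"""Raster and profile readers/writers plus result serialization.

Supported raster formats: ESRI ASCII grid (``.asc``), single-band TIFF
(``.tif``/``.tiff``, float32 heights or uint8 binary/categorical, cell
size in the resolution tag) and 16-bit grayscale PNG with a JSON sidecar
declaring the height scaling.  Profiles are two-column CSV
(distance, height); compositions are label,count CSV.
"""

from __future__ import annotations

import dataclasses
import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import BinaryMap, HeightMap

__all__ = [
    "read_raster",
    "write_raster",
    "read_profile_csv",
    "write_profile_csv",
    "read_composition_csv",
    "write_results",
]

_NODATA_DEFAULT = -9999.0


# ---------------------------------------------------------------- ESRI ASCII

def _write_esri_ascii(path: Path, data: np.ndarray, cell_size: float,
                      nodata_mask: np.ndarray | None) -> None:
    out = np.array(data, dtype=float)
    if nodata_mask is not None:
        out[nodata_mask] = _NODATA_DEFAULT
    header = (
        f"ncols {out.shape[1]}\n"
        f"nrows {out.shape[0]}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value {_NODATA_DEFAULT!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def _read_esri_ascii(path: Path) -> tuple[np.ndarray, float, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                meta[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"grid shape {data.shape} disagrees with header in {path}")
    return data, meta.get("cellsize", 1.0), meta.get("nodata_value", _NODATA_DEFAULT)


# --------------------------------------------------------------------- TIFF

def _write_tiff(path: Path, data: np.ndarray, cell_size: float,
                nodata_mask: np.ndarray | None) -> None:
    import tifffile

    if data.dtype.kind == "f":
        out = data.astype(np.float32)
        if nodata_mask is not None:
            out = out.copy()
            out[nodata_mask] = np.nan
    else:
        out = data
    res = Fraction(1.0 / cell_size).limit_denominator(10**8)
    res = (res.numerator, res.denominator)
    tifffile.imwrite(path, out, resolution=(res, res))


def _read_tiff(path: Path) -> tuple[np.ndarray, float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        cell_size = 1.0
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                cell_size = den / num
    return data, cell_size


# -------------------------------------------------------------------- PNG16

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_png16(path: Path, data: np.ndarray, cell_size: float,
                 nodata_mask: np.ndarray | None) -> None:
    from PIL import Image

    if nodata_mask is not None and nodata_mask.any():
        raise ValueError("PNG16 format cannot represent nodata cells")
    lo = float(data.min())
    hi = float(data.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    quant = np.round((data - lo) / scale).astype(np.uint16)
    Image.fromarray(quant).save(path)
    _sidecar(path).write_text(
        json.dumps({"cell_size": cell_size, "offset": lo, "scale": scale})
    )


def _read_png16(path: Path) -> tuple[np.ndarray, float]:
    from PIL import Image

    raw = np.asarray(Image.open(path), dtype=np.float64)
    meta = {"cell_size": 1.0, "offset": 0.0, "scale": 1.0}
    sc = _sidecar(path)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    return raw * meta["scale"] + meta["offset"], float(meta["cell_size"])


# ----------------------------------------------------------------- dispatch

_FORMATS = {".asc": "asc", ".tif": "tif", ".tiff": "tif", ".png": "png16"}


def write_raster(obj: HeightMap | BinaryMap | np.ndarray, path: str | Path,
                 cell_size: float | None = None) -> None:
    """Write a heightmap, binary map or categorical array; format from suffix."""
    path = Path(path)
    fmt = _FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"unknown raster format {path.suffix!r}")
    if isinstance(obj, HeightMap):
        data, cs, mask = obj.heights, obj.cell_size, obj.nodata_mask
    elif isinstance(obj, BinaryMap):
        data, cs, mask = obj.cells, obj.cell_size, None
    else:
        data, cs, mask = np.asarray(obj), cell_size or 1.0, None
    if fmt == "asc":
        _write_esri_ascii(path, data, cs, mask)
    elif fmt == "tif":
        _write_tiff(path, data, cs, mask)
    else:
        _write_png16(path, np.asarray(data, dtype=float), cs, mask)


def read_raster(path: str | Path, expected_kind: str = "height_float"):
    """Read a raster as HeightMap, BinaryMap or categorical int array.

    ``expected_kind``: ``height_float``, ``binary`` or ``categorical``.
    Binary rasters must contain only 0/1; offending values are named in
    the error.
    """
    path = Path(path)
    fmt = _FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"unknown raster format {path.suffix!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    nodata_value = None
    if fmt == "asc":
        data, cell_size, nodata_value = _read_esri_ascii(path)
    elif fmt == "tif":
        data, cell_size = _read_tiff(path)
    else:
        data, cell_size = _read_png16(path)

    if expected_kind == "height_float":
        data = np.asarray(data, dtype=float)
        mask = ~np.isfinite(data)
        if nodata_value is not None:
            mask |= data == nodata_value
        data = np.where(mask, 0.0, data)
        return HeightMap(data, cell_size=cell_size, nodata_mask=mask if mask.any() else None)
    if expected_kind == "binary":
        vals = np.unique(data)
        if nodata_value is not None:
            vals = vals[vals != nodata_value]
        bad = np.setdiff1d(vals, [0, 1])
        if bad.size:
            raise ValueError(
                f"{path} is not a binary raster: found values {bad.tolist()}"
            )
        cells = (data == 1).astype(np.uint8)
        return BinaryMap(cells, cell_size=cell_size)
    if expected_kind == "categorical":
        return np.asarray(np.rint(data), dtype=np.int64)
    raise ValueError(f"unknown expected_kind {expected_kind!r}")


# ----------------------------------------------------------------- profiles

def write_profile_csv(profile, path: str | Path) -> None:
    df = pd.DataFrame({"distance": profile.distances, "height": profile.heights})
    df.to_csv(path, index=False)


def read_profile_csv(path: str | Path):
    from .grids import Profile1D

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("profile CSV needs (distance, height) columns")
    dist = df.iloc[:, 0].to_numpy(dtype=float)
    spacing = float(np.diff(dist).mean()) if dist.size > 1 else 1.0
    return Profile1D(df.iloc[:, 1].to_numpy(dtype=float), spacing=spacing)


def read_composition_csv(path: str | Path):
    from .info_metrics import CompositionCounts

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("composition CSV needs (label, count) columns")
    return CompositionCounts(
        df.iloc[:, 1].to_numpy(dtype=np.int64),
        labels=[str(x) for x in df.iloc[:, 0].tolist()],
    )


# ------------------------------------------------------------------ results

def _flatten(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    flat: dict = {}
    for key, val in obj.items():
        if isinstance(val, dict):
            for k2, v2 in val.items():
                flat[f"{key}_{k2}"] = v2
        elif isinstance(val, (tuple, list)) and len(val) == 2 and all(
            isinstance(v, (int, float)) for v in val
        ):
            flat[f"{key}_min"], flat[f"{key}_max"] = val
        elif isinstance(val, (tuple, list)):
            flat[key] = ";".join(str(v) for v in val)
        else:
            flat[key] = val
    return flat


def write_results(results, path: str | Path, columns: list | None = None) -> None:
    """Serialize result objects (dataclasses or dicts) to CSV.

    Column order is stable (first-seen order); floats keep full precision.
    An empty list yields a header-only file when ``columns`` is given.
    """
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
        return
    rows = [_flatten(r) for r in results]
    df = pd.DataFrame(rows, columns=columns if (columns and not rows) else None)
    df.to_csv(path, index=False, float_format="%.17g")
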