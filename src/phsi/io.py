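"""File formats, run configuration and directory conventions.

Cubes travel as ENVI (text ``.hdr`` + raw binary, default bsq/float32,
wavelengths embedded in the header) or as multi-page TIFF (one band per
page, wavelengths in a ``.wavelengths.json`` sidecar).  Element-image sets
live in one directory as four cubes named ``ih``, ``iv``, ``i45``,
``irc``; calibration sweeps as ``angle_<deg>`` subdirectories.  ROI masks
are PNG/TIFF images where nonzero means true.  Floating-point round trips
are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .polarization import ElementImageSet, SpectralAxis, StokesCube
from .quantify import ROIMask

logger = logging.getLogger("phsi")

__all__ = [
    "read_cube",
    "write_cube",
    "read_envi",
    "write_envi",
    "read_tiff_cube",
    "write_tiff_cube",
    "read_mask",
    "write_mask",
    "read_element_set",
    "write_element_set",
    "read_sweep",
    "write_sweep",
    "read_stokes",
    "write_stokes",
    "RunConfig",
    "save_config_snapshot",
]

ELEMENT_NAMES = ("ih", "iv", "i45", "irc")
STOKES_NAMES = ("s0", "s1", "s2", "s3")

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32,
}
_DTYPE_TO_ENVI = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


# ---------------------------------------------------------------------------
# ENVI
# ---------------------------------------------------------------------------

def _envi_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".hdr":
        return p, p.with_suffix(".img")
    if p.suffix in {".img", ".dat", ".raw"}:
        return p.with_suffix(".hdr"), p
    return Path(str(p) + ".hdr"), Path(str(p) + ".img")


def write_envi(
    cube: np.ndarray,
    axis: SpectralAxis,
    path: str | Path,
    interleave: str = "bsq",
    dtype: np.dtype | type | None = None,
) -> Path:
    """Write a (rows, cols, bands) cube as an ENVI header + raw pair.

    Returns the header path.  ``dtype`` defaults to the cube's own dtype
    (float64 arrays are stored as float64, so the round trip is
    bit-exact).
    """
    hdr_path, img_path = _envi_paths(path)
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be (rows, cols, bands)")
    if cube.shape[2] != axis.n_bands:
        raise ValueError("cube band count does not match the spectral axis")
    if interleave not in {"bsq", "bil", "bip"}:
        raise ValueError("interleave must be bsq, bil or bip")
    dt = np.dtype(dtype) if dtype is not None else cube.dtype
    if dt not in _DTYPE_TO_ENVI:
        raise ValueError(f"unsupported ENVI dtype {dt}")
    data = cube.astype(dt, copy=False)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        ordered = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        ordered = np.transpose(data, (0, 2, 1))
    else:  # bip
        ordered = data
    wl = ", ".join(repr(float(w)) for w in axis.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + wl + "}\n"
    )
    hdr_path.write_text(header)
    np.ascontiguousarray(ordered).astype(dt.newbyteorder("<")).tofile(img_path)
    return hdr_path


def _parse_envi_header(text: str) -> dict[str, str]:
    # collapse brace-delimited multi-line values, then split on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str | Path) -> tuple[np.ndarray, SpectralAxis]:
    """Read an ENVI cube; returns (rows, cols, bands) data and its axis.

    Bands stored with unsorted wavelengths are reordered ascending with a
    logged warning.  Header/data inconsistencies are rejected with the
    offending field named.
    """
    hdr_path, img_path = _envi_paths(path)
    if not hdr_path.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr_path}")
    if not img_path.exists():
        raise FileNotFoundError(f"ENVI data file not found: {img_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing field {exc.args[0]!r}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"ENVI header field 'data type' = {dtype_code} unsupported")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("ENVI header field 'byte order' must be 0 (little-endian)")
    dt = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<")
    raw = np.fromfile(img_path, dtype=dt)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"ENVI header field 'bands'/'lines'/'samples' implies {expected} values "
            f"but the data file holds {raw.size}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"ENVI header field 'interleave' = {interleave!r} unsupported")

    match = re.search(r"wavelength\s*=\s*\{([^}]*)\}", hdr_path.read_text(), re.I)
    if match is None:
        raise ValueError("ENVI header missing field 'wavelength'")
    wl = np.array([float(x) for x in match.group(1).replace(",", " ").split()])
    if wl.size != bands:
        raise ValueError("ENVI header field 'wavelength' length != 'bands'")
    if np.any(np.diff(wl) <= 0):
        logger.warning("ENVI wavelengths not ascending; reordering bands")
        order = np.argsort(wl, kind="stable")
        wl = wl[order]
        cube = cube[:, :, order]
    return np.ascontiguousarray(cube), SpectralAxis(tuple(wl))


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_tiff_cube(cube: np.ndarray, axis: SpectralAxis, path: str | Path) -> Path:
    """Write a cube as a multi-page TIFF (one band per page) + JSON sidecar."""
    import tifffile

    p = Path(path)
    cube = np.asarray(cube)
    if cube.ndim != 3 or cube.shape[2] != axis.n_bands:
        raise ValueError("cube must be (rows, cols, bands) matching the axis")
    tifffile.imwrite(p, np.transpose(cube, (2, 0, 1)))
    sidecar = p.with_suffix(p.suffix + ".wavelengths.json")
    sidecar.write_text(json.dumps({"wavelengths_nm": list(axis.wavelengths_nm)}))
    return p


def read_tiff_cube(path: str | Path) -> tuple[np.ndarray, SpectralAxis]:
    import tifffile

    p = Path(path)
    data = tifffile.imread(p)
    if data.ndim == 2:
        data = data[None]
    cube = np.transpose(data, (1, 2, 0))
    sidecar = p.with_suffix(p.suffix + ".wavelengths.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"wavelength sidecar not found: {sidecar}")
    wl = np.asarray(json.loads(sidecar.read_text())["wavelengths_nm"], dtype=float)
    if wl.size != cube.shape[2]:
        raise ValueError("sidecar field 'wavelengths_nm' length != TIFF page count")
    if np.any(np.diff(wl) <= 0):
        logger.warning("TIFF wavelengths not ascending; reordering bands")
        order = np.argsort(wl, kind="stable")
        wl, cube = wl[order], cube[:, :, order]
    return np.ascontiguousarray(cube), SpectralAxis(tuple(wl))


def write_cube(cube: np.ndarray, axis: SpectralAxis, path: str | Path, **kwargs) -> Path:
    """Dispatch on extension: .tif/.tiff -> TIFF, anything else -> ENVI."""
    if Path(path).suffix.lower() in {".tif", ".tiff"}:
        return write_tiff_cube(cube, axis, path)
    return write_envi(cube, axis, path, **kwargs)


def read_cube(path: str | Path) -> tuple[np.ndarray, SpectralAxis]:
    if Path(path).suffix.lower() in {".tif", ".tiff"}:
        return read_tiff_cube(path)
    return read_envi(path)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path, label: str = "other") -> ROIMask:
    """Read a PNG/TIFF mask; nonzero pixels are true.  Empty masks reject."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # RGB(A) mask: any nonzero channel counts
        arr = arr[..., :3].max(axis=2)
    return ROIMask(arr != 0, label)


def write_mask(mask: ROIMask | np.ndarray, path: str | Path) -> Path:
    import imageio.v3 as iio

    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))
    return Path(path)


# ---------------------------------------------------------------------------
# element sets, sweeps, Stokes cubes
# ---------------------------------------------------------------------------

def write_element_set(
    images: ElementImageSet, directory: str | Path, fmt: str = "envi"
) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ext = ".tif" if fmt == "tiff" else ""
    for name in ELEMENT_NAMES:
        write_cube(getattr(images, name), images.axis, d / f"{name}{ext}")
    return d


def read_element_set(directory: str | Path) -> ElementImageSet:
    d = Path(directory)
    cubes = {}
    axis = None
    for name in ELEMENT_NAMES:
        for candidate in (d / f"{name}.hdr", d / f"{name}.tif", d / f"{name}.tiff"):
            if candidate.exists():
                cube, ax = read_cube(candidate)
                break
        else:
            raise FileNotFoundError(f"element cube '{name}' not found in {d}")
        cubes[name] = cube
        if axis is None:
            axis = ax
        elif ax != axis:
            raise ValueError(f"element cube '{name}' has a different spectral axis")
    return ElementImageSet(cubes["ih"], cubes["iv"], cubes["i45"], cubes["irc"], axis)


def write_sweep(sweep: Mapping[float, ElementImageSet], directory: str | Path) -> Path:
    d = Path(directory)
    for angle, images in sweep.items():
        write_element_set(images, d / f"angle_{angle:g}")
    return d


def read_sweep(directory: str | Path) -> dict[float, ElementImageSet]:
    d = Path(directory)
    sweep: dict[float, ElementImageSet] = {}
    for sub in sorted(d.glob("angle_*")):
        if not sub.is_dir():
            continue
        angle = float(sub.name.split("_", 1)[1])
        sweep[angle] = read_element_set(sub)
    if not sweep:
        raise FileNotFoundError(f"no angle_<deg> subdirectories found in {d}")
    return sweep


def write_stokes(cube: StokesCube, directory: str | Path, fmt: str = "envi") -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ext = ".tif" if fmt == "tiff" else ""
    for name in STOKES_NAMES:
        write_cube(getattr(cube, name), cube.axis, d / f"{name}{ext}")
    meta = {"normalized": bool(cube.normalized)}
    (d / "stokes.json").write_text(json.dumps(meta))
    return d


def read_stokes(directory: str | Path) -> StokesCube:
    d = Path(directory)
    cubes = {}
    axis = None
    for name in STOKES_NAMES:
        for candidate in (d / f"{name}.hdr", d / f"{name}.tif", d / f"{name}.tiff"):
            if candidate.exists():
                cube, ax = read_cube(candidate)
                break
        else:
            raise FileNotFoundError(f"Stokes cube '{name}' not found in {d}")
        cubes[name] = cube
        axis = axis or ax
    meta_path = d / "stokes.json"
    normalized = False
    if meta_path.exists():
        normalized = bool(json.loads(meta_path.read_text()).get("normalized", False))
    valid = None
    if normalized:
        valid = np.isfinite(cubes["s0"])
    return StokesCube(cubes["s0"], cubes["s1"], cubes["s2"], cubes["s3"], axis,
                      normalized=normalized, valid=valid)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable record of everything a run needs to be reproduced."""

    seed: int = 0
    shape: tuple[int, int] = (64, 64)
    spectral_axis: str = "test_scale"        # 'test_scale', 'default', or list
    wavelengths_nm: list[float] | None = None
    phantom: dict[str, Any] = field(default_factory=dict)
    noise: dict[str, Any] = field(default_factory=dict)
    glcm: dict[str, Any] = field(default_factory=dict)
    response_curves: str | None = None       # CSV path or None for built-ins
    output_dir: str = "."

    def axis(self) -> SpectralAxis:
        if self.wavelengths_nm:
            return SpectralAxis(tuple(self.wavelengths_nm))
        if self.spectral_axis == "default":
            return SpectralAxis.default()
        return SpectralAxis.test_scale()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "shape" in data:
            data["shape"] = tuple(data["shape"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return Path(path)


def save_config_snapshot(config: RunConfig, directory: str | Path) -> Path:
    """Write the run's config next to its outputs (phsi-config.yaml)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    return config.to_yaml(d / "phsi-config.yaml")
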