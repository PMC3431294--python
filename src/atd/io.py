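"""TIFF and sidecar I/O.

Images, volumes and PSFs travel as grayscale TIFF (8/16-bit integer or
32-bit float; multi-page for volumes).  Physical metadata - pixel size,
section thickness, provenance - travels in a JSON sidecar next to the TIFF
(``image.tif`` -> ``image.tif.json``) rather than in TIFF tags, whose
dialects vary across microscope vendors.  Integer data are never silently
rescaled; float data are written as 32-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .errors import InvalidParameterError, UnsupportedFormatError
from .psf import PointSpreadFunction
from .volume import ImageVolume

__all__ = [
    "read_image",
    "read_volume",
    "write_image",
    "write_volume",
    "read_psf",
    "write_psf",
    "RunConfig",
]

_ALLOWED_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def _read_sidecar(path: str | Path) -> dict[str, Any]:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _write_sidecar(path: str | Path, meta: dict[str, Any]) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def _load(path: str | Path) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    arr = tifffile.imread(p)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise UnsupportedFormatError(
            f"{p} looks like an RGB(A) TIFF; only grayscale images are supported"
        )
    if str(arr.dtype) not in _ALLOWED_DTYPES:
        raise UnsupportedFormatError(
            f"{p} has unsupported dtype {arr.dtype}; expected one of {_ALLOWED_DTYPES}"
        )
    return arr


def read_image(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a single 2D grayscale image with its sidecar metadata."""
    arr = _load(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path} is not a single 2D image")
    meta = _read_sidecar(path)
    meta.setdefault("dtype", str(arr.dtype))
    return arr.astype(float), meta


def read_volume(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a multi-page grayscale TIFF as a (z, y, x) array with metadata."""
    arr = _load(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise UnsupportedFormatError(f"{path} is not a grayscale image stack")
    meta = _read_sidecar(path)
    meta.setdefault("dtype", str(arr.dtype))
    return arr.astype(float), meta


def _prepare(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype.kind == "f":
        return arr.astype(np.float32)
    return arr


def write_image(
    arr: np.ndarray, path: str | Path, pixel_nm: float | None = None, **extra: Any
) -> None:
    """Write a 2D image (float data as 32-bit) plus a JSON sidecar."""
    tifffile.imwrite(path, _prepare(arr), photometric="minisblack")
    meta = {"dtype": str(_prepare(arr).dtype), **extra}
    if pixel_nm is not None:
        meta["pixel_nm"] = pixel_nm
    _write_sidecar(path, meta)


def write_volume(
    arr: np.ndarray,
    path: str | Path,
    pixel_nm: float | None = None,
    section_nm: float | None = None,
    **extra: Any,
) -> None:
    """Write a (z, y, x) stack as a multi-page TIFF plus a JSON sidecar."""
    arr = _prepare(arr)
    if arr.ndim != 3:
        raise InvalidParameterError("write_volume expects a (z, y, x) array")
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {"dtype": str(arr.dtype), **extra}
    if pixel_nm is not None:
        meta["pixel_nm"] = pixel_nm
    if section_nm is not None:
        meta["section_nm"] = section_nm
    _write_sidecar(path, meta)


def read_psf(path: str | Path, pixel_nm: float | None = None) -> PointSpreadFunction:
    """Read a PSF TIFF; pixel size comes from the sidecar unless overridden."""
    arr, meta = read_image(path)
    px = pixel_nm if pixel_nm is not None else meta.get("pixel_nm")
    if px is None:
        raise InvalidParameterError(
            f"{path} has no pixel_nm in its sidecar; pass the pixel size explicitly"
        )
    return PointSpreadFunction.from_array(arr, float(px))


def write_psf(psf: PointSpreadFunction, path: str | Path, **extra: Any) -> None:
    """Write a PSF as 32-bit float TIFF with pixel size and provenance sidecar."""
    write_image(psf.kernel, path, pixel_nm=psf.pixel_nm, **extra)


def read_volume_as(path: str | Path, pixel_nm: float, section_nm: float) -> ImageVolume:
    data, meta = read_volume(path)
    return ImageVolume(
        data,
        float(meta.get("pixel_nm", pixel_nm)),
        float(meta.get("section_nm", section_nm)),
    )


_CONFIG_KEYS = {"command", "params", "seed", "log_level", "inputs", "outputs"}


class RunConfig:
    """A declarative run description loaded from YAML or JSON.

    Keys: ``command`` (required), ``params`` (flag name -> value),
    ``inputs``/``outputs`` (paths; inputs must exist), ``seed``,
    ``log_level``.  Unknown keys are rejected so typos fail loudly.
    """

    def __init__(self, raw: dict[str, Any]):
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "command" not in raw:
            raise InvalidParameterError("config requires a 'command' key")
        self.command: str = raw["command"]
        self.params: dict[str, Any] = raw.get("params", {})
        self.seed: int = int(raw.get("seed", 0))
        self.log_level: str = raw.get("log_level", "INFO")
        self.inputs: dict[str, str] = raw.get("inputs", {})
        self.outputs: dict[str, str] = raw.get("outputs", {})
        for name, p in self.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r} does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        return cls(yaml.safe_load(text))
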