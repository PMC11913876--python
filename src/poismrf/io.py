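"""Image and provenance file I/O.

Images travel as single-channel 32-bit float TIFF or as plain CSV
(row-major, comma-separated, no header).  CSV round-trips are bitwise
exact (values written with 17 significant digits); TIFF round-trips are
exact to 32-bit float precision.  Run provenance is a plain-text
``key=value`` sidecar.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .exceptions import ConfigurationError, ImageFormatError
from .grids import ImageGrid

__all__ = ["read_image", "write_image", "write_provenance", "read_provenance"]


def read_image(path, kind: str = "truth") -> ImageGrid:
    """Read a ``.tif``/``.tiff`` or ``.csv`` image file.

    ``kind`` sets the validation applied (``observation`` demands
    nonnegative integer counts).
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        try:
            arr = np.asarray(tifffile.imread(path), dtype=float)
        except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
            raise ImageFormatError(f"cannot read TIFF image {path!r}: {exc}") from exc
    elif ext == ".csv":
        try:
            arr = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except Exception as exc:  # noqa: BLE001
            raise ImageFormatError(f"cannot parse {path!r} as comma-separated image: {exc}") from exc
    else:
        raise ImageFormatError(f"unsupported image extension {ext!r} (use .tif or .csv)")
    if arr.ndim != 2:
        raise ImageFormatError(f"{path!r} is not a single-channel 2-D image (shape {arr.shape})")
    try:
        return ImageGrid(arr, kind=kind)
    except ConfigurationError as exc:
        raise ImageFormatError(f"{path!r}: {exc}") from exc


def write_image(grid, path) -> None:
    """Write an image as 32-bit float TIFF or exact-round-trip CSV."""
    path = os.fspath(path)
    arr = np.asarray(grid.values if hasattr(grid, "values") else grid, dtype=float)
    if arr.ndim != 2:
        raise ConfigurationError("can only write 2-D images")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    elif ext == ".csv":
        np.savetxt(path, arr, delimiter=",", fmt="%.17g")
    else:
        raise ImageFormatError(f"unsupported image extension {ext!r} (use .tif or .csv)")


def write_provenance(path, entries: dict) -> None:
    """Write a flat ``key=value`` provenance sidecar (one pair per line)."""
    with open(path, "w") as fh:
        for k, v in entries.items():
            if "=" in str(k) or "\n" in str(k) or "\n" in str(v):
                raise ConfigurationError(f"provenance key/value not serializable: {k!r}")
            fh.write(f"{k}={v}\n")


def read_provenance(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "=" not in line:
                raise ImageFormatError(f"malformed provenance line {line!r}")
            k, v = line.split("=", 1)
            out[k] = v
    return out
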