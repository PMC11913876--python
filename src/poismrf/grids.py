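"""The 2-D pixel lattice container shared by every module.

An :class:`ImageGrid` is a thin, validated wrapper around a 2-D ``numpy``
array.  The ``kind`` tag records what the values mean:

``truth``
    a noiseless activity map (nonnegative reals),
``observation``
    recorded photon counts (nonnegative integers),
``estimate``
    a restored activity map (may be negative for unconstrained estimators
    such as Tikhonov regularization),
``map``
    a derived per-pixel quantity (posterior sd, bias, credible bound, ...).

Pixels are addressed ``(row, col)`` and vectorised row-major (C order), so
pixel ``(r, c)`` is element ``r * n_cols + c`` of the flat vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

KINDS = ("truth", "observation", "estimate", "map")


@dataclass
class ImageGrid:
    values: np.ndarray
    kind: str = "truth"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError(
                f"ImageGrid needs a 2-D array, got shape {self.values.shape}"
            )
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown image kind {self.kind!r}")
        if self.kind in ("truth", "observation") and np.any(self.values < 0):
            raise ConfigurationError(f"{self.kind} image must be elementwise >= 0")
        if self.kind == "observation" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ConfigurationError("observation image must be integer-valued counts")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.values.size

    def vec(self) -> np.ndarray:
        """Row-major flattening (the vector convention of the whole package)."""
        return self.values.ravel(order="C").copy()

    @classmethod
    def from_vec(cls, v: np.ndarray, n_rows: int, n_cols: int, kind: str = "estimate"):
        v = np.asarray(v, dtype=float)
        if v.size != n_rows * n_cols:
            raise ConfigurationError(
                f"vector of length {v.size} does not fill a {n_rows}x{n_cols} grid"
            )
        return cls(v.reshape(n_rows, n_cols), kind=kind)


def as_image(x, kind: str = "truth") -> ImageGrid:
    """Coerce an array or ImageGrid to an ImageGrid of the requested kind."""
    if isinstance(x, ImageGrid):
        return x
    return ImageGrid(np.asarray(x, dtype=float), kind=kind)
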