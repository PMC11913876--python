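"""Synthetic phantoms and forward simulation of gamma-camera observations.

The package is evaluated on simulated data, so this module is first-class:
it builds the piecewise-constant disk phantom (four hot disks of activity
``T`` ≈ 1,100 counts on a zero background, on a 29x58 grid), a
Gaussian-smoothed variant with soft edges, a reduced-exposure (shorter
scanning time) variant, and a mouse-like phantom with organ-shaped hot
blobs.  Observations are Poisson draws with mean ``exposure * A @ vec(x)``
where ``A`` is the point-spread system matrix of :mod:`poismrf.forward`.

The disk geometry below (radii 4/5/5/6 px on a 2x2 layout) is this
package's default reference phantom; all parameters are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .exceptions import ConfigurationError
from .grids import ImageGrid, as_image

__all__ = [
    "DiskPhantomSpec",
    "NoiseConfig",
    "generate_disk_phantom",
    "gaussian_smooth",
    "simulate_observation",
    "make_mouse_phantom",
]

_DEFAULT_RADII = (4.0, 5.0, 5.0, 6.0)
_DEFAULT_ROWS = (9.0, 9.0, 20.0, 20.0)
_DEFAULT_COLS = (14.0, 43.0, 14.0, 43.0)


@dataclass(frozen=True)
class DiskPhantomSpec:
    """Geometry of the hot-disk truth image.

    radii : disk radii in pixels.
    centers_row / centers_col : disk centres in pixel coordinates (0-based).
    intensity : activity of every hot pixel (background is 0).
    """

    radii: tuple = _DEFAULT_RADII
    centers_row: tuple = _DEFAULT_ROWS
    centers_col: tuple = _DEFAULT_COLS
    intensity: float = 1100.0
    n_rows: int = 29
    n_cols: int = 58

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        zr = np.asarray(self.centers_row, dtype=float)
        zc = np.asarray(self.centers_col, dtype=float)
        if not (r.size == zr.size == zc.size) or r.size == 0:
            raise ConfigurationError("radii and centre vectors must have equal nonzero length")
        if np.any(r <= 0):
            raise ConfigurationError("all disk radii must be > 0")
        if self.intensity <= 0:
            raise ConfigurationError("intensity must be > 0")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        inside = (
            (zr - r >= 0)
            & (zr + r <= self.n_rows - 1)
            & (zc - r >= 0)
            & (zc + r <= self.n_cols - 1)
        )
        if not np.all(inside):
            bad = int(np.flatnonzero(~inside)[0])
            raise ConfigurationError(
                f"disk {bad} (r={r[bad]}, centre=({zr[bad]}, {zc[bad]})) extends "
                f"outside the {self.n_rows}x{self.n_cols} grid"
            )
        for a in range(r.size):
            for b in range(a + 1, r.size):
                d = np.hypot(zr[a] - zr[b], zc[a] - zc[b])
                if d < r[a] + r[b]:
                    raise ConfigurationError(f"disks {a} and {b} overlap (centre distance {d:.2f})")


@dataclass(frozen=True)
class NoiseConfig:
    """Poisson observation noise settings.

    exposure : dimensionless scaling of the expected counts; models a change
        of scanning time.  1.0 is the baseline acquisition, 0.25 the default
        reduced-count regime.
    seed : seed for the Poisson draws; a fixed seed makes the observation
        reproducible bit-for-bit.
    """

    exposure: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.exposure <= 0:
            raise ConfigurationError("exposure must be > 0")


def generate_disk_phantom(spec: DiskPhantomSpec = DiskPhantomSpec()) -> ImageGrid:
    """Piecewise-constant truth: ``intensity`` inside any disk, 0 outside.

    A pixel belongs to a disk when its centre lies within the disk radius of
    the disk centre (Euclidean distance, inclusive).
    """
    rr, cc = np.meshgrid(
        np.arange(spec.n_rows, dtype=float),
        np.arange(spec.n_cols, dtype=float),
        indexing="ij",
    )
    hot = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    for r, zr, zc in zip(spec.radii, spec.centers_row, spec.centers_col):
        hot |= (rr - zr) ** 2 + (cc - zc) ** 2 <= float(r) ** 2
    return ImageGrid(np.where(hot, float(spec.intensity), 0.0), kind="truth")


def gaussian_smooth(x, kernel_sd: float, truncate: float = 4.0) -> ImageGrid:
    """Convolve a truth image with a normalized, truncated Gaussian kernel.

    The kernel is truncated at ``truncate * kernel_sd`` and renormalized at
    the image boundary (normalized convolution: the blurred image is divided
    by the blurred indicator of the support), so a constant image stays
    exactly constant and no mass wraps around the edges.
    """
    img = as_image(x, kind="truth")
    if kernel_sd <= 0:
        raise ConfigurationError("kernel_sd must be > 0")
    radius = int(truncate * float(kernel_sd) + 0.5)
    if radius == 0:
        return ImageGrid(img.values.copy(), kind="truth")
    num = ndi.gaussian_filter(img.values, kernel_sd, mode="constant", cval=0.0, truncate=truncate)
    den = ndi.gaussian_filter(
        np.ones_like(img.values), kernel_sd, mode="constant", cval=0.0, truncate=truncate
    )
    out = num / den
    # guard against fp undershoot: convolution cannot leave the data range
    np.clip(out, img.values.min(), img.values.max(), out=out)
    return ImageGrid(out, kind="truth")


def simulate_observation(x, A, noise: NoiseConfig = NoiseConfig()) -> ImageGrid:
    """Draw ``y_i ~ Poisson(exposure * (A @ vec(x))_i)`` independently."""
    img = as_image(x, kind="truth")
    if A.m != img.n_pixels:
        raise ConfigurationError(
            f"system matrix has {A.m} source pixels, image has {img.n_pixels}"
        )
    lam = noise.exposure * (A.matrix @ img.vec())
    if np.any(lam < -1e-9):
        raise ConfigurationError("negative expected counts from a valid truth image")
    lam = np.maximum(lam, 0.0)
    rng = np.random.default_rng(noise.seed)
    y = rng.poisson(lam).astype(float)
    # detector grid mirrors the image grid (n == m)
    return ImageGrid(y.reshape(img.n_rows, img.n_cols), kind="observation")


def make_mouse_phantom(n_rows: int, n_cols: int, seed: int = 0) -> ImageGrid:
    """Mouse-like truth image: an elliptical low-activity body with organ-like
    hot blobs (two kidneys and a bladder) on a zero background.

    Piecewise constant, values within [0, 1100]; deterministic for a fixed
    seed (the seed jitters the organ centres by up to one pixel).
    """
    if n_rows < 29 or n_cols < 58:
        raise ConfigurationError("mouse phantom needs a grid of at least 29x58")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(n_rows, dtype=float), np.arange(n_cols, dtype=float), indexing="ij")
    img = np.zeros((n_rows, n_cols))

    # body: low-activity ellipse (soft-tissue background uptake)
    brow, bcol = 0.50 * (n_rows - 1), 0.46 * (n_cols - 1)
    ar, ac = 0.40 * n_rows, 0.32 * n_cols
    body = ((rr - brow) / ar) ** 2 + ((cc - bcol) / ac) ** 2 <= 1.0
    img[body] = 60.0

    scale = min(n_rows, n_cols)
    jitter = lambda: rng.integers(-1, 2)  # noqa: E731
    organs = [
        (0.42 * (n_rows - 1), 0.36 * (n_cols - 1), 0.09 * scale, 950.0),   # left kidney
        (0.42 * (n_rows - 1), 0.56 * (n_cols - 1), 0.09 * scale, 950.0),   # right kidney
        (0.76 * (n_rows - 1), 0.46 * (n_cols - 1), 0.08 * scale, 1100.0),  # bladder
    ]
    for orow, ocol, orad, val in organs:
        orow += jitter()
        ocol += jitter()
        blob = (rr - orow) ** 2 + (cc - ocol) ** 2 <= orad**2
        img[blob] = val
    return ImageGrid(img, kind="truth")
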