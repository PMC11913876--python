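"""Point-spread forward model and Poisson likelihood.

The system matrix ``A`` maps source-pixel activity to expected detector
counts: ``E[y_i] = lambda_i = sum_j a_ij x_j``.  Entry ``a_ij`` is the
probability that a photon emitted from source pixel j is recorded in
detector cell i; it is an isotropic Gaussian point-spread function of
standard deviation ``psf_sd`` (pixels) evaluated at the centre offset
between the two pixels, truncated at ``truncation_radius`` and normalized
so every source pixel's retained kernel sums to 1.  Columns of source
pixels near the image boundary lose the part of their kernel that falls
off the detector grid, so their sums are < 1 — photons near the edge can
go unrecorded.  ``psf_sd = 0`` gives the identity (perfect detection).

The detector grid coincides with the image grid (n = m), matching a
planar gamma-camera acquisition at matched resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .exceptions import ConfigurationError, NumericError
from .grids import ImageGrid, as_image

__all__ = [
    "SystemMatrix",
    "build_system_matrix",
    "forward_project",
    "poisson_loglik",
    "loglik_delta",
]


@dataclass
class SystemMatrix:
    """Sparse n x m detection-probability matrix with its PSF parameters."""

    matrix: sp.csr_matrix
    psf_sd: float
    truncation_radius: float
    n_rows: int
    n_cols: int

    _csc: sp.csc_matrix = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def csc(self) -> sp.csc_matrix:
        """Column-compressed view (cached); used for single-pixel updates."""
        if self._csc is None:
            self._csc = self.matrix.tocsc()
            self._csc.sort_indices()
        return self._csc

    def column(self, j: int):
        """(detector indices, values) of column j's support."""
        c = self.csc
        sl = slice(c.indptr[j], c.indptr[j + 1])
        return c.indices[sl], c.data[sl]

    def save_text(self, path) -> None:
        """Persist in coordinate format: one ``row col value`` line per entry."""
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write(f"# n={self.n} m={self.m} psf_sd={self.psf_sd} "
                     f"truncation_radius={self.truncation_radius} "
                     f"n_rows={self.n_rows} n_cols={self.n_cols}\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r} {c} {v:.17g}\n")


def build_system_matrix(
    n_rows: int,
    n_cols: int,
    psf_sd: float,
    truncation_radius: float | None = None,
) -> SystemMatrix:
    """Construct the Gaussian-PSF system matrix for an ``n_rows x n_cols`` grid.

    ``truncation_radius`` defaults to ``4 * psf_sd``.  Pixels are indexed
    row-major; source pixel (r, c) spreads onto detector cells (r+di, c+dj)
    for all integer offsets with ``di**2 + dj**2 <= truncation_radius**2``,
    with weight proportional to ``exp(-(di**2+dj**2) / (2 psf_sd**2))``,
    normalized over the retained offsets.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if psf_sd < 0:
        raise ConfigurationError("psf_sd must be >= 0")
    m = n_rows * n_cols
    if psf_sd == 0:
        mat = sp.identity(m, format="csr")
        return SystemMatrix(mat, 0.0, truncation_radius or 0.0, n_rows, n_cols)
    if truncation_radius is None:
        truncation_radius = 4.0 * psf_sd
    if truncation_radius <= 0:
        raise ConfigurationError("truncation_radius must be > 0")

    R = int(np.floor(truncation_radius))
    di, dj = np.meshgrid(np.arange(-R, R + 1), np.arange(-R, R + 1), indexing="ij")
    keep = di**2 + dj**2 <= truncation_radius**2
    di, dj = di[keep], dj[keep]
    w = np.exp(-(di**2 + dj**2) / (2.0 * psf_sd**2))
    w /= w.sum()

    rows_src, cols_src = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows_src = rows_src.ravel()
    cols_src = cols_src.ravel()
    src_idx = np.arange(m)

    out_r, out_c, out_v = [], [], []
    for o in range(di.size):
        dr, dc, wv = int(di[o]), int(dj[o]), w[o]
        tr = rows_src + dr
        tc = cols_src + dc
        ok = (tr >= 0) & (tr < n_rows) & (tc >= 0) & (tc < n_cols)
        out_r.append(tr[ok] * n_cols + tc[ok])
        out_c.append(src_idx[ok])
        out_v.append(np.full(ok.sum(), wv))
    mat = sp.coo_matrix(
        (np.concatenate(out_v), (np.concatenate(out_r), np.concatenate(out_c))),
        shape=(m, m),
    ).tocsr()
    return SystemMatrix(mat, float(psf_sd), float(truncation_radius), n_rows, n_cols)


def forward_project(A: SystemMatrix, x) -> np.ndarray:
    """Expected counts ``lambda = A @ vec(x)``."""
    img = as_image(x, kind="truth")
    if img.n_pixels != A.m:
        raise ConfigurationError(
            f"image has {img.n_pixels} pixels, system matrix expects {A.m}"
        )
    v = img.vec()
    if np.any(v < 0):
        raise ConfigurationError("activity image must be nonnegative")
    return A.matrix @ v


def poisson_loglik(y: np.ndarray, lam: np.ndarray) -> float:
    """Poisson log-likelihood ``sum_i [y_i ln lam_i - lam_i - ln(y_i!)]``.

    Uses the convention ``0 * ln 0 = 0``; returns ``-inf`` when some
    ``y_i > 0`` has ``lam_i = 0`` (data impossible under the model).
    """
    y = np.asarray(y, dtype=float).ravel()
    lam = np.asarray(lam, dtype=float).ravel()
    if y.shape != lam.shape:
        raise ConfigurationError("y and lambda must have the same length")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ConfigurationError("y must be nonnegative integer counts")
    if np.any(lam < 0):
        raise ConfigurationError("lambda must be nonnegative")
    pos = y > 0
    if np.any(lam[pos] == 0):
        return -np.inf
    out = -lam.sum() - gammaln(y + 1.0).sum()
    out += float(np.sum(y[pos] * np.log(lam[pos])))
    return float(out)


def loglik_delta(y: np.ndarray, lam: np.ndarray, j: int, dx: float, A: SystemMatrix) -> float:
    """Change in Poisson log-likelihood when pixel j moves by ``dx``.

    Touches only the detector cells in column j's support; equals
    ``poisson_loglik(y, lam') - poisson_loglik(y, lam)`` where
    ``lam' = lam + dx * A[:, j]``.  Raises if the move would drive any
    expected count negative.
    """
    y = np.asarray(y, dtype=float).ravel()
    lam = np.asarray(lam, dtype=float).ravel()
    rows, vals = A.column(j)
    new = lam[rows] + vals * dx
    if np.any(new < -1e-12 * max(1.0, float(np.abs(lam).max(initial=1.0)))):
        raise NumericError(f"update dx={dx} on pixel {j} drives expected counts negative")
    new = np.maximum(new, 0.0)
    ysub = y[rows]
    pos = ysub > 0
    d = -float(np.sum(new - lam[rows]))
    if np.any(pos):
        old_pos = lam[rows][pos]
        new_pos = new[pos]
        if np.any(new_pos == 0):
            return -np.inf
        with np.errstate(divide="ignore"):
            d += float(np.sum(ysub[pos] * (np.log(new_pos) - np.log(old_pos))))
    return d
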