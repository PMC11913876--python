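"""Neighbourhood system, LMRF prior, hyper-priors and the joint log-posterior.

The image prior is a Markov random field with the Laplacian (absolute
difference) pair potential.  Writing ``S_j = sum_{t in d(j)} w_jt |x_j - x_t|``
for the local energy of pixel j over its first-order neighbourhood d(j), the
prior is the product of local conditionals

    pi(x | tau) = prod_j (2 tau_j)^(-1) exp(-S_j / tau_j),      x_j >= 0,

a *pseudo-likelihood*: each unordered neighbour pair contributes to both
endpoints' sums and no global normalizing constant is computed.  The
package treats this product literally as the target density, which is the
only reading under which posterior comparisons across tau are meaningful.

Two variants are supported: a *homogeneous* model with one global variance
``tau`` and the *locally adaptive* (inhomogeneous) model with per-pixel
``tau_j``, each given an independent exponential hyper-prior of rate
``gamma``.  ``gamma`` itself is either fixed (default, after calibration)
or given an exponential hyper-hyper-prior of rate ``theta`` and sampled.

All log-densities are reported up to one shared additive constant (the
constants independent of x, tau and gamma are dropped consistently).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError
from .grids import as_image

__all__ = [
    "NeighborhoodGraph",
    "PriorConfig",
    "build_neighborhood",
    "local_energy",
    "log_prior",
    "log_hyperprior",
    "log_joint_posterior",
    "tau_conditional_params",
    "gamma_conditional_params",
    "TauConditional",
]


@dataclass
class NeighborhoodGraph:
    """First-order adjacency in compressed form.

    ``indices[indptr[j]:indptr[j+1]]`` are the neighbours of site j and
    ``weights`` the matching pair weights (symmetric: w_jt == w_tj).
    """

    indptr: np.ndarray
    indices: np.ndarray
    weights: np.ndarray
    n_sites: int
    order: str = "first_2d"

    def neighbors(self, j: int):
        sl = slice(self.indptr[j], self.indptr[j + 1])
        return self.indices[sl], self.weights[sl]

    def degree(self, j: int) -> int:
        return int(self.indptr[j + 1] - self.indptr[j])

    @property
    def n_directed_edges(self) -> int:
        return int(self.indices.size)


def build_neighborhood(
    n_rows: int,
    n_cols: int,
    order: str = "first_2d",
    n_layers: int = 1,
    weight: float = 1.0,
) -> NeighborhoodGraph:
    """4-neighbour lattice graph (or 6-neighbour for a stacked 3-D grid).

    Sites are indexed layer-major then row-major: site
    ``l * n_rows * n_cols + r * n_cols + c``.  All retained pairs carry the
    same weight (default 1); the prior actually used in the restoration
    results carries no pair weights, but a uniform ``weight`` is exposed
    for the weighted generalisation.
    """
    if n_rows <= 0 or n_cols <= 0 or n_layers <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if order not in ("first_2d", "first_3d"):
        raise ConfigurationError(f"unknown neighbourhood order {order!r}")
    if order == "first_2d" and n_layers != 1:
        raise ConfigurationError("first_2d neighbourhood is single-layer")
    if weight < 0:
        raise ConfigurationError("pair weight must be >= 0")

    plane = n_rows * n_cols
    m = plane * n_layers
    indptr = np.zeros(m + 1, dtype=np.int64)
    nbrs = []
    for l in range(n_layers):
        for r in range(n_rows):
            for c in range(n_cols):
                cur = []
                if r > 0:
                    cur.append(((l * n_rows + r - 1) * n_cols) + c)
                if r < n_rows - 1:
                    cur.append(((l * n_rows + r + 1) * n_cols) + c)
                if c > 0:
                    cur.append((l * n_rows + r) * n_cols + c - 1)
                if c < n_cols - 1:
                    cur.append((l * n_rows + r) * n_cols + c + 1)
                if order == "first_3d":
                    if l > 0:
                        cur.append(((l - 1) * n_rows + r) * n_cols + c)
                    if l < n_layers - 1:
                        cur.append(((l + 1) * n_rows + r) * n_cols + c)
                j = (l * n_rows + r) * n_cols + c
                indptr[j + 1] = indptr[j] + len(cur)
                nbrs.extend(cur)
    indices = np.asarray(nbrs, dtype=np.int64)
    weights = np.full(indices.size, float(weight))
    return NeighborhoodGraph(indptr, indices, weights, m, order=order)


@dataclass(frozen=True)
class PriorConfig:
    """Prior and hyper-prior settings.

    mode : "homogeneous" (one global tau) or "inhomogeneous" (per-pixel tau_j).
    tau : global conditional variance (homogeneous mode; also the
        initial value when ``sample_tau`` is on).
    tau_vec : optional explicit per-pixel variances (inhomogeneous mode).
    sample_tau : update tau by MCMC.  Default on for the locally adaptive
        model (the variances are the point of the model) and off for the
        homogeneous model, where tau is a user choice unless enabled.
    gamma_rate : rate gamma of the exponential hyper-prior on each tau_j
        (1e-2 by default, the calibrated value).
    gamma_fixed : keep gamma at ``gamma_rate`` (default) instead of
        sampling it under the exp(theta) hyper-hyper-prior.
    theta : rate of the hyper-hyper-prior on gamma.
    tau_floor : hard lower bound on every variance.  The tau_j full
        conditional is improper at 0 on perfectly flat neighbourhoods
        (S_j = 0); the floor keeps the chain proper there and is far below
        any variance a non-flat neighbourhood produces.
    """

    mode: str = "inhomogeneous"
    tau: float = 50.0
    tau_vec: np.ndarray | None = None
    sample_tau: bool | None = None
    gamma_rate: float = 1e-2
    gamma_fixed: bool = True
    theta: float = 1e-2
    tau_floor: float = 1e-3

    def __post_init__(self):
        if self.mode not in ("homogeneous", "inhomogeneous"):
            raise ConfigurationError(f"unknown prior mode {self.mode!r}")
        if self.tau <= 0 or self.gamma_rate <= 0 or self.theta <= 0 or self.tau_floor <= 0:
            raise ConfigurationError("tau, gamma_rate, theta and tau_floor must be > 0")
        if self.tau_vec is not None:
            tv = np.asarray(self.tau_vec, dtype=float)
            if np.any(tv <= 0):
                raise ConfigurationError("all tau_j must be > 0")
            if np.any(tv < self.tau_floor):
                raise ConfigurationError("tau_floor must not exceed min(tau_vec)")
            object.__setattr__(self, "tau_vec", tv)
        if self.sample_tau is None:
            object.__setattr__(self, "sample_tau", self.mode == "inhomogeneous")

    def taus(self, m: int) -> np.ndarray:
        """Per-pixel variance vector of length m implied by the config."""
        if self.mode == "homogeneous":
            return np.full(m, float(self.tau))
        if self.tau_vec is not None:
            if self.tau_vec.size != m:
                raise ConfigurationError(
                    f"tau_vec has length {self.tau_vec.size}, image has {m} pixels"
                )
            return self.tau_vec.astype(float)
        return np.full(m, float(self.tau))


def local_energy(x, j: int, G: NeighborhoodGraph) -> float:
    """``S_j = sum_{t in d(j)} w_jt |x_j - x_t|``."""
    v = np.asarray(x.values if hasattr(x, "values") else x, dtype=float).ravel()
    idx, w = G.neighbors(j)
    return float(np.sum(w * np.abs(v[j] - v[idx])))


def _all_energies(v: np.ndarray, G: NeighborhoodGraph) -> np.ndarray:
    if G.indices.size == 0:
        return np.zeros(G.n_sites)
    deg = np.diff(G.indptr)
    diffs = np.abs(v[np.repeat(np.arange(G.n_sites), deg)] - v[G.indices])
    return np.add.reduceat(G.weights * diffs, G.indptr[:-1]) * (deg > 0)


def log_prior(x, G: NeighborhoodGraph, cfg: PriorConfig) -> float:
    """LMRF pseudo-likelihood log-density ``sum_j [-ln(2 tau_j) - S_j / tau_j]``."""
    v = np.asarray(x.values if hasattr(x, "values") else x, dtype=float).ravel()
    if v.size != G.n_sites:
        raise ConfigurationError("image size does not match neighbourhood graph")
    tau = cfg.taus(v.size)
    S = _all_energies(v, G)
    return float(np.sum(-np.log(2.0 * tau) - S / tau))


def log_hyperprior(cfg: PriorConfig, m: int | None = None) -> float:
    """Log-density of the variance hyper-prior (and of gamma when sampled).

    Inhomogeneous mode: ``sum_j [ln gamma - gamma tau_j]`` over the m
    per-pixel variances.  Homogeneous mode: a single term for the global
    tau.  When gamma is sampled its exp(theta) hyper-hyper term
    ``ln theta - theta gamma`` is added; when fixed it is omitted.
    """
    g = cfg.gamma_rate
    if cfg.mode == "homogeneous":
        out = np.log(g) - g * cfg.tau
    else:
        if cfg.tau_vec is not None:
            taus = cfg.tau_vec
        elif m is not None:
            taus = cfg.taus(m)
        else:
            raise ConfigurationError("inhomogeneous hyper-prior needs tau_vec or m")
        out = float(np.sum(np.log(g) - g * taus))
    if not cfg.gamma_fixed:
        out += np.log(cfg.theta) - cfg.theta * g
    return float(out)


def log_joint_posterior(y, x, cfg: PriorConfig, A, G: NeighborhoodGraph) -> float:
    """Unnormalized log posterior: likelihood + LMRF prior + hyper-priors."""
    from .forward import forward_project, poisson_loglik

    img = as_image(x, kind="truth")
    yv = np.asarray(y.values if hasattr(y, "values") else y, dtype=float).ravel()
    lam = forward_project(A, img)
    return (
        poisson_loglik(yv, lam)
        + log_prior(img, G, cfg)
        + log_hyperprior(cfg, m=img.n_pixels)
    )


@dataclass(frozen=True)
class TauConditional:
    """Full conditional of one local variance tau_j.

    Unnormalized density ``p(tau) = tau^(-1) exp(-S / tau - gamma * tau)``
    on (0, inf) — a generalized-inverse-Gaussian form with index 0.  When
    ``S == 0`` the density is non-integrable at 0 (``degenerate`` is set)
    and the sampler's tau_floor takes over.
    """

    S: float
    gamma: float
    mode: float
    degenerate: bool

    def log_density(self, tau):
        tau = np.asarray(tau, dtype=float)
        return -np.log(tau) - self.S / tau - self.gamma * tau


def tau_conditional_params(S: float, gamma: float) -> TauConditional:
    """Conditional density descriptor and its mode for one tau_j.

    The mode solves ``gamma tau^2 + tau - S = 0``:
    ``tau* = (-1 + sqrt(1 + 4 gamma S)) / (2 gamma)``.
    """
    if S < 0:
        raise ConfigurationError("local energy S must be >= 0")
    if gamma <= 0:
        raise ConfigurationError("gamma must be > 0")
    mode = (-1.0 + np.sqrt(1.0 + 4.0 * gamma * S)) / (2.0 * gamma)
    return TauConditional(S=float(S), gamma=float(gamma), mode=float(mode), degenerate=S == 0)


def gamma_conditional_params(tau_vec: np.ndarray, theta: float) -> tuple[float, float]:
    """Gamma full conditional given the variances: shape m+1, rate sum(tau)+theta."""
    tau_vec = np.asarray(tau_vec, dtype=float)
    if np.any(tau_vec <= 0) or theta <= 0:
        raise ConfigurationError("tau_j and theta must be > 0")
    return float(tau_vec.size + 1), float(tau_vec.sum() + theta)
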