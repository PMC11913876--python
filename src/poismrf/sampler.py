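"""Metropolis-within-Gibbs sampler over (x, tau, gamma) and chain summaries.

The target is the joint posterior of the restoration model: Poisson
likelihood with expected counts ``exposure * A @ x``, LMRF pseudo-likelihood
prior on x with variances tau, exponential hyper-prior of rate gamma on
the variances, and optionally an exponential hyper-hyper-prior on gamma.

One iteration sweeps every pixel (Gaussian random-walk MH with proposals
below zero rejected outright), then every variance (log-scale random-walk
MH against its generalized-inverse-Gaussian full conditional, truncated at
``tau_floor``), then redraws gamma exactly from its Gamma full conditional
when it is sampled.  Pixel proposal scales start at ``sqrt(max(x0_j, 1))``
(the Poisson posterior scale) and adapt toward a target acceptance rate
during burn-in only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from .exceptions import ConfigurationError
from .forward import SystemMatrix
from .grids import ImageGrid, as_image
from .priors import NeighborhoodGraph, PriorConfig

__all__ = [
    "ChainConfig",
    "ChainState",
    "Chain",
    "PosteriorSummary",
    "run_chain",
    "summarize_chain",
    "mh_update_pixel",
    "mh_update_tau",
    "gibbs_update_gamma",
    "seed_kernels",
    "potential_scale_reduction",
]


@dataclass(frozen=True)
class ChainConfig:
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    pixel_proposal_sd: float | None = None  # None: auto sqrt(max(x0, 1)) per pixel
    tau_proposal_sd: float = 0.5  # log-scale
    seed: int = 0
    update_order: str = "raster"  # or "random_permutation"
    adapt_target: float = 0.3
    adapt_rate: float = 0.25

    def __post_init__(self):
        if self.n_iter <= 0 or not (0 <= self.burn_in < self.n_iter) or self.thin <= 0:
            raise ConfigurationError("need 0 <= burn_in < n_iter and thin >= 1")
        if self.pixel_proposal_sd is not None and self.pixel_proposal_sd <= 0:
            raise ConfigurationError("pixel_proposal_sd must be > 0")
        if self.tau_proposal_sd <= 0:
            raise ConfigurationError("tau_proposal_sd must be > 0")
        if self.update_order not in ("raster", "random_permutation"):
            raise ConfigurationError(f"unknown update order {self.update_order!r}")

    @property
    def n_kept(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class ChainState:
    """One MCMC state: activity vector, variances, hyper-rate, log posterior."""

    x: np.ndarray
    tau_vec: np.ndarray
    gamma: float
    log_post: float


@dataclass
class Chain:
    """Thinned post-burn-in draws plus bookkeeping."""

    draws_x: np.ndarray  # (K, m)
    draws_tau: np.ndarray  # (K, m)
    draws_gamma: np.ndarray  # (K,)
    log_post: np.ndarray  # (K,)
    accept_rate_x: float
    accept_rate_tau: float
    n_rows: int
    n_cols: int
    chain_config: ChainConfig
    prior_config: PriorConfig
    exposure: float

    @property
    def n_draws(self) -> int:
        return self.draws_x.shape[0]

    @property
    def m(self) -> int:
        return self.draws_x.shape[1]

    def pixel_draws(self, positions) -> np.ndarray:
        """(K, len(positions)) draws at flat pixel indices; box-plot fodder."""
        return self.draws_x[:, np.asarray(positions, dtype=int)]


@dataclass
class PosteriorSummary:
    """Per-pixel posterior mean, sd, 2.5%/97.5% bounds and optional bias."""

    mean: np.ndarray
    sd: np.ndarray
    lci: np.ndarray
    ucl: np.ndarray
    bias: np.ndarray | None
    n_rows: int
    n_cols: int

    def map(self, name: str) -> ImageGrid:
        arr = getattr(self, name)
        if arr is None:
            raise ConfigurationError(f"summary has no {name!r} map (no truth supplied?)")
        return ImageGrid(arr.reshape(self.n_rows, self.n_cols), kind="map")

    @property
    def ci_width(self) -> np.ndarray:
        return self.ucl - self.lci


def seed_kernels(seed: int) -> None:
    """Seed the compiled kernels' RNG (used by the single-step update API)."""
    K.seed_rng(int(seed) % 2**31)


def _graph_arrays(G: NeighborhoodGraph):
    return (
        np.ascontiguousarray(G.indptr, dtype=np.int64),
        np.ascontiguousarray(G.indices, dtype=np.int64),
        np.ascontiguousarray(G.weights, dtype=np.float64),
    )


def _csc_arrays(A: SystemMatrix, exposure: float):
    c = A.csc
    return (
        np.ascontiguousarray(c.indptr, dtype=np.int64),
        np.ascontiguousarray(c.indices, dtype=np.int64),
        np.ascontiguousarray(c.data * exposure, dtype=np.float64),
    )


def run_chain(
    y,
    A: SystemMatrix,
    G: NeighborhoodGraph,
    cfg: PriorConfig = PriorConfig(),
    chain_cfg: ChainConfig = ChainConfig(),
    exposure: float = 1.0,
    x0: np.ndarray | None = None,
) -> Chain:
    """Run the sampler on observation y and return the thinned chain.

    ``exposure`` is the known acquisition-time factor of the observation
    (the model mean is ``exposure * A @ x``), so estimates stay on the
    activity scale of the truth regardless of counting time.
    Initialisation: ``x0 = y / exposure`` clipped to >= 0 (overridable),
    ``tau_j = 1`` in the adaptive model (the configured tau otherwise),
    ``gamma = gamma_rate``.  Fully reproducible for a fixed seed.
    """
    obs = as_image(y, kind="observation")
    m = obs.n_pixels
    if A.m != m:
        raise ConfigurationError("system matrix and observation sizes differ")
    if G.n_sites != m:
        raise ConfigurationError("neighbourhood graph and observation sizes differ")
    if exposure <= 0:
        raise ConfigurationError("exposure must be > 0")

    yv = obs.vec()
    if x0 is None:
        x = np.maximum(yv / exposure, 0.0)
    else:
        x = np.maximum(np.asarray(x0, dtype=float).ravel().copy(), 0.0)
        if x.size != m:
            raise ConfigurationError("x0 size mismatch")

    if cfg.mode == "inhomogeneous" and cfg.tau_vec is None and cfg.sample_tau:
        tau = np.ones(m)
    else:
        tau = cfg.taus(m)
    tau = np.maximum(tau, cfg.tau_floor)

    if chain_cfg.pixel_proposal_sd is not None:
        step = np.full(m, float(chain_cfg.pixel_proposal_sd))
    else:
        step = np.sqrt(np.maximum(x, 1.0))

    Aip, Arow, Aval = _csc_arrays(A, exposure)
    nbp, nbi, nbw = _graph_arrays(G)
    lam = np.zeros(m)

    Kn = chain_cfg.n_kept
    out_x = np.empty((Kn, m))
    out_tau = np.empty((Kn, m))
    out_gamma = np.empty(Kn)
    out_logpost = np.empty(Kn)

    K.seed_rng(int(chain_cfg.seed) % 2**31)
    acc_x, acc_t, _gamma, kept = K.run_chain_kernel(
        yv,
        x,
        tau,
        float(cfg.gamma_rate),
        lam,
        Aip,
        Arow,
        Aval,
        nbp,
        nbi,
        nbw,
        chain_cfg.n_iter,
        chain_cfg.burn_in,
        chain_cfg.thin,
        step,
        float(chain_cfg.tau_proposal_sd),
        float(cfg.tau_floor),
        float(cfg.theta),
        cfg.mode == "inhomogeneous",
        bool(cfg.sample_tau),
        bool(cfg.gamma_fixed),
        chain_cfg.update_order == "random_permutation",
        float(chain_cfg.adapt_target),
        float(chain_cfg.adapt_rate),
        out_x,
        out_tau,
        out_gamma,
        out_logpost,
    )
    assert kept == Kn
    return Chain(
        draws_x=out_x,
        draws_tau=out_tau,
        draws_gamma=out_gamma,
        log_post=out_logpost,
        accept_rate_x=float(acc_x),
        accept_rate_tau=float(acc_t),
        n_rows=obs.n_rows,
        n_cols=obs.n_cols,
        chain_config=chain_cfg,
        prior_config=cfg,
        exposure=float(exposure),
    )


def summarize_chain(chain: Chain, truth=None) -> PosteriorSummary:
    """Per-pixel posterior mean, sd, 95% credible bounds and (optionally) bias."""
    if chain.n_draws == 0:
        raise ConfigurationError("cannot summarize an empty chain")
    mean = chain.draws_x.mean(axis=0)
    sd = chain.draws_x.std(axis=0, ddof=0)
    lci = np.percentile(chain.draws_x, 2.5, axis=0)
    ucl = np.percentile(chain.draws_x, 97.5, axis=0)
    bias = None
    if truth is not None:
        tv = as_image(truth, kind="truth").vec()
        if tv.size != chain.m:
            raise ConfigurationError("truth size does not match chain")
        bias = mean - tv
    return PosteriorSummary(
        mean=mean, sd=sd, lci=lci, ucl=ucl, bias=bias,
        n_rows=chain.n_rows, n_cols=chain.n_cols,
    )


# ---------------------------------------------------------------------------
# single-step update API (the same compiled kernels the full sweep uses)
# ---------------------------------------------------------------------------

def _state_context(state: ChainState, A: SystemMatrix, exposure: float = 1.0):
    Aip, Arow, Aval = _csc_arrays(A, exposure)
    lam = np.zeros(A.n)
    K.recompute_lam(state.x, Aip, Arow, Aval, lam)
    return Aip, Arow, Aval, lam


def mh_update_pixel(
    state: ChainState,
    j: int,
    y,
    A: SystemMatrix,
    G: NeighborhoodGraph,
    cfg: PriorConfig,
    chain_cfg: ChainConfig,
    exposure: float = 1.0,
) -> tuple[ChainState, bool]:
    """One random-walk MH update of pixel j.  Seed via :func:`seed_kernels`."""
    yv = as_image(y, kind="observation").vec()
    Aip, Arow, Aval, lam = _state_context(state, A, exposure)
    nbp, nbi, nbw = _graph_arrays(G)
    step = chain_cfg.pixel_proposal_sd or float(np.sqrt(max(state.x[j], 1.0)))
    accepted = K.pixel_update(
        j, state.x, state.tau_vec, lam, yv, Aip, Arow, Aval, nbp, nbi, nbw, step
    )
    return state, bool(accepted)


def mh_update_tau(
    state: ChainState,
    j: int,
    G: NeighborhoodGraph,
    cfg: PriorConfig,
    chain_cfg: ChainConfig,
) -> tuple[ChainState, bool]:
    """One log-scale MH update of variance tau_j against its full conditional."""
    S = K.site_energy(state.x, j, *_graph_arrays(G))
    t, acc = K.tau_update(
        state.tau_vec[j], S, state.gamma, chain_cfg.tau_proposal_sd, cfg.tau_floor
    )
    state.tau_vec[j] = t
    return state, bool(acc)


def gibbs_update_gamma(state: ChainState, cfg: PriorConfig) -> ChainState:
    """Exact Gamma(m+1, sum(tau)+theta) draw for gamma; no-op when fixed."""
    if cfg.gamma_fixed:
        warnings.warn("gamma is fixed; gibbs_update_gamma is a no-op", stacklevel=2)
        return state
    shape = state.tau_vec.size + 1.0
    rate = float(state.tau_vec.sum()) + cfg.theta
    state.gamma = float(K.draw_gamma(shape, rate))
    return state


def potential_scale_reduction(draws_per_chain: list[np.ndarray]) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per component.

    ``draws_per_chain`` is a list of (K,) or (K, p) arrays from independently
    initialised chains of equal length.
    """
    arrs = [np.atleast_2d(np.asarray(d, dtype=float).T).T for d in draws_per_chain]
    n = min(a.shape[0] for a in arrs)
    stacked = np.stack([a[:n] for a in arrs])  # (c, n, p)
    c = stacked.shape[0]
    means = stacked.mean(axis=1)  # (c, p)
    variances = stacked.var(axis=1, ddof=1)  # (c, p)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W > 0, rhat, 1.0)
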