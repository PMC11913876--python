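"""Top-level run configuration and deterministic seed derivation.

A :class:`RunConfig` bundles everything an end-to-end run needs (phantom
geometry, noise, PSF, prior, chain settings).  One global seed
deterministically derives the per-module seeds, so a whole
simulate -> fit -> evaluate pipeline reproduces exactly from a single
integer.  Configurations round-trip losslessly through the flat
``key=value`` provenance format of :mod:`poismrf.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError
from .phantom import DiskPhantomSpec, NoiseConfig
from .priors import PriorConfig
from .sampler import ChainConfig

__all__ = ["RunConfig", "derive_seeds"]


def derive_seeds(seed: int, labels) -> dict:
    """Deterministically derive one sub-seed (< 2**31) per label."""
    ss = np.random.SeedSequence(int(seed))
    state = ss.generate_state(len(labels))
    return {lab: int(s % 2**31) for lab, s in zip(labels, state)}


@dataclass(frozen=True)
class RunConfig:
    phantom: DiskPhantomSpec = DiskPhantomSpec()
    regime: str = "sharp"  # sharp | smooth | low-count | mouse
    exposure: float = 1.0
    smooth_sd: float = 1.5
    delta: float = 1.2
    truncation_radius: float | None = None
    prior: PriorConfig = PriorConfig()
    chain: ChainConfig = ChainConfig()
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("sharp", "smooth", "low-count", "mouse"):
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.exposure <= 0 or self.smooth_sd <= 0 or self.delta < 0:
            raise ConfigurationError("exposure/smooth_sd must be > 0 and delta >= 0")

    def seeds(self) -> dict:
        return derive_seeds(self.seed, ["noise", "chain", "cv", "sweep", "mouse"])

    def noise(self) -> NoiseConfig:
        return NoiseConfig(exposure=self.exposure, seed=self.seeds()["noise"])

    def flat(self) -> dict:
        """Flat key=value view for the provenance sidecar (lossless)."""
        p = self.phantom
        out = {
            "regime": self.regime,
            "exposure": repr(self.exposure),
            "smooth_sd": repr(self.smooth_sd),
            "delta": repr(self.delta),
            "truncation_radius": repr(self.truncation_radius),
            "seed": self.seed,
            "phantom.radii": ",".join(repr(float(v)) for v in p.radii),
            "phantom.centers_row": ",".join(repr(float(v)) for v in p.centers_row),
            "phantom.centers_col": ",".join(repr(float(v)) for v in p.centers_col),
            "phantom.intensity": repr(p.intensity),
            "phantom.n_rows": p.n_rows,
            "phantom.n_cols": p.n_cols,
            "prior.mode": self.prior.mode,
            "prior.tau": repr(self.prior.tau),
            "prior.sample_tau": self.prior.sample_tau,
            "prior.gamma_rate": repr(self.prior.gamma_rate),
            "prior.gamma_fixed": self.prior.gamma_fixed,
            "prior.theta": repr(self.prior.theta),
            "prior.tau_floor": repr(self.prior.tau_floor),
            "chain.n_iter": self.chain.n_iter,
            "chain.burn_in": self.chain.burn_in,
            "chain.thin": self.chain.thin,
            "chain.tau_proposal_sd": repr(self.chain.tau_proposal_sd),
            "chain.update_order": self.chain.update_order,
        }
        return out

    @classmethod
    def from_flat(cls, d: dict) -> "RunConfig":
        def tup(key):
            return tuple(float(v) for v in d[key].split(","))

        phantom = DiskPhantomSpec(
            radii=tup("phantom.radii"),
            centers_row=tup("phantom.centers_row"),
            centers_col=tup("phantom.centers_col"),
            intensity=float(d["phantom.intensity"]),
            n_rows=int(d["phantom.n_rows"]),
            n_cols=int(d["phantom.n_cols"]),
        )
        trunc = d["truncation_radius"]
        prior = PriorConfig(
            mode=d["prior.mode"],
            tau=float(d["prior.tau"]),
            sample_tau=d["prior.sample_tau"] in ("True", True),
            gamma_rate=float(d["prior.gamma_rate"]),
            gamma_fixed=d["prior.gamma_fixed"] in ("True", True),
            theta=float(d["prior.theta"]),
            tau_floor=float(d["prior.tau_floor"]),
        )
        chain = ChainConfig(
            n_iter=int(d["chain.n_iter"]),
            burn_in=int(d["chain.burn_in"]),
            thin=int(d["chain.thin"]),
            tau_proposal_sd=float(d["chain.tau_proposal_sd"]),
            update_order=d["chain.update_order"],
        )
        return cls(
            phantom=phantom,
            regime=d["regime"],
            exposure=float(d["exposure"]),
            smooth_sd=float(d["smooth_sd"]),
            delta=float(d["delta"]),
            truncation_radius=None if trunc == "None" else float(trunc),
            prior=prior,
            chain=chain,
            seed=int(d["seed"]),
        )
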