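# poismrf

Bayesian restoration of photon-count images with **locally adaptive Markov
random field priors**.

Planar emission images (e.g. small-animal gamma-camera scans) are blurred
by the detector point-spread function and corrupted by Poisson counting
noise.  Recovering the underlying activity map is an ill-posed inverse
problem: a smoothing prior is needed, but a single global smoothing
strength either blurs edges or under-smooths flat regions.  `poismrf`
implements a hierarchical model in which the smoothing strength adapts
pixel by pixel, together with the simulation phantoms and classical
baselines needed to evaluate it.

## Model

Observed counts `y` relate to the activity image `x` (m pixels) through a
sparse system matrix `A` of detection probabilities built from an
isotropic Gaussian PSF of width δ (pixels), and a known acquisition-time
factor `e`:

    y_i ~ Poisson(e · Σ_j a_ij x_j)

The prior on `x` is a Laplacian Markov random field written as a product
of local conditionals over the first-order (4-neighbour) lattice, with
per-pixel conditional variances τ_j:

    π(x | τ) = Π_j (2 τ_j)^{-1} exp( − Σ_{t∈∂(j)} |x_j − x_t| / τ_j ),  x_j ≥ 0

Each τ_j carries an exponential hyper-prior of rate γ (τ_j | γ ~ Exp(γ));
γ is fixed at a calibrated value (default 10⁻²) or optionally sampled
under an Exp(θ) hyper-hyper-prior.  Small τ_j enforce local flatness, large
τ_j release edges — the variances are estimated jointly with the image, so
the model smooths noise without flattening boundaries.  Setting a single
global τ instead recovers the classical homogeneous MRF model.

Inference is Metropolis-within-Gibbs: Gaussian random-walk updates per
pixel (negative proposals rejected; likelihood deltas evaluated on the
sparse PSF column only), log-scale random-walk updates of each τ_j against
its generalized-inverse-Gaussian full conditional, and an exact
Gamma(m+1, Στ_j+θ) draw for γ when sampled.  Chains are reproducible
bit-for-bit under a fixed seed; hot loops are numba-compiled.

Also included: the four-disk evaluation phantom (hot activity 1,100 on a
zero background, 29×58 grid) with smoothed-edge and reduced-exposure
variants and a mouse-like phantom; ordinary and Tikhonov-regularized least
squares with cross-validated penalty; MSE/bias/credible-interval reports;
and the γ calibration sweep.

## Worked example

Restore a reduced-exposure (quarter counting time) observation of the
sharp phantom with the locally adaptive model:

```python
import poismrf as pm

truth = pm.generate_disk_phantom()                       # 29x58, hot 1100 / background 0
A = pm.build_system_matrix(29, 58, psf_sd=1.2)           # Gaussian PSF system matrix
G = pm.build_neighborhood(29, 58)                        # first-order 4-neighbour lattice
obs = pm.simulate_observation(truth, A, pm.NoiseConfig(exposure=0.25, seed=12))

cfg = pm.PriorConfig(mode="inhomogeneous", gamma_rate=1e-2)
chain = pm.run_chain(obs, A, G, cfg, pm.ChainConfig(seed=2), exposure=0.25)
summ = pm.summarize_chain(chain, truth=truth)

j = 20 * 58 + 14                                         # centre of a hot disk on row 20
print(f"hot pixel: mean {summ.mean[j]:.2f}, sd {summ.sd[j]:.2f}, "
      f"95% CI [{summ.lci[j]:.2f}, {summ.ucl[j]:.2f}]")
est = pm.ImageGrid.from_vec(summ.mean, 29, 58, kind="estimate")
print(f"posterior-mean MSE: {pm.mse(est, truth):.1f}")
```

prints

```
hot pixel: mean 1117.27, sd 22.73, 95% CI [1070.38, 1161.48]
posterior-mean MSE: 10004.0
```

The hot-disk pixel (true activity 1,100) is recovered to within 2% from a
quarter of the counts, with a credible interval of width ≈ 91.  For
comparison, the Tikhonov baseline on the same (exposure-corrected) data,
`pm.tikhonov_solve(obs.values / 0.25, A, 0.1)`, reaches MSE 23546.2 and
drives background pixels as low as −75: the quadratic penalty smooths
signal and noise alike and cannot honour nonnegativity.  Running the
homogeneous-τ model instead (`pm.compare_models`) shows the adaptive
model's advantage directly — lower whole-image MSE and markedly narrower
credible intervals inside the hot disks.

The same pipeline is scriptable from the shell:

```
poismrf simulate --regime low-count --seed 3 --out out/sim
poismrf fit --obs out/sim/obs.csv --truth out/sim/truth.csv \
            --exposure 0.25 --model inhomogeneous --out out/fit
poismrf compare --obs out/sim/obs.csv --truth out/sim/truth.csv \
            --exposure 0.25 --out out/cmp
poismrf tikhonov --obs out/sim/obs.csv --lambda auto --out out/tk
poismrf sweep-gamma --obs out/sim/obs.csv --truth out/sim/truth.csv --out out/sweep
```

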