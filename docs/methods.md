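# Methods

## Model

The package restores a nonnegative activity image `x ∈ R^m` from Poisson
counts `y ∈ N^n` observed through a linear detector model.

**Likelihood.**  `y_i ~ Poisson(λ_i)` independently, with
`λ = e · A x`.  `A` is the n×m system matrix whose entry `a_ij` is the
probability that a photon emitted from source pixel j is recorded in
detector cell i; `e > 0` is the known acquisition-time (exposure) factor.
The detector grid coincides with the image grid (n = m), as in a planar
gamma-camera acquisition at matched resolution.  The log-likelihood is
`Σ_i [y_i ln λ_i − λ_i − ln y_i!]` with the `0·ln 0 = 0` convention;
`ln y!` uses the log-gamma function.

**System matrix.**  `a_ij` is an isotropic Gaussian of standard deviation
δ (pixels) evaluated at the integer centre offset between pixels j and i,
truncated at radius 4δ and normalized so that the retained offsets sum to
1.  Normalizing after truncation makes every interior column sum exactly
to 1 (entries are genuine detection probabilities) while columns of
boundary pixels lose their off-grid mass and sum to < 1, modelling photons
that escape the detector near the edge.  δ = 0 yields the identity
(perfect acquisition).  δ defaults to 1.2 px — a value producing clearly
visible edge blur at the phantom scale; it is a package choice, exposed in
every interface, since no single physical value is canonical.

**Prior.**  The image prior is a Laplacian Markov random field expressed
as a product of local conditionals over the first-order lattice
neighbourhood ∂(j) (4 neighbours in 2-D; a 6-neighbour stacked-grid option
exists for volumetric lattices):

    π(x | τ) = Π_j (2τ_j)^(-1) exp(−S_j/τ_j),   S_j = Σ_{t∈∂(j)} w_jt |x_j − x_t|,

with all pair weights w_jt = 1 (a uniform weight option is exposed for
the weighted generalisation).  This product is a **pseudo-likelihood**:
each unordered neighbour pair contributes to both endpoints' sums, and no
joint normalizing constant exists in closed form.  The package treats the
product literally as the target density — the only reading under which
posterior evaluations at different τ are comparable — and documents all
log-densities "up to one shared constant".

**Hyper-priors.**  Locally adaptive (inhomogeneous) model:
`τ_j | γ ~ Exp(γ)` independently.  Homogeneous model: a single global τ
(user-fixed, or MH-updated under the same Exp(γ) prior).  γ is fixed by
default at the calibrated value 10⁻²; alternatively `γ ~ Exp(θ)`
(θ = 10⁻² by default) and γ is then redrawn exactly from its conjugate
Gamma(m+1, Στ_j + θ) full conditional each iteration.

## Sampler

Metropolis-within-Gibbs, one iteration =

1. **Pixels** (raster order by default; random permutation available):
   Gaussian random-walk proposal on x_j; proposals < 0 rejected outright.
   The acceptance log-ratio is computed locally — the likelihood part
   touches only the sparse PSF column of pixel j (and only cells with
   y_i > 0 need a logarithm); the prior part touches j and its
   neighbours, since the pair term |x_j − x_t| appears in S_j (scaled by
   1/τ_j) and in S_t (scaled by 1/τ_t).  Unit tests verify the local
   delta against full recomputation of the joint posterior.
2. **Variances**: for each τ_j a log-scale Gaussian random walk
   (sd 0.5) targeting `p(τ) ∝ τ^(-1) exp(−S_j/τ − γτ)`, a
   generalized-inverse-Gaussian density with index 0 and mode
   `(−1 + √(1+4γS_j)) / (2γ)`.  In log-space the Jacobian cancels the
   τ^(-1) factor.  Proposals below `tau_floor` are rejected, which
   truncates the support to `[tau_floor, ∞)` while preserving detailed
   balance; when S_j = 0 the untruncated conditional is non-integrable at
   0 and the floor is what keeps the chain proper on flat regions.
   `tau_floor = 10⁻³` (intensity units) is negligible relative to any
   variance a non-flat neighbourhood produces.
3. **γ**: exact conjugate Gamma draw (when not fixed).

**Initialisation** follows the data: `x⁰ = y/e` (clipped at 0), `τ_j⁰ = 1`
(adaptive model) or the configured τ, `γ⁰ = gamma_rate`.

**Proposal scales.**  Pixel proposal sds start at `sqrt(max(x⁰_j, 1))`
(the Poisson posterior scale) and adapt multiplicatively toward 30%
acceptance during burn-in with a diminishing adaptation rate; adaptation
freezes at the end of burn-in so the post-burn-in kernel is a fixed,
valid MCMC kernel.  Default chain: 20,000 iterations, 10,000 burn-in,
thinning 10 (95% credible intervals from the 2.5/97.5 percentiles of the
thinned draws).

**Numerical hygiene.**  λ is updated incrementally during pixel sweeps and
resynchronized from scratch every 100 iterations and at every saved state;
the stored log-posterior is recomputed at save points and verified in
tests against an independent pure-Python evaluation.  All chain
randomness flows through one integer seed; chains are reproducible
bit-for-bit.

## Synthetic data

The disk phantom places four non-overlapping hot disks (radii 4, 5, 5, 6
px; centres at rows 9/9/20/20, columns 14/43/14/43) of constant activity
1,100 on a zero background of a 29×58 grid — piecewise constant with two
exact levels.  Three degradation regimes are emulated: *sharp*
(exposure 1), *smooth* (truth pre-convolved with a normalized truncated
Gaussian kernel, sd 1.5 px, edge-renormalized), and *low-count*
(exposure 0.25, modelling a quartered scanning time).  A mouse-like
phantom (elliptical low-uptake body, two kidney-like blobs, one
bladder-like blob, values ≤ 1,100) exercises less symmetric geometry.
Observations are pure Poisson draws from `e · A x` — detector dead time,
scatter, attenuation and electronic noise are *not* modelled, so passing
tests demonstrate correctness of the estimator under the stated model,
not robustness to physics the simulator does not contain.

## Calibration of γ and evaluation

`calibration_sweep_gamma` fixes γ at each point of the grid
{10⁻⁴ … 10³}, runs the adaptive model, and records the MSE of the
posterior mean against the truth.  Sweep chains are shortened to
6,000 iterations / 3,000 burn-in — the curve needs MSE levels, not tight
per-pixel summaries.  On the reference phantom the curve is lowest around
γ = 10⁻² and rises steeply and monotonically for γ ≥ 1 (over-shrunk
variances flatten real edges); γ = 10⁻¹ sits within chain noise of the
10%-of-minimum plateau band (equilibrium ratio ≈ 1.11), and for γ ≤ 10⁻³
the hyper-prior becomes so diffuse that the fit approaches unregularized
Poisson deconvolution and the MSE grows again.  The error budget is
dominated by the ~430-pixel edge band around the disks.  γ = 10⁻² is the
package default.

`compare_models` fits the homogeneous and adaptive models on the same
observation and reports per-model MSE, bias/sd/CI maps and a side-by-side
per-pixel table (`ucl/lci/mean` per model, two decimals).  The
homogeneous comparator samples its single τ under the same Exp(γ)
hyper-prior rather than requiring a hand-picked value, so the comparison
measures the value of *local* adaptivity, not of a particular global τ.
On the low-count phantom the adaptive model gives lower whole-image MSE
and distinctly narrower credible intervals inside the hot disks, at the
price of slightly bolder interval claims at edge pixels.

**Baselines.**  Ordinary least squares `(AᵀA)⁻¹Aᵀy` (Cholesky, with an
explicit singularity error carrying a condition estimate) and Tikhonov
regularization `(AᵀA + λLᵀL)⁻¹Aᵀy` with identity regularizer `L`.  The
penalty is the standard `‖Lx‖²` form.  λ is chosen by 5-fold
cross-validation over detector cells (seeded permutation folds; held-out
counts predicted from the fold-trained solution; ties toward smaller λ;
eigendecomposition of AᵀA reused across the 25-point log-spaced grid), or
set manually (e.g. λ = 0.1).  No nonnegativity constraint is imposed, so
restored backgrounds can go negative — a deliberate display of the
quadratic penalty's limitation.

## Design choices and limitations

* **Truncate-then-normalize PSF columns** (rather than truncating an
  already-normalized infinite kernel): makes interior detection
  probabilities sum to exactly 1 and confines sub-unit sums to boundary
  pixels, where they have a physical reading.
* **Pure Poisson noise**: any additive measurement error is absorbed into
  count noise; the likelihood is exactly the model used for inference.
* **Exposure in the model, not the data**: reduced-count fits keep
  estimates on the activity scale by scaling the mean, never the counts.
* **Rejection at `tau_floor`** instead of clipping: clipping would place
  point mass at the floor and bias the variance conditional.
* The pseudo-likelihood prior is improper as a joint distribution;
  comparisons of posterior values across different τ configurations are
  meaningful only under the pseudo-likelihood reading.
* Chain-length defaults (20,000 main / 6,000 sweep iterations) are the
  package's reference problem sizes for the 29×58 phantom; larger images
  or weaker data may need longer chains — check the potential scale
  reduction helper on dispersed starts.
* Second-order (8-neighbour) cliques, spatially varying or
  depth-dependent PSFs, attenuation, and full tomographic reconstruction
  are out of scope; the neighbourhood graph supports stacked 3-D lattices
  but the simulator is 2-D.
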