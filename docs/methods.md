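# Methods

`radialcs` reconstructs a 2-D MR image from noisy, radially undersampled
k-space data. This note records the model, the numerical choices behind the
implementation, and what the synthetic experiments do and do not show.

## Measurement model

The image `x` (real, on the 8-bit scale [0, 255]) is observed through

    y = M ∘ F(x + n),

where `F` is the unitary 2-D Fourier transform (DC centred), `M` a boolean
sampling mask, and `n` additive image-domain noise. The operator
`Φ = M ∘ F` is a partial isometry: `Φ†Φ` is diagonal in the Fourier basis
with eigenvalues in {0, 1}, so its spectral radius is 1 regardless of image
size — penalty parameters transfer unchanged across resolutions.

Radial acquisition is emulated by rasterizing `n_s` equispaced diameters
(seeded global angular offset) onto the Cartesian grid, with
`n_s = round(π n / 2)` as the Nyquist-satisfying full-sampling reference.
The rasterized set is then symmetrized under the DFT conjugate pairing
`i ↔ (n − i) mod n`: a real image has conjugate-symmetric spectra, and
without the symmetrization the boundary row/column of the grid breaks the
pairing and `Φ†Φ` stops being an exact projector. True non-Cartesian
trajectories (gridding/NUFFT) are out of scope; the solver only ever needs
the set of sampled Cartesian locations.

## Objective and ADMM scheme

The reconstruction minimizes

    ‖Φx − y‖² + η Σᵢ ‖Rᵢx − Lᵢ‖² + λ Σᵢ L(Lᵢ) + β Σ |Φx − y|,

where `Rᵢx` stacks the vectorized patches most similar to the i-th anchor
patch into an `(f², Sᵢ)` matrix, `L(X) = Σⱼ log(σⱼ(X) + ε)` is the LogDet
rank surrogate, and the last term is an L1 penalty on the sampled k-space
residual. With the split `x = y_split` (multiplier `z`, penalty `γ`,
over-relaxation `ω ∈ (0, 2)`) each block has a closed-form update:

* **L-block** — weighted singular-value thresholding of each group at
  threshold `τ_g = λ/(2η)`: every singular value is replaced by the global
  minimizer of `½(δ − σ)² + τ_g log(δ + ε)`, which is either 0 or the larger
  root `((σ − ε) + √((σ + ε)² − 4τ_g))/2`, whichever scores lower (ties
  prefer 0, i.e. lower rank).
* **y-block** — the normal equations `(cΦ†Φ + γI) y = cΦ†y_data − z + γx`
  are diagonal in Fourier space and solved coefficient-wise.
* **x-block** — one linearized proximal step with relaxation, projected
  onto the intensity box `[0, 255]` (the natural constraint set for
  magnitude MR images).
* **z-block** — `z ← z − γ(x − ω y_split − (1 − ω) x_prev)`.

Iterations stop at `max_iter = 100` sweeps or when the relative iterate
change drops below `tol = 1e-4`.

### Scale convention

Internally the solver works on intensities normalized to unit peak
(`x/255`). The default regularization weights `(λ, β, η) =
(0.1, 0.05, 0.01)` are only meaningful on that scale: on raw 8-bit
intensities the shrinkage threshold `λ/(2η) = 5` would sit at ~1% of the
noise singular level and the regularizer would be inert.

### Shrinkage acts on the noise-standardized group residual

Two refinements to the plain L-block proved necessary:

1. **Centring.** The group mean patch (the DC component, singular value
   `σ₁`) is removed before shrinkage and restored afterwards. Shrinking
   `σ₁` biases flat regions dark by `≈ τ_g/σ₁` per sweep; the rank
   surrogate is meant to tax *deviations* between similar patches, not
   their common content.
2. **Noise standardization.** The residual is divided by the expected
   noise singular level `σ_n (√f² + √Sᵢ)` before shrinkage (and re-scaled
   after), with `σ_n` the declared noise standard deviation on the unit
   scale, floored at two grey levels. The fixed threshold `λ/(2η)` then
   acts in units of the noise floor, so the regularizer keeps the same
   strength under any noise family or level. A threshold calibrated at one
   σ otherwise over-smooths weaker noise and leaves stronger noise
   (e.g. the nonuniform family, effective σ ≈ 58) untouched.

### Inverse-variance data weighting

`reconstruct` scales the quadratic-fidelity weight as
`c = 2 · (σ_ref/σ_n)²` with `σ_ref = 20`, the uniform-Gaussian reference
level of the noise-family experiments at which the stated regularization
constants are calibrated (again flooring `σ_n` at two grey levels). This is
ordinary maximum-likelihood weighting expressed relative to that reference:
with heavy noise the data are trusted less and the nonlocal prior carries
more weight; with clean data the fidelity term dominates and noiseless
fully-sampled problems are recovered essentially exactly. The proximal
weight `τ` is enlarged alongside (`τ = max(3.5, c + 1.5)`) so that
`1/(τ + γ)` always majorizes the curvature `c + η·max(coverage)` of the
smooth terms — with the bare stability bound `τ > ρ(Φ†Φ) = 1` the
linearized x-step overshoots and oscillates.

### L1 subgradient smoothing

The k-space L1 term contributes `β Φ† sign(Φx − y)` to the x-step. The hard
complex sign `r/|r|` has unit magnitude however small the residual, which
sustains a limit cycle of amplitude `≈ β/(τ + γ)` (about 3 grey levels) and
caps noiseless recovery near 45 dB. The implementation uses the continuous
selection `r / max(|r|, δ)` with `δ = 0.01 ×` (box width): for genuinely
noisy residuals (`|r| ≥ σ/255 ≫ δ`) it is the exact sign, and near the
nonsmooth point the force ramps linearly to zero (the minimal-norm element
of the subdifferential at 0). With it the same noiseless run reaches
~100 dB and stops after one sweep.

### Group matching schedule

Similarity matching runs once, on the zero-filled initializer
(`max_regroups = 1`; a `regroup_every` schedule is available). Re-matching
on progressively regularized iterates is a ratchet: each re-match on a
smoother image produces more uniform groups, which shrink to still smoother
images — measured on the standard problem, every additional re-match costs
about 1 dB. The group *contents* `Rᵢx` are re-extracted from the current
iterate at every sweep regardless.

Mild continuation multiplies `(λ, β, η)` by 0.95 every 10 sweeps, keeping
the shrinkage threshold `λ/(2η)` constant while gradually releasing the
prior.

## Patch grouping

Anchors lie on a regular grid with stride `f − 1` (one-pixel overlap keeps
every pixel covered while bounding the group count; halving the stride
quadruples the per-sweep eigendecomposition cost for no measurable quality
change at 256²). Candidates inside the `W × W` window are ranked by squared
Euclidean distance to the anchor, ties broken by raster order; the anchor
is always the first member. The adaptive group size is the number of
candidates within distance `c·f²·σ²` (`c = 3`), clipped to `[10, 60]` and
to the number of in-image candidates. Patch and window sizes follow the
noise level: `f = 7, W = 21` below noise variance 30, `f = 9, W = 31` at or
above. Aggregation back to the image is the uniform per-pixel average with
exact coverage accounting, so `aggregate ∘ extract = id`.

The per-sweep shrinkage batches groups by `Sᵢ` and eigendecomposes the Gram
matrix of the smaller side (`min(f², Sᵢ) ≤ 60`), which is 2–3× faster than
batched SVD of the rectangular matrices and agrees with it to ~1e-9.

## LogDet estimation

Beyond the exact eigendecomposition path, `logdet(C)` for SPD `C` is
estimated by the k-terms power series: with `a = ‖C‖_∞` (maximum absolute
row sum — a general SPD matrix can have negative row sums, so absolute
values are used) and `B = I − C/a`,

    logdet(C) ≈ N log a − N · (1/m) Σⱼ Σᵢ₌₁ᵏ (sⱼᵀ Bⁱ sⱼ) / (i · sⱼᵀ sⱼ),

over `m` standard-normal probes. Normalizing by `sᵀs` makes each probe term
exactly unbiased for `tr(Bⁱ)/N · N` (the direction of a Gaussian vector is
uniform on the sphere), and `Bⁱ s` is evaluated by the recursion `v ← Bv`
without ever forming a matrix power, so the cost is `O(k·m·N²)` dense
(`O(k·m·nnz)` sparse) with `O(N)` extra storage per probe. The series
converges for eigenvalues of `C` in `(0, 2a)`, which scaling by `‖C‖_∞`
guarantees. In the solver the exact path is the default for the small group
matrices; the estimator is exposed for objective monitoring and for the
accuracy/cost ablation (`radialcs ablate`), whose cost is asserted via an
operation counter rather than wall-clock time.

## Quality indexes

MSE is the mean form (so the PSNR definition
`10 log₁₀(255²/MSE)` is exact, with a `sum_form` flag for the raw sum);
PSNR is +inf for identical images. SSIM is the *global*
universal-quality-index form `4 u_x u_y σ_xy / ((u_x² + u_y²)(σ_x² +
σ_y²))` computed from whole-image moments — not the windowed variant — with
1e-8 stabilizers on the denominator factors. Note that this global form
assigns +1 to `x̂ = −x` (both sign flips cancel); anti-correlation is
negative only when means stay positive, e.g. for the inverted image
`255 − x`.

## Synthetic data

Phantoms are the standard 10-ellipse Shepp–Logan head phantom (rescaled to
[0, 255]) and a seeded piecewise-constant ellipse collage with one
oscillatory texture band. Noise families: i.i.d. Gaussian; mean-centred
Rayleigh (centring keeps `E[y] = x`, as the additive model assumes);
nonuniform Gaussian with per-pixel σ drawn once from Uniform[1, 100];
salt-and-pepper with corrupted fraction `density`. Noisy images are *not*
clipped to [0, 255] before encoding — clipping would corrupt the additive
model — and the adaptive grouping receives each family's nominal variance
(`σ²`; `(2 − π/2)σ²` for Rayleigh; `(lo² + lo·hi + hi²)/3` for nonuniform;
`density · 127.5²` for salt-and-pepper). One global seed derives
per-role generators (phantom, noise, mask angle, probes) via a
crc32-keyed `SeedSequence`, so every artifact is independently
reproducible.

What the phantom experiments do **not** show: performance on real
anatomies (texture statistics of MR images are richer than the collage
band), Rician magnitude-image noise, coil-array effects, or true
non-Cartesian sampling-density effects. Reported PSNR/SSIM values are
specific to these phantoms; only the *relative* orderings (full model vs
baseline vs zero-fill, robustness across noise families) are the claims
the test suite checks.

## Problem sizes used in the checks

The headline comparison runs at 256×256, sensing rate 0.3, Gaussian σ = 20,
100 sweeps, averaged over 5 seeds (the default solver configuration
throughout). The noise-family robustness comparison runs at 128×128 — the
orderings it checks are stable in size, and the smaller grid keeps the full
four-family sweep proportionate to the rest of the suite. Brute-force
cross-checks (grouping, coverage, dense normal-equation solves) run on
16–64 pixel grids where the O(n²)–O(n⁶) reference implementations are
exact and cheap.

## Known limitations

* The adaptive-count rule (distance threshold `c·f²·σ²`) saturates at
  `S_max = 60` for strong noise, so the effective group size is usually 60
  there; the bounds, not the threshold, are then what matters.
* The L1 k-space term largely duplicates the role of the quadratic
  fidelity under Gaussian noise; its benefit shows mainly under
  impulsive (salt-and-pepper) corruption.
* Convergence of the over-relaxed linearized scheme is observed, not
  proved; the majorization rule for `τ` removes the only instability seen
  in practice.
* At sensing rates below ~0.1 the zero-filled initializer is so aliased
  that the one-shot group matching mislabels patches; reconstruction
  quality degrades accordingly.
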