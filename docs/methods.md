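# Methods

## Problem and model

The package reconstructs a complex 2D image `u ∈ C^N` from undersampled
k-space measurements

    f = F_p u + n,

where `F_p` is the partially sampled, unitary, centered 2D DFT (support
given by a boolean sampling mask) and `n` is zero-mean complex Gaussian
noise with per-channel standard deviation `σ`.  The prior is the
sparseland patch model: every `s×s` patch `R_l u` (periodic extraction,
stride `r`, so that `Σ_l R_lᵀR_l = ω I` with `ω = (s/r)²`) is close to a
sparse combination `D α_l` of unit-norm dictionary atoms.  The relaxed
regularizer is

    J(u) = Σ_l ( ‖α_l‖_w + (λ/2) ‖D α_l − R_l u‖² ),

where `‖·‖_w` is either the plain `l1` norm (the baseline, "TBMDU") or a
reweighted surrogate of the nonconvex `lp` quasi-norm, `0 < p ≤ 1`:
iteratively reweighted `l1` with weights `W = 1/(|α|^{1−p} + ε)` or
iteratively reweighted `l2` with `W = 1/(|α|^{2−p} + ε)` ("WTBMDU-L1/L2").
Both weight rules are nonincreasing in `|α|`: small coefficients are
penalized harder, which pushes them to exact zero while large ones keep
(most of) their value — the behavior that distinguishes `lp` (p<1) from
plain `l1`.

## Algorithm

Two nested levels:

* **Outer level — Bregman data feedback.**  Each outer iteration `k`
  approximately solves the regularized problem against fed-back data `f_k`
  and then sets `f_{k+1} = f_k + f − F_p u^{k+1}`.  The feedback ramps up
  the effective data weight so that even a small fidelity parameter `μ`
  eventually enforces `‖F_p u − f‖ ≤ ε`.  Stopping: residual below the
  noise bound `σ√(2Q)` (`Q` = sampled-cell count; the plain `σ` rule is
  available via `stop_scaled_bound=False`), or, for noiseless data,
  relative image change below `rel_tol`; hard cap `k_max`.  If the cap is
  reached the last iterate is returned with `converged=False` in the
  history, never an exception; a >10× residual blow-up in one outer sweep
  raises `DivergenceError`.

* **Inner level — alternating-direction sweeps.**  With the constraint
  `z_l = R_l u − D α_l` split off, each of the `m` sweeps updates, in
  order: the weight matrix (from the current coefficients and the ε
  schedule), the coefficients (one ISTA-type step, rule per variant), the
  auxiliary residual `Z = (β(Ru − DΓ) + Y)/(λ+β)`, the multiplier
  `Y ← Y + β(Ru − Z − DΓ)`, and the dictionary (gradient step along
  `Y Γᴴ` with per-atom renormalization).  After the sweeps one image
  update closes the outer iteration.

The coefficient rules share the gradient step
`Γ + (λ+β) Dᴴ y′ / (γλβ)` with the intermediate variable
`y′ = T₀(−DΓ + B + Y/β)`, `B = Ru − Z`, `T₀ = λβ/(λ+β)`:

* plain: complex soft-threshold at `(λ+β)/(γλβ)`;
* reweighted-l1: the same threshold scaled entrywise by `W`;
* reweighted-l2: the exact minimizer of the weighted ridge surrogate,
  `(γΓ + (λ+β)Dᴴy′/(λβ)) / (γ + (λ+β)W/(λβ))`.

`γ` must dominate the spectral radius of `DᴴD` for these steps to be
majorization–minimization steps (each decreases its own surrogate; this is
tested).  The complex soft-threshold reduces magnitudes and preserves
phase; conjugate transposes are used throughout so every step is the true
gradient of the real-valued objective on complex data.

**Image update.**  Because patch extraction is periodic and the DFT
unitary, the image block has a closed form.  With `g = Rᵀ(DΓ)` the
aggregated sparse approximation,

    û(κ) = (β ĝ(κ) + μ f_k(κ)) / (βω + μ)   on sampled κ,
    û(κ) = ĝ(κ)/ω                            elsewhere.

The patch target is the sparse approximation `DΓ`, not `DΓ + Z`: `Z`
carries the part of each patch the sparse code deliberately discards, so
including it would make the image update the identity on unsampled
frequencies and disable the regularization.  This matches the classical
"frequency interpolation" structure of patch-dictionary CS-MRI.

## Composition choices

Several aspects are not determined by the update equations themselves;
the package fixes them as follows (each was selected by measuring solver
stability and reconstruction quality on the synthetic benchmarks, and each
is a config knob or a documented constant):

* **Majorization constant `γ`** — default `None` → automatic
  `1.5 × eigmax(DᴴD)`, the smallest safe value times a margin.  The ISTA
  step length is `1/γ`, so larger values slow the coefficient updates
  proportionally; with only `m·k_max` sweeps available, a tight `γ` is
  what makes the inner problems actually get solved.  A user-set `γ`
  below `1.05 × eigmax` is raised automatically; the radius is re-checked
  at every dictionary refresh.
* **Weight normalization** — weight matrices are rescaled to unit mean
  before entering a coefficient step.  The raw weights have absolute
  scale `≤ 1/ε`, which would put the weighted variants on a different
  (much weaker) threshold scale than the plain rule; unit-mean rescaling
  realizes the penalty-balance heuristic (`E(W) ≈ γT₀`) multiplicatively,
  so all variants share the plain-l1 operating point and differ only in
  the *relative* treatment of small vs. large coefficients.  For `p = 1`,
  `ε = 0` the weights are identically 1 and the reweighted-l1 variant
  reproduces the plain trajectory exactly (tested to 1e−10).
* **Splitting-state policy** — the thresholding rules (plain and
  reweighted-l1) reset `(Z, Y)` at the start of every outer iteration:
  they act as early-stopped proximal filters on the *new* image's patches,
  and carrying the multiplier would let its accumulation cancel the
  thresholding within a few outer iterations.  The reweighted-l2 rule
  carries `(Z, Y)` across outer iterations: its block update is an exact
  ridge minimizer whose bias is removed by the accumulated multiplier
  (standard augmented-Lagrangian exactness).  Coefficients `Γ` and the
  dictionary are warm-started across outer iterations for all variants.
  Override with `carry_dual`.
* **Dictionary step normalization** — the gradient `YΓᴴ` scales with
  image intensity and patch count, so the configured step `ξ` is divided
  by the largest column norm of `YΓᴴ`; `ξ = 0.01` then means "rotate each
  atom by at most 1% per sweep" at any intensity scale.  Atoms whose
  update collapses below norm 1e−12 keep their previous value.
* **ε schedule** — `ε_t = ε₀(1−decay)^t` with `ε₀ = 5`, 2% decay, and `t`
  the cumulative inner-sweep counter (never reset), so the weight rules
  tighten monotonically toward the true `lp` surrogate over the whole run.
* **DFT normalization and boundary handling** — unitary centered DFT
  (Parseval holds, penalty balance is scale-free) and periodic patch
  extraction (makes `RᵀR = ωI` exact, which the closed-form image update
  requires).  Patch offsets are enumerated row-major, pixels within a
  patch column-major; results are invariant to these conventions but
  reproducibility requires fixing them.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `s`, `r`, `K` | 6, 1, 1 | patch side, stride, dictionary overcompleteness (J = K·s²) |
| `lam` (λ) | 12 | patch-residual penalty: the sparse code must fit each patch to ≈ 1/λ per coefficient |
| `beta` (β) | 0.0056 | patch-level AL penalty; recommended range [1/500, 1/100] (warning outside) |
| `mu` (μ) | auto | image-data penalty; balance rule ρNβ/s² (`mu_rule="full"` drops ρ) |
| `gamma` (γ) | auto | ISTA majorization constant, ≥ 1.05 × eigmax(DᴴD) |
| `xi` (ξ) | 0.01 | relative dictionary step per sweep |
| `p` | 0.5 | lp exponent of the reweighted rules, (0, 1] |
| `m`, `k_max` | 3, 15 | inner sweeps per outer iteration; outer cap |
| `eps0`, `decay` | 5, 0.02 | ε-schedule start and per-sweep decay |

Intensities are assumed on a [0, 255] scale (the synthetic phantoms are
generated so, and the PSNR definition `20 log₁₀(255/RMSE)` presumes it);
λ, β and the ε schedule are calibrated to that scale.

## Sampling masks

Four Cartesian-grid trajectory families: variable-density 2D random
(radially decaying sampling probability, polynomial exponent 3 by default,
drawn without replacement so the realized fraction is exact), pseudo-radial
(digital lines through DC at uniformly spaced angles; spoke count fitted to
the target fraction), 1D-random Cartesian (full readout lines, phase
encodes drawn by the same variable-density law), and a Cartesian
rasterization of variable-density Archimedean spiral arms.  The DC cell is
always sampled; all generators are deterministic given (kind, shape,
parameters, seed).

## Metrics

PSNR `= 20 log₁₀(255/RMSE)` on magnitudes, with the reference affinely
mapped to [0, 255] and the same map applied to the test image (identical
images report the 300 dB cap).  HFEN is the `l2` norm of the difference of
Laplacian-of-Gaussian-filtered magnitudes (15×15 taps, σ = 1.5,
mean-subtracted so constants are annihilated, zero-padded borders), with a
normalized form divided by the filtered reference norm.

## Synthetic data

Three phantom families stand in for clinical scans: the analytic modified
Shepp-Logan ellipse phantom (piecewise-constant anatomy); a seeded textured
phantom mixing Voronoi regions, oriented sinusoids and thin curvilinear
tracks (emulating vessel-rich anatomy); and a patchwise exactly-k-sparse
phantom with known coefficients for support-recovery experiments.
Acquisition is simulated by masking the unitary DFT and adding complex
Gaussian noise on the sampled cells.  What these phantoms do **not**
emulate: coil sensitivities and parallel imaging, B0 inhomogeneity and
phase maps of real scans, partial-volume texture statistics of in-vivo
tissue.  Passing the synthetic benchmarks therefore demonstrates the
solver's correctness and the qualitative benefit of reweighting, not
clinical image quality.

## Benchmark scale and expected behavior

The shipped benchmarks run on 128×128 phantoms with 10 outer × 3 inner
iterations (seconds per reconstruction on one core): noiseless 30%
pseudo-radial sampling of the Shepp-Logan phantom gives a zero-filled
PSNR of ≈ 20 dB, the plain solver ≈ 24.4 dB, reweighted-l1 (p = 0.5)
≈ 25.2 dB and reweighted-l2 (p = 0.7) ≈ 27.0 dB; on the textured phantom
at 25% sampling the reweighted variants gain 0–1.4 dB over the plain
solver depending on seed and p.  The outer data residual decreases
monotonically on these noiseless runs, and with full sampling the Bregman
feedback drives the reconstruction above 50 dB within a few iterations.
PSNR can peak before the final iteration on some instances (the
constrained solution need not be the best iterate); the full history is
always returned so this is observable.

## Known limitations

* Single-coil, single-slice 2D only; no NUFFT/non-Cartesian gridding.
* The dictionary update is a normalized gradient step, deliberately mild;
  it refines the DCT initialization but is not a K-SVD-style learner.
* The thresholding variants rely on early stopping of the inner splitting
  (by design, `m` is small); running them to inner convergence removes the
  filtering and returns a near data-consistent image.
* Weight matrices, ε schedule and λ/β defaults presume intensities on a
  [0, 255] scale; rescale inputs accordingly.
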