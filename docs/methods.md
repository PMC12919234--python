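# Methods

## Model

`dcflow` implements *Dynamic Compression Flows* (DCF): a pair of jointly
trained velocity fields over a high-dimensional observation space
`x ∈ R^D`, indexed by two auxiliary coordinates,

* a **compressive flow** `u_φ(x, τ)` over a compression coordinate
  `τ ∈ [0, 1]` (τ = 1 is data space, τ = 0 the low-dimensional source), and
* a **dynamical flow** `v_θ(x, τ, s, hist)` over physical time, valid at
  every compression level, where `s ∈ [0, 1]` is the position inside one
  sampling interval `Δt` and `hist` an optional lag-`h` history at the same
  τ.

Both are trained simulation-free by conditional flow matching on linear
bridges whose endpoints are supplied by a deterministic **encoder
coupling**

    x^(0) = b + L D^{1/2} μ_ψ(x),      D = diag(d_1, …, d_M),  d_i > 0,

with `L` the Q-factor of a thin non-pivoted QR factorization of an
unconstrained matrix (sign convention: positive diagonal of R, which makes
the factorization a deterministic, smooth function of its input) and
`μ_ψ` a nonlinear feature map whose raw output is ℓ2-norm-capped and then
standardized coordinate-wise by running EMA statistics. The τ-bridge is

    x^(τ) = (1 − τ) x^(0) + τ x^(1),       u* = x^(1) − x^(0),

and the dynamical bridge double-interpolates: consecutive frames are first
τ-bridged at a shared τ, then linearly interpolated in `s`, with constant
target `v* = (x_{k+1}^(τ) − x_k^(τ)) / Δt`.

**Nested dropout.** Each training element samples a prefix length
`K ~ Geom(p)` (clamped to `[1, M]`) and zeroes feature coordinates beyond
`K` in all three loss terms of that element. This breaks the permutation
symmetry of the latent coordinates, orders them by importance, and gives
the source distribution genuinely low-dimensional support. The combined
objective is

    L = α·L_cf + β·L_df + η·L_align,       α = β = η = 1 by default,

where `L_align = E‖x − x^(0,K)‖²` selects, among the feature maps
consistent with the flows, the one whose masked encoding reconstructs the
data. Together — deterministic QR, coordinate-wise normalization, prefix
ordering — the latent coordinates are identifiable up to one sign per
coordinate, which the evaluation module checks by per-coordinate Pearson
correlation across independently seeded runs (matched by index; no
permutation search, since a permutation ambiguity would be a failure).

## Assumptions

* Uniform time sampling `t = kΔt` (Δt = 1 internal units by default).
* Continuous-valued observations (no discrete/spike data without prior
  smoothing).
* Deterministic, zero-width bridges (no Gaussian path variance).
* Training pairs require a full lag-h history; trajectories shorter than
  `h + 2` are excluded.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `M` (latent width) | `min(D, 256)` | columns of L; nested dropout rarely activates coordinates beyond the clamp, so a bottlenecked M is equivalent to the square parameterization whenever `M ≥ k_max` in practice |
| `p` (nested-dropout rate) | 1/50 | E(K) = 1/p is the latent budget; 1/50 is used for every preset study |
| `d_init` | 1e-3 | initial per-coordinate scale; small so that rarely-activated coordinates contribute negligible mass to the effective-dimension sum and informative coordinates must *grow* |
| norm cap `c` | `3·√M` | per-sample ℓ2 bound on raw features (≈3 standard units per coordinate) |
| EMA decay | 0.99 | running mean/std of raw features; statistics are constants within a step, updated after the forward pass |
| σ floor | 1e-4 | guards constant features |
| `d` floor | 1e-6 | keeps scales positive and the latent projection well-conditioned |
| lr / encoder-linear lr | 1e-3 / 1e-2 | Adam; the coupling's linear part (b, L_raw, ρ with d = softplus(ρ) + ε) has few parameters and uses the faster rate so scales can traverse orders of magnitude within a run |
| lr schedule | ×0.1 after 70% of steps | see "Numerical choices" |
| grad clip | 1.0 | global norm |
| rtol, atol | 1e-5 | adaptive RK45 (Dormand–Prince) local error control |

## Inference

*Flowed* representations integrate `u_φ` per frame from τ = 1 down to a
target level; *simulated* representations compress one initial frame and
roll the dynamical flow forward autoregressively, integrating
`dx/ds = Δt · v_θ(x, τ, s, hist)` over `s ∈ [0, 1]` per step and shifting
the history window (history is initialized from flowed compressions of
observed frames). Latent coordinates are the left inverse of the linear
part, `μ̃ = D^{-1/2} Lᵀ (x̃^(0) − b)`; velocities project the same way
without the bias. The **effective dimension** `K_eff` is the smallest
prefix whose cumulative `d_i` reach 95% of the total, in stored coordinate
order. Integration runs in float64 via SciPy's adaptive RK45, which uses
the Dormand–Prince 4(5) embedded pair; training runs in float32.

## Synthetic data and what it does (not) show

The generators emulate the statistical structure the method assumes —
high-dimensional observations driven by few smooth latent degrees of
freedom:

* **Rotating-ball videos**: 10 videos × 50 frames of 28×28 grayscale; a
  soft-edged disk (radius 3 px, 1 px anti-aliasing falloff) orbits
  counterclockwise (mathematical orientation, image y-axis up) at radius
  8 px, one full period per video, with a random phase per video. A
  one-dimensional periodic latent embedded nonlinearly in 784 pixels.
* **Embedded oscillator**: a planar rotation (radius 1, one period per 50
  steps) mapped into D = 20 by a random orthonormal matrix plus isotropic
  Gaussian noise (sd 0.05 ≈ 5% of signal variance in total) — a fast
  surrogate with known intrinsic dimension 2.
* **Constant shift**: `x_{k+1} = x_k + w` exactly; the unique optimal
  dynamical field is the constant `w`, giving an analytic training oracle.

These datasets are noise-poor and perfectly stationary compared to real
neural or behavioral recordings; passing on them demonstrates the
machinery (identifiability, ordering, dynamics-preserving compression),
not robustness to heavy-tailed noise, non-repeatability, or
non-stationarity.

## Numerical choices

* **QR sign convention**: forcing diag(R) > 0 removes the per-column ±1
  ambiguity of plain QR; residual sign ambiguity of the representation
  then stems only from feature-map symmetry, which is what the
  sign-insensitive identifiability check expects.
* **One K per batch element**, shared by all three loss terms of that
  element, so alignment and both bridges see one consistent masked
  encoding.
* **Independent τ draws** for the compressive and dynamical terms; the
  dynamical term uses a single τ for both endpoints and the history
  (the double interpolation requires equal compression levels).
* **Two-phase learning rate**: the dynamical targets are low-SNR (the
  per-step displacement is small against observation noise), and constant-
  rate Adam leaves the regression visibly shrunk toward zero — simulated
  rollouts under-rotate. Dropping all rates by 10× for the final 30% of
  steps settles the fit; this is the default schedule.
* **History order**: oldest-first, no padding; boundary samples are
  excluded rather than invented.
* **Degenerate inputs**: rank-deficient `L_raw` raises; all-zero scale
  vectors raise; constant features are guarded by the σ floor; non-finite
  states are rejected at field entry, and a non-finite loss aborts training
  with the offending batch attached.
* **Loop-closure metric**: endpoint gap over trajectory diameter in the
  first `min(3, K_eff)` latent coordinates. Coordinates beyond `K_eff`
  carry ~zero scale, and the `D^{-1/2}` normalization would amplify their
  noise into the metric.

## Design choices where the design was open

* The convolutional feature map uses only the mean path of the
  convolutional encoder (no sampling step, no KL term).
* Encoder gradients from the two flow-matching losses are *not* stopped
  (joint training of the coupling); a config switch
  (`stop_encoder_flow_grads`) exposes the alternative.
* The three losses are optimized jointly, not alternately.
* Simulated rollouts are fully autoregressive after an observed warm-up;
  they never re-condition on observations mid-rollout.
* Scalar conditioners (τ, s) enter as sinusoidal embeddings (frequencies
  1–30 rad over the unit interval) added through learned projections at
  every block; histories are flattened and concatenated (MLP) or
  channel-concatenated (conv).
* Desk-scale presets: the ball study trains the reduced conv feature map
  (channels 16/32/64) with MLP velocity fields for 3000 steps; the
  oscillator study is MLP throughout (width 128, depth 3, 6000 steps).
  These sizes are the package's reference study conditions; all reported
  quantities in the test suite and the acceptance script are computed at
  these sizes.

## Known limitations

* No discrete-data support (spike counts need prior smoothing).
* `K_eff` is a conservative, threshold-based summary, not an estimate of
  intrinsic dimension; it depends on the nested-dropout budget `1/p`.
* Long-horizon rollouts accumulate autoregressive error; the package's
  rollout checks cover one period of the synthetic dynamics.
* Single-device, float32 training only; no mixed precision, no
  distributed training.
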