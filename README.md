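# dcflow — Dynamic Compression Flows

`dcflow` infers low-dimensional, *dynamics-preserving* latent
representations of high-dimensional time series — neural population
recordings, behavioral video, audio spectrograms — by jointly learning two
velocity fields with conditional flow matching:

* a **compressive flow** `u_φ(x, τ)` transporting states along a
  compression coordinate τ between data space (τ = 1) and a learned
  low-dimensional source subspace (τ = 0), and
* a **dynamical flow** `v_θ(x, τ, s, x_hist)` modeling temporal evolution
  at *every* compression level.

The coupling between data points and source points is a deterministic,
jointly trained encoder

    x^(0) = b + L D^{1/2} μ_ψ(x^{(1)}),     D = diag(d_1, …, d_M), d_i > 0,

with `L` orthonormal (thin non-pivoted QR, positive diag(R)) and `μ_ψ` a
normalized nonlinear feature map. Training samples linear bridges
`x^(τ) = (1−τ)x^(0) + τx^(1)` (compressive) and a double interpolation in
(τ, s) between consecutive frames (dynamical), regressing each field onto
its constant bridge velocity, plus a masked alignment loss:

    L = α·L_cf + β·L_df + η·L_align,       α = β = η = 1.

**Nested dropout** — masking a geometric random prefix `K ~ Geom(p)` of
latent coordinates in every term — orders the coordinates by importance,
gives the source distribution low-dimensional support, and (together with
the deterministic QR and feature normalization) makes the representation
**identifiable up to a per-coordinate sign**: two training runs agree
coordinate-by-coordinate, which is rare among nonlinear dimension-reduction
methods and is checked explicitly by this package's evaluation module. The
**effective dimension** is summarized as the smallest prefix K with
`Σ_{i≤K} d_i ≥ 0.95 Σ_i d_i`.

Everything differentiable is implemented on a small numpy reverse-mode
autodiff core (`dcflow/_autodiff.py`); flows are integrated as neural ODEs
with SciPy's adaptive Dormand–Prince RK45. See `docs/methods.md` for the
full model description and numerical choices.

## Worked example

Train on the bundled synthetic study — a planar oscillator (intrinsic
dimension 2) embedded in 20 ambient dimensions with 5% observation noise —
and inspect what the model recovered:

```python
import numpy as np
from dcflow.presets import (oscillator_data_config, oscillator_model_config,
                            oscillator_train_config)
from dcflow.synthetic_data import make_embedded_oscillator
from dcflow.training import train
from dcflow.encoder import effective_dimension
from dcflow.inference import simulate_rollout, summarize_latents
from dcflow.evaluation import loop_closure_ratio, reconstruction_error

data = make_embedded_oscillator(oscillator_data_config())
state, log = train(data, oscillator_train_config(seed=0),
                   oscillator_model_config())

d = state.encoder.d_values()
print("leading scales d_i:", np.round(d[:4], 3))
print("K_eff:", effective_dimension(d, 0.95))

_, recon = reconstruction_error(data.frames()[:150], state)
print("round-trip error: {:.2%} of data variance".format(recon["relative"]))

roll = simulate_rollout(data.data[0, 0], state, tau=0.0, n_steps=50)
summ = summarize_latents(roll, state)
print("loop closure:", round(loop_closure_ratio(summ.mu,
                                                min(3, summ.k_eff)), 3))
```

Output of this exact script (seed 0):

```
leading scales d_i: [0.496 0.471 0.008 0.001]
K_eff: 2
round-trip error: 0.00% of data variance
loop closure: 0.141
```

Reading: the scale vector collapses onto two coordinates — the model
recovered the true intrinsic dimension (`K_eff = 2`) out of a latent budget
of E(K) = 50; the compressive flow round trip (τ = 1 → 0 → 1) loses
essentially nothing; and a 50-step simulated rollout of the dynamical flow
at τ = 0 traces a closed loop in latent space (endpoint-to-start gap ≈ 14%
of the loop diameter), matching the periodic ground truth.

The same pipeline is available from the shell:

```bash
dcf make-data oscillator --out osc.h5 --seed 0
dcf train --data osc.h5 --out model.h5 --seed 0
dcf compress --checkpoint model.h5 --data osc.h5 --tau 0.0 --out states0.h5
dcf summarize --checkpoint model.h5 --states states0.h5 --out latents.h5 --csv mu.csv
dcf eval recon --checkpoint model.h5 --data osc.h5 --out recon.json
```

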