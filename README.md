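# radialcs

Compressed-sensing reconstruction of noisy, radially undersampled MRI.

MRI acquisition is slow: every k-space sample costs scan time, and
undersampling trades time for aliasing artifacts while measurement noise
corrupts what is acquired. `radialcs` implements a fast CS reconstruction
for this setting, aimed at people simulating or prototyping undersampled
MR imaging pipelines: it recovers an image `x` from pseudo-radially
masked, noisy k-space data `y = M ∘ F(x + n)` by solving

    min_{x, {L_i}}  ‖Φx − y‖² + η Σ_i ‖R_i x − L_i‖²
                    + λ Σ_i logdet((L_i L_iᵀ)^{1/2} + εI) + β Σ |Φx − y|

with the alternating-direction method of multipliers (over-relaxation
ω ∈ (0, 2)). Here `Φ = M ∘ F` is the masked unitary Fourier transform,
`R_i x` stacks the patches most similar to the i-th anchor patch into an
`(f², S_i)` matrix, and the LogDet term is a smooth nonconvex rank
surrogate: groups of mutually similar patches are approximately low-rank,
and shrinking their singular values — each by the closed-form minimizer of
`½(δ−σ)² + τ log(δ+ε)` — suppresses noise and aliasing while preserving
shared structure. A k-terms power-series Hutchinson estimator of `logdet`
(probe recursion `v ← Bv`, cost `O(k·m·N²)`) is provided alongside the
exact eigendecomposition path, together with the plain CS baseline
(`η = β = λ = 0`), zero-filling, pseudo-radial mask generation, four
noise families, and MSE/PSNR/global-SSIM quality indexes.

Everything runs on synthetic phantoms (Shepp–Logan and a piecewise
texture collage), so no scanner data are needed. See `docs/methods.md`
for the model details and design choices.

## Worked example

```python
import numpy as np
from radialcs import *

truth = make_phantom(PhantomSpec(128))
noise = NoiseModel(family="gaussian", sigma=20, seed=0)
mask = make_radial_mask(truth.shape, sensing_rate=0.3, seed=0)
obs = encode(add_noise(truth, noise), mask)

params = ReconParams(noise_variance=noise.variance)
img, trace = reconstruct(obs, params, ground_truth=truth)
zf = np.clip(adjoint(obs), 0, 255)
print(f"achieved sensing rate: {mask.sensing_rate:.3f} ({mask.n_spokes} spokes)")
print(f"zero-fill     : PSNR {psnr(truth, zf):.2f} dB, SSIM {ssim(truth, zf):.3f}")
print(f"reconstruction: PSNR {psnr(truth, img):.2f} dB, SSIM {ssim(truth, img):.3f}")
print(f"stopped after {trace[-1]['iteration']} sweeps, ADMM residual {trace[-1]['residual']:.4f}")
```

prints

```
achieved sensing rate: 0.301 (33 spokes)
zero-fill     : PSNR 22.02 dB, SSIM 0.905
reconstruction: PSNR 25.32 dB, SSIM 0.961
stopped after 100 sweeps, ADMM residual 0.0001
```

Only 30% of k-space was sampled and the samples carry σ = 20 Gaussian
noise; naive zero-filling leaves streaking and noise (22 dB), while the
nonlocal low-rank reconstruction recovers 25.3 dB and most of the
structural similarity. The trace records objective, ADMM residual and
PSNR per sweep.

The same pipeline is scriptable from the shell:

```bash
radialcs simulate   --size 256 --sensing-rate 0.3 --sigma 20 --seed 1 --out run/
radialcs reconstruct --kspace run/kspace.npz --out run/
radialcs benchmark  --size 128 --seed 1 --out bench/   # methods x noise families
radialcs ablate     --out ablation/                    # logdet estimator study
```

`simulate` writes the phantom, noisy image, mask (PNG/NIfTI) and a
k-space container plus a manifest with seeds and content hashes;
`reconstruct` writes the reconstruction, per-sweep trace CSV and a
quality report.

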