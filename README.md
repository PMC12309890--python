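# spiralcine

A workbench for **real-time spiral cardiac cine MRI reconstruction**. It
simulates a self-gated, variable-density spiral bSSFP acquisition of a
beating short-axis left-ventricle phantom and reconstructs the heavily
undersampled real-time frames (13 spiral arms, ~48 ms temporal footprint)
with a **score-based diffusion model conditioned by diffusion posterior
sampling (DPS)**, alongside classical baselines: naive gridded
reconstruction, l1-total-variation (ADMM), l1-wavelet (FISTA), and
low-rank + sparse decomposition. It is aimed at MRI reconstruction
researchers who want a small, fully tested, CPU-scale re-implementation of
this acquisition/reconstruction chain with no external data dependencies.

## The model

Image recovery is the linear inverse problem

    y = A x,   A = M F S,

with coil sensitivities `S`, unitary Fourier transform `F` and sampling mask
`M`; spiral samples are moved onto the Cartesian grid by GRAPPA operator
gridding (GROG). Baselines solve `min_x ||Ax - y||^2 + λ ψ(x)`.

The diffusion route models the prior over cine frames with a
variance-exploding SDE whose noise scale is geometric,
`σ(t) = σ_min (σ_max/σ_min)^t` (σ_min = 0.01, σ_max = 378, N = 2000 steps).
A score network `s_θ(x, σ)` is trained by denoising score matching,

    min_θ E || σ s_θ(x0 + σ z, σ) + z ||²,   z ~ N(0, I),

with Adam (lr 2·10⁻⁴ after linear warm-up, batch 1) and an EMA of the
weights. Reconstruction runs the reverse diffusion sampler for the last
n = 100 of N = 500 inference steps, warm-started from the coil-combined
temporal average `x_avg` forward-diffused to step n. Every step forms the
Tweedie denoised estimate and descends the data-fidelity gradient:

    x_n     = x_avg + σ_n N(0, I)
    x_{i-1} = x_i + (σ_i² - σ_{i-1}²) s_θ(x_i, σ_i) [+ √(σ_i²-σ_{i-1}²) z if i ≠ 1]
    x̂0(x_i) = x_i + σ_i² s_θ(x_i, σ_i)
    x_{i-1} ← x_{i-1} - γ_i ∇_{x_i} ||y - A x̂0(x_i)||²,   γ_i = 1/||y - A x̂0(x_i)||

The gradient is differentiated *through the score*; the numpy score network
implements its own backward pass, so no autodiff framework is needed.

The acquisition side reproduces the study design: 13 equidistant
variable-density interleaves per frame (adjacent-arm increment ≈ 28°,
effective FOV 9 cm at the k-space center falling to 3 cm at the edge,
slew- and amplitude-limited waveforms with moment-nulling rewinders), blocks
of `Ncine = ceil(t_RR / 48 ms)` repeated patterns, and gap-filling pattern
rotations `(2π/13)·(1/2, 1/4, 3/4, 1/8, 5/8, …)` between heartbeats so that
self-gated binning over nine heartbeats pools **104 equidistant arms** per
segmented cardiac phase.

## Worked example

Run the end-to-end pipeline — phantom, free-breathing spiral acquisition
(2 blocks × 10 frames at 96×96, 8 coils), self-calibrated GROG, sensitivity
estimation, all five reconstruction methods, metrics and volumetry:

```bash
cat > demo.yaml <<'YAML'
phantom:    {matrix: 96}
schedule:   {mode: free_breathing, n_heartbeats: 2, n_cine: 10}
diffusion:  {train_steps: 3000, channels: 24, warmup_steps: 500}
evaluation: {crop_size: 64}
seeds:      {master: 7}
YAML
spiralcine run --config demo.yaml
```

which prints (about 15 minutes, dominated by score training):

```
naive    SSIM 0.7801 ± 0.0101 | NRMSE 0.3125 ± 0.0449 | PSNR 23.04 ± 0.51 dB
tv       SSIM 0.9787 ± 0.0022 | NRMSE 0.0454 ± 0.0014 | PSNR 39.71 ± 0.69 dB
wavelet  SSIM 0.9434 ± 0.0060 | NRMSE 0.1020 ± 0.0054 | PSNR 32.69 ± 0.72 dB
lrs      SSIM 0.9545 ± 0.0034 | NRMSE 0.1090 ± 0.0095 | PSNR 32.14 ± 1.02 dB
dps      SSIM 0.8418 ± 0.0042 | NRMSE 0.1060 ± 0.0083 | PSNR 32.37 ± 0.98 dB
volumetry: EDV 14.4 mL, ESV 5.8 mL, EF 59.5%
```

Reading the output: metrics follow the quantitative protocol (per-frame
myocardium-centered crop, per-image [0,1] rescale, comparison against the
coil-combined reference reconstruction). Every regularized method clearly
beats the naive gridded reconstruction; the diffusion reconstruction beats
naive with a toy 24-channel score network, while the compressed-sensing
methods profit from the phantom's piecewise-smooth structure. The recovered
ejection fraction (59.5%) matches the phantom's programmed contraction
(59.9% by disc geometry). `--out DIR` additionally writes the raw HDF5
container, NIfTI reconstructions, a metrics CSV and timing records, all
stamped with the config hash.

Other CLI verbs: `schedule`, `simulate`, `train-score`, `reconstruct`
(any method on a raw container), `evaluate`, and `repeat-recon` (the
stochastic-variability study: repeated DPS reconstructions of one frame,
50 repetitions by default). The same functionality is available as a
library; see `spiralcine.workbench.run_pipeline` and `docs/methods.md` for
the science and the numerical choices.

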