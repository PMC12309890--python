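# Methods

`spiralcine` is a workbench for real-time spiral cardiac cine MRI
reconstruction. It simulates a self-gated, variable-density spiral bSSFP
acquisition of a beating left-ventricle phantom and reconstructs the
undersampled real-time frames with a score-based diffusion model conditioned
by posterior sampling, alongside compressed-sensing baselines. This note
records the models, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## Forward model

Reconstruction is posed as the linear inverse problem `y = A x` with
`A = M F S`: coil sensitivities `S` (one complex map per receive coil), the
unitary centered 2D Fourier transform `F`, and a binary Cartesian sampling
mask `M`. Coil combination is the sensitivity-conjugate weighted sum
`x = sum_i conj(S_i) x_i`. k-space coordinates are expressed in cycles/FOV,
normalized so the nominal resolution edge sits at 0.5; coordinate `k` maps to
grid index `k*N + N//2`.

## Acquisition schedule

A real-time frame consists of 13 equidistant variable-density spiral
interleaves (adjacent-arm increment 360/13 ~ 28 deg) with a 48 ms temporal
footprint. The spiral's effective sampling FOV decreases linearly from 9 cm
at the k-space center to 3 cm at the edge; the waveform is integrated on a
fixed raster, slew-limited near the center (high curvature) and
amplitude-limited outside, with substepped Euler integration so the discrete
waveform respects the hardware limits (40 mT/m, 170 mT/m/ms defaults), and a
triangular rewinder that nulls the zeroth gradient moment exactly. The raster
is refined automatically when a coarse step cannot land near the k-space edge
without leaving the sampled box. Readout samples satisfy monotone |k| and the
half-open box invariant; the rewinder excursion necessarily exceeds the box
while the gradients ramp down and is stored separately (no data is acquired
during it).

In breath-hold mode the pattern repeats for `Ncine = ceil(tRR / 48 ms)`
frames (one block slightly exceeding one RR interval); the first heartbeat is
a transient block and is excluded from binning. After each block the whole
pattern rotates by a gap-filling angle: bit-reversal-ordered fractions of the
base gap, `(2*pi/13) * (1/2, 1/4, 3/4, 1/8, 5/8, ...)`. With the identity
prepended, the union after `2^m` patterns is exactly equidistant; nine
heartbeats (one transient + eight rotations) give 104 equidistant arms per
binned cardiac phase. Free-breathing mode uses `Ncine = 10` frames per block
and nine blocks (~5 s); because equidistant unions exist only at
power-of-two pattern counts, the rotation list wraps after eight patterns so
the temporal average remains a 104-arm equidistant set.

Self-gating uses the repeated k = 0 sample: the RSS coil magnitude per frame
is band-pass filtered at 0.5-3 Hz (zero-phase, covering 30-180 bpm) and
peaks at a minimum spacing of 0.4 s serve as triggers; the period estimate is
the median trigger spacing. Frames are binned to phase
`floor(((t - preceding trigger)/local RR) * n_phases)`.

## Synthetic phantom and simulator

The phantom is a short-axis left ventricle: a bright blood pool inside a
myocardial annulus in a torso ellipse, with bSSFP-like contrast
(blood 1.0, myocardium 0.28, background 0.12) and a smooth low-order phase
map making the object complex. The endocardial radius follows a raised-cosine
program between its diastolic (24 mm) and systolic (15.2 mm) values — about
60% area ejection fraction — while the epicardium conserves annulus area.
Optional respiration translates the scene in-plane (off by default,
breath-hold emulation). Blood-pool masks are computed by 8x supersampled
exact coverage, so mask volumetry recovers the programmed ejection fraction
to well under 1% at matrix 96. Coil sensitivities are Gaussian-profiled
coils on a ring with linear plus mildly random phase, seeded.

Acquisition is simulated by exact type-2 discrete Fourier summation of the
coil-weighted frames at the rotated arm coordinates — no gridding
approximation — so the simulator is an independent oracle for the
reconstruction chain. Complex Gaussian noise with sd
`noise_sigma * max|signal|` is added; the default `noise_sigma = 0.005`
corresponds to ~35 dB image-domain SNR in the naive reconstruction, a
realistic cine regime. The default working matrix is 96 (512 is supported
but not required for any experiment).

## Gridding and calibration

Off-grid spiral samples are moved to their nearest Cartesian grid point by
GRAPPA operator gridding (GROG): fractional powers `G^delta` of unit-shift
coil-mixing operators, applied via eigen-decomposition, with colliding
samples averaged arithmetically. Two calibration routes exist:

* `grog_calibrate` fits unit-shift operators from a fully sampled Cartesian
  block by least squares — the classical formulation, appropriate when such
  a block exists.
* `grog_self_calibrate` (used by the pipeline) fits the shift-operator
  generators directly from consecutive raw samples along each arm:
  `y(k+delta) ~ expm(dx*Lx + dy*Ly) y(k)` linearized around the midpoint
  (second-order accurate), after averaging frames that share a trajectory
  (repeated patterns in a block), which suppresses noise without mixing
  inconsistent geometry. Singular values of `expm(L)` are capped at 1.5 to
  bound the noise amplification of fractional powers. At desk scale this
  grids a noiseless frame to ~2.5% relative error against exact masked
  k-space, whereas block calibration from any gridded average of the spiral
  data itself is badly biased.

Sensitivities are estimated from the apodized central region of the
temporal-average k-space divided by its RSS (threshold 5% of the maximum RSS
defines the support; phase referenced to the first coil) — a deliberately
simple low-resolution calibration; its recovery error against the generating
maps is below 5% on the support. Data consistency uses the uncompensated
mask `M` (no density weighting), matching the operator definition.

## Score-based diffusion model

The variance-exploding SDE uses the geometric noise scale
`sigma(t) = sigma_min (sigma_max/sigma_min)^t`, `sigma_min = 0.01`,
`sigma_max = 378`, discretized at N = 2000 training steps (sigma_0 = 0).
Training minimizes the sigma^2-weighted denoising score-matching loss
`E ||sigma s_theta(x0 + sigma z, sigma) + z||^2` with Adam (lr 2e-4 after a
linear warm-up, betas 0.9/0.999, batch 1) and an EMA of the weights
(rate 0.999), which is returned as the trained score.

The score network is a compact time-conditioned convolutional denoiser in
pure numpy with hand-written forward/backward passes: complex images travel
as two real channels; the inner CNN (3x3 convolutions, SiLU, per-channel
bias conditioning from Fourier features of log sigma) is wrapped in the
standard denoiser preconditioning `D = c_skip x + c_out F(c_in x)`, from
which the score is `(D - x)/sigma^2`. The explicit backward pass provides
the exact vector-Jacobian product through the score that conditioned
reconstruction requires. An analytic Gaussian score (exact for a Gaussian
prior) is available as an oracle for sampler tests.

Unconditional sampling uses the reverse diffusion sampler
`x_{i-1} = x_i + (sigma_i^2 - sigma_{i-1}^2) s(x_i, sigma_i) +
sqrt(sigma_i^2 - sigma_{i-1}^2) z`, with no noise added at the final step.
Conditioned reconstruction (diffusion posterior sampling) evaluates the
Tweedie denoised estimate `x0hat = x + sigma^2 s(x, sigma)` at every step and
descends the data-fidelity gradient `grad ||y - A x0hat||^2` (chain rule
through the score via the VJP) with step size `gamma = 1/||y - A x0hat||`
(zero-residual guard 1e-12; no additional constant scaling). Reconstruction
warm-starts from the coil-combined temporal average, normalized by its
magnitude maximum and forward-diffused to step n = 100 of an N = 500
inference discretization of the same sigma range; the warm-start noise level
is taken from the inference grid. Per-frame seeds fan out from a master seed
by hashing (stage, frame), so frame results are reproducible and
order-independent.

The empirical step-size rule presumes a sufficiently strong prior: with the
score forced to zero, the unregularized descent drifts away from the warm
start. The toy network reaches that regime at desk scale with 24 channels
and ~3000 optimizer steps (a few CPU minutes); the weaker 16-channel /
2000-step configuration trains (loss halves) but underperforms the naive
reconstruction when used inside DPS.

## Baselines

All solvers minimize `||Ax - y||^2 + lambda * psi(x)` (no 1/2 on the data
term) after normalizing by the maximum of the naive reconstruction:

* naive — adjoint of `A` plus coil combination;
* l1-TV — isotropic 2D total variation via ADMM (defaults lambda 0.03,
  40 iterations; penalty rho = 1 with 10 inner CG steps), forward
  differences with Neumann boundary, grouped complex soft-thresholding; the
  objective is monitored and a >10% increase raises an error;
* l1-wavelet — FISTA with monotone restart (defaults lambda 0.03,
  30 iterations; step 1/L with L = 2 for unitary A), Daubechies-4, 3
  levels, periodized; complex magnitude soft-thresholding of the detail
  bands (the coarsest approximation is not penalized, so the large-lambda
  limit keeps the coarse approximation);
* low rank + sparse — whole-series proximal alternation (defaults
  lambda_L = lambda_S = 0.02, 60 iterations): singular-value thresholding
  of the Casorati matrix (pixels x frames), temporal-frequency
  soft-thresholding of the residual, unit-step gradient data consistency.
  Thresholds are relative — lambda_L scales the largest initial singular
  value, lambda_S the largest initial temporal-frequency magnitude — since
  data are normalized per series. The temporal-frequency sparse step is
  ordering-dependent by design; permutation equivariance holds for the
  Casorati SVT step.

TV and wavelet reconstruct frames independently (2D); LRS operates on the
whole series.

## Evaluation protocol

Metrics crop each frame to a window centered on the myocardium (120 px at
full scale; proportionally smaller at desk matrices), rescale every image
individually to [0, 1] by min-max, and compute SSIM (11-px Gaussian window,
sigma 1.5, K1 = 0.01, K2 = 0.03), NRMSE (normalized by the reference
Euclidean norm) and PSNR (capped at 100 dB for identical images). Because of
the per-image rescale, the metrics are invariant to common positive affine
transforms of both inputs.

Quantitative comparisons follow the retrospective protocol: each real-time
frame's sampling mask is applied to the clean reference k-space, and the
metric reference is the coil-combined reconstruction of the full reference
k-space with the same estimated maps. This isolates the reconstruction
method from gridding idiosyncrasies of the prospective path and mirrors how
segmented references are used when fully sampled real-time frames cannot
exist. The fully prospective path (reconstructing the gridded raw samples
directly) remains available behind a config switch; at low SNR it need not
preserve the method ordering.

Cardiac function uses slice-summation volumetry from blood-pool masks
(fractional pixel coverage supported): diastole/systole are the phases of
global max/min summed area, `SV = EDV - ESV`, `EF = 100 SV/EDV`. Agreement
between two series is summarized by Bland-Altman bias and
bias +/- 1.96 * sd limits (sample sd). Per-stage and per-frame wall-clock
times are logged for information only.

## What the synthetic experiments show — and what they do not

The phantom exercises the full chain (schedule, gating, gridding,
calibration, every reconstruction method, metrics, volumetry) under
controlled conditions with known ground truth, so tests can assert exact
structural facts (104-arm unions, adjacent-arm increments, EF recovery) and
method orderings (naive below every regularized method; DPS above naive with
a sufficiently trained score). It does not emulate bSSFP banding or
off-resonance blurring, through-plane motion, flow, realistic coil noise
correlations, or anatomical variability, and the toy score network is far
smaller than a full score-model architecture — passing tests demonstrate
correctness of the algorithms at desk scale, not clinical image quality.
Problem sizes were chosen for a single CPU: matrix 96 for the pipeline
demonstrations, 64 x 64 / 3000 optimizer steps for score training in the
test suite, 50 repetitions for the stochastic-variability study.

## Known limitations

* GROG accuracy at 6-8 desk-scale coils is below what ~30-coil arrays
  provide; the singular-value cap trades a small bias for bounded noise
  amplification.
* The ADMM TV solver converges linearly and needs several hundred
  iterations for 1e-6 agreement with the exact 1D denoising solution; the
  40-iteration default matches the reference protocol, not full
  convergence.
* DPS quality is tied to prior strength; the toy network's capacity, not
  the sampler, is the binding constraint at desk scale.
* The self-gating detector assumes a dominant cardiac modulation of the DC
  signal; heavy arrhythmia or respiratory contamination of the band is not
  handled.
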