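# Methods

## Scope

`mp3rage` implements a quantitative T1-mapping stack for
magnetization-prepared rapid gradient-echo acquisitions with two or three
readouts (MP2RAGE / MP3RAGE): a deterministic steady-state forward model,
classical lookup-table inversion, a Monte-Carlo maximum-a-posteriori (MAP)
estimator with per-voxel uncertainty, a two-pool selective inversion
recovery (SIR) reference fit, a patch-based residual-CNN calibration of
MAP T1 maps to IR T1 values, and a seeded digital phantom that makes the
whole chain testable without any scan data.

## Forward model

One inversion cycle of length `cycle_tr_s` contains an adiabatic inversion
(efficiency `eff`), K gradient-echo blocks of `n_excitations` pulses with
nominal flip angle `alpha` spaced `TR_exc` apart, and free-recovery gaps.
Longitudinal magnetization (M0 = 1) evolves by composition of affine maps:
inversion `Mz -> -eff*Mz`, recovery `Mz -> Mz e^{-t/T1} + (1-e^{-t/T1})`,
and per excitation period `Mz -> Mz cos(b1*alpha) E1 + (1-E1)` with
`E1 = e^{-TR_exc/T1}`. A run of m periods composes in closed form through
the geometric series; the full cycle is affine `Mz -> A Mz + B` and the
steady state is `B/(1-A)`. The readout samples the block center, m = n/2
periods after block start (fractional exponents permitted). This
convention reproduces non-negative timing gaps for the default protocol
(TI 1010/3683/6355 ms, TR_exc 6 ms, cycle 8.25 s, n = 225, alpha = 4 deg,
eff = 0.84); `derive_block_timing` validates any other protocol and
rejects negative gaps.

Because no closed-form reference exists in the package's sources, the
analytic fixed point is validated against an independent oracle that
iterates the elementary per-excitation maps for 60 full cycles; agreement
is ~4e-15 across a 500-point T1 grid (tests assert 1e-10).

Ideal GRE signals are real (`sin(b1*alpha) * Mz`); complexity enters only
through the noise model, which adds independent Gaussian noise to the real
and imaginary channel of each readout. The "uniform" T1-weighted image
combines two complex GREs as `Re(conj(G_i) G_j) / (|G_i|^2 + |G_j|^2)`,
bounded in [-0.5, 0.5] by the AM-GM inequality, with 0/0 := 0. A
beta-regularized variant (`beta = 0.25 * mean(|G_i|^2+|G_j|^2)` by
default) exists for registration-support imagery only.

## Lookup point estimate

`build_lookup` tabulates S(T1) on the largest strictly monotone contiguous
T1 sub-grid containing 1.5 s and inverts it by monotone interpolation;
out-of-range values are masked, never clipped. Per-voxel B1 correction
interpolates S(T1) linearly between the two bracketing tables of a
41-point B1 grid spanning [0, 2].

## Monte-Carlo MAP estimation

The posterior `P(T1 | S)` is built per B1 factor by simulating the forward
model on a 500-point T1 grid spanning (0, 5] s (T1 = 0 is unphysical and
excluded), adding Gaussian noise of sd `noise_sigma` (default 0.005, in
forward-model signal units where M0 = 1) to both channels of each GRE,
recombining uniform images from the noisy complex values, and histogramming
into 100 bins over [-0.5, 0.5] (1-D on S12 in pair mode; 100 x 100 on
(S12, S13) in joint MP3RAGE mode). Sampling is stratified — every grid
point receives an equal share of the trials (a remainder is spread over the
leading points so counts sum exactly to `n_trials`) — which realizes the
uniform T1 prior and makes the per-T1 likelihood normalization exact.
Bayes' theorem then reduces to column normalization. The MAP estimate is
the posterior argmax (ties break to the smaller T1), the uncertainty is
the discrete posterior standard deviation, and empty bins or out-of-range
S yield invalid voxels. Each (B1, grid-point) pair owns a Philox
counter-keyed substream, so results are bit-reproducible and independent
of evaluation order. Volumes use the nearest B1 grid factor per voxel.

A resolution limit worth stating: one 0.01-wide S bin corresponds to
`0.01 / |dS/dT1|` seconds of T1 — between 3 and 8 grid steps of the
500-point grid over T1 in [0.5, 3.5] for the default protocol. At very
low noise the posterior within a bin is exactly tied, so MAP estimates
are quantized to bins and can deviate from the continuous point estimate
by up to one bin width in T1 regardless of the trial budget. The noise
estimate from an ROI (`estimate_noise_roi`) takes the largest per-channel
standard deviation over all GREs and rescales it by the ratio of the
modeled signal range (T1 in [0.5, 5], b1 = 1) to the acquired magnitude
range, approximately preserving the contrast-to-noise ratio; noise is
treated as globally homogeneous.

## SIR reference fitting

The two-pool model couples free-water and macromolecular longitudinal
magnetization with equal intrinsic rates (R1f = R1m = R1) and exchange
`kmf` (macromolecular -> free) and `kfm = psr * kmf`. Recovery of the
deviation from equilibrium has eigen-rates `R1` and `R1 + kmf (1+psr)`
with eigenvectors `(kmf, kfm)` and `(1, -1)` — a biexponential evaluated
in closed form (validated against adaptive ODE integration to < 1e-6
relative). The sequence model assumes complete saturation after each
readout, recovery over the pre-delay `td` (default 2.5 ms as specified
for the protocol; unusually short for an SIR pre-delay, configurable),
scaling by the inversion coefficients (Sf fitted, Sm fixed from a
B1-dependent lookup), and recovery over ti. The default sampling grid is
the 13 printed inversion times from 6 ms to 8 s. Fitting uses bounded
trust-region least squares over (R1, PSR, kmf, Sf, M0f) with bounds
r1 in [0.1, 5] /s, psr in [0, 0.5], kmf in [0, 100] /s, sf in [-1, 0];
signed signals by default with a magnitude-fit flag for polarity-free
data; deterministic multi-start is available. T1 = 1/R1f. Degenerate
(flat or zero) voxels are flagged, not raised.

## Calibration network

A patch-based residual regressor maps a P x P in-plane patch of MAP T1
values (P in {1, 5, 9, 13}, default 5; optionally sigma-T1 as a second
channel) to the IR T1 at the center voxel. The topology is an 18-layer
residual network adapted to tiny inputs: a 3x3 stride-1 stem without
max-pooling, four stages of two basic blocks with widths (w, 2w, 4w, 8w),
stage downsampling replaced by stride 1 whenever the running spatial
extent is below 4, global average pooling, and a single-output affine
head. Because no GPU framework is assumed, the network and its
backpropagation are implemented directly on numpy (im2col convolutions,
batch normalization, Adam) in float32; training is seeded and
reproducible. The base width w is configurable: w = 64 reproduces the
classical channel plan, while the package's benchmark configurations use
w = 4 so that CPU training of a fold completes in minutes; the phantom
calibration task saturates well below this capacity.

Training minimizes MSE with adaptive-moment gradient descent at learning
rate 1e-5, batches of 256 patches, up to 10,000 steps (benchmark
configurations use 2,000), validation every 50 steps, and early stopping
once the best validation loss is 1,000 steps old (20 evaluations);
the best-validation checkpoint is returned. Inputs and targets are in
seconds without standardization — both live on the same ~[0.5, 3.5] s
scale. Two initialization choices matter at this learning rate: the
affine head is zero-initialized with its bias set to the training-target
mean, so the model starts as an unbiased constant predictor rather than
spending thousands of steps unlearning a random offset. Validation loss
is computed on at most 2,048 seeded-subsampled validation patches to
bound evaluation cost. Leave-one-out cross-validation rotates the test
subject across four folds (train 2 / validate 1 / test 1) with a
subject-disjointness assertion; patch-size and noise-level sensitivity
sweeps rebuild MAP maps per noise level with 1e6 trials.

## Digital phantom

Each subject is a 48 x 48 x 5 volume (five axial slices, echoing the IR
acquisition's slice count) with concentric in-plane tissue shells — CSF
core (r <= 5), SGM ring (r <= 9), WM bulk (r <= 16), CGM shell (r <= 21),
background outside — thick enough to survive 3-cube erosion. Tissue T1
ground truths are the IR reference values (WM 1.48 s, SGM 1.74 s, CGM
2.05 s; CSF 4.3 s as a placeholder inside the prior support, excluded
from metrics), each scaled per subject by a seeded +/-2 % jitter. The B1+
field is a smooth in-plane tilted-plane-plus-bowl polynomial within
[0.7, 1.3], constant through-slice. MP3RAGE GREs are simulated from the
forward model with quadrature Gaussian noise (default sd 0.005, the
operating noise level); SIR volumes use per-tissue two-pool parameters
(WM psr 0.12, GM psr 0.06, kmf 10 /s, sf -0.95 — literature-typical
placeholders, configurable and never asserted as measured values). The
MP2RAGE-vs-IR discrepancy is emulated by multiplying WM/SGM/CGM voxels of
the MAP map by tissue factors 0.828 / 0.891 / 0.953 (the observed
relative values) times a smooth zero-mean 2 % spatial field, giving the
calibrator both a tissue-dependent bias and spatial structure to exploit.

What the phantom does not emulate: anatomical geometry, partial-volume
mixing, through-slice B1 variation, spatially varying noise, registration
error, and T2*/B0 effects. Passing tests therefore demonstrate the
correctness of the estimators and the learnability of a
multiplicative-plus-smooth-field bias — not performance on real brains.

## Numerical choices and degenerate inputs

* T1 grid excludes zero; signals at non-positive T1 raise domain errors;
  background phantom voxels carry pure noise and are masked downstream.
* Histogram conservation is exact (|S| <= 0.5 always; edge values land in
  the outermost bins).
* Geometric-series composition handles the cos(alpha) E1 -> 1 limit
  explicitly.
* Exchange-free (kmf + kfm = 0) SIR recovery falls back to the
  single-exponential form; with psr = 0 the model coincides with
  single-pool inversion recovery to 1e-10.
* Population (not sample) variance in the Bland-Altman decomposition so
  rmse^2 = bias^2 + variance holds to machine precision; limits of
  agreement are bias +/- 1.96 sd. Relative value is the ratio of tissue
  means per subject, averaged across subjects (a voxelwise-ratio variant
  is available behind a flag). Metrics use the intersection of validity
  masks and report voxel counts.
* Label erosion applies a cube structuring element to one tissue (CGM by
  default) and sends eroded voxels to background.
* Paired t-tests with zero-variance differences are flagged degenerate
  rather than returning spurious statistics.

## Problem sizes

The test suite and the acceptance script run the study conditions at
desk scale: 4 subjects of 48 x 48 x 5 voxels, 1e6 Monte-Carlo trials for
operating tables (1e7 where single tables are validated), 2,000-step
calibration training at base width 4, and per-tissue voxel subsamples for
voxelwise SIR fitting. These sizes are the package's benchmark defaults;
all of them are configuration parameters.

## Known limitations

* The MAP estimator's S-bin quantization (above) bounds its agreement
  with the continuous point estimate; a finer binning would trade memory
  and trial efficiency for resolution.
* MAP MP3RAGE (joint mode) shares the pair-mode binning and inherits its
  B1 sensitivity; the third readout's inversion time is not optimized for
  B1 insensitivity.
* The numpy training loop is single-threaded; full-width (w = 64)
  training is possible but slow on one CPU.
* The SIR pre-delay default of 2.5 ms follows the documented protocol but
  is short enough that pre-inversion magnetization is nearly saturated;
  if a protocol intends seconds-scale pre-delays, set `td_s` accordingly.
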