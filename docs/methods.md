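# Methods

`dcedirect` quantifies subtle blood–brain-barrier leakage from dynamic
contrast-enhanced (DCE) MRI. It implements the conventional quantification
chain — variable-flip-angle T1 mapping, spoiled-gradient-echo (SPGR)
signal-to-concentration conversion, and voxelwise tracer-kinetic fitting —
and a direct-inference convolutional network that maps the measured signal
time series straight to pharmacokinetic maps, trained with a joint
parameter + kinetic-model-consistency loss. A seeded digital reference
object makes the whole stack trainable and testable at desk scale.

## Signal model

The SPGR steady state at flip angle α and repetition time TR is
S_ss(T1) = M0 sin α (1 − E)/(1 − cos α E) with E = e^(−TR/T1). Pre-contrast
T10 is estimated pointwise from two flip angles (2° and 12° by default) via
the closed-form variable-flip-angle inversion; M0 follows algebraically from
the 12° image and T10. The dynamic series is modelled in baseline-offset
form,

    S(t) = S_ss(T1(t)) + [S(0) − S_ss(T10)],

with 1/T1(t) = 1/T10 + r1 Ct(t), so that Ct = 0 reproduces the measured
baseline *exactly* even when (M0, T10) imperfectly describe it. The
inversion to concentration is the exact algebraic inverse of this form; it is
closed-form per voxel and frame. Frames whose signal exceeds the SPGR
saturation asymptote are masked invalid rather than raising. Invalid voxels
everywhere in the package are NaN plus an explicit boolean mask.

Units: TR and T1 in seconds, concentration in mM, relaxivity r1 in
s⁻¹mM⁻¹ (so L = r1·Ct·TR is dimensionless); kinetic rates are expressed in
min⁻¹, the time axis being converted to minutes only at the kinetics
boundary. Default protocol constants: TR = 8.24 ms, flip angles 2°/12°,
r1 = 4.2 s⁻¹mM⁻¹, 1 baseline + 20 dynamic frames at 73 s, hematocrit 0.45.

Negative concentrations produced by noise through the inversion are kept by
default so that fitting sees unbiased noise; clipping is opt-in.

## Tracer-kinetic models and fitting

Patlak: Ct(t) = vp Cp(t) + Ktrans ∫₀ᵗ Cp dτ. Extended Tofts:
Ct(t) = vp Cp(t) + Ktrans ∫₀ᵗ Cp(τ) e^(−kep(t−τ)) dτ, parameterized as
(Ktrans, kep, vp); ve = Ktrans/kep is derived output. The plasma curve comes
from a whole-blood vascular input function (mean over an in-plane 3×3 patch,
e.g. in the superior sagittal sinus) divided by (1 − Hct). No bolus-delay
correction is applied: at 73 s sampling the arteriovenous delay is far below
the frame interval.

Quadrature is cumulative trapezoid on the native grid. The exponential
convolution uses the recursion
I_i = E_i I_{i−1} + (Δt_i/2)(Cp_i + E_i Cp_{i−1}), E_i = e^(−kep Δt_i),
which reduces *bit-exactly* to the trapezoid sum at kep = 0 — the Patlak
model is the exact kep → 0 limit of the implementation, not merely an
approximation. The baseline frame is the t = 0 quadrature anchor with
Cp(0) = 0 and is excluded from fit residuals.

Patlak parameters are ordinary least squares on the design [∫Cp, Cp]
(closed form, vectorized over voxels; rank-deficient designs flag the voxel
invalid). Extended Tofts minimizes the residual sum of squares with
bounded L-BFGS-B, an analytic gradient (the convolution's kep-derivative is
obtained by differentiating its recursion), and a 30-iteration cap. The
solver runs to its iteration budget rather than stopping on a loose
relative-change test (tight `ftol`/`gtol`), because the low-Ktrans/high-kep
corner of the parameter space is a flat valley where default tolerances
declare victory early. Internally the parameters are scaled by typical brain
magnitudes (10⁻³, 0.3, 10⁻²) to condition the quasi-Newton Hessian. Bounds
default to Ktrans ∈ [0, 0.1] min⁻¹, kep ∈ [0, 10] min⁻¹, vp ∈ [0, 1], with
initial point (10⁻³, 0.1, 0.02) — the low-permeability brain regime; all are
arguments. Non-convergence is reported in the per-voxel `FitReport`, never
raised.

On a noiseless 5×5×5 grid spanning Ktrans ∈ [10⁻³, 10⁻²] min⁻¹,
kep ∈ [0.05, 1] min⁻¹, vp ∈ [0.005, 0.05], the fit recovers all three
parameters within 1% relative at ≥ 95% of grid points inside the iteration
budget (the residual failures sit at the Ktrans = 10⁻³, kep = 1 corner where
the backflux term is barely identifiable from 21 samples).

## Direct inference network

The network maps a 24 × 24 patch with the T dynamic frames stacked as
channels to a 24 × 24 × n parameter patch (n = 2 for Patlak, 3 for extended
Tofts). First layer: each frame is filtered independently by a 4 × 4 kernel
(depthwise convolution) and the frames are then combined by learned 1 × 1
weights into 32 feature maps — the stated per-frame filtering + aggregation
semantics admit more than one reading; this depthwise-then-pointwise
factorization is the one implemented. Two parallel pathways follow: a local
pathway of three standard 4 × 4 convolutions and a global pathway of three
dilated 4 × 4 convolutions (dilation 2, 4, 8). The local depth is chosen to
mirror the three dilated layers so the concatenation is symmetric. The
concatenated pathways are fused by a 4 × 4 convolution with 64 filters,
followed by per-voxel fully connected layers (1 × 1 convolutions, widths 256
and 128) and the n-channel linear output. ReLU follows every layer except
the output; all convolutions are stride-1 and zero-padded (the even kernel
pads 1-before/2-after per axis, times the dilation) so every layer preserves
the 24 × 24 extent.

The implementation is pure numpy with hand-written backpropagation:
channels-last layout, HWIO weights, im2col as contiguous tap copies so both
passes are BLAS matrix products; the input gradient is the transposed
convolution written as per-tap accumulation. Gradients are verified against
central finite differences in the test suite (in float64, with biases nudged
off zero so no pre-activation sits exactly on a ReLU kink, where the
subgradient convention and finite differences legitimately disagree).

### Loss

For predicted maps θ̃ and targets θ (themselves produced by conventional
fitting, or ground truth on synthetic data):

    L = ‖θ − θ̃‖² + λ ‖Ct(t) − f_tk(θ̃)‖²,

where f_tk is the Patlak or extended Tofts forward model evaluated through
the same differentiable quadrature as the fitting code, using the *training*
subject's plasma curve; at test time no input function is consumed. λ
defaults to 1. The literal form (plain sums, raw parameter scale) is the
functional default; training uses mean-per-element normalization of each
term and per-channel standardization of the parameter term, because Ktrans
(~10⁻³) and vp (~10⁻²) differ by an order of magnitude and an unscaled MSE
would let vp dominate. The network learns standardized outputs; prediction
applies the inverse transform. Raw mode reproduces the plain sum exactly
(the tests pin a hand-evaluated one-voxel case).

### Training protocol

Patches are cut on a stride-6 lattice (a 24-wide patch is then covered by
exactly 16 patches at every interior voxel). The full-size protocol is Adam
at learning rate 10⁻³ with per-update decay lr_k = lr₀/(1 + 10⁻⁴ k)
(the stated "decay rate" is read as a learning-rate schedule, not weight
decay), at most 200 epochs, mini-batches of 1000 patches, an 80/20
train/validation split, early stopping after 15 epochs without validation
improvement, and restoration of the best-validation-epoch weights. Inputs
are normalized by the subject's mean positive baseline signal (config
`input_scaling`, the alternative being raw intensities); the same statistic
is recomputed from the test volume at prediction time, so transfer across
subjects needs no shared calibration. All randomness — split, shuffling,
weight initialization — flows from one seed. Cross-validation is
leave-one-subject-out.

At prediction time each slice is tiled with stride-6 patches; every voxel's
estimate is the average over all patches containing it (16 in the interior,
the actual count near borders). The tiling additionally snaps a final origin
to the right/bottom edge so border voxels that a pure lattice would miss are
still covered; interior counts are unaffected.

## Digital reference object

Each synthetic subject is an elliptical "brain" of normal-appearing white
matter containing a central deep-gray-matter ellipse, three white-matter-
hyperintensity blobs, one recent-stroke-lesion blob, and a small venous
vessel column sized to host a 3 × 3 input-function patch; blob placement
jitters with the seed and every class is guaranteed ≥ 1% of in-brain voxels.
Ground-truth parameters are tissue-conditional Gaussian draws (truncated at
zero) around means Ktrans (min⁻¹): NAWM 10⁻³, WMH 2·10⁻³, DGM 1.5·10⁻³,
RSL 5·10⁻³; vp: 0.01/0.015/0.03/0.02, vessel vp 0.6; relative spread 10%.
These encode the expected tissue ordering (lesional tissue leakier than
NAWM; vessel dominated by plasma volume) at the subtle-leakage magnitudes
relevant to small-vessel disease and post-stroke imaging; they are generator
defaults, not measurements. kep = Ktrans/ve with ve = 0.2 for extended Tofts
phantoms. T10: white matter 0.6 s, WMH 0.8 s, gray matter 1.0 s, blood
1.4 s (1.5 T values).

The plasma input function is a biexponential bolus
Cp(t) = D(a₁e^(−m₁t) + a₂e^(−m₂t)) for t > 0 — defaults a₁ = 33 mM,
m₁ = 2 min⁻¹, a₂ = 3.3 mM, m₂ = 0.05 min⁻¹, D = 1 — which on the 73 s grid
peaks at the first post-injection frame near 6 mM and decays to ~1 mM by 24
minutes, the shape family of venous curves at this temporal resolution.
Per-subject log-normal jitter (10%) multiplies peak and tail separately, so
subjects share a curve family but not a curve.

Simulation composes parameter sampling → kinetic forward → SPGR forward →
additive zero-mean Gaussian noise with std = σ × (mean in-brain baseline
signal), independent per voxel and frame; σ defaults to 2%. Gaussian rather
than Rician noise keeps the concentration inversion unbiased at the
simulated SNR; a Rician floor is out of scope. Every intermediate (labels,
truth, input function, noiseless concentration and signal, relaxation maps)
is stored so each pipeline stage can be tested against the stage that
generated it, and the whole dataset is a pure function of its spec and seed.

What the phantom does *not* emulate: anatomical geometry, motion and
registration artifacts, B1/flip-angle error, partial-volume mixing at tissue
boundaries, protocol variation across sites. Tests passing on the phantom
therefore validate the numerics and the learning machinery, not robustness
to those real-data effects.

## Evaluation

nRMSE is the masked RMSE normalized by the reference range within the mask
(range-normalization is a pinned convention; reported numbers depend on it).
SSIM is the Gaussian-weighted structural similarity (σ = 1.5, population
covariance), data range from the reference inside the mask, averaged over
masked voxels. Agreement between estimators uses Bland–Altman limits
(mean difference ± 1.96 SD) and Lin's concordance correlation coefficient
with population moments. Tissue-wise method comparison reduces each subject
× tissue to one summary value (the median) and applies the paired two-sided
Wilcoxon signed-rank test across subjects — the pairing unit is the subject;
no multiple-testing correction. Identical samples return the null-center
statistic with p = 1. Curve-fit error tables are computed per 2D slice
(nRMSE over the slice's space–time block, SSIM averaged over frames) with
mean ± SD aggregated across slices.

## Desk-scale end-to-end experiment

`dcedirect.experiments.run_end_to_end` generates a six-subject 64 × 64 × 4
Patlak phantom at σ = 2%, trains on five subjects and evaluates on the
held-out sixth. The desk-scale network keeps the architecture family
(depthwise first layer, dual pathways, dilations 2/4/8, 4 × 4 kernels) at
reduced width — 16 filters, 32 at the fusion layer, 64/32 dense — and trains
with mini-batches of 64 for at most 50 epochs (patience 10); these sizes are
chosen once for a single-CPU run of minutes. Training inputs are the noisy
signal; consistency-loss concentrations are obtained by inverting the noisy
signal — exactly what a real pipeline would feed. Evaluation covers tissue
voxels (vessels and background excluded: intravascular voxels are not a
permeability target and the Patlak model reduces to its vp term there).
Reported quantities: Pearson correlation of predicted vs ground-truth
Ktrans and median absolute Ktrans error of the network against voxelwise
Patlak fitting of the same noisy data — the direct-inference robustness
claim as a measurable comparison. The noise-averaging built into patchwise
training gives the network its advantage over the per-voxel fit at this
noise level; at σ = 0 the comparison favors the (then exact) linear fit.
Like any small seeded training run the outcome varies with the seed: across
the seeds examined the error ordering (network at or below the fit) was
stable, while the Ktrans correlation moved by several hundredths (0.86–0.93)
because fifty epochs do not always reach the same point on the loss curve.
The experiment and its tests therefore fix the seed.

## Known limitations

* The first-layer reading (depthwise + pointwise) is the single point most
  open to alternative interpretation of the architecture.
* The numpy trainer is single-threaded BLAS; full-size training (32/64,
  256/128, batches of 1000, 200 epochs) is functional but meant for GPU-free
  demonstration, not production throughput.
* Voxelwise extended-Tofts fitting loops per voxel; expect ~1 ms/voxel.
* No B1 correction, Rician noise floor, bolus-arrival estimation,
  registration, or segmentation — masks and aligned volumes are inputs.
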