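# Methods

This package simulates, end to end, a fiber-optic common-path OCT distal
sensor that guides the axial position of a microsurgical tool (a subretinal
injector) by tracking retinal boundaries in individual A-scans. The three
stages — semantic segmentation of 1D depth profiles, Kalman fusion of
position and velocity measurements, and proportional depth-targeting control
with a velocity-limited motor — are the method under study; the retina, the
hand tremor, and the motor are synthetic stand-ins so the whole loop runs on
a desk.

## Coordinate and unit conventions

Pixel 0 of every A-scan is the fiber end (the reference reflector of a
common-path interferometer sits at the tip, so the tip is depth zero).
Depth increases with index at 2.7 um per pixel axially. All positions are
fractional pixel indices internally; micrometers appear only at API edges
via `pixel_size_um`. One control unit `u` moves the measured boundary
position by one pixel of optical path (motor micrometers divided by 2.7), so
a single unit system runs through the plant model, the Kalman filter, and
the control law.

## Phantom (`octrack.phantom`)

An A-scan is rendered as a piecewise-constant reflectivity profile over the
eight classes (VH, GCL, IPL, INL-OPL, ONL-ELM, PR, CH, below-retina),
multiplied by unit-mean exponential speckle (fully developed speckle
intensity statistics, coefficient of variation 1), attenuated exponentially
with depth, blurred by a Gaussian axial PSF, and floored with additive
detector noise clipped at zero. The label mask is the noise-free class of
every pixel, and the exact fractional boundary positions are carried
alongside the mask — metrics score against these, not against re-derived
mask edges.

Defaults and why:

- **Layer thicknesses** (GCL 60, IPL 70, INL-OPL 80, ONL-ELM 120, PR 80,
  CH 250 um; per-scan jitter SD 5 um, per-eye mean offsets SD 15 um): round
  values plausible for a large-mammal retina. They are modeling choices, not
  measurements — no layer-thickness table exists for the tissue the method
  was originally demonstrated on.
- **Reflectivity palette** (VH 0.02, GCL 0.60, IPL 0.25, INL-OPL 0.55,
  ONL-ELM 0.10, PR 1.00, CH 0.45, below 0.04): alternating bright
  (plexiform, photoreceptor) and dark (nuclear) bands, the appearance that
  makes retinal OCT segmentable in the first place. An earlier draft palette
  made the IPL and the depth-attenuated choroid identical in effective
  brightness, which is both physically wrong (the bands are distinguishable
  in practice) and an identifiability trap: the dice-trained network
  absorbed the IPL into the choroid at some initializations.
- **Attenuation** 5e-4 per um: mild single-pass decay, ~0.55x across the
  retina; keeps deep layers visible the way system dynamic range does.
- **PSF sigma** 0.8 px (~1.9 px FWHM = ~5 um): the axial resolution of a
  1060 nm center / 100 nm bandwidth swept source, at 2.7 um sampling.
- **Block averaging**: the acquisition chain averages eight sequential
  A-scans before segmentation, so dataset samples and simulator frames are
  averages of eight independent-speckle renders (speckle CV ~0.35). Single
  realizations are available (`n_average=1`) but are not what the network
  ever sees in the real signal path.

Tremor is two seeded sinusoids plus optional white jitter: drift (default
300 um peak-to-peak at 0.2 Hz) and physiological tremor (50 um peak-to-peak
at 10 Hz, mean axial speed 2·pp·f = 1 um/ms), mean-removed. Real tremor is
broadband; sinusoids reproduce the magnitude/frequency orders the
compensation loop must handle and make analytic checks possible.

What the phantom does **not** model: spectral-domain physics (fringes,
k-sampling, FFT artifacts), transverse beam effects (speckle decorrelation
under lateral motion, integration-volume changes), diseased-retina
morphology, and absolute SNR of any particular instrument. Passing tests
show the algorithms are implemented correctly and behave as designed under
controlled conditions; they do not certify performance on tissue.

## Preprocessing (`octrack.preprocess`)

Background subtraction clamps negative residuals at zero. Eight-scan blocks
are averaged elementwise. The 320-px crop is located by cross-correlating
each raw A-scan with a template (the dataset mean after aligning every
scan's retinal surface to index 0 and zeroing values below 5% of the
maximum); the maximizing displacement estimates the surface position, and
the window starts 40 px above it so the surface sits near the crop top with
room for the whole retina below. Cross-correlation is circular (FFT-based)
on raw intensities with integer lags; ties break toward the smallest
displacement; correlations are rounded at 1e-9 before the argmax so
floating-point noise cannot break ties. Out-of-range windows clamp to the
valid range and set a flag. `depth0_px` bookkeeping guarantees
raw index = crop offset + local index everywhere.

Training sets are augmented with five extra copies per scan, rolled by a
uniform integer shift in [-15, 15]; vacated pixels replicate the edge value
(intensity) and edge class (labels) — zero-filling would fabricate class
transitions at the window edges. Train/test splits are by synthetic eye
identity, never by scan.

## Network (`octrack.nn`, `octrack.unet1d`)

The segmentation model is a 1D U-net family: `b` contracting blocks (conv →
batch norm → ReLU → max-pool), `b` expanding blocks (transposed conv →
optional skip concatenation → conv → batch norm → ReLU), one convolution per
block, the same channel count everywhere, and a 1x1 convolution head to 8
classes with softmax. The receptive field is

    r = s^b (1 + 2(k-1)) - k

with kernel k (default 15), sampling size s, and depth b; the default
configuration (b=3, s=4, 12 channels, no skips) has r = 1841 >> 320, so
every output pixel sees the whole scan — position within the layer stack is
inferable even though a CNN has no explicit coordinate input. Note that
(k=15, s=2, b=4) evaluates to 449 (sometimes quoted rounded up to 450), and
(k=15, s=2, b=3) gives only 217, which is why the reduced-depth variants
raise s to 4.

Numerical choices: zero "same" padding inside blocks (without it the
length bookkeeping of single-conv blocks cannot close); transposed-conv
kernel = stride = s (pure upsampling, no overlap artifacts); per-A-scan max
normalization of inputs (speckle is multiplicative, so the profile is
scale-free); He initialization; float32 throughout.

The layers are implemented directly in numpy with hand-derived backward
passes (im2col convolutions, standard batch-norm backward, argmax-routed
pooling gradients) and verified against central-difference gradients in the
test suite. At this model size (~13k parameters, 320-px inputs) numpy
matrix multiplication trains the network in minutes on one CPU core.

## Training and evaluation (`octrack.train_eval`)

The recipe: generalized dice loss, Adam, at most 20 epochs, mini-batch 128,
learning rate 1e-3 dropped tenfold after epoch 10. The loss is

    GDL = 1 - 2 (Σ_c w_c Σ_i r_ci p_ci) / (Σ_c w_c Σ_i (r_ci + p_ci)),
    w_c = 1 / (Σ_i r_ci)^2,

with weights computed per batch and classes absent from the batch truth
excluded (their weight is a 0/0). The gradient w.r.t. probabilities is
chained through the softmax analytically.

Dice-family losses have a known failure mode: a replicate can converge with
one thin class entirely absorbed by a neighbor, at which point the saturated
softmax leaves no gradient to recover it. This is initialization-dependent.
`fit_with_restarts` trains up to two replicate initializations and keeps the
better one by mean IoU on a validation eye held out of the fitting set — the
practice of training an architecture several times and selecting by
performance, automated.

Metrics: mean IoU averages per-class TP/(TP+FP+FN) over classes present in
truth or prediction (a class absent from both is excluded rather than
counted as 0/0). Boundary errors compare measured positions with the
generator's exact fractional boundaries: MSE (signed mean), MUE (unsigned
mean), AME (max absolute), in pixels and micrometers; invalid measurements
(a class missing from a predicted mask) are excluded pairwise and counted.
MUE >= |MSE| and AME >= MUE hold by construction and are property-tested.

Problem sizes used by the scripted runs: 11 eyes x 200 scans (9 train eyes,
x6 augmentation -> 10,800 training samples; 2 test eyes -> 400 scans), one
validation eye for replicate selection. One replicate trains in about five
minutes on a single core; these sizes are the package's chosen desk-scale
study conditions.

## Tracking (`octrack.tracking`)

The boundary position is read off a segmented mask as the mean of the
bottommost upper-class pixel and the topmost lower-class pixel — applied
literally even when a noisy mask interleaves the classes, and returning an
invalid (NaN) measurement when either class is absent. Velocity comes from
the circular cross-correlation shift between consecutive (block-averaged)
A-scans minus the motor step commanded in between, divided by the control
period.

The Kalman filter uses the constant-velocity model F = [[1, dt], [0, 1]],
control input B = [1, 0]^T, full-state observation H = I, white-acceleration
process noise Q = G G^T σ_a² with G = [dt²/2, dt]^T, and diagonal R. The
gain is the standard K = P Hᵀ (H P Hᵀ + R)⁻¹ (an extra additive P term that
sometimes appears in print is dimensionally inconsistent and is not
implemented). A missing position measurement corrects with the velocity row
of H only, so the position coasts on the model.

Defaults: dt = 3 ms (a 128-spectrum block at 100 kHz plus ~1.5 ms
processing); σ_a = 4000 px/s² (permits ~50 um maneuvers within 100 ms);
R = diag(1 px², (200 px/s)²), set from the stationary-sensor noise floor of
the simulated system; proportional gain c = 0.5 — a loop-shaping choice:
high enough to track 10 Hz tremor at a 333 Hz control rate, low enough to
stay well-damped with a cycle of latency. The filter is shift-equivariant
and never increases covariance at a correction; both are property-tested.

## Closed loop (`octrack.closedloop`)

The motor is an ideal position actuator with a per-cycle step clamp
u_max = v_max · dt (v_max = 12.5 mm/s → 13.9 px at 3 ms) and configurable
integer-cycle latency; piezo stick-slip dynamics are not modeled. The plant
is x_k = x_{k-1} + u_{k-1-delay} + hand motion, with the hand trajectory
entering the phantom as a depth shift and the accumulated motor extension
folded into the next frame's rendering. Before activation the control
output is computed but not applied. The crop window is located once at run
start and then held fixed, so tracked boundaries move within a stationary
window the way they do in an M-scan display.

Three experiment designs: stationary sensor (noise floor of the tracker),
fixed motor (stationary sample, active targeting; steady-state statistics
are also reported from the first cycle the estimate comes within 2 px of the
setpoint, excluding the saturated approach), and free hand (tremor plus
compensation from an activation time onward; per-boundary SD before and
after). The free-hand run can add slow per-cycle thickness drift
(low-pass-filtered noise at the jitter SD) emulating lateral tremor sweeping
the beam across non-uniform retina — this is what makes the untargeted
boundary wander more than the targeted one. Metrics use tracker estimates,
as a real rig must; scoring against generator ground truth is available as
the simulation's privilege. `align_mscan` rolls each column so the tracked
boundary sits on a constant row (integer rolls, edge fill; invalid trace
entries flag their columns and stay unrolled).

## Known limitations

- The phantom's speckle is spatially white; real speckle has axial
  correlation set by the PSF and decorrelates under transverse motion.
- Boundary measurement by the bottommost/topmost rule is deliberately
  brittle to stray pixels (it is the rule under study); the AME statistics
  are dominated by such events, as the error tables' large AME values show.
- The motor model omits hysteresis and slew shaping; latency is a pure
  integer-cycle delay.
- Training determinism holds for a fixed numpy/BLAS build; bit-identical
  losses across different BLAS libraries are not guaranteed.
- Absolute performance numbers from the simulation characterize the phantom
  conditions above, not any tissue or instrument.
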