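# Methods

`gbpct` implements a complete desk-scale emulation of a grating-based
phase-contrast CT (gbPC-CT) denoising study: phantom construction,
phase-stepping acquisition with photon noise, signal retrieval, filtered
back projection of both signal chains, self-supervised denoising
(Noise2Inverse), baseline denoisers, and a quantitative evaluation suite
(PSNR/SSIM/edge-preservation ratios plus noise-power-spectrum analysis).
This note records the model, the parameter choices and their rationale,
the numerical decisions, and what the synthetic setting does and does not
establish about real measurements.

## Forward model

A Talbot–Lau interferometer steps its phase grating over one period; each
detector pixel then sees a sinusoidal *stepping curve*.  The simulator
uses the standard monochromatic, parallel-beam idealisation.  With flux
`F` per pixel per step, fringe visibility `V`, and `n` steps, the
expected counts at step `s` are

    I(s) = F · T · [1 + V · cos(2π s/n + φ)],     s = 0 … n−1

where, for each projection angle:

* `T = exp(−R[μ])` — `R[·]` the parallel-beam line integral (Radon
  transform) of the attenuation map `μ` (units 1/px, so `R[μ]` is
  dimensionless);
* `φ = C · ∂x R[δ]` — the transverse derivative (central finite
  difference along the detector, zero-padded at the edges) of the
  projected refractive-index decrement `δ`, scaled by a single
  dimensionless *phase sensitivity* `C` that stands in for the
  hardware-specific chain (wavelength, inter-grating distance, analyzer
  period).

The reference (flat-field) scan has `T = 1`, `φ = 0`.  Photon noise is
Poisson on the expected counts.  Dark-field (visibility reduction),
detector blur, grating imperfections and beam hardening are not
modelled: the analyses downstream use only transmission and differential
phase.

The simulator validates `|φ| < π` on the noiseless forward model and
rejects recipes that would wrap, since phase unwrapping is out of scope
(experimentally, samples are immersed in a water bath for the same
reason).

### The reference scan's exposure

Flat fields are measured without the sample and are routinely acquired
at high dose; the simulator gives the reference scan a flux multiplier
`reference_exposure_factor` (default 61.55, the 1231/20 ratio of the
reference and low-dose protocols the study conditions mirror), and
retrieval divides the fitted reference mean by it.  Besides realism this
matters structurally: a *noisy shared* reference would correlate the
noise of disjoint angle subsets, violating the independence assumption
on which self-supervised splitting rests.  With the high-dose reference
the measured loss decomposition (below) holds to ~1%.

## Signal retrieval

The per-pixel stepping curve is fitted in closed form by its first
discrete Fourier coefficient — for an equidistantly sampled single
harmonic this *is* the least-squares solution, it is deterministic, and
it is exact at machine precision on noiseless data (the round-trip test
asserts ≤1e−10 relative).  Transmission is the ratio of fitted means,
the differential phase the wrapped difference of fitted phases, with
phases mapped to (−π, π] and the tie at −π mapped to +π.  Degenerate
fits (amplitude below 1e−12 of the mean) and zero-mean reference pixels
are masked rather than propagated.

Patchwise phase retrieval (PPR) pools the step series of a
(2r+1)² neighborhood into one joint fit.  Because all pooled pixels
share (a, b, φ) in the model, summing the series and fitting once is the
exact joint least-squares solution; the implementation uses a uniform
filter (square window, zero-padded borders).  r = 0 reproduces the
per-pixel path bit-for-bit.  Pooling trades resolution for variance:
tests assert both the variance reduction on flat scans and the edge
blurring on a step profile.

At a fixed total photon budget the variance of the retrieved phase is
independent of the number of grating steps (asserted within 10% for
n ∈ {4, 5, 8}); the package's default of five steps therefore does not
tie results to the sampling scheme.  The invariance is a small-noise
statement: at very low flux the phase estimator saturates (and can
wrap), and the test works at a total budget of 5000 photons where the
estimator is in its linear regime.

## Reconstruction

Both chains are filtered back projection over angles uniform in [0, π):
projections are filtered in the Fourier domain on zero-padded axes
(≥2× width) and back-projected with linear interpolation,
pixel-centre coordinates, and weight π/n_angles.

* **Attenuation**: `p = −ln T`, ramp (Ram-Lak) filter.  The ramp is
  built by sampling the band-limited spatial-domain kernel
  (h[0] = 1/4, h[odd n] = −1/(πn)²) and transforming — the classical
  construction that avoids the DC deficiency of naively sampling |f|
  (which loses ~10% of the reconstruction gain at 64 px).
* **Electron density**: the differential phase is integrated during
  reconstruction by an odd Hilbert-type filter with frequency response
  ≈ −i·sgn(f)/(2π), likewise built from its band-limited spatial kernel
  h[odd n] = 1/(π²n).  The output recovers δ with unit gain (the
  noiseless disk reconstructs to 0.1% interior RMSE); δ is proportional
  to electron density, so the tomogram is an electron-density map up to
  a known physical constant.

Because each projection is filtered independently and back projection is
linear, a reconstruction from any angle subset (weight π/n_used) is an
unbiased estimator of the full-angle image, and the mean of K disjoint
subset reconstructions equals the full reconstruction *exactly* (machine
precision; asserted).  This identity, not an approximation, is what
makes sinogram splitting valid.

Correctness is checked two independent ways: against explicit
least-squares inversion of the brute-force system matrix on 16×16
phantoms (≤3% interior RMSE for both filter paths — the derivative
forward model for the Hilbert path), and against an independent FBP
implementation, which agrees bit-for-bit on odd-sized grids where the
centre conventions coincide.

Whole-pixel translation equivariance holds in the interior to about
3e−3 relative (asserted at 5e−3): the projector and back projector
interpolation grids do not commute exactly with translation, so machine
precision is not attainable for this property.

## Noise2Inverse

The projection angles are split into K interleaved subsets
(angle i → subset i mod K), each reconstructed separately.  Training
pairs follow the X:1 strategy: input = mean of K−1 sub-tomograms,
target = the held-out one; inference averages the network output over
all K held-out configurations.  (The 1:X variant is implemented behind
the same interface but off by default.)  For a network `f` frozen with
respect to the data, independence and unbiasedness of the subset noise
give

    E‖f(x_{J^c}) − x_J‖² = E‖f(x_{J^c}) − z_J‖² + E‖z_J − x_J‖²,

i.e. the self-supervised loss is the unknowable ground-truth loss plus a
constant — minimising one minimises the other.  The test suite verifies
this decomposition empirically (100 noise realizations, within 15%;
measured ~1%).

**Network.**  A small residual dilated CNN: six 3×3 convolution layers
of eight channels with dilation cycle (1, 2, 4, 8, 16, 1), leaky-ReLU
activations, and a 1×1 head added to the input (~3.1k parameters).  The
widening-then-closing dilation cycle spans the long-range correlations
of Hilbert-reconstructed noise at 64-px slice size.  The head is
initialised near zero so the network starts near the identity (and a
noiseless input==target task trains to <1e−6 loss), but not exactly
zero — an exactly zero head passes no gradient to the hidden layers on
the first steps.  Forward, backward and the Adam optimiser are written
directly on numpy arrays; at this scale training runs in minutes on one
CPU.  A densely connected mixed-scale prototype gave no better PSNR at
equal budget, so the simpler architecture was kept.

**Training.**  MSE on randomly cropped 32-px patches (6 per pair per
epoch), with the eight square symmetries as seeded augmentation; Adam at
lr 5e−3, linearly decayed to a tenth over the second half of 250 epochs;
global gradient-norm clipping at 1.  All inputs and targets share one
affine normalisation (zero mean, unit variance, computed from the
training inputs).  Training is bit-reproducible for a fixed seed on a
fixed platform.

**Model selection.**  Per the protocol this pipeline emulates, training
runs past the optimum and the model is selected by maximising an IQA
metric (PSNR by default) against a reference image; in the lab that
reference is a high-dose scan, here it is the synthetic ground truth
(`select_epoch`, ties to the earliest epoch).  `train_and_select`
extends the same reference-guided criterion across three sub-seeded
restarts, because a minority of initialisations converges to a poor
optimum that plain training-loss monitoring cannot flag — on these
short slice stacks a low self-supervised loss can reflect memorisation
of the noisy targets rather than denoising, so only the
reference-anchored metric separates good runs from bad ones.  Separate
models are trained per signal type — their noise spectra differ too
much for one model — with split-count defaults K = 4 (attenuation) and
K = 2 (electron density).

## Baselines and adapters

Gaussian blur (per-slice, reflective borders) is the classical
smoothing baseline.  BM3D and statistical iterative reconstruction are
third-party tools reached through `baselines.run_external`; the BM3D
adapter activates only when the optional `bm3d` package is installed
(its noise-σ input estimated from a background ROI via
`estimate_background_sigma`), and no open SIR backend is wired in — the
seam raises an actionable error.  Neither algorithm is reimplemented.

## Image quality assessment

RMSE and PSNR follow the standard definitions with the PSNR peak taken
as the supremum norm of the *reference* image (images are float; no
dtype maximum exists), which makes PSNR reference-anchored and
asymmetric.  SSIM is the canonical local-statistics form — Gaussian
window (σ = 1.5), stabilisers C₁ = (0.01·L)², C₂ = (0.03·L)² with L the
data range (default: the reference's peak-to-peak) — implemented
in-package and verified against a brute-force sliding-window oracle.
Edge preservation uses Canny maps computed with one shared parameter
set (σ = 1.4, hysteresis thresholds 0.1/0.2 as fractions of the
*reference's* maximum gradient magnitude, so both images face identical
absolute thresholds): EPRa = |R∩D|/|R| measures edges retained,
EPRr = |R∩D|/|D| measures the absence of false structures; an edgeless
distorted image yields EPRr = 1 by convention.  Slice stacks aggregate
as mean ± population standard deviation over slices.

## Noise power spectra

Empty-beam scans isolate reconstruction noise.  The NPS estimator:
subtract the ensemble mean, 2D DFT, squared magnitudes, ensemble
average, radial average in 32 bins over (0, 0.5] cycles/px; band
summaries weight bins by annulus area and exclude the DC bin.  Power is
reported in arbitrary units; every claim is a ratio within one run.
The structural results the suite asserts: the electron-density NPS has
a strictly larger low-frequency fraction than the attenuation NPS
(the 1/|k| signature of phase integration versus the |k| ramp);
Gaussian blur removes a much larger share of attenuation noise power
than of electron-density noise power; the trained denoiser reduces both
the low (k<0.1) and high (k>0.3) bands for both signals.

## Study conditions (generator defaults)

| Parameter | Default | Why |
| --- | --- | --- |
| visibility | 0.115 | the measured fringe visibility of the emulated setup |
| grating steps | 5 | the emulated protocol's stepping scheme |
| angles | 200 | ≈2× the Nyquist recommendation ⌈π·64/2⌉ for 64 px — the denoiser's double-sampled acquisition |
| slices | 8 | the denoiser trains across a slice stack (the emulated protocol used 49 slices) |
| flux/step (low dose) | 50 | places the low-dose FBP in the noise-dominated regime with denoising headroom of the order the emulated study reports (several dB); at much higher flux the desk-scale phantom's FBP error is structure-dominated and no denoiser can improve PSNR |
| reference flux factor | 61.55 | the 1231/20 mGy dose ratio of the reference protocol |
| phase sensitivity C | 6 | keeps the noiseless phantom's \|φ\| ≤ ~0.55 rad, well clear of wrapping |
| μ, δ scales | 0.02/px, 0.01 | ~cm-scale soft tissue at the chosen grid: bath line integral ≈ 1.2 (T ≈ 0.3) |

The phantom is a water-bath disk containing elliptical tissue regions of
two contrast classes and thin (2 px) fiber structures as detail probes;
stacks vary the structure placement per slice.  The mean-glandular-dose
helper computes MGD = Σ_E DgN(E)·K(E)·κ (κ = 0.114 R/mGy) from
user-supplied coefficient and kerma tables; no DgN tabulations ship with
the package, and the simulator's only dose notion is the total-photon
proxy n_angles × n_steps × flux.

## What the synthetic setting does not show

The generator emulates Poisson counting statistics, the stepping-curve
signal encoding, and the distinct noise propagation of the two filter
chains — the properties the analyses rest on.  It does not emulate
polychromatic spectra, cone-beam geometry, detector cross-talk, grating
drift, dark-field contrast or anatomical texture.  Passing tests
therefore establish the *internal* correctness of retrieval,
reconstruction, splitting and scoring, and the *directional* findings
(which noise lives where; what each denoiser can and cannot remove; the
preferred split counts) — not the numerical image-quality values any
particular instrument would deliver.  Printed IQA tables from real
measurements are not reproducible here, since the underlying scans are
not public.

## Problem sizes

Default analyses run on one CPU in minutes: 64×64 slices, 8-slice
stacks, 200 angles, 250 training epochs with 3 restarts (roughly three
minutes for the attenuation model and one for the electron-density
model, selection included), 16-realization NPS ensembles.  The
system-matrix oracle runs at 16×16 (a 768×256 matrix), where explicit
least-squares is well-conditioned and fast.
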