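# Methods

This note records the models, conventions and numerical choices behind
`p3nmr`, in the order the data flows through the package.

## Signal model and processing

The time-domain signal (FID) is a superposition of damped complex
exponentials,

    x(t_1..t_n) = sum_j A_j  prod_d  exp(-t_d / tau_dj)
                                     exp(+i (2 pi w_dj t_d + phi_dj)),

sampled at integer evolution times t_d = 0..T_d-1 (the dwell time is the
unit of time, so frequencies are in cycles/dwell with Nyquist band
|w| < 0.5 and relaxation times are in dwell units).  Quadrature detection
in every dimension gives the 2^n hypercomplex components (States
convention), stored as an array of shape (2,)*n + (T_1..T_n).

Processing is the standard chain applied dimension-at-a-time: first time
point halved (DC offset suppression), apodization, zero filling, complex
FT, quadrature split.  The default window is cosine-squared,
cos^2(pi t / 2T); the claim that a non-decaying signal processed this way
spans at most three grid points at half height was verified numerically
(FWHM = 2.0 points at zero fill 2) and is enforced by a test.  The
frequency axis convention, used everywhere: index 0 is -Nyquist and w = 0
maps to index N/2, so a peak at w sits at fractional index N (w + 0.5).

Two analytic constants make amplitude bookkeeping exact rather than
Monte-Carlo estimated, both consequences of the linearity of processing:

* noise gain: unit-SD time-domain noise produces frequency-domain noise
  of SD sqrt(prod_d sum_t w_d(t)^2);
* peak height: a unit-amplitude on-resonance peak processes to height
  prod_d sum_t w_d(t) exp(-t/tau_d) (off-grid peaks lose a few percent to
  scalloping).

Peak amplitudes are therefore specified in units of the frequency-domain
noise SD ("sigma-units"): the generator converts a sigma-unit amplitude
to the time-domain amplitude through these constants, and the simulated
noise is white unit-SD time-domain noise, which is mathematically
identical to the procedure of processing noise separately and normalizing
it in the frequency domain.

## Label masks

A binary mask marks peak maxima: the grid index nearest each peak's
fractional position per dimension; when the position falls 0.25-0.75
between two indices, both neighbours are labeled (so a 2D peak labels 1,
2 or 4 pixels — 2.25 on average).  A dual-label partner outside the grid
is dropped.

## Synthetic world (benchmark defaults)

Parameter ranges emulate 2D 1H-15N / 3D 1H-15N-13C correlation spectra:
256 peaks per spectrum, amplitudes log-uniform over 1:200 sigma-units
(weakest peaks at one sigma), frequencies uniform in +-0.45 cycles/dwell,
relaxation times log-uniform in [8, 128] dwells, phases uniform in +-5
degrees.  The full-size simulator default grid is 128 complex points per
indirect dimension and 512 direct; the benchmark grid used by the tests
and the acceptance script is 32 x 128 complex (indirect x direct),
processed at zero fill 4 to a 128 x 512 probability grid.  This reduction
keeps single-CPU runtimes practical and deliberately reproduces the
~1:100 peak:background pixel ratio of 2D correlation maps (576 labeled
pixels in 65536), the regime in which pixel-wise probability calibration
is meaningful.  3D benchmark spectra use 16 x 16 x 64 complex points with
the peak set assembled from four sign groups (+, +, -, -).

What the generator does **not** emulate: t1-noise streaks, solvent
ridges, baseline roll, J-multiplets, lineshape distortions from pulse
imperfections.  A green test on this world therefore certifies the
machinery (training, calibration, localization against theory), not
robustness to artifacts of real spectrometers.

## Noise families

* Conventional (fully sampled) spectra: Gaussian, generated in the time
  domain and processed like the signal.
* CS-IST-reconstructed NUS baselines: a Cauchy/Gaussian additive
  combination whose weights walk linearly from purely Gaussian at 100%
  sampling to purely Cauchy at and below 5% (the two printed endpoints;
  the linear schedule between them is this package's choice).  The Cauchy
  scale is matched to the Gaussian interquartile range so the robust
  sigma stays stable along the schedule.
* 2D skyline projections of 3D spectra: an equal-weight double Gaussian
  with means separated by 0-5 component SDs.

All normalization uses the robust scale 1.4826 x MAD, since sample SDs
are undefined under Cauchy components.

## NUS and CS-IST

Schedules cover the indirect dimensions, always keep the first increment,
and come in uniform-random and Poisson-gap flavours (sinusoidally
weighted gap lengths per dimension, seed-adjusted to the exact point
count).  Reconstruction operates after Fourier processing of the fully
sampled direct dimension, on the *virtual-echo* assembly of the
echo/antiecho combinations over the doubled indirect grid — for a phased
signal this is a single complex exponential across the whole doubled
grid, hence maximally sparse and absorptive.  Without this symmetrization
the dispersive component makes the spectrum insufficiently sparse and IST
converges to badly wrong amplitudes; with it, a Poisson-gap schedule at
30% sampling recovers an SNR-50 peak to a pixel and a few percent.

The iteration accumulates the soft-thresholded residual spectrum with a
threshold equal to 0.9 x the *current* residual maximum of each
sub-problem, times an envelope decaying linearly to zero (a fixed
initial-max threshold stalls).  Measured increments are re-imposed every
iteration, so the result is exactly data-consistent and the measured-point
residual decreases monotonically.  Iteration count defaults to 200.

Time-domain regeneration inverts the processing chain exactly when the
quadrature components are retained; from absorption-only data it rebuilds
the quadrature components dimension-at-a-time through the causality
(Hilbert) relation — exact up to the imaginary parts of the first time
points, which are invisible in the real spectrum and taken as zero.  The
"zero-fill twice before probability generation" rule is implemented as
regeneration plus reprocessing at doubled zero fill (total factor 4 over
the acquisition grid).

## Network

Per spectral dimension, a 64-point section through the probed point
(probed point at 0-based position 32) is digested by five gated
convolution layers (kernel 2, stride 2, no padding, 10 channels; output =
tanh-branch x logistic-branch), shrinking 64 -> 2 positions = 20
features.  Branches have independent weights.  The concatenated features
pass a gated dense head (20 then 10 units, gated the same way) and one
logistic output unit: 8091 parameters for 3D, 5551 for 2D; a closed-form
count is tested against the built model.

Input scaling: spectra are centered at their median (skyline projections
have a positive baseline), divided by the robust noise sigma, and
compressed with arcsinh, which is linear at the noise level and
logarithmic across the 1:200 dynamic range; without compression the
first-layer gates saturate at strong peaks.  Out-of-grid cross positions
are zero-filled (the baseline value of noise-free regions).

Training minimizes BCE with Adam (learning rate 0.001 at the full 2^16
batch size; the desk-scale benchmark uses batch 4096 — roughly the
original steps-per-epoch — with rate 3e-3 under cosine annealing), early
stopping on the BCE of a 4:1 validation split, output bias initialized at
the base-rate logit.  Training corpora keep *every* labeled pixel — the
scarce class — plus uniformly drawn background pixels up to the corpus
budget; the enriched class mix is then corrected back to the ~1:100
deployment ratio by a constant logit offset (exact for a uniformly
undersampled majority class), which keeps pixel probabilities calibrated
while using ~19x more positive examples than a ratio-preserving corpus.
The 1:100 resampling operation itself (all positives, negatives
subsampled to the ratio) is available and tested; it is the right tool
when the corpus budget is not the binding constraint.

## Staged 3D inference

Direct 3D evaluation is impractical at the true ~1:10^4 class ratio, so:
probability maps are computed for the three orthogonal skyline
projections (models trained on the bimodal projection noise); each 3D
point gets the product of its projected probabilities; points whose
geometric mean (k-th root of the product over k used projections) exceeds
2.5% form the region of interest, evaluated by the 3D model; everything
outside is exactly zero.  A high-sensitivity support spectrum can replace
any skyline projection by index mapping (sizes must match exactly; no
interpolation).  Targeted-acquisition build-up curves run
subsample -> CS-IST -> staged inference -> peak count at a conservative
20% cutoff per sampling fraction.

## Peak picking

Candidates are strict local maxima over the full 3^n - 1 neighbourhood at
or above the cutoff (plateaus yield nothing — determinism), refined per
dimension by the three-point quadratic vertex
delta = (y- - y+) / (2 (y- - 2 y0 + y+)), clipped to (-0.5, 0.5); edge
maxima stay unrefined in the edge dimension.  No merging of nearby maxima
and no minimum separation beyond the local-maximum definition.

## Evaluation statistics

Detection uses vicinity matching with a 2-pixel Euclidean radius (the
printed precision is "one to two spectral points"; the radius is
configurable).  Detectable pixels belong to peaks with sigma-unit
intensity strictly above 2 / sqrt(nus_fraction) — the square-root scaling
reproduces the printed 2/5/9-sigma triple at 100/15/5% sampling, while
the literal 2/fraction form (which would give 13 and 40) is available via
configuration.  Skill scores normalize the Brier score and BCE against
the constant base-rate predictor; reliability curves bin predictions in
tenths and omit empty bins.  The overlap score of a peak sums I_i/(I_0
d^2) over neighbours closer than 16 pixels (Euclidean, post-zero-fill
grid), excluding coincident peaks with a flag.

## Localization limits

The Fisher information of the four-quadrature-channel time-domain model
(channels RR, RI, IR, II; parameters per peak A, tau_x, tau_y, w_x, w_y,
phi_x, phi_y) is assembled from analytic derivatives and verified against
central finite differences.  CRLBs are square roots of the diagonal of
the inverse; frequency bounds are also expressed in pixels of the
standard (zero-fill 2) processed grid — the same unit in which picked
positions from the finer probability grid are reported (divided by 2).
Condition numbers above 1e12 flag the bound as singular (e.g. duplicate
peaks).  Two peaks are classified unresolvable when their Euclidean pixel
separation does not exceed 3 x the reference peak's Euclidean frequency
CRLB from the joint (both peaks free) Fisher matrix.

Bayesian uncertainties sample the same model with priors: half-normal on
amplitude, relaxation times and noise SD (scales 3x truth); normal on
frequencies, centered at truth, SD = 3 pixels of digital resolution;
normal on phases centered at zero with SD 30 degrees (weak prior) or 4
degrees (strong prior, matching the +-5 degree training band).  The
sampler is adaptive random-walk Metropolis — the environment provides no
gradient-based probabilistic framework, and the contract is the
posterior, not the algorithm — with the initial proposal covariance taken
from the Fisher matrix at the truth (log-parameter Jacobian folded in)
plus prior precisions, four chains, and Haario covariance adaptation
during burn-in.  Runs are accepted when the split R-hat of both
frequencies is at most 1.05; positive parameters are sampled on the log
scale with the Jacobian in the prior density.

Single-peak studies evaluate the probability map only inside a window
around the known peak (a pure compute saving: the network's field of
view is unchanged) and pool per-dimension position errors; two-peak
studies integrate the probability over boxes of half-width 16 fine-grid
pixels around the pair.

## Design choices where the source was open

* Table of simulation ranges unavailable: the defaults above, chosen to
  reproduce the printed dynamic range, phase band and class ratio.
* Mixture-weight schedule between the printed endpoints: linear.
* Vicinity radius: 2 pixels (unprinted; "one to two spectral points").
* "Zero-filled twice" before probability generation: factor 2 on top of
  standard zero fill 2.
* Dense-head gating mirrors the convolutional gating (two weight sets per
  hidden layer).
* Support spectra replace (not augment) the corresponding projection.
* No merging of picked maxima closer than a pixel.
* MCMC prior scales for amplitude/relaxation/noise: 3x ground truth.

## Known limitations

* The benchmark world is Gaussian/Cauchy/bimodal-noise synthetic data;
  no claim is made about artifact-rich experimental spectra.
* CS-IST amplitude accuracy degrades for uniform-random schedules (which
  undersample early evolution times); Poisson-gap schedules are the
  default for a reason.
* The desk-scale training corpus (2e5 cross-objectives) is ~80x smaller
  than the full-scale recipe (2^24); the probability maps are correspondingly
  less confident, which shows up directly in the skill scores.
* The Hilbert regeneration assumes phased, absorptive input; residual
  phase errors leak into the regenerated imaginary parts.
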