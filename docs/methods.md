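# Methods

`libseed` reimplements, end to end, a chemometric workflow for deciding the
cultivar of a grape seed from its laser-induced breakdown spectroscopy
(LIBS) emission spectrum: spectral simulation, preprocessing, interval
partial least squares (iPLS) region selection, four supervised classifiers,
and contingency-table comparison of their prediction results.  This note
records the model assumptions, the defaults and why they were chosen, and
what the synthetic data can and cannot establish.

## The synthetic-data generator

No public LIBS spectra of grape seeds exist, so the package ships a
simulator whose defaults encode the study design every downstream stage
assumes:

- **Design.** 3 cultivars x 59 pellets = 177 samples.  Each sample spectrum
  is the arithmetic mean of 16 craters x 5 accumulations = 80 single-shot
  spectra.
- **Wavelength axis.** An Echelle spectrometer disperses with roughly
  constant resolving power R = lambda/Delta-lambda, so channel spacing grows
  in proportion to wavelength.  The axis is therefore a geometric grid
  `lambda_{i+1} = lambda_i (1 + 1/R)` running 230-880 nm.  R is solved
  numerically (once, cached) so that the closed band 380.01-860.04 nm
  contains exactly 13,435 channels — the retained variable count of the
  emulated instrument; the solution is R ≈ 1.645 x 10^4.  Whether the real
  instrument's channels were uniformly spaced is unknown; the choice only
  affects the simulator.
- **Lines.** Each emission line is a Lorentzian of configurable FWHM
  (Lorentzian broadening dominates in atmospheric-pressure LIBS plasmas;
  a Gaussian profile is a config option).  The cultivar signal lives in six
  lines between 402.74 and 426.87 nm — Sr II 407.78 nm, the CN band heads at
  416.70 / 418.07 / 419.65 / 421.51 nm, and Ca I 422.66 nm — via per-cultivar
  intensity multipliers.  Twelve class-independent background lines (Ca II,
  Fe I, Mg I, Na I, H-alpha, N I, K I, O I) populate the rest of the range so
  that region selection has competition to reject.
- **Class-contrast structure.**  The default multipliers make the CN-band
  amplitudes roughly monotone in the cultivar code (0.70 / 1.00 / ~1.25)
  while Ca I decreases (1.25 / 1.00 / 0.80) and Sr II is non-monotone.  This
  matters: the region-selection step regresses the *numeric* class code
  1/2/3 on the spectrum with a linear PLS model, which can only rank a
  region highly if the three class centroids are close to affinely
  independent and roughly ordered along some direction.  A contrast pattern
  whose centroids are collinear but mis-ordered would carry classifier
  signal yet be invisible to PLS1 — a worthwhile failure mode to know about,
  but not the regime the workflow assumes.
- **Noise model.** Additive Gaussian detector noise per shot
  (`noise_sd = 30` counts against peak amplitudes of 800-6000; an optional
  heteroscedastic mode scales the sd with sqrt(intensity)); mean-one
  log-normal amplitude jitter per shot (sigma 0.15, plasma fluctuation) and
  per sample (sigma 0.10 per line plus a global sigma 0.05 pellet-coupling
  factor).  Averaging 80 shots suppresses the shot-level terms by
  1/sqrt(80), so sample-to-sample spread is dominated by the per-sample
  terms — as in replicate-pellet measurements.  The continuum baseline is a
  low-order polynomial that dips near zero around 685 nm, so averaged noise
  produces genuinely negative channels and the clipping stage has real work.
- **Determinism.** One master seed; per-sample generators are spawned from a
  `SeedSequence`, making datasets bit-reproducible.

What the simulator does **not** model: Saha/Boltzmann plasma equilibria,
self-absorption, matrix effects, wavelength drift, detector nonlinearity.
Tests passing on this generator show the *pipeline logic* is right (the
splits, searches, statistics and limits behave as designed); they do not
certify accuracy figures on real instrument data.

## Preprocessing

Order is fixed: trim to the closed band [380.01, 860.04] nm -> clip
negatives to zero -> wavelet denoise -> min-max normalise.

Wavelet denoising uses Daubechies-6 at decomposition level 3 (PyWavelets,
symmetric extension).  The thresholding rule is a package choice: soft
thresholding of all detail levels at the universal threshold
sigma sqrt(2 ln N), sigma estimated per spectrum as MAD(finest
details)/0.6745 — the standard shrinkage recipe that suppresses broadband
noise while leaving resolved peaks nearly intact (an isolated noiseless
peak keeps its height within 5%).

Min-max normalisation `x* = (x - min)/(max - min)` is applied **per
spectrum** by default, so every sample spans [0, 1] exactly; a per-dataset
scope is available.  A degenerate (constant) spectrum is an error.

## PLS1, RMSECV and iPLS

The PLS1 core is NIPALS with mean centring and no variable scaling — the
chemometrics default, and deterministic because the single-response case
needs no inner iteration.  One fit yields the regression vector for every
latent-variable (LV) count up to the maximum, so cross-validation scores
all model orders from one decomposition per fold.  (sklearn's
`PLSRegression(scale=False)` reproduces its predictions to 1e-8; it is used
as an oracle in tests, never as the implementation.)

RMSECV is sqrt(mean squared cross-validated residual) with every sample
predicted exactly once.  The fold scheme is a package choice (the
convention is instrument-lab specific): 10-fold contiguous blocks by
default, venetian blinds and leave-one-out available; assignment is
deterministic.

iPLS: for each k in 10..30 the variable axis is split into k contiguous
index-equidistant intervals (sizes differing by at most one, remainder to
the earliest intervals — 13,435 over k=14 gives nine intervals of 960 then
five of 959).  Splitting is equidistant in *variable index*, not
wavelength: that is what reproduces the 960-variable second subinterval,
and on a constant-R axis equal index counts mean denser nm coverage at the
short-wavelength end.  Each interval gets a local PLS1 model with 1..15 LVs
(capped at the interval width and training-fold rank); the best LV count
minimises RMSECV with ties to fewer LVs; the winning interval minimises
RMSECV across all (k, interval) with ties to the first scanned.  The
full-spectrum model's RMSECV and LV count are reported alongside.  Class
labels enter as the numeric response 1/2/3 (a one-response regression, not
PLS2; this is the coding the workflow prescribes).

Region selection runs on the calibration split only.

## Calibration/prediction split

Within each cultivar's acquisition order, samples 2, 5, 8, ... (every third,
starting at 2) form the prediction set: 39 calibration / 20 prediction per
cultivar, 117/60 overall.  The split is deterministic; nothing downstream
reads prediction labels before evaluation.

## Classifiers

All hyperparameter searches are exhaustive over their stated grids and
scored by 5-fold stratified cross-validated accuracy **on the calibration
set**; ties break toward the first (smallest) grid point.  All randomness
derives from the run seed.

- **SVM** (via sklearn's libsvm binding): RBF kernel, one-vs-one voting,
  C and gamma on the 17 x 17 grid of integer powers of two 2^-8..2^8.  The
  Gram matrix is precomputed per gamma, making the grid cheap at full
  spectral width.
- **RBF network**: exact design — one Gaussian hidden unit centred on each
  calibration sample, activation `exp(-(0.8326 ||x - c|| / spread)^2)` so
  that activation is 0.5 at distance = spread; linear output layer (plus
  bias) solved by least squares onto one-hot targets; class = argmax.
  Spread grid 1..100 step 1.  Duplicate calibration samples (which occur in
  the zero-noise limit) switch the solve to a ridge-regularised normal
  equation (lambda = 1e-8) with a warning.
- **ELM**: random input weights and biases, uniform on [-1, 1] from the
  seeded generator; logistic-sigmoid hidden layer; output weights by
  Moore-Penrose pseudoinverse onto one-hot targets.  Hidden-unit grid
  1..n_calibration; the nested grids share one random projection, so the
  scan is deterministic and cheap.  The design-matrix condition number is
  recorded.
- **CNN**: the fixed architecture conv(32 kernels, size 3) + BN + ReLU ->
  maxpool(2,2) -> conv(16, size 3) + BN (no activation) -> dense 512 + BN +
  ReLU + dropout 0.5 -> dense 32 + BN + ReLU + dropout 0.2 -> dense 3 +
  ReLU -> softmax, trained with Adam at learning rate 1e-5, batch 20
  (last incomplete batch kept), softmax cross-entropy, Xavier-uniform
  init, weight decay 1e-4 on conv/dense weights (the decay coefficient and
  Adam moments are package defaults; batch-norm momentum 0.9, eps 1e-5).
  The pre-softmax ReLU and the activation-free second convolution are kept
  as specified — unusual, but part of the architecture; `final_relu=False`
  is available.  The engine is a small single-precision NumPy
  forward/backward implementation; with a fixed seed and thread count the
  loss curve is bitwise reproducible, and backprop is verified against
  finite differences in the tests.

## Evaluation

Per model and split: 3x3 confusion matrix (rows = true cultivar), per-class
accuracy = diagonal/row sum, overall accuracy = trace/total; accuracies are
reported to one decimal percent.  Pairwise model comparison on the shared
60-sample prediction set builds the 2x2 (correct, incorrect) table; if all
four expected counts are >= 5 the uncorrected Pearson chi-square (df = 1,
closed form `n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))`) is used, otherwise the
two-sided Fisher exact test; p-values are reported to three decimals.  The
Pearson branch applies no continuity correction — the plain asymptotic
statistic is the convention this workflow follows, and the expected-count
dispatch covers the small-cell cases where it would matter.  (McNemar's
paired test would arguably suit paired predictions better; it is out of
scope by design.)

## Problem sizes and profiles

The default pipeline profile is desk-scale: everything runs at the full
study design (177 x 13,435) except the CNN, which trains for 100 epochs
(not 1000) and, on the "full" region, on the wavelength axis decimated to
at most 2048 channels.  `cnn.full_profile: true` restores the 1000-epoch
undecimated recipe.  The test suite additionally uses a coarse axis
(R = 2000, ~1,634 retained channels) and 9 samples per cultivar where only
logic, not scale, is under test.

## Known limitations

- Line amplitudes are phenomenological; no physical units or plasma
  temperature dependence.
- The iPLS response coding (1/2/3) makes region ranking sensitive to how
  class centroids are ordered in feature space (see above); the simulator
  deliberately stays in the benign regime.
- Accuracy tables on *real* grape-seed spectra are not reproducible here:
  no public LIBS spectra of grape seeds exist.  All reported accuracies in
  this package refer to synthetic data.
- The exact-design RBF network stores one unit per calibration sample and
  scales accordingly (O(n^2) design matrix).
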