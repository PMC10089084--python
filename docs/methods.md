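# Methods

This note documents the models, parameters and design choices behind
`nanobarcode`, and what the synthetic experiments do and do not show.

## Barcode scheme

A barcode is a per-dye level tuple over the panel (DiO, DiI, DiD), levels
0/1/2 encoding 0, 1 and 10 µM in the formulation; with *n* levels and *m*
dyes there are *nᵐ − 1* codes (the all-zero particle is unusable). The
canonical id ordering groups codes by which dyes are present — singles
first (panel order, levels ascending, ids 1–6), then dye pairs
(DiO–DiI, DiO–DiD, DiI–DiD; lexicographic levels; ids 7–18), then triples
(19–26). The id ↔ levels table is exported with every dataset
(`barcode_table`) so downstream consumers never depend on the convention
implicitly. Published figures of comparable schemes are ambiguous about
their exact id assignment, so the ordering here is a package convention,
chosen to be fully specified and stable.

Acquisition uses six channels: three *main* channels pairing each dye's
optimal laser with its emission window — α (638 nm / 648–750 nm, DiD),
β (552 / 563–620, DiI), δ (488 / 498–538, DiO) — and three *additional*
channels — γ (552 / 648–750), ε (488 / 563–620), ζ (488 / 648–750) —
capturing cross-excitation, bleed-through and energy transfer. A channel is
valid whenever its emission window lies above the laser line. The ε window
is taken as 563–620 nm, identical to β.

## Optical forward model

Per particle, with encapsulated loads `a_d` (µM-equivalent units):

* **Quenching (ACQ)**: emissive load `m_d = a_d / (1 + a_d / Q_d)` with
  `Q = 50` for every dye, mirroring a bulk titration that saturates around
  50 µM. Linear at low load, saturating to `Q`, strictly monotone.
* **Excitation**: for laser *l*, the excited load of dye *d* is
  `E[d, l] · m_d`. The excitation matrix is diagonal-dominant per dye;
  off-diagonal entries (DiI at 488: 0.25; DiD at 552: 0.12; …) follow the
  shape of typical carbocyanine absorption spectra. They are free
  parameters of the simulator, not measurements of any instrument.
* **FRET**: excitations are reallocated along the spectrally-downhill pairs
  DiO→DiI, DiO→DiD, DiI→DiD, applied sequentially in that order. The
  transferred fraction from donor to acceptor is `m_a / (m_a + K)` with
  `K = 10` load units — a saturating, implementable stand-in for a
  phenomenon that has no tractable mechanistic model in this system. The
  reallocation conserves the per-laser excitation total exactly (asserted
  by a 1000-case fuzz test); transferred excitations emit with the
  *acceptor's* emission row, which is what populates ε and ζ.
* **Emission**: channel signal
  `S_c = G · Σ_d y_d · e_d(laser_c) · W[d, window_c]`, with per-dye quantum
  yields `y = (0.6, 0.55, 0.5)`, emission-window fractions `W` shaped like
  the dyes' emission spectra (DiO has the long red tail), and gain
  `G = 840` photons per unit emissive load. `G` was chosen so that a
  high-level single-dye particle reaches a main-channel peak
  signal-to-noise ratio of ≈ 20 under the camera model below.

## Particle population

Radius is lognormal with mean 50 nm and CV 0.1 (a PDI < 0.1 population).
Encapsulated load scales with particle volume:
`a_d = C_d · (r/r̄)³ · exp(η_d)`, with `η_d ~ N(0, sd²)` an independent
per-dye lognormal encapsulation factor. Zero-level dyes carry exactly zero
load.

`encapsulation_sd = 1.0` is the default and defines the realistic ("hard")
regime. The value is derived from the documented behaviour of the real
system rather than from particle-size statistics alone: the post-quenching
gap between the 1 µM and 10 µM levels is ln(8.5) ≈ 2.1 in log units, and
real single-particle intensity histograms of adjacent levels overlap
markedly, which requires a per-dye log-sd near half that gap. At this value
the 26-class reader lands in the 55–60 % accuracy range with the
multi-layer perceptron among the top families — the same operating regime
reported for the real system — whereas smaller spreads (e.g. 0.25) yield a
nearly separable population (≈ 98 %) that misrepresents the problem. The
"easy" regime used as a contrast in tests sets `radius_cv = 0.02`,
`encapsulation_sd = 0.05`.

## Rendering and camera model

Each particle is rendered per channel as a pixel-integrated symmetric 2-D
Gaussian (error-function quadrature, exact per pixel) whose integral equals
the expected channel signal. The width follows
`FWHM_c = sqrt((0.51 · λ_ex,c / NA)² + d²)` with NA 1.4 and the particle
diameter `d` — 201 nm diffraction-limited at 552 nm, ≈ 225 nm for a 100 nm
particle — and `σ = FWHM / 2.355`; the channel dependence enters through
the excitation wavelength only (confocal approximation; Airy core replaced
by a Gaussian, standard in single-molecule localization practice). Images
are 504 × 504 px at 92.45 nm/px. A uniform background (5 photons/px) is
always added; with noise on, pixel counts are Poisson draws plus Gaussian
read noise (sd 2) plus a 100-count offset, rounded and clipped to 16 bits
(clipping is logged). Particle placement is uniform with a 1 µm minimum
pairwise separation, enforced by dart throwing with bounded retries.

Not modelled: photobleaching, blinking, defocus, chromatic offsets between
channels, scanner distortions.

## Localization

Detection runs a difference-of-Gaussians band-pass (scales σ_psf and
2 σ_psf), takes 3 × 3 local maxima above `k = 5` times a robust noise
estimate (1.4826 × MAD of the filtered image, floored at 0.3 counts — the
quantization noise floor — so noiseless images do not produce spurious
maxima), and merges maxima closer than 3 px into the brighter one. Fitting
is unweighted least squares of a pixel-integrated Gaussian (centre, σ,
integrated intensity, constant background) over a 7 × 7 px window; a fit is
rejected when the solver fails, σ leaves (0.3, 3) × the nominal PSF σ, or
the centre leaves the window. Unweighted least squares tracks the standard
integrated-Gaussian behaviour of single-molecule tools at these SNRs and is
swappable.

The merged reference image is the pixelwise *sum* of the six planes in a
64-bit accumulator — summation (not maximum) keeps the merged intensity
feature linear in the channel signals. Each merged-image localization
becomes one particle; per channel, references claim the nearest unused
channel localization within 120 nm, greedily in reference order with ties
to the lower index. At the enforced 1 µm particle separation greedy
matching equals optimal assignment. Unmatched channel slots carry the
sentinel intensity 0 / sigma 0: the 14-vector stays dense, and a zero is
itself informative for zero-level dyes. Coordinates are in nm with pixel
centres at (i + 0.5) · pixel size; ground-truth labels are attached by
nearest truth particle within the same 120 nm radius.

## Barcode reader

Features are Z-score standardized with training-fold statistics (constant
features map to 0). The comparison roster holds fifteen families — MLP,
LightGBM, random forest, extra trees, SVM (RBF and linear), logistic
regression, k-NN, decision tree, LDA, ridge, Gaussian naive Bayes, QDA,
AdaBoost, and gradient-boosted trees — evaluated with stratified 10-fold
cross-validation at library defaults and sorted on mean accuracy; a family
that fails to fit scores 0 with a logged warning. Stratified folds are used
because the class distribution is deliberately unbalanced and the
train/test split (80/20) is itself stratified.

Tuning is a random search over a small per-family grid (for the MLP:
hidden-layer width doubling and constant vs adaptive learning rate, plus
L2 strength) with the library default always the first candidate, so the
tuned CV accuracy never falls below the untuned one. Per-class precision
uses the convention that a class never predicted has precision 0 — the
backward-elimination argmin needs this. Sensitivity is per-class recall;
macro averages are reported.

## Analysis suite

* **Backward elimination** re-splits, re-compares the roster, re-tunes the
  top family and re-evaluates at every iteration, then drops the class with
  the worst per-class precision (ties: lowest id), down to a single class
  (trivially perfect). The per-iteration top family may change.
* **Y-scrambling** permutes training labels, refits the *untuned* family
  and scores the untouched test set; default 100 repeats.
* **Feature importance** is gain-weighted split importance from a
  tree-ensemble family (LightGBM by default); the ablation and learning
  curves use untuned models so that curve shape is not confounded with
  tuning noise.
* **PCA** mean-centres the 14 features without variance scaling (matching
  the common MATLAB default) and decomposes by SVD; a standardized variant
  sits behind a flag since either convention is defensible.
* **Virtual mixtures** sample equal per-class counts from a held-out pool
  without replacement, strip the labels and return a sealed key for
  scoring.

## Problem sizes

The test suite and `scripts/acceptance.py` run the end-to-end experiments
at 26 classes × 200 particles per class per regime (≈ 21 fields of view),
compare a three-family roster (LightGBM, LDA, k-NN) under 10-fold CV and
tune with budget 5 at 3 folds; backward elimination runs on a
100-per-class subsample with an LDA-only roster, and Y-scrambling uses 10
repeats (the 100-repeat default is retained in the configuration). These
sizes are the package's reproducibility baseline; all of them scale up
through the configuration.

## What the synthetic experiments show — and what they do not

Passing tests show that the pipeline reads back what the forward model
wrote: detection recall ≥ 99 % at SNR 20, fitted intensities matching
expected signals to < 1 % noiselessly, matching identical to a brute-force
oracle, conservation and monotonicity of the photon bookkeeping, and the
qualitative accuracy-vs-classes and chance-level controls. They do not
certify performance on real confocal data: the cross-talk matrices, FRET
constants and quantum yields are plausible free parameters, not calibrated
measurements.

One structural difference from the real system is worth stating plainly.
Here the expected channel signals are a *deterministic* function of the
three emissive loads, so the three main channels form a (generically
invertible) three-equation system and the additional channels mostly add
redundancy and SNR. Consequently the accuracy cost of training on α/β/δ
features alone is small in this simulator (≈ 2–5 points depending on the
family), far below the large drop reported for real data, where the extra
channels carry genuinely independent information about unmodelled
photophysics. Reproducing that effect would require per-particle latent
variability in the dye–dye coupling itself, which the current forward-model
contract (deterministic load → signal map) deliberately excludes.

## Known limitations

* Single 2-D plane, co-registered channels, no drift: the reading step is
  easier than on a real microscope.
* The quench constant acts per dye; cross-dye crowding effects fold into
  the encapsulation spread rather than a joint saturation.
* The MLP family is excluded from the default end-to-end roster purely for
  wall-clock reasons; it is in the 15-family comparison roster and tunable
  like any other family.
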