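# Methods

`chemocal` implements a chemometric workflow for quantifying a binary drug
mixture — paracetamol (PAR) and hyoscine butylbromide (HYO) — together with
four toxic impurities (p-nitrophenol PNP, p-chloroacetanilide PCA, tropic
acid TRO, p-aminophenol PAP) from zero-order UV absorption spectra, without
chromatographic separation.  This note records the models, the synthetic
data generator that stands in for measured spectra, the numerical choices,
and the limits of what the test suite demonstrates.

## Experimental design

Calibration uses a five-level, six-factor, 25-run multilevel design.  Run 1
is the centre point; runs 2–25 are generated from a single length-24 coded
sequence (levels −2…+2), with factor column *k* the cyclic rotation of that
sequence by *k* − 1 positions.  This construction guarantees that each
column contains every level exactly five times, and that the design
regenerates deterministically from one constant (`DESIGN_GENERATOR`).
Coded levels map affinely to concentrations, `conc = center + level · step`
(µg/mL), with per-analyte (center, step): PAR (6, 1), HYO (20, 2),
PNP (3, 1), PCA (0.6, 0.1), TRO (8, 2), PAP (4, 1).  Eight fixed runs
{5, 8, 10, 11, 14, 15, 17, 22} form the default validation set (17/8
split); a seeded random split is available for simulation studies.
Concentrations are stored rounded to 2 decimals, matching how such designs
are pipetted and printed.

One cell of the published version of this design (run 24, PAR) is printed
as 5.00 µg/mL, which would break both the level balance of the PAR column
and the cyclic relation every other column obeys; the package uses the
structurally consistent 4.00 µg/mL.

## Synthetic spectra

Measured pure-component spectra for this system are not publicly tabulated,
so all model exercises run on synthetic data from a bilinear Beer–Lambert
generator: `A = C Sᵀ + E` on the fixed 230.0–266.0 nm grid (0.1 nm, 361
points, path length 1 cm), with `E` iid Normal(0, σ²), homoscedastic.  The
default noise level is σ = 0.002 absorbance, a typical photometric
repeatability figure for a benchtop UV instrument; it is a free simulation
parameter.

Each default pure spectrum is a sum of two Gaussian bands: a strong band in
a shared 243–246 nm absorption region (σ ≈ 4 nm, ≈ 9 nm FWHM) and a
narrower analyte-specific secondary band near one edge of the window.  The
shared band makes all six spectra heavily overlapping — the minimum
pairwise congruence coefficient (uncentered cosine, the standard spectral
similarity measure in curve resolution) is 0.69 — which is the regime that
motivates multivariate calibration in the first place.  The secondary bands
play the role that shoulders and secondary maxima play in real spectra:
they make the six components mutually identifiable, give the purest-variable
search distinct channels, and pin the non-negative factorization near the
true profiles.  Band heights are balanced so each analyte contributes
comparable absorbance at its design concentrations and the strongest design
mixture peaks at ≈ 2 absorbance units.

What the generator does **not** emulate: baseline drift, stray light,
wavelength-registration error, heteroscedastic (signal-dependent) noise,
and inter-analyte chemical interactions.  Tests passing on this generator
therefore demonstrate the correctness of the algorithms and the internal
consistency of the pipeline under ideal bilinear conditions — not
instrument-level robustness.

## Direct calibration models

All direct models are inverse calibrations mapping a 361-point spectrum to
six concentrations, with spectra and concentrations mean-centered at fit
time (centering stored with the model).

* **PCR** regresses responses on the scores of the first *h* principal
  components of the centered spectra (SVD, components by decreasing
  singular value).
* **PLS** is NIPALS PLS2 — one joint model for all six responses, matching
  the single 8-LV multiresponse model of classical toolbox practice.  PLS1
  per analyte would also be possible but is not the default.
* **Latent-variable count** is chosen by leave-one-out cross-validation:
  RMSECV(h) pools squared errors over all analytes
  (`sqrt(Σ err² / (n·6))`), per-analyte curves are also reported, and the
  smallest *h* attaining the minimum wins ties.  Candidate counts exceeding
  the rank of a leave-one-out fold (e.g. on noise-free rank-6 data) are
  reported as infeasible rather than failing the whole search.
* **ANN** is the classical 361–6–6 feed-forward topology with linear
  ("purelin") transfer functions in both layers.  The composed map is
  affine, so the training optimum coincides with multiresponse OLS — which
  makes the net a consistency check on the latent-variable models rather
  than a more expressive one.  Training is full-batch gradient descent on
  the MSE from seeded Normal(0, 0.01) weights with backtracking step-size
  control (halve on an ascent step, ×1.2 recovery after success); the
  fixed-rate variant (`adaptive=False`) raises on divergence with advice to
  reduce the rate.  The default 100 epochs mirrors the classical
  Levenberg–Marquardt budget; plain gradient descent needs a few thousand
  epochs to converge to OLS level (seconds of compute), and the
  convergence-level tests train that long.

## MCR-ALS

Curve resolution factorizes `A ≈ C Sᵀ` with non-negativity on both factors,
enforced by fast non-negative least squares (fnnls, the Bro–de Jong
active-set method on the normal-equation cross-products; KKT-checked and
tested against exhaustive active-set enumeration).  The ALS inner loops
solve all columns unconstrained at once and rerun fnnls only on columns
that go negative.

Initialization is SIMPLISMA: purity `p_j = σ_j/(μ_j + α)` with a 5% noise
allowance α, successive selections orthogonalized by the determinant-based
weight from the correlation-around-origin matrix of length-scaled
variables; the concentration directions at the selected purest wavelengths
give the spectral estimate by NNLS.  Initialization from supplied pure
spectra is also available.

After each full ALS iteration the spectral columns are renormalized to unit
Euclidean norm (scale moved into C), resolving the bilinear scale
ambiguity and making lack-of-fit trajectories comparable.  Convergence:
relative change of `lof = 100·sqrt(ΣE²/ΣA²)` below 0.1% (default), an
exact fit, or the iteration cap.  `r2 = 100·(1 − ΣE²/ΣA²)` always obeys
`r2 = 100 − lof²/100`.  A resolved profile collapsing to zero raises a
warning and flags the decomposition.

Quantitation resolves the augmented matrix (calibration + unknown rows
jointly), aligns components to analytes by maximum absolute correlation
between resolved concentration columns and the known calibration
concentrations (ambiguous alignments are an error), fits a per-analyte
straight line resolved-vs-known on the calibration rows, and inverts it
for the unknowns.  This makes the output invariant to the permutation and
positive-scaling ambiguities of the factorization.

Even on noise-free data the non-negative factorization is unique only up to
a small feasible rotation set; with the default library the SIMPLISMA-
initialized solution matches the true spectra to congruence ≥ 0.9997 per
component, and validation recoveries stay within ±1%.  With heavier overlap
(no distinguishing features) the rotation set grows and resolved profiles
degrade — a genuine property of MCR, not an implementation artifact.

## Figures of merit

Per analyte: RMSEC/RMSEP (`sqrt(Σ(pred−truth)²/n)`, no df correction, the
common toolbox convention), per-sample recoveries `100·pred/truth` with
mean and RSD (sample sd, n−1), and the predicted-vs-actual OLS line on the
calibration set (slope S, intercept, Pearson r, residual sd
`s = sqrt(Σresid²/(n−2))`).  Detection limits use LOD = 3.3 (s/S) and
LOQ = 10 (s/S); by construction LOQ/LOD = 10/3.3 ≈ 3.03.  The `s` in these
formulas is the residual standard deviation of the merit line — "standard
deviation of the response" is ambiguous in common usage, and published
tables sometimes print LOQ as exactly 3 × LOD, which is inconsistent with
the formulas themselves; the formulas are what is implemented.

## Method-comparison statistics

Two-sample comparisons are computed from group summaries (mean, SD, n):
pooled equal-variance t (two-tailed; Welch behind a flag — pooled is the
natural partner of the variance-ratio check), F as larger/smaller variance,
and one-way ANOVA both from raw recovery vectors and from printed SS/df
rows (the two routes agree exactly by construction).  Critical values come
from the t and F distributions (scipy), two-tailed for t, upper-tail for F,
at α = 0.05 by default.  The published comparison table for this assay
prints t = 0.44 and F = 3.15 for one method/analyte pair whose own printed
means/SDs give 2.29 and 3.22 — the printed summaries and printed statistics
are mutually inconsistent; this package always computes from the summaries.

A vectorized null simulation (5 groups × 6 replicates, 10⁴ replicates)
verifies the type-I error of the ANOVA at α = 0.05 lands in [0.04, 0.06].

## Greenness scoring

Eco-scale: penalty points are ledger inputs (the hazard-derivation rules
that produce them are upstream of this package); score = 100 − ΣPP, rated
ideal (100), excellent (> 75), acceptable (50–75), inadequate (< 50).
AGREE: twelve principle scores in [0, 1] combined as a weighted arithmetic
mean (equal weights by default; the published 0.76/0.61 scores for this
assay are not reproducible because per-segment inputs were not published,
so no attempt is made to back-solve them).  GAPI: fifteen categorical
green/yellow/red fields, entered by the user; the package counts colors and
compares methods by red count (ties reported as ties).

## Tablet assay

The assay starts from nominal stock concentrations (tablet weighing and
sonication are physical steps outside computational scope): stock
5000.00 µg/mL PAR / 100.00 µg/mL HYO, diluted 2.5 → 100 mL then 1 → 25 mL
to 5.00 / 0.10 µg/mL.  Because 0.10 µg/mL HYO lies far below the calibrated
16–24 µg/mL range, the measured solution is spiked with 16.00 µg/mL HYO
standard; predictions subtract the spike before the label-claim
computation (`100·found/nominal`).  A corrected HYO below −0.05 µg/mL is
flagged as failed spike accounting.  Note the asymmetry this creates: a
small absolute error on the ~16 µg/mL measurement is large relative to the
0.10 µg/mL nominal, so HYO label claims are intrinsically noisier than PAR
claims at the same spectral noise.

## Problem sizes and determinism

The test suite and the acceptance script run the full 25-mixture design at
361 wavelengths — the study's own scale; nothing is scaled down.  All
stochastic steps (noise draws, ANN initialization, null simulations) are
driven by explicit seeds, and the CLI produces byte-identical outputs for
identical seeded inputs.

## Known limitations

* The generator's Gaussian band shapes and homoscedastic noise are idealized;
  none of the instrument artifacts listed above are modeled.
* MCR-ALS correctness-of-rotation depends on the data carrying selective
  information; the package reports congruence diagnostics but cannot make
  an unidentifiable system identifiable.
* The ANN is deliberately affine; nonlinear transfer functions and
  early-stopping on a monitored split are out of scope.
* Greenness scoring computes from user-entered ledgers/profiles; it does
  not derive penalty points or GAPI colors from chemical metadata.
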