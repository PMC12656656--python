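# Methods

## The measurement problem

Pediatric head CT protocols trade radiation dose against the ability to
distinguish gray from white matter, the contrast that drives hemorrhage
detection. The quantities involved are: CTDIvol (mGy), the scanner's
standardized dose output; SD (HU), the pixel standard deviation in a
homogeneous region, used as the image-noise metric; and CNR, the
gray/white (or rod/background) mean difference divided by the reference
region's SD. Scanners modulate tube current under automatic exposure
control (AEC) to hit a user-set target SD in [1, 10]; lower targets demand
more dose. The package's job is to (a) measure SD/CNR with the standard
ROI protocols, (b) model their dose dependence, and (c) solve for
operating thresholds, all testable end to end on synthetic data.

## ROI protocols and metric definitions

Phantom protocol: circular 10 mm-diameter ROIs, one on a low-contrast rod
(M) and one on adjacent homogeneous background (B). Clinical protocol:
square 10×10-pixel ROIs placed in caudate-like gray matter and
internal-capsule-like white matter, several per tissue. The sources these
protocols descend from describe the clinical ROIs as "circular 10 × 10
pixels", which is self-contradictory; we resolve it as square-by-pixels
for clinical and circular-by-mm for phantom ROIs, and record the shape on
every ROI so either can be used in both arms.

Definitions, chosen once and used everywhere:

* SD within an ROI is the sample (n−1) standard deviation — matches
  common CT-QA software, and the brute-force oracle in the tests uses the
  same convention.
* Combined noise is the root sum of squares of the two ROI SDs. With
  equal, independent noise in both ROIs this is √2 times the single-ROI
  SD, which is why an AEC target of 5 corresponds to a combined SD near
  7.07 — the two scales must not be conflated.
* Multiple same-tissue ROIs are pooled by averaging the means and
  combining SDs as the root mean square (preserves noise power), then one
  CNR is computed from the pooled statistics. Pooling first, then one
  CNR, is a design decision; computing per-ROI CNRs and averaging them is
  a different estimator with a different small-sample bias.
* CNR is signed, gray matter (or rod) as minuend; no absolute value.
* Circular-ROI pixel membership is centre-of-pixel inclusion; a 10 mm ROI
  at 0.5 mm spacing encloses 314 ± 4 pixels (π·5²/0.25 = 314.16).

## Dose–quality models

Noise: SD = A·d^(−B), d = CTDIvol. The canonical estimator is ordinary
least squares of ln SD on ln d (A = exp(intercept), B = −slope): it is
deterministic, closed-form, and exact on noiseless data. A nonlinear
least-squares refinement (initialised from the log-space solution) is
available behind a flag and agrees with it to 1e−6 on noiseless data;
the two differ only in how multiplicative vs additive noise is weighted.
Fits with exactly two points return the exact line through them with a
flag instead of standard errors; collinear or zero-spread inputs return
flagged results rather than raising, so batch runs complete.

CNR–noise: ln CNR = a₂·SD² + a₁·SD + a₀, fitted by OLS on (SD², SD, 1),
evaluated only on SD ∈ (0, 20]. The CNR = 2 threshold is the smallest
positive root of a₂·SD² + a₁·SD + (a₀ − ln 2), solved in closed form with
a bracketed brentq fallback for numerically marginal cases; a root at the
SD → 0 boundary is reported as no-solution, since SD = 0 is not an
achievable operating point.

Figure of merit: FOM = A·CNR^B/CTDIvol, with A and B from the noise fit,
implemented literally despite its odd dimensional semantics because that
is the published form; the more common CNR²/dose definition is available
behind `definition="cnr2_per_dose"`, never as default. The FOM dose trend
FOM = a·d^b is fitted log-log, but only when the observed doses span at
least a factor of two — narrower ranges cannot support a power-law claim
and are refused explicitly (this is why one vendor group in the default
run reports a refusal rather than coefficients).

Group summaries use two-sided Student-t 95% CIs on the mean; groups of
one report the mean with an absent CI. No inferential tests are run
anywhere: the analysis is descriptive by design.

## Reference coefficient sets and the column mapping

Two published coefficient sets are embedded as constants:
set 1 = (−0.002, −0.145, 1.43) and set 2 = (0.0061, −0.231, 1.73),
together with the 10-row CNR-vs-SD lookup they generated (columns
"clinical" and "phantom"). Back-substitution shows set 1 reproduces the
*clinical* column and set 2 the *phantom* column — the opposite of how the
equations were labelled in the source. `verify_against_paper` therefore
resolves the mapping empirically (per model, the column with the smaller
maximum relative error) and reports it, rather than asserting either
labelling. Verification tolerance is 1.5% relative (0.5% at SD ∈ {1, 3,
5}); the printed coefficients are rounded, and back-substituting them can
reach ≈1.2% error at SD = 10, so a tighter tolerance would reject correct
arithmetic.

## Synthetic data: what it emulates, and what it does not

Phantom: a 15 cm water-equivalent disc (60 HU background) with cylindrical
rods at 0.3/0.5/1.0% contrast and 2–15 mm diameters on a 50 mm ring, three
contrast groups in 120° sectors. Percent contrast maps to HU at
1% ≡ 10 HU, the conventional low-contrast-module scale (configurable).
Default raster: 512² at 0.5 mm/pixel; tests use 192² at 1 mm for speed.

Brain: an elliptical head (120×150 mm default) with a 6 mm skull ring at
1000 HU, white-matter parenchyma at 30 HU and caudate-like gray-matter
ellipses at 38 HU (validated to lie in the plausible 30–40 HU band). ROI
placement is computed from the known geometry — no segmentation.

Noise: stationary additive Gaussian with SD(d) = √((A·d^(−B))² + f²),
B = 0.5 by default; optional Gaussian-kernel correlation (FWHM in mm,
renormalised to preserve the per-pixel SD) mimics reconstruction texture.
The floor f (default 0) emulates dose-independent electronic/
reconstruction noise; switching it on reproduces the empirically observed
flattening of CNR gains above ~40 mGy, which a pure power law cannot.
AEC inverts the quantum term: d = (A/target)^(1/B).

Multi-facility fixture: eight sites across three vendor groups with
per-site AEC targets (2.5–4.0) and exam counts (19, 15, 9, 7, 16, 6, 5,
13; 90 exams total). Each site's amplitude is back-solved as
A = target·√(nominal dose) so its AEC solution lands at a realistic
pediatric head dose (≈23–42 mGy); per-exam doses scatter lognormally
(σ = 0.18 default) around that solution, standing in for patient-size
driven modulation. These are fixture calibrations chosen to produce
plausible multi-site structure, not estimates of any real scanner.

What the generator does *not* model: projection/reconstruction physics
(no sinograms, beam hardening, or vendor kernels), helical/z-axis
effects, anatomical variability, motion, or inter-observer ROI placement.
Passing tests therefore demonstrate that the measurement and modelling
machinery is correct under the stated noise model — not that real
scanners obey it; the B ∈ [0.4, 0.6] recovery checks are consistency
checks of the pipeline, not physics validation.

## Seeds and determinism

A single integer master seed is required everywhere (no silent default)
and split deterministically per image via `numpy.random.SeedSequence`
spawning, so adding a facility does not reshuffle another facility's
noise. Identical configuration and seed give byte-identical CSV outputs;
this is tested.

## Problem sizes

The default study runs 8 facilities × 5 doses × 3 replicates = 120
phantom images and 90 clinical slices at 512², completing in a few
seconds. The test suite and the acceptance script run the same pipeline
at 192²/1 mm, which leaves every ROI with ≥ 78 pixels and all recovery
tolerances comfortably met. Recovery simulations use 100 replicates of
n = 50 (noise law) and n = 60 (CNR curve) points with multiplicative
lognormal noise σ = 0.05.

## Known limitations

* The 10 mGy protocol dose floor is enforced at acquisition level and
  must be relaxed explicitly (`min_ctdivol=0`) for sub-floor experiments.
* The quadratic-exponential CNR(SD) form is empirical; for the phantom
  arm, where CNR = contrast/SD_B exactly, it is an approximation that
  fits well over SD ∈ (2, 15) but should not be extrapolated.
* Threshold doses solved from a fitted noise curve can land far outside
  the observed dose range (e.g. when a site's AEC keeps SD near 3, the
  dose "at SD = 5" is an extrapolation); such solutions are flagged
  `extrapolated` in the report rather than suppressed.
* Vendor tube-voltage/pitch differences are carried as metadata only;
  their physical effect is absorbed into each site's (A, B).
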