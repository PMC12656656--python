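# ctdoseiq

Quantitative dose–image-quality analysis for pediatric head CT, built for
medical physicists and radiographers who tune scan protocols. The package
measures image noise and contrast-to-noise ratio (CNR) with the standard
ROI protocols, models how both change with radiation dose (CTDIvol), and
solves for the operating point — image noise SD ≈ 5 HU corresponding to
CNR ≈ 2 — that hemorrhage-screening protocols target. Because clinical CT
data are rarely shareable, the package ships a synthetic generator that
emulates both measurement arms of a multicenter study: a Catphan-style
low-contrast phantom module and basal-ganglia-level brain slices acquired
under automatic exposure control (AEC).

## Models

Noise follows a power law in dose (the B = ½ case is the familiar
"noise ∝ 1/√mAs" behaviour):

    SD = A · CTDIvol^(−B)

Phantom metrics use a rod ROI (M) and a background ROI (B); clinical
metrics use gray-matter (GM) and white-matter (WM) ROIs:

    SD  = √(SD_M² + SD_B²)            CNR = (ROI_M − ROI_B) / SD_B
    SD  = √(SD_GM² + SD_WM²)          CNR = (ROI_GM − ROI_WM) / SD_WM

CNR declines with noise along a quadratic-exponential curve, which is
what makes the threshold solvable in closed form:

    CNR = exp(a₂·SD² + a₁·SD + a₀)

Dose efficiency is summarised by a figure of merit using the power-law
coefficients, and its own dose trend by a second power function:

    FOM = A · CNR^B / CTDIvol,        FOM ≈ a · CTDIvol^b

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables under `results/`. Running them in order (all use seed 1):

```
$ python analysis/01_simulate_study.py
simulated 90 examinations across 8 facilities (seed 1)
CTDIvol: mean 34.8 mGy (range 16.5-63.9)
CNR: mean 2.70 (range 1.66-3.77)
  facility A: n=19, CTDIvol 23.52 (21.55-25.49) mGy, CT value 34.00 HU
  ...

$ python analysis/02_phantom_dose_ladder.py
120 phantom measurements: 8 facilities x 5 doses x 3 replicates (seed 1)
pooled noise law: SD = A * dose^(-B), A = 26.97, B = 0.499 (R2 log-space 1.0000)

$ python analysis/03_fit_dose_models.py
phantom/Canon: SD = A * dose^(-B), A = 20.21, B = 0.496
...
SD at CNR=2 (clinical): 5.67 HU
SD at CNR=2 (phantom): 6.85 HU
dose at SD=5 (phantom:FUJI): 40.6 mGy

$ python analysis/04_verify_printed_models.py
printed_set_1: matches the 'clinical' column (max rel. error 1.200%)
printed_set_2: matches the 'phantom' column (max rel. error 0.246%)
  printed_set_1 at SD=5: predicted CNR 1.925
  printed_set_2 at SD=5: predicted CNR 2.070
```

Reading the output: the generator's noise exponent is recovered at
B ≈ 0.5 from the images alone; the fitted CNR(SD) curves cross CNR = 2
between SD ≈ 5 and 7; and the two published reference coefficient sets
reproduce their CNR lookup columns to within 1.2%, with solve-backs at
CNR = 2 giving SD = 4.77 and 5.20 — bracketing the SD ≈ 5 operating
point. The same machinery is scriptable through the CLI
(`ctdoseiq simulate|measure|fit|report|verify`), e.g.
`ctdoseiq report --out-dir out --seed 1` writes the full Markdown report
with all intermediate tables.

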