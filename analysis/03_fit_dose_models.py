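#!/usr/bin/env python
"""Fit the dose-image-quality models and solve the operating thresholds.

Reads the measurement tables written by 01/02, fits per-manufacturer
power-law noise models and pooled quadratic-exponential CNR(SD) models,
computes per-manufacturer FOM dose trends, and solves for the dose at
SD = 5 and the SD at CNR = 2. Writes results/fits.json and
results/cnr_lookup.csv.
"""

import json
from pathlib import Path

import pandas as pd

from ctdoseiq.pipeline import PipelineConfig, _cnr_lookup, _fits_to_jsonable, fit_models

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = PipelineConfig(seed=SEED)
    phantom = pd.read_csv(OUT / "phantom_measurements.csv")
    clinical = pd.read_csv(OUT / "clinical_measurements.csv")
    fits, thresholds = fit_models(phantom, clinical, config)

    for arm in ("phantom", "clinical"):
        for manu, d in sorted(fits[arm].items()):
            if manu == "pooled_quadexp":
                continue
            f = d["power_law"]
            print(f"{arm}/{manu}: SD = A * dose^(-B), "
                  f"A = {f.amplitude_a:.2f}, B = {f.exponent_b:.3f}")
        qe = fits[arm].get("pooled_quadexp")
        if qe is not None:
            print(f"{arm} pooled: ln CNR = {qe.a2:.5f} SD^2 {qe.a1:+.4f} SD "
                  f"{qe.a0:+.4f} (n={qe.n_points})")
    for arm, sd in sorted(thresholds["sd_at_target_cnr"].items()):
        if sd is not None:
            print(f"SD at CNR=2 ({arm}): {sd:.2f} HU")
    for key, dose in sorted(thresholds["dose_at_target_sd"].items()):
        if dose is not None:
            note = " [extrapolated]" if thresholds["extrapolated"].get(key) else ""
            print(f"dose at SD=5 ({key}): {dose:.1f} mGy{note}")

    lookup = _cnr_lookup(fits)
    lookup.to_csv(OUT / "cnr_lookup.csv", index=False)
    with open(OUT / "fits.json", "w") as fh:
        json.dump({"fits": _fits_to_jsonable(fits),
                   "thresholds": _fits_to_jsonable(thresholds)},
                  fh, indent=2, sort_keys=True)
    print(f"wrote {OUT / 'fits.json'} and {OUT / 'cnr_lookup.csv'}")


if __name__ == "__main__":
    main()
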