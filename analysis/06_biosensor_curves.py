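#!/usr/bin/env python
"""Biosensor curve reductions: spectrum, dose-response, and thermal melt.

Fits the generated plate-reader-style tables — a two-Gaussian emission
spectrum, a variable-slope logistic cGMP dose-response (reporting EC50),
and a Boltzmann melt (reporting Tm and slope) — and compares each fitted
parameter with the generator's ground truth. Outputs under
results/curves/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from coev import curves

ROOT = Path(__file__).resolve().parent.parent / "results"
INP = ROOT / "inputs"
OUT = ROOT / "curves"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    dfs = pd.read_csv(INP / "spectrum.tsv", sep="\t")
    sfit = curves.fit_spectrum(dfs["wavelength_nm"], dfs["y"], n_components=2)
    print(f"spectrum: components at {sfit.centers[0]:.1f} and "
          f"{sfit.centers[1]:.1f} nm (planted 410, 510), "
          f"residual RMS {sfit.residual_rms:.4f}")

    dfd = pd.read_csv(INP / "dose_response.tsv", sep="\t")
    dfit = curves.fit_dose_response(dfd["concentration_M"], dfd["y"])
    truth = json.loads((INP / "dose_response.truth.json").read_text())
    print(f"dose-response: EC50 {dfit.ec50 * 1e9:.1f} nM "
          f"(planted {10 ** float(truth['log_ec50']) * 1e9:.1f} nM), "
          f"hill {dfit.hill:.2f}, "
          f"log(EC50) {dfit.log_ec50:.3f} +/- {dfit.se['log_ec50']:.3f}")
    if dfit.underdetermined:
        print("  note: no plateau within data; EC50 is a lower bound")

    dfm = pd.read_csv(INP / "melt.tsv", sep="\t")
    mfit = curves.fit_melt(dfm["temperature_C"], dfm["y"])
    print(f"melt: Tm {mfit.tm:.2f} C (planted 65.23), "
          f"slope {mfit.slope:.2f} C (planted -2.64)")

    results = {
        "spectrum": {"centers_nm": sfit.centers, "widths_nm": sfit.widths,
                     "amplitudes": sfit.amplitudes},
        "dose_response": {"ec50_nM": dfit.ec50 * 1e9,
                          "log_ec50": dfit.log_ec50, "hill": dfit.hill,
                          "underdetermined": dfit.underdetermined},
        "melt": {"tm_C": mfit.tm, "slope_C": mfit.slope},
    }
    with open(OUT / "fits.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
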