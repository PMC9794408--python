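#!/usr/bin/env python
"""Rapid-light-curve fitting across the treatment grid.

Simulates the 8-step (0-420 umol photons m^-2 s^-1) RLC for every treatment
cell, computes ETR = Fq'/Fm' x PAR x 0.15 x A per step, fits the
Jassby-Platt tanh model, and tabulates alpha, ETRmax (fitted asymptote and
observed maximum) and Ek = ETRmax/alpha.  Also prints the closed-form
phycobilisome-contamination bound on the apparent Fv/Fm.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from phycoflux.pam import FluorescenceSignals, apparent_fvfm, fit_rlc
from phycoflux.synthetic_data import GroundTruth, simulate_rlc


def main() -> None:
    truth = GroundTruth(seed=1)
    rows = []
    for index, (intensity, spectrum) in enumerate(truth.treatment_grid):
        params = fit_rlc(simulate_rlc(truth, sample=index))
        rows.append(
            {
                "intensity": intensity,
                "spectrum": spectrum,
                "alpha": params.alpha,
                "etr_max": params.etr_max,
                "etr_max_observed": params.etr_max_observed,
                "ek": params.ek,
                "p_value": params.p_value,
            }
        )
    table = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/photoparams.csv", index=False, float_format="%.6g")

    alpha, etr_max = truth.rlc_truth
    print(f"RLC truth: alpha={alpha}, ETRmax={etr_max}, Ek={etr_max / alpha:.1f}")
    print(
        f"fitted over {len(table)} samples: alpha {table['alpha'].median():.3f}, "
        f"ETRmax {table['etr_max'].median():.2f}, Ek {table['ek'].median():.1f}"
    )

    fm, b, c = 4.0, 0.4, 10.0  # bC = Fm regime
    base = apparent_fvfm(FluorescenceSignals(1.0, fm, b, c))
    bumped = apparent_fvfm(FluorescenceSignals(1.0, fm, 1.1 * b, c))
    print(
        "apparent Fv/Fm change for +10% phycobilisome absorption (bC = Fm): "
        f"{100 * (base - bumped) / base:.2f}% (< 5%)"
    )
    print("table written to results/photoparams.csv")


if __name__ == "__main__":
    main()
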