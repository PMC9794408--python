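# phycoflux

Photophysics of red algal phycobilisome light harvesting: global kinetic
analysis of excitation energy transfer (EET) from time-resolved
fluorescence, reflectance-based pigment absorbance, chromophore
quantification, and PAM-derived photosystem parameters — with a
synthetic-data generator that emulates the spectroscopy of a red coralline
alga acclimating to mesophotic light.

## The problem

Red algae such as *Lithothamnion glaciale* thrive at ocean depths where
chlorophyll-*a* alone could not sustain photosynthesis.  Their
phycobilisomes — antenna complexes of phycoerythrin (PE), phycocyanin (PC)
and allophycocyanin (APC), carrying the chromophores phycourobilin (PUB),
phycoerythrobilin (PEB) and phycocyanobilin (PCB) — absorb the mid-visible
light that dominates at depth and funnel the excitation to photosystems I
and II.  Quantifying how fast and how completely that funnel works, and how
its pigment composition shifts with light intensity and spectrum, requires
stitching together several measurement modalities.  This package implements
each computational step as a tested library (`src/phycoflux/`) driven by
narrative analysis scripts (`analysis/`).

## The model

Time-resolved fluorescence surfaces `I(t, λ)` are analysed with a
three-compartment sequential cascade A → B → C.  With transfer times
`τ_AB`, `τ_BC`, natural decays `τ_dA = τ_dB = 1000 ps` (the exciton
lifetime of PE in water) and terminal decay `τ_C` (charge separation), the
total depopulation rates are

    k_A = 1/τ_AB + 1/τ_dA,  k_B = 1/τ_BC + 1/τ_dB,  k_C = 1/τ_C

and the surface is modelled as

    I(t, λ) = Σ_i S_i(λ) · (n_i ⊛ IRF)(t)

where `n_i` are the closed-form Bateman populations, `S_i(λ)` the
compartment-associated emission spectra and the IRF a Gaussian (15 ps
FWHM).  Fitting uses **variable projection**: for trial time constants the
spectra are the exact linear least-squares solution, so only the time
constants are iterated (trust-region least squares, multi-start).

Around the kinetic core:

- **optics** — `D(λ) = log10(1/R(λ))`, baseline-corrected by the mean
  750–800 nm absorbance; band readouts at 680 (chl-*a*), 630 (PC, with a
  0.7 overlap correction), 565 (PE) and 495 nm (PUB).
- **pigments** — Beer–Lambert chromophore quantification,
  `c = A/(ε·l)·M_r`, with native ε of 105,000 (PUB), 136,000 (PEB) and
  102,000 M⁻¹cm⁻¹ (PCB), `M_r` = 587 g/mol.
- **pam** — the contamination model `f0 = F0 + bC`, `fm = Fm + bC`
  (apparent Fv/Fm = `(Fm−F0)/(Fm+bC)`), the absorbed fraction
  `A = 1 − 10^−D`, `ETR = Fq′/Fm′ · PAR · 0.15 · A`, and Jassby–Platt
  rapid-light-curve fits `ETR(E) = ETRmax·tanh(αE/ETRmax)` giving α,
  ETRmax and `Ek = ETRmax/α`.
- **eet** — excitation-spectrum readouts (PSI fluorescence detected at
  720 nm, normalised at 570 nm) giving chromophore EET contributions and
  the PEB:PCB EET ratio `I565/(0.7·I620)`.
- **transfer efficiency** — two first-order channels competing for one
  excited state: `η = (1/τ_transfer)/(1/τ_transfer + 1/τ_decay)`.
- **synthetic_data** — generates every input with known ground truth;
  **workflow** ties the stages into a deterministic, seeded pipeline over
  the 4-intensity × 3-spectrum treatment grid.

## Worked example

```sh
python analysis/02_global_kinetics.py --n-seeds 20 --seed 1
```

prints

```
20 surfaces fitted (100% converged)
  transfer constants: median 50.0 ps (truth 50)
  terminal decay:     median 219.9 ps (truth 220)
  PE-band reduction:  median 29.4% (truth 30%)
  PE band 560-610 nm decays in 110 ps
  light-harvesting efficiency at 120 ps vs 1500 ps: 92.6%
```

Each line is a recovery check: surfaces are simulated with 50 ps transfer
steps, a 220 ps terminal decay and 2% shot-like noise, then refitted from
start values perturbed by ±30%.  The fitted compartment spectra recover the
built-in 30% reduction of the PE band between the A and B compartments; the
560–610 nm band decays with an effective ~110 ps time (the PE → core
transfer time, an order of magnitude faster than the 1500 ps decay of PE in
water), and the competing-rates efficiency at 120 ps is 92.6%.

The other scripts follow the same pattern: `01` writes the synthetic data
set, `03` runs reflectance → absorbance → band readouts and Beer–Lambert
quantification, `04` fits rapid light curves, `05` reads excitation-spectrum
EET contributions, `06` runs the full pipeline and aggregates treatment
means ± SE.  Tables land in `results/`.

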