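# Methods

## Kinetic model

The light-harvesting cascade is a linear three-compartment chain A → B → C
with per-compartment loss.  A delta pulse populates A (`n_A(0) = 1`); the
rates are parameterised by time constants (ps):

- `τ_AB`, `τ_BC` — transfer times between compartments (free, start 60 ps);
- `τ_dA`, `τ_dB` — natural exciton decays of the PE/PC pools (fixed,
  1000 ps, the measured lifetime of PE hexamers in water);
- `τ_C` — terminal decay representing charge separation in the
  photosystems (free, start 250 ps);
- Gaussian IRF, FWHM 15 ps (typical synchroscan streak resolution), centre
  t₀ = 0; both configurable.

Populations are evaluated analytically as mixtures of `t^p e^{−kt}` terms
(Bateman solution).  Near-degenerate rate pairs — the default
configuration has `k_A = k_B` exactly — switch to the analytic
`t·e^{−kt}` (and `t²·e^{−kt}`) limit forms below a relative rate gap of
10⁻⁶, avoiding catastrophic cancellation.  The Gaussian-IRF convolution of
every term is closed-form: the exponentially modified Gaussian for `p = 0`,
computed through `exp(a + log_ndtr(·))` for stability at large `t/σ`, and
its first/second rate derivatives for `p = 1, 2` via the recursions
`g₁ = (t − σ²k)·g₀ + σ·φ(t/σ)` and `g₂ = σ²·g₀ + (t − σ²k)·g₁`.

### Global fit (variable projection)

For trial time constants θ the compartment spectra solve an exact linear
least-squares problem (`numpy.linalg.lstsq`, or bounded non-negative least
squares when `nonneg_amplitudes=True`); the residual as a function of θ
alone is minimised with `scipy.optimize.least_squares` (trust-region
reflective) on log-parameters, which keeps the constants positive without
explicit bounds.  Convergence: `ftol = 1e−10` (relative SSR change) with an
iteration cap of 500 per free parameter.  Five multiplicatively perturbed
starts (uniform ±30%) guard against local minima; the best-SSR run wins.
Amplitudes are unconstrained by default (target-analysis convention);
standard errors come from the Gauss–Newton covariance in log space,
propagated to the constants.  Non-convergence is flagged on the result,
never raised; a surface of rank < 3 in time triggers an identifiability
warning.  `tie_transfer=True` shares one constant between `τ_AB` and
`τ_BC` — the defaults fit them independently, since nothing in the data
model forces them equal.

### Derived summaries

- **Transfer efficiency** `η = (1/τ_t)/(1/τ_t + 1/τ_d)`, the branching
  ratio of two first-order channels.  The competing decay defaults to
  1500 ps (PE in water) while the cascade model fixes its internal natural
  decays at 1000 ps; the two values serve different roles and are both
  overridable.  At τ_t = 120 ps the formula gives 92.6% — reported as
  computed, even where ~94% is quoted for the same constants elsewhere;
  the formula value is the reproducible one.
- **Band decay time** integrates the surface over a wavelength band and
  fits `a·e^{−t/τ}` from the trace maximum onward (unweighted least
  squares).  On a multi-compartment surface this is an *effective* time:
  with the default spectra the 560–610 nm PE band decays in ~110 ps even
  though the elementary steps are 50 ps, because the B and C compartments
  retain residual PE emission.  That emergent ~120 ps is the physically
  meaningful PE → core transfer time; the band readout is deliberately not
  the A-compartment lifetime (47.6 ps), which is only returned when the
  other compartments carry no PE amplitude.

## Synthetic data

The generator produces all inputs with known truth; its defaults are the
study conditions, not tuning knobs.

- **Surfaces** — forward model exactly as fitted (same code path, so the
  zero-noise surface is bitwise identical to `predict_surface`); grid
  −50…500 ps at 2 ps × 550…760 nm at 2 nm.  Noise is zero-mean Gaussian
  with sd `noise_scale·sqrt(max(signal, floor))` — shot-like scaling with a
  variance floor (`floor = 0.01` of the unit peak) so the baseline is not
  noiseless; `noise_scale = 0.02`.  Values may go below zero, as in real
  background-subtracted streak images.
- **Compartment spectra** — Gaussian bands: A, PE at 585 nm (FWHM 40);
  B, the same PE band at 0.7× plus PC 640 (FWHM 30) and chlorophyll 720
  (FWHM 60); C, weak PE (0.2×), PC red-shifted to 655, an APC shoulder at
  675 and strong chlorophyll at 720.  Band positions/widths follow the
  described emission ranges (PE 560–610, PC 620–660, chlorophyll
  680–760 nm); exact widths and relative amplitudes are package choices.
- **Reflectance** — absorbance bands at 440/495/535/565/630/680 nm (peak
  heights 0.50/0.35/0.30/0.45/0.25/0.50, FWHM 20–30 nm) plus a flat 0.2
  non-pigment offset, returned as `R = 10^−D`.
- **RLCs** — eight steps 0…420 µmol photons m⁻²s⁻¹; yields invert the
  Jassby–Platt ETR through `ETR = yield·E·0.15·A` (limit `α/(0.15A)` at
  E = 0), Gaussian noise sd 0.02.  Default truth α = 0.12, ETRmax = 6
  (Ek = 50) with A = 0.9 keeps yields physical; steeper configurations
  (e.g. α = 0.3) imply yields > 1 and generate a warning rather than a
  rejection, because the tanh-fit arithmetic remains well-defined.
- **Excitation spectra** — PUB/PEB/PCB Gaussians at 495/565/620 nm
  (weights 0.8/1.0/0.5) plus a direct-chlorophyll term at 620 nm equal to
  30/70 of the PCB term; normalised to 1 at 570 nm.  The 0.7 readout
  correction exactly undoes the direct-chlorophyll term, so the encoded
  PEB:PCB EET ratio is `w_PEB/w_PCB`.
- **Treatments** — the crossed design (350/80/20/2.5 µmol photons m⁻²s⁻¹ ×
  mesophotic/shallow, plus shallow+red at 350 only).  Replicates within a
  cell differ only through their noise substreams; the generator does not
  model acclimation effects, temporal drift, photobleaching or exciton
  annihilation.  Passing recovery tests therefore demonstrate estimator
  correctness under the assumed noise model, not robustness to the
  systematic structure of real specimens.
- **Seeding** — one master seed; each operation/sample uses
  `SeedSequence((seed, op, sample))`, so outputs are independently
  reproducible.

## Numerical and design choices

- Decadic (base-10) absorbance throughout; off-grid band positions read by
  linear interpolation, with an optional ±window local-maximum (optics) or
  15 nm FWHM Gaussian-weighted (EET) readout.
- The 0.7 chlorophyll/PC overlap split is applied only at the 630 nm
  absorbance readout and the 620 nm excitation readout, mirroring how the
  correction is used in practice.
- Multi-wavelength biliprotein protocols are supported as a runtime
  coefficient table (`linear_combination_concentration`); the shipped
  default is single-wavelength Beer–Lambert, since no specific protocol
  equations are bundled.
- `PhotoParams.etr_max` is the fitted tanh asymptote — required for the
  `Ek = ETRmax/α` identity — with the observed maximum ETR exposed
  separately as `etr_max_observed`.
- The PUB 495 nm contribution estimator is an explicit package choice
  (`r/(1+r)` on the PUB:PEB EET ratio, with a geometric-mean alternative);
  its inputs and estimator name are always reported with the value.
- The workflow report keeps missing stages as explicit nulls and collects
  per-sample errors without aborting the run; aggregation is descriptive
  (mean ± SE) and inferential statistics are deliberately out of scope.

## Problem sizes

Recovery experiments use 50 noise realisations (the analysis driver
defaults to 20 for a quick look) on the full 276 × 106 grid; one
variable-projection fit with five starts takes well under a second, the
50-seed experiment seconds to tens of seconds.  The residual whiteness
check uses 20 single-start fits; the RLC Monte-Carlo uses 200 curves.

## Known limitations

- The chain topology is strictly sequential with per-compartment loss;
  branched routes (e.g. PE → core bypassing PC) are not separately
  parameterised and fold into the effective constants.
- PSI and PSII emission are not separated spectrally, matching the
  measurement the model describes.
- The 1500 ps competing-decay default and the 120 ps PE-band time enter
  the efficiency as point values; no uncertainty propagation is attempted.
- `band_decay_time` fits a single exponential to an intrinsically
  multi-exponential tail; its value depends mildly on the fit window
  (from the maximum onward) and is reported as an effective time.
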