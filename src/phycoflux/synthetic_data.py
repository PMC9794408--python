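"""Synthetic spectroscopy inputs with known ground truth.

Every input the pipeline consumes can be generated here: time-resolved
fluorescence surfaces from the A->B->C cascade with compartment-associated
Gaussian band spectra and shot-like noise, multi-band pigment reflectance
spectra, tanh-shaped rapid light curves, and PSI fluorescence-excitation
spectra.  The defaults encode the study conditions the analysis assumes:
transfer times of 50 ps, natural PE/PC decays of 1000 ps, a 220 ps terminal
decay, a 15 ps FWHM Gaussian IRF, 2% shot-like noise, absorbance bands at
440/495/535/565/630/680 nm, and a 4-intensity x 3-spectrum treatment grid
(350/80/20/2.5 umol photons m^-2 s^-1; mesophotic, shallow, shallow+red —
the red-supplemented spectrum at the highest intensity only).

Seeding contract: one master seed; every operation (and every sample of a
treatment grid) draws from its own deterministic substream, so individual
outputs are reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import CompartmentModel, SpectralAmplitudes, TimeWavelengthSurface, predict_surface
from .optics import SpectrumTable
from .pam import PSII_CHLOROPHYLL_FRACTION, RLCTable, jassby_platt

__all__ = [
    "GaussianBand",
    "GroundTruth",
    "INTENSITY_LEVELS",
    "SPECTRUM_LABELS",
    "default_treatment_grid",
    "gaussian_band",
    "simulate_surface",
    "simulate_reflectance",
    "simulate_rlc",
    "simulate_excitation_spectrum",
]

INTENSITY_LEVELS = (350.0, 80.0, 20.0, 2.5)  # umol photons m^-2 s^-1
SPECTRUM_LABELS = ("mesophotic", "shallow", "shallow+red")

# fixed substream tags per operation (second word of the rng seed sequence)
_OP_SURFACE, _OP_REFLECTANCE, _OP_RLC, _OP_EXCITATION = 1, 2, 3, 4

GaussianBand = tuple[float, float, float]  # (center nm, FWHM nm, peak height)


def default_treatment_grid() -> list[tuple[float, str]]:
    """The experiment's crossed design: shallow+red at 350 umol only."""
    grid = [(i, s) for s in ("mesophotic", "shallow") for i in INTENSITY_LEVELS]
    grid.append((350.0, "shallow+red"))
    return grid


def _default_compartment_bands() -> dict[str, list[GaussianBand]]:
    # A: PE emission 560-610; B: PE reduced by 30% plus PC and chlorophyll;
    # C: weak PE, red-shifted PC at 655, APC shoulder, strong chlorophyll.
    return {
        "A": [(585.0, 40.0, 1.0)],
        "B": [(585.0, 40.0, 0.7), (640.0, 30.0, 0.8), (720.0, 60.0, 0.6)],
        "C": [(585.0, 40.0, 0.2), (655.0, 30.0, 0.6), (675.0, 30.0, 0.4), (720.0, 60.0, 1.0)],
    }


def _default_pigment_bands() -> list[GaussianBand]:
    # chlorophyll Soret 440 / Qy 680, PUB 495, PE 535 + 565, PC 630
    return [
        (440.0, 30.0, 0.50),
        (495.0, 20.0, 0.35),
        (535.0, 20.0, 0.30),
        (565.0, 20.0, 0.45),
        (630.0, 20.0, 0.25),
        (680.0, 25.0, 0.50),
    ]


@dataclass(frozen=True)
class GroundTruth:
    """Complete parameterisation of one synthetic specimen."""

    model: CompartmentModel = field(default_factory=CompartmentModel)
    compartment_bands: dict[str, list[GaussianBand]] = field(
        default_factory=_default_compartment_bands
    )
    noise_scale: float = 0.02  # relative shot-noise factor
    noise_floor: float = 0.01  # variance floor as fraction of unit signal
    seed: int = 0
    pigment_bands: list[GaussianBand] = field(default_factory=_default_pigment_bands)
    pigment_offset: float = 0.2  # flat non-pigment absorbance
    rlc_truth: tuple[float, float] = (0.12, 6.0)  # (alpha, etr_max)
    rlc_absorbed: float = 0.9  # absorbed fraction A used to invert ETR
    rlc_noise_sd: float = 0.02  # Gaussian sd on simulated yields
    excitation_weights: dict[str, float] = field(
        default_factory=lambda: {"pub": 0.8, "peb": 1.0, "pcb": 0.5}
    )
    treatment_grid: list[tuple[float, str]] = field(default_factory=default_treatment_grid)

    def __post_init__(self) -> None:
        if self.noise_scale < 0 or self.noise_floor < 0 or self.rlc_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        for bands in list(self.compartment_bands.values()) + [self.pigment_bands]:
            for center, fwhm, peak in bands:
                if fwhm <= 0:
                    raise ValueError(f"band width must be > 0 (band at {center} nm)")
                if peak < 0:
                    raise ValueError(f"band peak must be >= 0 (band at {center} nm)")
        alpha, etr_max = self.rlc_truth
        if alpha <= 0 or etr_max <= 0:
            raise ValueError("rlc_truth alpha and etr_max must be > 0")
        if not (0 < self.rlc_absorbed <= 1):
            raise ValueError("rlc_absorbed must be in (0, 1]")
        for intensity, label in self.treatment_grid:
            if intensity not in INTENSITY_LEVELS:
                raise ValueError(f"intensity {intensity} not in {INTENSITY_LEVELS}")
            if label not in SPECTRUM_LABELS:
                raise ValueError(f"spectrum label {label!r} not in {SPECTRUM_LABELS}")

    def amplitudes(self, wavelength_grid: np.ndarray) -> SpectralAmplitudes:
        """Compartment-associated spectra evaluated on a wavelength grid."""
        w = np.asarray(wavelength_grid, dtype=float)
        spectra = {
            name: sum((gaussian_band(w, *band) for band in bands), np.zeros_like(w))
            for name, bands in self.compartment_bands.items()
        }
        return SpectralAmplitudes(w, spectra["A"], spectra["B"], spectra["C"])

    def rng(self, op: int, sample: int = 0) -> np.random.Generator:
        """Deterministic substream for one operation (and sample index)."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, op, sample)))

    def peb_pcb_eet_truth(self) -> float:
        """The PEB:PCB EET ratio the excitation generator encodes.

        The direct-chlorophyll term makes the PCB band carry 1/0.7 of the
        PCB weight at 620 nm, which the 0.7 readout correction undoes, so
        the encoded ratio is simply w_peb / w_pcb.
        """
        return self.excitation_weights["peb"] / self.excitation_weights["pcb"]


def gaussian_band(w: np.ndarray, center: float, fwhm: float, peak: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return peak * np.exp(-0.5 * ((np.asarray(w, dtype=float) - center) / sigma) ** 2)


def _check_grid(grid: np.ndarray, name: str) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or np.any(np.diff(g) <= 0):
        raise ValueError(f"{name} grid must be 1-D and strictly increasing")
    return g


def simulate_surface(
    truth: GroundTruth,
    time_grid: np.ndarray,
    wavelength_grid: np.ndarray,
    sample: int = 0,
) -> tuple[TimeWavelengthSurface, TimeWavelengthSurface]:
    """Noisy fluorescence surface plus its noiseless ground-truth surface.

    The clean surface is exactly the kinetics forward model; per-cell noise
    is zero-mean Gaussian with sd ``noise_scale * sqrt(max(signal, floor))``
    (shot-like), so values may dip below zero.  The measurement window is
    expected to cover at least -50..500 ps at <= 2 ps steps and
    550..760 nm; narrower grids only warn.
    """
    t = _check_grid(time_grid, "time")
    w = _check_grid(wavelength_grid, "wavelength")
    if t[0] > -50 or t[-1] < 500 or np.max(np.diff(t)) > 2 + 1e-9:
        warnings.warn("time grid narrower/coarser than the -50..500 ps, 2 ps design", stacklevel=2)
    if w[0] > 550 or w[-1] < 760:
        warnings.warn("wavelength grid does not span 550-760 nm", stacklevel=2)
    clean = predict_surface(truth.model, truth.amplitudes(w), t, w)
    if truth.noise_scale == 0:
        return clean, clean
    rng = truth.rng(_OP_SURFACE, sample)
    sd = truth.noise_scale * np.sqrt(np.maximum(clean.intensity, truth.noise_floor))
    noisy = clean.intensity + rng.normal(0.0, 1.0, clean.intensity.shape) * sd
    return TimeWavelengthSurface(t, w, noisy), clean


def simulate_reflectance(
    truth: GroundTruth, wavelength_grid: np.ndarray, sample: int = 0
) -> SpectrumTable:
    """Reflectance R = 10**(-D) from Gaussian absorbance bands plus offset."""
    w = _check_grid(wavelength_grid, "wavelength")
    if w[0] > 400 or w[-1] < 800:
        warnings.warn("wavelength grid does not span 400-800 nm", stacklevel=2)
    d = truth.pigment_offset + sum(
        (gaussian_band(w, *band) for band in truth.pigment_bands), np.zeros_like(w)
    )
    return SpectrumTable(w, 10.0 ** (-d))


def simulate_rlc(
    truth: GroundTruth,
    steps: np.ndarray | None = None,
    sample: int = 0,
) -> RLCTable:
    """Rapid light curve consistent with the tanh ETR model.

    Yields are the Jassby-Platt ETR inverted through
    ETR = yield * E * 0.15 * A (the E -> 0 limit alpha/(0.15 A) at the dark
    step) with Gaussian noise of sd ``rlc_noise_sd``.
    """
    if steps is None:
        steps = np.arange(0.0, 421.0, 60.0)
    e = np.asarray(steps, dtype=float)
    if np.any(e < 0):
        raise ValueError("irradiance steps must be nonnegative")
    e = np.sort(e)
    alpha, etr_max = truth.rlc_truth
    denom = PSII_CHLOROPHYLL_FRACTION * truth.rlc_absorbed
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(e > 0, jassby_platt(e, alpha, etr_max) / (e * denom), alpha / denom)
    if np.any(y > 1):
        warnings.warn("rlc_truth implies Fq'/Fm' above 1 at low irradiance", stacklevel=2)
    if truth.rlc_noise_sd > 0:
        rng = truth.rng(_OP_RLC, sample)
        y = np.clip(y + rng.normal(0.0, truth.rlc_noise_sd, y.shape), 0.0, None)
    return RLCTable(e, y, absorbed=truth.rlc_absorbed)


def simulate_excitation_spectrum(
    truth: GroundTruth, wavelength_grid: np.ndarray, sample: int = 0
) -> SpectrumTable:
    """PSI-detected excitation spectrum, normalised to 1 at 570 nm.

    Weighted PUB (495 nm), PEB (565 nm) and PCB (620 nm) Gaussian bands plus
    a direct-chlorophyll term at 620 nm equal to 30/70 of the PCB term.
    """
    w = _check_grid(wavelength_grid, "wavelength")
    if w[0] > 450 or w[-1] < 650:
        warnings.warn("wavelength grid does not span 450-650 nm", stacklevel=2)
    wt = truth.excitation_weights
    value = (
        gaussian_band(w, 495.0, 35.0, wt["pub"])
        + gaussian_band(w, 565.0, 40.0, wt["peb"])
        + gaussian_band(w, 620.0, 35.0, wt["pcb"] * (1.0 + 3.0 / 7.0))
    )
    anchor = float(np.interp(570.0, w, value))
    return SpectrumTable(w, value / anchor)
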