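"""Reflectance-derived pigment absorbance.

Surface reflectance spectra R(lambda) of algal thalli are converted to
decadic absorbance D(lambda) = log10(1/R), corrected for non-pigment
attenuation by subtracting the mean absorbance in the pigment-free
750-800 nm window, and read out at the characteristic band positions:
chlorophyll-a 680 nm, phycocyanin (PC) 630 nm, phycoerythrin (PE) 565 nm and
the phycourobilin (PUB) shoulder at 495 nm.  Chlorophyll-a contributes ~30%
of the 590-640 nm absorbance, so the PC readout carries a 0.7 correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumTable",
    "BandReadout",
    "reflectance_to_absorbance",
    "baseline_correct",
    "band_readout",
    "peb_pcb_absorbance_ratio",
]

PC_OVERLAP_FACTOR = 0.7  # PC fraction of the 590-640 nm chlorophyll/PC overlap

BASELINE_WINDOW = (750.0, 800.0)


@dataclass(frozen=True)
class SpectrumTable:
    """A wavelength-indexed series (reflectance, absorbance, excitation...)."""

    wavelength: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if w.ndim != 1 or v.shape != w.shape:
            raise ValueError("wavelength and value must be matching 1-D arrays")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "wavelength", w)
        object.__setattr__(self, "value", v)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelength[0] <= lo and hi <= self.wavelength[-1]

    def at(self, wavelength: float, window: float = 0.0) -> float:
        """Value at a wavelength (linear interpolation off-grid).

        With ``window`` > 0 returns the maximum over ±window/2 nm instead of
        the point value — some band maxima drift a few nm between samples.
        """
        w = self.wavelength
        if wavelength < w[0] or wavelength > w[-1]:
            raise ValueError(f"{wavelength} nm outside coverage [{w[0]}, {w[-1]}] nm")
        if window > 0:
            lo = max(wavelength - window / 2.0, w[0])
            hi = min(wavelength + window / 2.0, w[-1])
            grid = np.unique(np.concatenate([w[(w >= lo) & (w <= hi)], [lo, hi]]))
            return float(np.max(np.interp(grid, w, self.value)))
        return float(np.interp(wavelength, w, self.value))

    def window_mean(self, lo: float, hi: float) -> float:
        mask = (self.wavelength >= lo) & (self.wavelength <= hi)
        if not np.any(mask):
            raise ValueError(f"no points in [{lo}, {hi}] nm")
        return float(np.mean(self.value[mask]))


@dataclass(frozen=True)
class BandReadout:
    """Baseline-corrected absorbance at the pigment band positions."""

    chlorophyll_a: float  # 680 nm
    pc_raw: float  # 630 nm, uncorrected
    pc_corrected: float  # 0.7 x pc_raw
    pe: float  # 565 nm
    pub: float  # 495 nm
    baseline: float  # mean absorbance 750-800 nm before correction


def reflectance_to_absorbance(spectrum: SpectrumTable) -> SpectrumTable:
    """D(lambda) = log10(1 / R(lambda)).

    Reflectance must be positive; values above 1 (white-standard calibration
    overshoot) are permitted with a warning and map to negative absorbance.
    """
    r = spectrum.value
    if np.any(r <= 0):
        bad = spectrum.wavelength[r <= 0]
        raise ValueError(f"nonpositive reflectance at {bad[0]:.1f} nm")
    if np.any(r > 1):
        warnings.warn("reflectance > 1 encountered (calibration overshoot)", stacklevel=2)
    return SpectrumTable(spectrum.wavelength, np.log10(1.0 / r))


def baseline_correct(absorbance: SpectrumTable) -> SpectrumTable:
    """Subtract the mean 750-800 nm absorbance (non-pigment attenuation)."""
    lo, hi = BASELINE_WINDOW
    if not absorbance.covers(lo, hi):
        raise ValueError(f"spectrum must cover the {lo:.0f}-{hi:.0f} nm baseline window")
    offset = absorbance.window_mean(lo, hi)
    return SpectrumTable(absorbance.wavelength, absorbance.value - offset)


def band_readout(absorbance: SpectrumTable, window: float = 0.0) -> BandReadout:
    """Read the pigment band absorbances from a baseline-corrected spectrum.

    ``window`` > 0 switches from point readout (default) to a local maximum
    over a ±window/2 nm span.
    """
    if not absorbance.covers(480.0, 700.0):
        raise ValueError("spectrum must cover 480-700 nm for the band readout")
    baseline = (
        absorbance.window_mean(*BASELINE_WINDOW)
        if absorbance.covers(*BASELINE_WINDOW)
        else float("nan")
    )
    pc_raw = absorbance.at(630.0, window)
    return BandReadout(
        chlorophyll_a=absorbance.at(680.0, window),
        pc_raw=pc_raw,
        pc_corrected=PC_OVERLAP_FACTOR * pc_raw,
        pe=absorbance.at(565.0, window),
        pub=absorbance.at(495.0, window),
        baseline=baseline,
    )


def peb_pcb_absorbance_ratio(readout: BandReadout) -> float:
    """PEB:PCB absorbance ratio: PE at 565 nm over the corrected PC value."""
    if readout.pc_corrected <= 0:
        raise ValueError("PC absorbance is nonpositive; PEB:PCB ratio undefined")
    return readout.pe / readout.pc_corrected
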