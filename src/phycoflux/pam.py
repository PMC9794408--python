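"""PAM fluorometry: contamination model, ETR and rapid light curves.

Blue-light PAM instruments on red algae detect phycobilisome fluorescence
alongside chlorophyll-a.  Where the phycobilisomes absorb a fraction ``b`` of
the excitation light and emit flash-invariant fluorescence ``C``, the
measured signals are f0 = F0 + bC and fm = Fm + bC, so the apparent
dark-adapted quantum yield is (Fm - F0)/(Fm + bC) — an underestimate of the
true Fv/Fm = (Fm - F0)/Fm.

Electron transport rate at each rapid-light-curve (RLC) step is

    ETR = Fq'/Fm' * PAR * 0.15 * A

with 0.15 the fraction of red-algal chlorophyll-a associated with PSII and
A = 1 - 10**(-D) the fraction of light absorbed by photosynthetic pigments
(D the mean 400-700 nm absorbance).  RLCs are fitted with the saturating
exponential-free Jassby-Platt form ETR(E) = ETRmax * tanh(alpha E / ETRmax),
yielding the initial slope alpha, the asymptote ETRmax and the minimum
saturating irradiance Ek = ETRmax / alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluorescenceSignals",
    "RLCTable",
    "PhotoParams",
    "PSII_CHLOROPHYLL_FRACTION",
    "apparent_signals",
    "apparent_fvfm",
    "absorbed_fraction",
    "etr",
    "jassby_platt",
    "fit_rlc",
]

PSII_CHLOROPHYLL_FRACTION = 0.15


@dataclass(frozen=True)
class FluorescenceSignals:
    """True chlorophyll signals plus the phycobilisome contamination terms."""

    f0: float  # minimal chlorophyll fluorescence F0
    fm: float  # maximal chlorophyll fluorescence Fm
    b: float = 0.0  # fraction of excitation light absorbed by phycobilisomes
    c: float = 0.0  # flash-invariant phycobilisome fluorescence C

    def __post_init__(self) -> None:
        if not (self.fm > self.f0 >= 0):
            raise ValueError("require Fm > F0 >= 0")
        if not (0 <= self.b <= 1):
            raise ValueError("b must be in [0, 1]")
        if self.c < 0:
            raise ValueError("C must be >= 0")


@dataclass(frozen=True)
class RLCTable:
    """Rapid-light-curve records: irradiance steps and effective yields."""

    irradiance: np.ndarray  # E, umol photons m^-2 s^-1, nondecreasing
    yield_: np.ndarray  # Fq'/Fm'
    absorbed: float = 1.0  # fraction A of light absorbed, [0, 1]
    psii_fraction: float = PSII_CHLOROPHYLL_FRACTION

    def __post_init__(self) -> None:
        e = np.asarray(self.irradiance, dtype=float)
        y = np.asarray(self.yield_, dtype=float)
        if e.ndim != 1 or y.shape != e.shape:
            raise ValueError("irradiance and yield must be matching 1-D arrays")
        if np.any(e < 0) or np.any(np.diff(e) < 0):
            raise ValueError("irradiance steps must be nonnegative and nondecreasing")
        if np.any(y < 0):
            raise ValueError("yields must be nonnegative")
        if np.any(y > 1):
            warnings.warn("Fq'/Fm' values above 1: unphysical for a quantum yield", stacklevel=2)
        if not (0 <= self.absorbed <= 1):
            raise ValueError("absorbed fraction must be in [0, 1]")
        object.__setattr__(self, "irradiance", e)
        object.__setattr__(self, "yield_", y)

    def etr_values(self) -> np.ndarray:
        return np.array(
            [
                etr(y, e, self.psii_fraction, self.absorbed)
                for e, y in zip(self.irradiance, self.yield_)
            ]
        )


@dataclass
class PhotoParams:
    """Fitted photosystem descriptors from an RLC."""

    alpha: float
    etr_max: float  # fitted tanh asymptote (defines ek)
    ek: float  # etr_max / alpha
    etr_max_observed: float  # largest ETR actually measured
    fvfm_apparent: float | None = None
    ssr: float = float("nan")
    p_value: float = float("nan")
    converged: bool = True
    message: str = ""


def apparent_signals(sig: FluorescenceSignals) -> tuple[float, float]:
    """PAM-measured (f0, fm) = (F0 + bC, Fm + bC)."""
    bc = sig.b * sig.c
    return sig.f0 + bc, sig.fm + bc


def apparent_fvfm(sig: FluorescenceSignals) -> float:
    """Apparent dark-adapted yield (Fm - F0)/(Fm + bC).

    Equals the true Fv/Fm iff bC = 0, otherwise strictly below it; strictly
    decreasing in both b and C.
    """
    return (sig.fm - sig.f0) / (sig.fm + sig.b * sig.c)


def absorbed_fraction(d: float) -> float:
    """A = 1 - 10**(-D), D the mean baseline-corrected 400-700 nm absorbance."""
    if d < 0:
        raise ValueError("mean absorbance D must be >= 0")
    return 1.0 - 10.0 ** (-d)


def etr(
    yield_: float,
    par: float,
    psii_fraction: float = PSII_CHLOROPHYLL_FRACTION,
    absorbed: float = 1.0,
) -> float:
    """Electron transport rate: yield * PAR * psii_fraction * A."""
    if yield_ < 0:
        raise ValueError("yield must be >= 0")
    if yield_ > 1:
        warnings.warn("Fq'/Fm' above 1: unphysical for a quantum yield", stacklevel=2)
    if par < 0:
        raise ValueError("PAR must be >= 0")
    if not (0 <= absorbed <= 1):
        raise ValueError("absorbed fraction must be in [0, 1]")
    return yield_ * par * psii_fraction * absorbed


def jassby_platt(e: np.ndarray, alpha: float, etr_max: float) -> np.ndarray:
    """Saturating RLC response ETR(E) = ETRmax * tanh(alpha E / ETRmax)."""
    return etr_max * np.tanh(alpha * np.asarray(e, dtype=float) / etr_max)


def fit_rlc(table: RLCTable, fvfm_apparent: float | None = None) -> PhotoParams:
    """Fit the Jassby-Platt curve to an RLC and derive alpha, ETRmax, Ek.

    Start values: alpha from the slope over the first two nonzero steps,
    ETRmax from the largest observed ETR.  A flagged (non-raised) result is
    returned when the fit fails to converge or lands on a nonpositive
    parameter.  The fit significance is the F-test p-value of the two
    parameter model against a constant-zero model.
    """
    e = table.irradiance
    nonzero = e > 0
    if np.unique(e[nonzero]).size < 4:
        raise ValueError("need at least 4 distinct nonzero irradiance steps")
    y = table.etr_values()
    etr_obs = float(np.max(y))

    def flagged(msg: str) -> PhotoParams:
        return PhotoParams(
            alpha=float("nan"),
            etr_max=float("nan"),
            ek=float("nan"),
            etr_max_observed=etr_obs,
            fvfm_apparent=fvfm_apparent,
            converged=False,
            message=msg,
        )

    if etr_obs <= 0:
        return flagged("all ETR values are zero; nothing to fit")

    first = np.flatnonzero(nonzero)[:2]
    alpha0 = max(float(np.mean(y[first] / e[first])), 1e-6)
    p0 = [alpha0, etr_obs]
    try:
        popt, _ = optimize.curve_fit(jassby_platt, e, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        return flagged(f"curve fit did not converge: {err}")
    alpha, etr_max = (float(v) for v in popt)
    if alpha <= 0 or etr_max <= 0:
        return flagged("nonpositive parameter estimate")

    resid = y - jassby_platt(e, alpha, etr_max)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum(y**2))
    dof = e.size - 2
    if dof > 0 and ssr > 0 and sst > ssr:
        f_stat = ((sst - ssr) / 2.0) / (ssr / dof)
        p_value = float(stats.f.sf(f_stat, 2, dof))
    else:
        p_value = 0.0 if sst > ssr else float("nan")

    return PhotoParams(
        alpha=alpha,
        etr_max=etr_max,
        ek=etr_max / alpha,
        etr_max_observed=etr_obs,
        fvfm_apparent=fvfm_apparent,
        ssr=ssr,
        p_value=p_value,
        converged=True,
    )
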