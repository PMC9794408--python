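"""Sequential three-compartment excitation-energy-transfer kinetics.

The light-harvesting cascade of red algal phycobilisomes is modelled as three
kinetic compartments A -> B -> C populated by a delta-pulse excitation of A:
A is dominated by phycoerythrin (PE) emission, B carries reduced PE plus
phycocyanin (PC) and chlorophyll-a emission, and C the terminal
PC/allophycocyanin/photosystem emission whose decay represents charge
separation.  Each compartment i has an associated emission spectrum S_i(lambda)
and the measured time-resolved fluorescence surface is

    I(t, lambda) = sum_i S_i(lambda) * (n_i (*) IRF)(t)

with n_i the Bateman populations of the cascade and IRF a Gaussian instrument
response.  Global (target) analysis recovers the transfer/decay time constants
and the compartment-associated spectra from a measured surface by variable
projection: for trial rate constants the spectra solve a linear least-squares
problem, and only the handful of time constants are iterated nonlinearly.

Rates are parameterised by time constants in picoseconds:

    k_A = 1/tau_ab + 1/tau_da      (transfer to B + natural PE decay)
    k_B = 1/tau_bc + 1/tau_db      (transfer to C + natural PC decay)
    k_C = 1/tau_c                  (charge separation in the photosystems)

Populations are closed-form mixtures of ``t**p * exp(-k t)`` terms; the
Gaussian-IRF convolution of every such term also has a closed form
(exponentially modified Gaussian and its rate derivatives), so no numerical
convolution is ever needed in the forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr

__all__ = [
    "CompartmentModel",
    "TimeWavelengthSurface",
    "SpectralAmplitudes",
    "GlobalFitResult",
    "FitFailure",
    "solve_populations",
    "population_terms",
    "convolve_irf",
    "convolved_populations",
    "predict_surface",
    "fit_global",
    "transfer_efficiency",
    "band_decay_time",
]

# relative rate gap below which the analytic degenerate (t*exp) limit is used
_DEGENERATE_RTOL = 1e-6

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class FitFailure(RuntimeError):
    """Raised when a kinetic fit cannot produce a usable estimate."""


@dataclass(frozen=True)
class CompartmentModel:
    """Rate constants (ps) and IRF parameters of the A->B->C cascade.

    ``free`` lists the parameters varied by :func:`fit_global`; the natural
    decays ``tau_da``/``tau_db`` default to 1000 ps fixed (the exciton
    lifetime of PE hexamers in water) and only the two transfer times and the
    terminal decay are fitted.
    """

    tau_ab: float = 50.0
    tau_bc: float = 50.0
    tau_da: float = 1000.0
    tau_db: float = 1000.0
    tau_c: float = 220.0
    irf_fwhm: float = 15.0
    irf_t0: float = 0.0
    free: tuple[str, ...] = ("tau_ab", "tau_bc", "tau_c")

    def __post_init__(self) -> None:
        for name in ("tau_ab", "tau_bc", "tau_da", "tau_db", "tau_c"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive finite time constant, got {value!r}")
        if self.irf_fwhm < 0:
            raise ValueError("irf_fwhm must be >= 0")
        unknown = set(self.free) - {"tau_ab", "tau_bc", "tau_da", "tau_db", "tau_c"}
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")

    @property
    def rates(self) -> tuple[float, float, float]:
        """Total depopulation rates (k_A, k_B, k_C) in 1/ps."""
        return (
            1.0 / self.tau_ab + 1.0 / self.tau_da,
            1.0 / self.tau_bc + 1.0 / self.tau_db,
            1.0 / self.tau_c,
        )


@dataclass(frozen=True)
class TimeWavelengthSurface:
    """Fluorescence intensity on a time (ps) x wavelength (nm) grid."""

    time: np.ndarray
    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        w = np.asarray(self.wavelength, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or w.ndim != 1:
            raise ValueError("time and wavelength must be 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if y.shape != (t.size, w.size):
            raise ValueError(
                f"intensity shape {y.shape} does not match (time, wavelength) = ({t.size}, {w.size})"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity contains non-finite values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "wavelength", w)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class SpectralAmplitudes:
    """Compartment-associated emission spectra S_A, S_B, S_C on one grid."""

    wavelength: np.ndarray
    s_a: np.ndarray
    s_b: np.ndarray
    s_c: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength, dtype=float)
        for name in ("s_a", "s_b", "s_c"):
            s = np.asarray(getattr(self, name), dtype=float)
            if s.shape != w.shape:
                raise ValueError(f"{name} length {s.size} does not match wavelength grid {w.size}")
            object.__setattr__(self, name, s)
        object.__setattr__(self, "wavelength", w)

    def as_matrix(self) -> np.ndarray:
        """(3, n_wavelength) stack in compartment order A, B, C."""
        return np.vstack([self.s_a, self.s_b, self.s_c])

    def band_integral(self, lo: float, hi: float) -> tuple[float, float, float]:
        """Trapezoidal integral of each compartment spectrum over [lo, hi] nm."""
        mask = (self.wavelength >= lo) & (self.wavelength <= hi)
        if mask.sum() < 2:
            raise ValueError(f"band [{lo}, {hi}] nm covers fewer than 2 grid points")
        w = self.wavelength[mask]
        return tuple(float(np.trapezoid(s[mask], w)) for s in (self.s_a, self.s_b, self.s_c))


@dataclass
class GlobalFitResult:
    model: CompartmentModel
    amplitudes: SpectralAmplitudes
    residual: np.ndarray
    ssr: float
    stderr: dict[str, float]
    converged: bool
    n_starts: int = 1
    message: str = ""


# ---------------------------------------------------------------------------
# closed-form populations


def _close(ka: float, kb: float, scale: float) -> bool:
    return abs(ka - kb) < _DEGENERATE_RTOL * scale


def population_terms(model: CompartmentModel) -> list[list[tuple[int, float, float]]]:
    """Exponential-mixture representation of the Bateman populations.

    Returns one term list per compartment; each term ``(p, k, c)`` stands for
    ``c * t**p * exp(-k t)`` (for t >= 0).  Near-degenerate rate pairs switch
    to the analytic ``t * exp`` limit to avoid catastrophic cancellation.
    """
    ka, kb, kc = model.rates
    a1 = 1.0 / model.tau_ab  # A -> B transfer rate
    a2 = 1.0 / model.tau_bc  # B -> C transfer rate
    scale = max(ka, kb, kc)
    c = a1 * a2

    n_a = [(0, ka, 1.0)]

    if _close(ka, kb, scale):
        n_b = [(1, ka, a1)]
        if _close(ka, kc, scale):
            n_c = [(2, ka, c / 2.0)]
        else:
            d = ka - kc
            n_c = [(0, kc, c / d**2), (0, ka, -c / d**2), (1, ka, -c / d)]
    else:
        g = a1 / (kb - ka)
        n_b = [(0, ka, g), (0, kb, -g)]
        if _close(ka, kc, scale):
            n_c = [
                (1, ka, c / (kb - ka)),
                (0, kb, c / (kb - ka) ** 2),
                (0, ka, -c / (kb - ka) ** 2),
            ]
        elif _close(kb, kc, scale):
            n_c = [
                (0, ka, c / ((kb - ka) * (kc - ka))),
                (0, kc, -c / ((kb - ka) * (kc - ka))),
                (1, kb, -c / (kb - ka)),
            ]
        else:
            n_c = [
                (0, ka, c / ((kb - ka) * (kc - ka))),
                (0, kb, c / ((ka - kb) * (kc - kb))),
                (0, kc, c / ((ka - kc) * (kb - kc))),
            ]
    return [n_a, n_b, n_c]


def _eval_terms(terms, t: np.ndarray) -> np.ndarray:
    """Evaluate a term mixture on t (zero for t < 0), no IRF."""
    out = np.zeros_like(t, dtype=float)
    pos = t >= 0
    tp = t[pos]
    for p, k, coeff in terms:
        out[pos] += coeff * tp**p * np.exp(-k * tp)
    return out


def solve_populations(
    model: CompartmentModel, time_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bateman populations n_A, n_B, n_C for n_A(0) = 1 (no IRF)."""
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    terms = population_terms(model)
    return tuple(_eval_terms(tt, t) for tt in terms)


# ---------------------------------------------------------------------------
# Gaussian-IRF convolution (exponentially modified Gaussian, erfc form)


def _emg(t: np.ndarray, k: float, sigma: float, power: int) -> np.ndarray:
    """Closed-form (t**p exp(-k t) theta(t)) (*) Gaussian(0, sigma).

    The p = 0 case is the exponentially modified Gaussian written via
    log(erfc) for numerical stability; p = 1, 2 follow by differentiating
    with respect to the rate.
    """
    if sigma == 0.0:
        g = np.where(t >= 0, np.exp(-k * np.clip(t, 0, None)), 0.0)
        if power == 0:
            return g
        return t**power * g
    # exp(s^2 k^2/2 - k t) * 0.5 erfc((s k - t/s)/sqrt(2)), via log_ndtr:
    # 0.5 erfc(z) = ndtr(-z sqrt(2))
    a = 0.5 * (sigma * k) ** 2 - k * t
    g0 = np.exp(a + log_ndtr(t / sigma - sigma * k))
    if power == 0:
        return g0
    g1 = (t - sigma**2 * k) * g0 + sigma / np.sqrt(2.0 * np.pi) * np.exp(-(t**2) / (2.0 * sigma**2))
    if power == 1:
        return g1
    if power == 2:
        return sigma**2 * g0 + (t - sigma**2 * k) * g1
    raise ValueError(f"unsupported power {power}")


def convolve_irf(
    terms: list[tuple[int, float, float]],
    time_grid: np.ndarray,
    irf_fwhm: float,
    irf_t0: float = 0.0,
) -> np.ndarray:
    """Convolve an exponential-term mixture with a Gaussian IRF.

    ``terms`` is a list of ``(power, rate, coeff)`` triples as produced by
    :func:`population_terms`.  With ``irf_fwhm = 0`` the signal is simply
    shifted to ``irf_t0``.  The convolution preserves the time integral of
    the input.
    """
    if irf_fwhm < 0:
        raise ValueError("irf_fwhm must be >= 0")
    t = np.asarray(time_grid, dtype=float) - irf_t0
    sigma = irf_fwhm * _FWHM_TO_SIGMA
    out = np.zeros_like(t, dtype=float)
    for p, k, coeff in terms:
        out += coeff * _emg(t, k, sigma, p)
    return out


def convolved_populations(model: CompartmentModel, time_grid: np.ndarray) -> np.ndarray:
    """(n_time, 3) matrix of IRF-convolved compartment populations."""
    terms = population_terms(model)
    cols = [convolve_irf(tt, time_grid, model.irf_fwhm, model.irf_t0) for tt in terms]
    return np.column_stack(cols)


def predict_surface(
    model: CompartmentModel,
    amplitudes: SpectralAmplitudes,
    time_grid: np.ndarray,
    wavelength_grid: np.ndarray,
) -> TimeWavelengthSurface:
    """Forward model: I(t, lambda) = sum_i S_i(lambda) (n_i (*) IRF)(t)."""
    t = np.asarray(time_grid, dtype=float)
    w = np.asarray(wavelength_grid, dtype=float)
    if not np.array_equal(w, amplitudes.wavelength):
        raise ValueError("wavelength grid does not match the amplitude spectra")
    pops = convolved_populations(model, t)
    intensity = pops @ amplitudes.as_matrix()
    return TimeWavelengthSurface(t, w, intensity)


# ---------------------------------------------------------------------------
# derived scalar summaries


def transfer_efficiency(tau_transfer: float, tau_decay: float = 1500.0) -> float:
    """Fraction of excitations transferred before natural decay.

    Two first-order channels compete for the same excited state: transfer
    with rate 1/tau_transfer and loss with rate 1/tau_decay, giving
    efficiency (1/tau_transfer) / (1/tau_transfer + 1/tau_decay).  The
    default competing decay is the 1500 ps exciton lifetime of PE in water.
    """
    if not (tau_transfer > 0):
        raise ValueError("tau_transfer must be > 0")
    if np.isinf(tau_decay):
        return 1.0
    if not (tau_decay > 0):
        raise ValueError("tau_decay must be > 0")
    return (1.0 / tau_transfer) / (1.0 / tau_transfer + 1.0 / tau_decay)


def band_decay_time(surface: TimeWavelengthSurface, band: tuple[float, float]) -> float:
    """Effective decay time (ps) of the band-integrated fluorescence tail.

    Integrates the surface over the wavelength band, then fits a single
    exponential (with free amplitude) to the trace from its maximum onward.
    For a multi-compartment surface this is an effective time; on the PE band
    (560-610 nm) it measures the overall PE depopulation rate.
    """
    lo, hi = band
    w = surface.wavelength
    if lo < w[0] or hi > w[-1] or lo >= hi:
        raise ValueError(f"band [{lo}, {hi}] nm outside wavelength grid [{w[0]}, {w[-1]}]")
    mask = (w >= lo) & (w <= hi)
    if mask.sum() < 2:
        raise ValueError("band covers fewer than 2 wavelength points")
    trace = np.trapezoid(surface.intensity[:, mask], w[mask], axis=1)
    i0 = int(np.argmax(trace))
    t = surface.time[i0:]
    y = trace[i0:]
    if t.size < 4:
        raise FitFailure("too few points after the trace maximum for a tail fit")
    if y[-1] >= y[0] or y[0] <= 0:
        raise FitFailure("band trace does not decay after its maximum")
    # crude log-slope start value from the endpoints of the positive tail
    pos = y > 0
    tau0 = (t[pos][-1] - t[pos][0]) / max(np.log(y[pos][0] / y[pos][-1]), 1e-6)
    tau0 = float(np.clip(tau0, 1.0, 1e5))

    def model(tt, amp, tau):
        return amp * np.exp(-(tt - t[0]) / tau)

    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=[y[0], tau0], maxfev=10000)
    except RuntimeError as err:  # pragma: no cover - pathological traces
        raise FitFailure(f"tail fit did not converge: {err}") from err
    tau = float(popt[1])
    if tau <= 0:
        raise FitFailure("tail fit returned a nonpositive decay time")
    return tau


# ---------------------------------------------------------------------------
# global analysis by variable projection


def _solve_amplitudes(pops: np.ndarray, intensity: np.ndarray, nonneg: bool) -> np.ndarray:
    """Linear step: best S (3, n_wl) for fixed populations."""
    if nonneg:
        s = np.empty((pops.shape[1], intensity.shape[1]))
        for j in range(intensity.shape[1]):
            s[:, j], _ = optimize.nnls(pops, intensity[:, j])
        return s
    s, *_ = np.linalg.lstsq(pops, intensity, rcond=None)
    return s


def fit_global(
    surface: TimeWavelengthSurface,
    start: CompartmentModel | None = None,
    *,
    nonneg_amplitudes: bool = False,
    tie_transfer: bool = False,
    n_starts: int = 5,
    start_spread: float = 0.3,
    seed: int | np.random.Generator | None = 0,
    max_iter: int = 500,
) -> GlobalFitResult:
    """Global target analysis of a fluorescence surface by variable projection.

    For trial nonlinear time constants the compartment spectra are the exact
    linear least-squares solution, so only the free time constants (log
    parameterised to stay positive) are iterated with a trust-region
    least-squares solver.  ``n_starts`` runs from multiplicatively perturbed
    start values (uniform within ±``start_spread``) guard against local
    minima; the best-SSR solution is returned.  ``tie_transfer`` constrains
    tau_ab = tau_bc to a single shared constant.

    Non-convergence is reported through ``converged=False``, never raised.
    """
    if start is None:
        start = CompartmentModel(tau_ab=60.0, tau_bc=60.0, tau_c=250.0)
    rng = np.random.default_rng(seed)
    y = surface.intensity
    if np.linalg.matrix_rank(y) < 3:
        warnings.warn(
            "surface has rank < 3 in time: compartments may be unidentifiable", stacklevel=2
        )

    free = [p for p in start.free if not (tie_transfer and p == "tau_bc")]
    if not free:
        raise ValueError("no free parameters to fit")

    def build(theta: np.ndarray) -> CompartmentModel:
        values = dict(zip(free, np.exp(theta)))
        if tie_transfer and "tau_ab" in values:
            values["tau_bc"] = values["tau_ab"]
        return replace(start, **values)

    def residual(theta: np.ndarray) -> np.ndarray:
        pops = convolved_populations(build(theta), surface.time)
        s = _solve_amplitudes(pops, y, nonneg_amplitudes)
        return (y - pops @ s).ravel()

    theta0 = np.log([getattr(start, p) for p in free])
    best = None
    for i in range(max(1, n_starts)):
        if i == 0:
            theta_start = theta0
        else:
            theta_start = theta0 + np.log(1.0 + rng.uniform(-start_spread, start_spread, len(free)))
        try:
            sol = optimize.least_squares(
                residual,
                theta_start,
                method="trf",
                ftol=1e-10,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=max_iter * (len(free) + 1),
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return GlobalFitResult(
            model=start,
            amplitudes=SpectralAmplitudes(
                surface.wavelength,
                np.zeros_like(surface.wavelength),
                np.zeros_like(surface.wavelength),
                np.zeros_like(surface.wavelength),
            ),
            residual=y.copy(),
            ssr=float(np.sum(y**2)),
            stderr={},
            converged=False,
            n_starts=n_starts,
            message="all starts failed",
        )

    model = build(best.x)
    pops = convolved_populations(model, surface.time)
    s = _solve_amplitudes(pops, y, nonneg_amplitudes)
    resid = y - pops @ s
    ssr = float(np.sum(resid**2))

    # standard errors from the Gauss-Newton approximation in log space,
    # propagated back to the time constants
    stderr: dict[str, float] = {}
    dof = resid.size - len(free) - 3 * surface.wavelength.size
    if dof > 0 and best.jac is not None:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (ssr / dof)
            se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
            for name, tau, se in zip(free, np.exp(best.x), se_log):
                stderr[name] = float(tau * se)
                if tie_transfer and name == "tau_ab":
                    stderr["tau_bc"] = stderr["tau_ab"]
        except np.linalg.LinAlgError:
            pass

    return GlobalFitResult(
        model=model,
        amplitudes=SpectralAmplitudes(surface.wavelength, s[0], s[1], s[2]),
        residual=resid,
        ssr=ssr,
        stderr=stderr,
        converged=bool(best.success),
        n_starts=n_starts,
        message=best.message,
    )
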