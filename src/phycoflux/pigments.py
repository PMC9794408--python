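"""Chromophore quantification from extract absorbance.

Phycobilin chromophore concentrations follow single-wavelength Beer-Lambert
with native molar extinction coefficients: A = epsilon * c * l, so
c = A / (epsilon * l) [mol/L], converted to mass with the chromophore molar
mass (587 g/mol for PUB, PEB and PCB alike).  Multi-wavelength biliprotein
protocols that express each pigment as a linear combination of absorbance
readings are supported through a configurable coefficient table.

Composition summaries (percent shares, PE:PC, phycobilisome:chlorophyll)
operate on a :class:`PigmentPanel` of concentrations in consistent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ExtinctionTable",
    "PigmentPanel",
    "bilin_concentration",
    "linear_combination_concentration",
    "composition_percent",
    "pbs_chl_ratio",
    "pe_pc_ratio",
]

CHROMOPHORE_MR = 587.0  # g/mol, PUB, PEB and PCB alike

DEFAULT_EXTINCTION = {  # M^-1 cm^-1, native coefficients
    "PUB": 105_000.0,
    "PEB": 136_000.0,
    "PCB": 102_000.0,
}


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-chromophore molar extinction (M^-1 cm^-1) and molar mass (g/mol)."""

    epsilon: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXTINCTION))
    mr: dict[str, float] = field(
        default_factory=lambda: {k: CHROMOPHORE_MR for k in DEFAULT_EXTINCTION}
    )

    def __post_init__(self) -> None:
        for name, eps in self.epsilon.items():
            if eps <= 0:
                raise ValueError(f"extinction coefficient for {name} must be > 0")
        for name, mr in self.mr.items():
            if mr <= 0:
                raise ValueError(f"molar mass for {name} must be > 0")


@dataclass(frozen=True)
class PigmentPanel:
    """Pigment concentrations (mg/L or mg/g tissue; units tracked)."""

    chlorophyll_a: float = 0.0
    pe: float = 0.0
    pc: float = 0.0
    apc: float = 0.0
    pub: float = 0.0
    peb: float = 0.0
    pcb: float = 0.0
    units: str = "mg/L"

    def __post_init__(self) -> None:
        for name in ("chlorophyll_a", "pe", "pc", "apc", "pub", "peb", "pcb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be >= 0")

    def get(self, name: str) -> float:
        return float(getattr(self, name.lower().replace("-", "_")))

    def per_gram(self, extraction_volume_ml: float, tissue_g: float) -> "PigmentPanel":
        """Convert mg/L in the extract to mg per g of tissue."""
        if self.units != "mg/L":
            raise ValueError(f"expected mg/L panel, got {self.units}")
        if extraction_volume_ml <= 0 or tissue_g <= 0:
            raise ValueError("extraction volume and tissue mass must be > 0")
        f = (extraction_volume_ml / 1000.0) / tissue_g
        return replace(
            self,
            chlorophyll_a=self.chlorophyll_a * f,
            pe=self.pe * f,
            pc=self.pc * f,
            apc=self.apc * f,
            pub=self.pub * f,
            peb=self.peb * f,
            pcb=self.pcb * f,
            units="mg/g",
        )


def bilin_concentration(
    absorbance: float,
    epsilon: float,
    path_cm: float = 1.0,
    mr: float = CHROMOPHORE_MR,
) -> tuple[float, float]:
    """Beer-Lambert chromophore quantification.

    Returns ``(molar, mass)`` concentration: molar in mol/L
    (= absorbance / (epsilon * path)) and mass in g/L (= molar * Mr).
    """
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    if epsilon <= 0 or path_cm <= 0 or mr <= 0:
        raise ValueError("epsilon, path and Mr must be > 0")
    molar = absorbance / (epsilon * path_cm)
    return molar, molar * mr


def linear_combination_concentration(
    absorbances: dict[float, float],
    coefficients: dict[float, float],
    intercept: float = 0.0,
) -> float:
    """Pigment concentration as a linear combination of absorbance readings.

    Spectrophotometric biliprotein protocols express each pigment as
    ``sum_j c_j * A(lambda_j) + intercept``; the coefficient table (keyed by
    wavelength, nm) is supplied by the caller for the protocol in use.
    """
    missing = set(coefficients) - set(absorbances)
    if missing:
        raise ValueError(f"absorbance readings missing for wavelengths {sorted(missing)}")
    value = intercept + sum(c * absorbances[wl] for wl, c in coefficients.items())
    if value < 0:
        raise ValueError("coefficient combination produced a negative concentration")
    return value


def composition_percent(panel: PigmentPanel, members: tuple[str, ...]) -> dict[str, float]:
    """Percent share of each member in the subset total (sums to 100)."""
    values = {m: panel.get(m) for m in members}
    total = sum(values.values())
    if total <= 0:
        raise ValueError("all members are zero; composition undefined")
    return {m: 100.0 * v / total for m, v in values.items()}


def pbs_chl_ratio(panel: PigmentPanel) -> float:
    """Total phycobilisome (PE + PC + APC) over chlorophyll-a concentration."""
    if panel.chlorophyll_a <= 0:
        raise ValueError("chlorophyll-a concentration must be > 0 for PBS:Chl")
    return (panel.pe + panel.pc + panel.apc) / panel.chlorophyll_a


def pe_pc_ratio(panel: PigmentPanel) -> float:
    """Phycoerythrin over phycocyanin bulk concentration."""
    if panel.pc <= 0:
        raise ValueError("PC concentration must be > 0 for PE:PC")
    return panel.pe / panel.pc
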