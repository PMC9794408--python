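"""Delimited-text readers/writers for the pipeline's exchange formats.

Surfaces are CSV matrices with wavelengths (nm) across the first row and
times (ps) down the first column; spectra are two-column ``wavelength_nm,
value`` tables; RLC tables are ``step_umol,yield`` tables with the absorbed
fraction recorded in a comment header; ground truth goes to YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import CompartmentModel, TimeWavelengthSurface
from .optics import SpectrumTable
from .pam import RLCTable
from .synthetic_data import GroundTruth

__all__ = [
    "write_surface",
    "read_surface",
    "write_spectrum",
    "read_spectrum",
    "write_rlc",
    "read_rlc",
    "write_truth",
    "read_truth",
]


def write_surface(path: str | Path, surface: TimeWavelengthSurface) -> None:
    frame = pd.DataFrame(surface.intensity, index=surface.time, columns=surface.wavelength)
    frame.index.name = "time_ps"
    frame.to_csv(path, float_format="%.10g")


def read_surface(path: str | Path) -> TimeWavelengthSurface:
    frame = pd.read_csv(path, index_col=0)
    return TimeWavelengthSurface(
        frame.index.to_numpy(dtype=float),
        np.array([float(c) for c in frame.columns]),
        frame.to_numpy(dtype=float),
    )


def write_spectrum(path: str | Path, spectrum: SpectrumTable) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelength, "value": spectrum.value}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_spectrum(path: str | Path) -> SpectrumTable:
    frame = pd.read_csv(path)
    return SpectrumTable(frame["wavelength_nm"].to_numpy(float), frame["value"].to_numpy(float))


def write_rlc(path: str | Path, table: RLCTable) -> None:
    path = Path(path)
    header = f"# absorbed={table.absorbed:.10g} psii_fraction={table.psii_fraction:.10g}\n"
    body = pd.DataFrame({"step_umol": table.irradiance, "yield": table.yield_}).to_csv(
        index=False, float_format="%.10g"
    )
    path.write_text(header + body)


def read_rlc(path: str | Path) -> RLCTable:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    return RLCTable(
        frame["step_umol"].to_numpy(float),
        frame["yield"].to_numpy(float),
        absorbed=float(meta.get("absorbed", 1.0)),
        psii_fraction=float(meta.get("psii_fraction", 0.15)),
    )


def write_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = asdict(truth)
    payload["model"] = asdict(truth.model)
    payload["model"]["free"] = list(truth.model.free)
    payload["treatment_grid"] = [[i, s] for i, s in truth.treatment_grid]
    Path(path).write_text(yaml.safe_dump(_plain(payload), sort_keys=False))


def read_truth(path: str | Path) -> GroundTruth:
    payload = yaml.safe_load(Path(path).read_text())
    model_kw = payload.pop("model")
    model_kw["free"] = tuple(model_kw["free"])
    payload["compartment_bands"] = {
        k: [tuple(b) for b in v] for k, v in payload["compartment_bands"].items()
    }
    payload["pigment_bands"] = [tuple(b) for b in payload["pigment_bands"]]
    payload["rlc_truth"] = tuple(payload["rlc_truth"])
    payload["treatment_grid"] = [(float(i), s) for i, s in payload["treatment_grid"]]
    return GroundTruth(model=CompartmentModel(**model_kw), **payload)


def _plain(obj):
    """Recursively coerce numpy scalars/arrays and tuples to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
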