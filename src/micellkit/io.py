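"""File formats: enthalpogram CSV, scattering tables, observables, snapshots."""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .itc import EnthalpogramCurve
from .mc.observables import MCObservables
from .mc.state import LatticeState
from .sas import ScatteringCurve

__all__ = [
    "read_enthalpogram", "write_enthalpogram",
    "read_scattering", "write_scattering",
    "observables_frame", "write_xyz_snapshot", "write_json",
]

_TEMP_RE = re.compile(r"(\d{3}(?:\.\d+)?)\s*K", re.IGNORECASE)


def read_enthalpogram(path, temperature: float | None = None) -> EnthalpogramCurve:
    """Read a `concentration_mol_dm3, dH_kJ_mol[, sigma]` CSV/TSV.

    The temperature is taken from a ``temperature_K`` column if present,
    else parsed from the filename (e.g. ``itc_298.15K.csv``), unless given
    explicitly.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if temperature is None:
        if "temperature_K" in df.columns:
            temperature = float(df["temperature_K"].iloc[0])
        else:
            m = _TEMP_RE.search(path.name)
            if not m:
                raise ValueError(f"cannot determine temperature for {path}")
            temperature = float(m.group(1))
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return EnthalpogramCurve(temperature, df["concentration_mol_dm3"].to_numpy(),
                             df["dH_kJ_mol"].to_numpy(), sigma)


def write_enthalpogram(path, curve: EnthalpogramCurve) -> None:
    df = pd.DataFrame({
        "concentration_mol_dm3": curve.concentration,
        "dH_kJ_mol": curve.enthalpy,
        "temperature_K": curve.temperature,
    })
    if curve.sigma is not None:
        df["sigma"] = curve.sigma
    df.to_csv(path, index=False)


def read_scattering(path, units: str | None = None) -> ScatteringCurve:
    """Read a 3-column (Q, I, σ) whitespace or CSV table.

    A ``# units: nm^-1`` (or ``A^-1``) header line declares the Q unit;
    otherwise pass ``units`` explicitly (default nm⁻¹).
    """
    path = Path(path)
    header_units = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.search(r"units?\s*[:=]\s*(\S+)", line)
                if m:
                    header_units = m.group(1)
            else:
                break
    data = np.loadtxt(path, comments="#", delimiter="," if path.suffix == ".csv" else None)
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma,
                           units or header_units or "nm^-1")


def write_scattering(path, curve: ScatteringCurve) -> None:
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    with open(path, "w") as fh:
        fh.write(f"# units: {curve.units}\n# Q I(Q)" + (" sigma" if curve.sigma is not None else "") + "\n")
        np.savetxt(fh, np.column_stack(cols))


def observables_frame(observables: list[MCObservables]) -> pd.DataFrame:
    """Tidy per-temperature observable summary."""
    return pd.DataFrame([{
        "tstar": o.tstar, "phi": o.phi, "n_chains": o.n_chains,
        "E_per_chain": o.e_per_chain, "CV": o.cv,
        "Rg2": o.rg2_mean, "Na": o.na_mean, "phase_label": o.phase_label,
    } for o in observables])


def write_xyz_snapshot(path, state: LatticeState, comment: str = "") -> None:
    """Extended XYZ with species labels A/B and per-atom chain indices."""
    N = state.topology.n_monomers
    letters = {1: "A", 2: "B"}
    with open(path, "w") as fh:
        fh.write(f"{state.pos.size}\n{comment or 'lattice snapshot'}\n")
        for m, s in enumerate(state.pos):
            x, y, z = state.spec.coords(int(s))
            sp = letters[int(state.species[int(s)])]
            fh.write(f"{sp} {x} {y} {z} # chain {m // N}\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return float(obj)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")
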