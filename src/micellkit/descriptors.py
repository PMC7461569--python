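"""Micelle geometric and thermochemical descriptor arithmetic.

Operates on tabulated micelle models of 8-s-8 gemini surfactants
(alkanediyl-α,ω-bis(dimethyloctylammonium) dications): the equal-volume
sphere radius R = (3V/4π)^(1/3), the mass density of an N-mer micelle of
known volume, and the per-CH₂ energy increment of spacer elongation from a
series of single-molecule SCF energies.

Densities follow the dication-mass convention: bromide counterions are
dissociated into the ambient solution and are excluded from the micelle mass
by default (this is the convention under which the reference descriptor
table is internally consistent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASS, AVOGADRO

__all__ = [
    "MolecularFormula",
    "gemini_dication_formula",
    "equal_volume_radius",
    "micelle_density",
    "spacer_energy_increment",
    "check_descriptor_table",
]

_CUBIC_A_PER_CM3 = 1e24  # Å³ per cm³


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts and molar mass of a molecular ion."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    @property
    def molar_mass(self) -> float:
        """g mol⁻¹ from standard atomic masses (electron mass neglected)."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.counts)

    def __str__(self) -> str:
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in self.counts)


def gemini_dication_formula(spacer: int, include_counterions: bool = False) -> MolecularFormula:
    """Formula of the 8-s-8 gemini ion: C_{20+s}H_{46+2s}N₂²⁺.

    Two octyl tails (C8H17), four N-methyls and an s-carbon methylene spacer
    on two quaternary nitrogens.  With ``include_counterions`` the two
    bromides are added (neutral salt)."""
    if spacer < 2:
        raise ValueError("spacer must have at least 2 carbons")
    counts = [("C", 20 + spacer), ("H", 46 + 2 * spacer), ("N", 2)]
    if include_counterions:
        counts.append(("Br", 2))
        return MolecularFormula(tuple(counts), charge=0)
    return MolecularFormula(tuple(counts), charge=2)


def equal_volume_radius(volume: float) -> float:
    """Radius (Å) of the sphere with the same volume (ų) as the micelle."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def micelle_density(n_units: int, formula: MolecularFormula, volume: float) -> float:
    """Mass density (g cm⁻³) of an N-mer micelle of volume V (ų)."""
    if n_units < 1:
        raise ValueError("need at least one building unit")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return n_units * formula.molar_mass / (AVOGADRO * volume / _CUBIC_A_PER_CM3)


def spacer_energy_increment(spacers, energies) -> float:
    """Energy lowering per added spacer CH₂, from an SCF-energy series.

    Least-squares slope of E_SCF versus spacer length, returned as the
    magnitude of the (negative) slope.  Units follow the input energies
    (the reference series is in 10⁻¹⁵ J per molecule).
    """
    s = np.asarray(spacers, dtype=float)
    e = np.asarray(energies, dtype=float)
    if s.size < 2 or np.unique(s).size < 2:
        raise ValueError("need at least two distinct spacer lengths")
    slope = np.polyfit(s, e, 1)[0]
    return float(abs(slope))


def check_descriptor_table(table: pd.DataFrame,
                           radius_tol: float = 0.01,
                           density_tol: float = 1e-3) -> pd.DataFrame:
    """Consistency check of a micelle descriptor table.

    For each row, recomputes the equal-volume radius from V and the density
    from (N, surfactant formula, V) and compares with the tabulated values.
    Expects the column layout of :data:`micellkit.reference.MICELLE_DESCRIPTORS`.
    Returns a frame with recomputed values, absolute deviations and pass flags.
    """
    rows = []
    for _, row in table.iterrows():
        spacer = int(str(row["surfactant"]).split("-")[1])
        formula = gemini_dication_formula(spacer)
        r_calc = equal_volume_radius(row["V_A3"])
        d_calc = micelle_density(int(row["N"]), formula, row["V_A3"])
        rows.append({
            "surfactant": row["surfactant"], "N": int(row["N"]),
            "R_calc_A": r_calc, "R_dev_A": abs(r_calc - row["R_A"]),
            "d_calc": d_calc, "d_dev": abs(d_calc - row["d_g_cm3"]),
            "radius_ok": abs(r_calc - row["R_A"]) <= radius_tol,
            "density_ok": abs(d_calc - row["d_g_cm3"]) <= density_tol,
        })
    return pd.DataFrame(rows)
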