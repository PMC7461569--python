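"""Published reference tables for the 8-s-8 gemini surfactant family.

These are literature input tables consumed by the descriptor and
thermodynamics modules: COSMO-derived micelle descriptors, the calorimetric
micellisation-thermodynamics table for the 8-8-8 surfactant, and the SCF
energies of single molecules versus spacer length.  They are inputs, not
results computed by this package.
"""

from __future__ import annotations

import pandas as pd

# COSMO micelle descriptors.  Seven micelle models under four surfactants;
# the surfactant assignment of each column is inferred (and verified) from
# the density-consistency check in `micellkit.descriptors`.
# Columns: surfactant label, N building units, V / Å^3, A / Å^2,
# R / Å (equal-volume-sphere radius), d / g cm^-3, R_g / Å.
MICELLE_DESCRIPTORS = pd.DataFrame(
    [
        ("8-6-8", 6, 3724.9, 1502.5, 9.62, 1.0666, 7.47),
        ("8-6-8", 9, 5720.9, 2152.9, 11.09, 1.0417, 9.16),
        ("8-7-8", 6, 3860.0, 1559.7, 9.73, 1.0655, 7.71),
        ("8-7-8", 8, 5205.0, 1895.4, 10.75, 1.0535, 8.61),
        ("8-8-8", 8, 5409.8, 2020.2, 10.89, 1.0481, 8.72),
        ("8-9-8", 7, 4807.8, 1807.7, 10.47, 1.0658, 8.20),
        ("8-9-8", 13, 9133.3, 3103.6, 12.97, 1.0419, 10.52),
    ],
    columns=["surfactant", "N", "V_A3", "A_A2", "R_A", "d_g_cm3", "Rg_A"],
)

# Calorimetric micellisation (and, where present, micelle-transformation)
# thermodynamics for aqueous 8-8-8.  `transition` rows describe the second
# (shape-transformation) step of bell-shaped enthalpograms, with C being
# C_trans instead of the c.m.c.
# Columns: T / K, C / mol dm^-3, its quoted uncertainty, ΔG / kJ mol^-1,
# ΔH / kJ mol^-1, TΔS / kJ mol^-1, ΔS / J mol^-1 K^-1, transition flag.
THERMO_8_8_8 = pd.DataFrame(
    [
        (283.15, 0.092, 0.09, -17.12, 5.66, 22.78, 80.45, False),
        (288.15, 0.082, 0.08, -17.57, 5.80, 23.37, 81.12, False),
        (293.15, 0.077, 0.007, -17.90, 4.52, 22.42, 76.45, False),
        (298.15, 0.071, 0.007, -18.27, 3.67, 21.94, 73.58, False),
        (303.15, 0.065, 0.006, -18.64, 3.29, 21.93, 72.33, False),
        (308.15, 0.062, 0.006, -18.90, 2.31, 21.20, 68.80, False),
        (313.15, 0.063, 0.006, -19.02, 1.39, 20.41, 65.17, False),
        (318.15, 0.049, 0.005, -19.83, 1.36, 21.19, 66.60, False),
        (318.15, 0.116, 0.008, -17.40, -2.10, 15.30, 48.09, True),
        (323.15, 0.032, 0.003, -21.15, 0.47, 21.62, 66.91, False),
        (323.15, 0.088, 0.005, -18.29, -2.16, 16.14, 49.95, True),
        (328.15, 0.023, 0.002, -22.22, 0.52, 22.74, 69.29, False),
        (328.15, 0.113, 0.01, -17.67, -2.82, 14.85, 45.25, True),
        (333.15, 0.122, 0.01, -17.56, -3.99, 13.57, 40.73, False),
        (338.15, 0.130, 0.01, -17.46, -4.10, 13.36, 39.52, False),
        (343.15, 0.145, 0.01, -17.24, -4.05, 13.19, 38.44, False),
    ],
    columns=["T_K", "C_mol_dm3", "C_err", "dG_kJ_mol", "dH_kJ_mol",
             "TdS_kJ_mol", "dS_J_mol_K", "transition"],
)

#: SCF energies of single 8-s-8 molecules in implicit water (B3LYP/def2-TZVP),
#: 10⁻¹⁵ J per molecule, versus spacer length s.
SCF_ENERGY_VS_SPACER = pd.DataFrame(
    {"spacer": [6, 7, 8, 9], "E_scf_1e15_J": [-4.95, -5.12, -5.29, -5.46]}
)

#: Chain counts used in the self-assembly simulations at L = 78, N = 26 for
#: volume fractions 0.02 … 0.20 (step 0.02).
REFERENCE_CHAIN_COUNTS = {
    0.02: 182, 0.04: 365, 0.06: 548, 0.08: 730, 0.10: 913,
    0.12: 1095, 0.14: 1278, 0.16: 1460, 0.18: 1643, 0.20: 1825,
}
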