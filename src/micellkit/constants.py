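"""Physical constants and unit conventions used across the package.

All ITC quantities are in kJ mol⁻¹ and mol dm⁻³, temperatures in kelvin,
lattice lengths in units of the lattice constant *a*, scattering vectors in
nm⁻¹ unless declared otherwise.
"""

#: Molar gas constant, J mol⁻¹ K⁻¹ (CODATA 2018, exact).
GAS_CONSTANT = 8.314462618

#: Avogadro constant, mol⁻¹ (SI 2019, exact).
AVOGADRO = 6.02214076e23

#: Molar concentration of pure water at 298.15 K, mol dm⁻³
#: (997.047 g dm⁻³ / 18.0153 g mol⁻¹).  Used to convert surfactant molarity
#: to mole fraction in the Gibbs-energy expression.
WATER_MOLARITY_298K = 55.345

#: IUPAC 2021 standard atomic masses, g mol⁻¹.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "Br": 79.904,
}

#: FCC lattice coordination number.
FCC_COORDINATION = 12
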