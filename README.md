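# micellkit

Do the shapes of isothermal-titration-calorimetry curves encode structural
transitions of surfactant micelles?  `micellkit` is a toolkit for pursuing
that question for cationic **gemini surfactants** (alkanediyl-α,ω-
bis(dimethylalkylammonium) bromides, denoted 8-s-8 by their tail/spacer/tail
carbon counts).  It bundles the three computational pillars of such a study:

* **ITC analysis** (`micellkit.itc`) — fits enthalpograms ΔH_d(C_s) with a
  generalized-logistic ("modified Boltzmann") sigmoid over linear baselines,

      ΔH_d = ΔH_f + (ΔH_i − ΔH_f)·[1 + e^{(C_s − C_cmc)/ΔC_s}]^{−n},

  and bell-shaped curves with two conjoined steps.  The c.m.c (and the
  shape-transformation concentration C_trans) is the zero of ∂²ΔH_d/∂C_s²;
  ΔH_mic is the baseline gap at that point;
  ΔG_mic = (0.5 + β)·RT·ln X_cmc with counterion-binding degree β; and
  TΔS_mic = ΔH_mic − ΔG_mic.
* **Lattice Monte Carlo** (`micellkit.mc`) — a gemini molecule coarse-grained
  as an A8-B2-A6-B2-A8 pentablock chain on an FCC lattice (z = 12, bond a√2)
  in explicit lattice solvent, with contact energies
  ε_AB = ε_AS = ε = χkT/(z−2), single-monomer-exchange Metropolis moves,
  parallel tempering across a T* = kT/ε ladder, and per-temperature
  observables (E*/n_c, C_V, R_g², N_a) plus deterministic morphology labels
  (micelles M, rods R, channel networks CH, cylinders C).
* **Small-angle scattering** (`micellkit.sas`) — Guinier fits
  I(Q) = I(0)·e^{−Q²R_g²/3} with the (QR_g)max shape indicator, Kratky
  compactness analysis, a GNOM-style regularized indirect Fourier transform
  to the pair distance distribution p(r), and the sphere relation
  R_g² = (3/5)R².

Two further modules make the package self-contained:
`micellkit.descriptors` (micelle descriptor arithmetic: equal-volume
radii, dication-mass densities, the per-CH₂ spacer energy increment) and
`micellkit.synth` (seeded generators of synthetic enthalpograms and
sphere scattering curves, so every analysis runs and is tested without
external data).

## Worked example

The numbered scripts under `analysis/` run the full study at desk scale and
write their tables under `results/`.  Reference-table arithmetic:

```text
$ python analysis/01_reference_tables.py
descriptor table: 7/7 radii and 7/7 densities consistent (max |ΔR| = 0.0049 Å, max |Δd| = 5.9e-05 g/cm³)
thermodynamic closure: all 16 rows reproduce TΔS within 0.01 kJ/mol; β back-solves to 0.52–0.64
spacer elongation lowers the molecular SCF energy by 0.17e-15 J per CH2
```

The first line recomputes every equal-volume sphere radius R = (3V/4π)^⅓
and micelle density d = N·M/(N_A·V) in the published COSMO descriptor table
(e.g. V = 9133.3 ų → R = 12.97 Å, and the 13-mer 8-9-8 micelle → 1.0419
g cm⁻³ under the dication-mass convention).  The second line verifies the
Gibbs–Helmholtz identity row by row in the 8-8-8 thermodynamics table
(e.g. at 343.15 K: TΔS = −4.05 − (−17.24) = 13.19 kJ mol⁻¹, ΔS = 38.44
J mol⁻¹ K⁻¹) and back-solves the counterion-binding degree β ≈ 0.52–0.64
from each (ΔG, c.m.c, T) triple.

Scattering shape analysis on synthetic micelle-sized spheres (R_g ≈ 1.70 nm):

```text
$ python analysis/04_sas_shape_analysis.py
ideal: Rg 1.729 nm (true 1.704), (QRg)max 1.29 -> globular, Kratky bell: True, p(r) peak 2.31 nm, support 4.29 nm
noisy: Rg 1.762 nm (true 1.704), (QRg)max 1.26 -> globular, Kratky bell: True, p(r) peak 2.31 nm, support 4.34 nm
polydisperse: Rg 1.841 nm (true 1.704), (QRg)max 1.27 -> globular, Kratky bell: True, p(r) peak 2.42 nm, support 5.06 nm
aggregating: Rg 1.839 nm (true 1.704), (QRg)max 1.27 -> globular, Kratky bell: True, p(r) peak 2.31 nm, support 4.40 nm
```

Each row reports the Guinier radius of gyration, the (QR_g)max shape class
(values of 1.2–1.3 mean globular particles), the Kratky compactness flag,
and the location/support of the PDDF obtained by indirect Fourier transform
— for a homogeneous sphere of radius R the p(r) peak sits near 1.05·R and
the support ends at D_max = 2R.

`analysis/02_itc_synthetic_recovery.py` fits seeded noisy single- and
double-sigmoid enthalpograms and reports 95%-CI coverage of the true
inflections (≥ 90% over 200 seeds), and
`analysis/03_simulate_self_assembly.py` runs the desk-scale Monte Carlo:
a temperature scan at φ = 0.02 locating the critical micelle temperature
as the specific-heat maximum, and a low-T* composition scan showing
aggregates that grow (N_a), branch and finally percolate as φ rises from
0.04 to 0.16.

A `micellkit` command-line interface wraps the same library for shell use:
`micellkit fit-itc`, `micellkit analyze-sas`, `micellkit descriptors`,
`micellkit simulate-mc`, `micellkit gen-synthetic`.

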