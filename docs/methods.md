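# Methods

`micellkit` asks a single scientific question in three computational
languages: do the shapes of isothermal-titration-calorimetry (ITC) curves
for cationic gemini surfactants encode structural transitions of their
micelles?  The package provides (i) the calorimetric analysis that extracts
transition concentrations and thermodynamics from enthalpograms, (ii) a
coarse-grained lattice Monte Carlo model in which the morphology sequence
can be observed directly, and (iii) the small-angle-scattering analysis
that sizes and classifies the aggregates.  This note records the models,
their assumptions, the tunable parameters, and the numerical choices made
where the design was genuinely open.

## 1. Enthalpogram model and micellisation thermodynamics

### Model

One titration at temperature T yields the dilution enthalpy ΔH_d versus
cumulative surfactant concentration C_s (mol dm⁻³).  Away from transitions
the data follow linear baselines; each transition is a generalized-logistic
("modified Boltzmann") step

    ΔH_d(C_s) = ΔH_f(C_s) + [ΔH_i(C_s) − ΔH_f(C_s)] · (1 + e^{(C_s−C₀)/ΔC_s})^{−n}

with linear pre/post baselines ΔH_i = H_ia + H_ib·C_s, ΔH_f = H_fa + H_fb·C_s,
centre C₀, width ΔC_s > 0 and asymmetry exponent n > 0.  (The source
literature prints this equation with unbalanced brackets; the form above is
the one that satisfies the stated low- and high-concentration baseline
limits.)  Bell-shaped curves — seen in the temperature window where
micelles reorganize — are modelled as **two conjoined steps** over a shared
piecewise-linear baseline (pre / inter / post lines), fitted jointly.  The
functional form of the conjoined curve is not prescribed anywhere; the
sum-of-steps over a three-line baseline is this package's choice, the
simplest form whose two inflections and two baseline gaps are separately
interpretable.

The reported quantities are:

* **c.m.c** (and **C_trans** for the second step): the zero of
  d²ΔH_d/dC_s² nearest the fitted centre (for n = 1 with flat baselines this
  is exactly the centre; asymmetry and baseline slopes shift it).  Roots are
  bracketed on a scan of ±8ΔC_s around the centre and polished with Brent's
  method on the analytic second derivative (finite differences of the model
  for the two-step curve).  When several roots exist the one nearest the
  fitted centre is taken.
* **ΔH_mic = ΔH_f(c*) − ΔH_i(c*)** at the inflection c*; for the two-step
  model each step uses its adjacent baseline pair.
* **ΔG_mic = (0.5 + β)·R·T·ln X_cmc** with counterion-binding degree β
  (an experimental input, per temperature, from conductivity) and mole
  fraction X = C/(C + C_w).  The water molarity C_w defaults to 55.345
  mol dm⁻³ (pure water at 298.15 K) and is configurable; its temperature
  dependence is deliberately off by default, since the β values back-solved
  from the reference table (0.52–0.64) are consistent with the fixed-C_w
  molarity convention.
* **TΔS = ΔH − ΔG**, ΔS = 1000·TΔS/T (Gibbs–Helmholtz identity).

### Fitting and uncertainties

Fits use Levenberg–Marquardt least squares (lmfit) with σ-weights when the
curve carries uncertainties.  Initialization: step centres from the
steepest points of a Savitzky–Golay-smoothed numerical derivative, widths
from the half-maximum spread of the derivative peak, baselines from the
outer quartiles/quintiles of the data, exponents from 1.  Two-step fits run
in two stages (exponents pinned at 1, then released) to keep the centres
well conditioned; exponents are bounded to [0.2, 5], a generous range for
the mild asymmetries of real enthalpograms.  A fit whose centre leaves the
data range is refused.

The uncertainty reported for c.m.c / C_trans is the **delta-method standard
error of the inflection**: the second-derivative root is re-located under
small perturbations of each fitted parameter and the gradient is contracted
with the fit covariance.  The raw centre parameter of a generalized
logistic is strongly correlated with its exponent and its linearized CI
undercovers; the inflection — the quantity actually reported — is much
better behaved (92–97% empirical coverage of 95% intervals in the seeded
recovery batteries).

### What is and is not reproducible at desk scale

The Gibbs–Helmholtz closure of the published 8-8-8 thermodynamics table
holds to 0.01 kJ mol⁻¹ in every row (the tabulated ΔS values were evidently
computed from unrounded upstream numbers, so recomputed ΔS can differ in
the last printed digit).  The experimental c.m.c values themselves require
the raw enthalpograms, which were never deposited; they are covered here
through the closure identity and through synthetic-recovery batteries.

## 2. Coarse-grained lattice Monte Carlo

### Model

The lattice is the even-parity sublattice of an L³ cubic grid — face
centred cubic with L³/2 sites, coordination z = 12, bond length a√2, fully
periodic.  One gemini surfactant is an A8-B2-A6-B2-A8 pentablock chain
(N = 26): A = CH₂-level tail/spacer beads, B = head beads (two per
quaternary-ammonium head).  Bonds connect nearest-neighbour sites and can
neither stretch nor break.  Unoccupied sites are solvent S.  Contact
energies are ε_AB = ε_AS = ε = χkT/(z−2) and zero otherwise, so the reduced
energy E* = E/ε is the count of A–B plus A–S nearest-neighbour contacts and
T* = kT/ε is the reduced temperature.  Bonded A–B pairs within a chain are
counted as contacts — the simplest reading of a pairwise contact energy;
since every chain carries the same fixed number of intra-chain A–B bonds
this adds a constant per chain and shifts no observable except by offset.

**Chain count.**  At volume fraction φ the monomer budget is
⌊φ·L³/2⌋ sites, converted to the nearest whole number of chains (ties to
even).  For L = 78 this reproduces the published counts 182, 365, 548, 730,
913, 1095, 1278, 1460, 1643, 1825 for φ = 0.02…0.20 — including the
half-way case φ = 0.02 (4745/26 = 182.5 → 182), which no direct rounding of
φ·L³/(2N) reproduces together with the others.

**Moves.**  Single-monomer exchange (the "simple motion algorithm"): a
uniformly random monomer and one of its 12 neighbour sites are drawn; if
the site is solvent and every bond of the monomer would remain a
nearest-neighbour bond, the exchange is accepted with Metropolis
probability min(1, e^{−ΔE*/T*}).  The proposal is symmetric, so detailed
balance holds; ΔE* is computed locally and bookkeeping is exact (integer
energies, verified against full recounts).  One Monte Carlo step (MCS) is
one statistical attempt per monomer.  No crankshaft/reptation/cooperative
moves are used.

**Protocol.**  (i) athermal equilibration (ε/kT = 0, i.e. every admissible
move accepted), (ii) thermal equilibration with parallel tempering —
replicas at a geometric ladder of T*, adjacent pairs (alternating parity)
swapping configurations with probability
min(1, e^{(1/T*_i − 1/T*_j)(E*_i − E*_j)}) every 100 MCS — and (iii) data
collection with exchanges off, energies sampled every 100 MCS and
structural observables every 1000 MCS.  One master seed spawns independent
placement, per-replica sweep and exchange streams; runs are bit-reproducible.

**Observables.**  E*/n_c; specific heat per chain
C_V = (⟨E*²⟩ − ⟨E*⟩²)/(n_c·T*²) (the fluctuation estimator; the reference
plots give no formula, and the per-chain normalization matches the
per-chain energy curves); mean-squared radius of gyration per chain from
minimum-image-unwrapped coordinates; aggregation number N_a as the
number-average cluster size (weight-average available), where two chains
belong to one cluster when any A bead of one touches an A bead of the
other.

**Phase labels.**  Per cluster: relative shape anisotropy κ² of the
gyration tensor, percolation through the periodic box (detected as a
BFS revisit with a mismatched unwrapped offset, per axis), and skeleton
branch points (occupied 3a-cells of the cluster with ≥3 occupied
26-neighbours).  Fixed, configurable rules map these to labels: percolation
along ≥2 axes with a branched skeleton → CH (channel network); one axis,
unbranched → C (cylinder); one axis, branched → R/CH; otherwise the
chain-weighted fraction of rod-like clusters (κ² > 0.4) grades
M (< 0.10) → M/R (< 0.50) → R/CH.  All thresholds are artifact choices,
validated on constructed fixtures (compact blobs → M, spanning filament →
C, three crossing spanning filaments → CH).  Note that κ² itself is **not**
monotone along the morphology sequence: rods are anisotropic but
space-filling channel networks are again nearly isotropic, so the growth
of aggregates across φ is tracked by N_a, total branch points and
percolation count, not by κ² alone.

### Problem sizes

The production protocol (L = 78, 72 temperatures, 3+3+2 ×10⁶ MCS) is
exposed as the `production` preset and needs cluster-class resources.  All
shipped analyses and tests use the `desk` preset: L = 30, 12 temperatures,
10⁵ MCS per stage, which reproduces the qualitative phenomenology — the
single specific-heat maximum at low φ (the critical micelle temperature),
the energy drop through aggregation, and the growth/branching of
aggregates with φ at low T* — in minutes on one CPU.  The desk-scale CMT
for φ = 0.02 lies near T* ≈ 5, so phenomenology scans use a geometric
ladder on [1, 9] to bracket the transition; the general-purpose default
ladder remains [1, 5] (configurable), which covers the morphology sequence
below the CMT.  With only 10–20 chains the C_V estimator is noisy; peak
counting is therefore done on a 3-point moving average with a 20%
prominence floor.

## 3. Small-angle scattering analysis

* **Guinier.**  ln I regressed on Q² (σ-weighted) over the largest low-Q
  window satisfying Q·R_g ≤ 1.3, iterated to self-consistency (the cap is
  the globular-particle bound and is configurable; limit cycles on noisy
  data resolve to the smaller window).  Flat or rising curves report
  R_g = 0 rather than an imaginary radius.  An optional low-Q point skip
  excludes the aggregation upturn, which is treated qualitatively only.
* **Shape indicator.**  (Q·R_g)max classifies 0.9–1.3 → globular,
  < 0.8 → elongated; the published rule leaves [0.8, 0.9] and ≥ 1.3
  unassigned, which is surfaced as an explicit `indeterminate` class.
* **Kratky.**  Q²I(Q) vs Q with exact first-order uncertainty propagation.
  The compactness flag requires the transform's maximum to be strictly
  interior and the high-Q tail to fall below 70% of the peak — true for
  spheres, false for the Gaussian-chain (Debye) plateau.
* **PDDF.**  I(Q) = 4π∫p(r)·sinc(Qr)dr is inverted on a 101-point r-grid
  over [0, D_max] with pinned endpoints p(0) = p(D_max) = 0, a
  second-difference smoothness penalty weighted by α, and optional
  non-negativity (NNLS).  α is chosen by the maximum-curvature (L-curve)
  corner of the residual/seminorm trade-off unless given.  R_g² follows
  from ∫r²p/(2∫p).  On noise-free synthetic spheres the recovered p(r)
  peak and support match the analytic sphere PDDF
  p(r) ∝ r²(1 − 3r/4R + r³/16R³) to within one grid step (support compared
  with the same threshold estimator on both curves).
* **Sphere relations.**  R_g² = (3/5)R² and its inverse.

The published experimental R_g range (1.6–1.9 nm) depends on the raw
curves and instrument windows and is not reproducible from printed numbers;
the synthetic pipeline instead demonstrates estimator accuracy (≤2% on
noise-free spheres; ≤3% median error at 5% relative noise) at exactly that
size scale.

## 4. Descriptor arithmetic

Equal-volume sphere radius R = (3V/4π)^{1/3} and micelle density
d = N·M/(N_A·V) for N-mer micelles of the 8-s-8 dication
C_{20+s}H_{46+2s}N₂ (two octyl tails, four N-methyls, an s-carbon spacer;
IUPAC 2021 atomic masses).  The reference descriptor table is only
internally consistent when the bromide counterions are **excluded** from
the micelle mass — they are dissociated into solution — so the
dication-mass convention is the default (a flag includes them).  The
reference table prints seven data columns under four surfactant headers;
the column-to-surfactant assignment used here is the unique one that
reproduces all seven densities to 10⁻³ g cm⁻³ and is marked as inferred.
The per-CH₂ spacer energy increment is the least-squares slope of the
single-molecule SCF energies versus spacer length (0.17×10⁻¹⁵ J per CH₂
for the tabulated series).

## 5. Synthetic data

The generators produce exactly the statistical structure the analyses
assume — and no more:

* ITC: forward model plus additive homoscedastic Gaussian noise
  (σ = 0.05 kJ mol⁻¹ by default) on a linear concentration grid reaching
  5× the last step centre, 60 points for one step and 140 for two (a
  multi-day titration resolves both transition regions).  Real
  enthalpograms have heteroscedastic, injection-correlated errors and
  instrument baselines; passing recovery tests therefore demonstrates
  estimator correctness under the stated error model, not robustness to
  instrument artifacts.
* SAS: sphere form factor, optionally number-averaged over a lognormal
  radius distribution with volume² weighting (Gauss–Hermite quadrature in
  log R), flat background, relative Gaussian noise, optional low-Q
  power-law upturn; Q-grid 0.063–5.8 nm⁻¹ mimicking the experimental
  window.  Real micelles are neither homogeneous nor spherical, so these
  curves validate the transform chain, not the structural model.

Both generators are deterministic for a fixed seed and emit their ground
truth beside the data.

## 6. Known limitations

* The two-step decomposition assumes well-separated inflections; strongly
  overlapping steps (|C_trans − c.m.c| ≲ 2 widths) are not identifiable.
* β is consumed, not estimated; no conductivity model is included.
* The lattice model has no electrostatics, explicit counterions or
  solvent structure; temperature enters only through ε/kT.
* Phase labels are threshold rules on a finite box; near phase boundaries
  and at desk scale labels fluctuate between adjacent morphologies.
* The IFT is a dilute-limit transform; inter-particle structure factors
  and instrument smearing are out of scope.
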