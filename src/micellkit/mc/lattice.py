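"""FCC lattice geometry, chain topology and the contact-energy model.

The lattice is the even-parity sublattice of an L³ simple-cubic grid
(x + y + z even), which is face-centred cubic with L³/2 sites, coordination
number z = 12 and bond length a√2: the twelve nearest-neighbour offsets are
the (±1, ±1, 0)-type vectors.  Periodic boundary conditions apply in all
three directions, and the (±1, ±1, 0) offsets preserve parity, so the even
sublattice is closed under neighbour steps.

A gemini surfactant is coarse-grained as an A8-B2-A6-B2-A8 pentablock chain
(N = 26): A monomers are CH₂-level tail/spacer units, each pair of B
monomers one quaternary-ammonium head.  Unoccupied sites are solvent S.
The only non-zero contact energies are ε_AB = ε_AS = ε = χkT/(z − 2), so
the reduced energy E* = E/ε is simply the number of A–B plus A–S
nearest-neighbour contacts, and T* = kT/ε.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import FCC_COORDINATION

__all__ = ["NEIGHBOR_OFFSETS", "LatticeSpec", "ChainTopology", "EnergyModel",
           "GEMINI_PENTABLOCK", "chain_count"]

#: The twelve (±1, ±1, 0)-type FCC nearest-neighbour offsets (length a√2).
NEIGHBOR_OFFSETS = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if abs(dx) + abs(dy) + abs(dz) == 2],
    dtype=np.int64,
)

SPECIES_SOLVENT, SPECIES_A, SPECIES_B = 0, 1, 2


@dataclass(frozen=True)
class LatticeSpec:
    """Periodic FCC simulation box of edge L (lattice-constant units)."""

    L: int = 78

    def __post_init__(self):
        if self.L % 2 != 0 or self.L < 6:
            raise ValueError("box edge L must be even and at least 6")

    @property
    def n_sites(self) -> int:
        """Number of FCC sites: L³/2."""
        return self.L**3 // 2

    @property
    def n_cells(self) -> int:
        """Size of the embedding cubic grid, L³ (flat-index space)."""
        return self.L**3

    def flat_index(self, coords) -> np.ndarray:
        c = np.asarray(coords, dtype=np.int64) % self.L
        return (c[..., 0] * self.L + c[..., 1]) * self.L + c[..., 2]

    def coords(self, flat) -> np.ndarray:
        flat = np.asarray(flat, dtype=np.int64)
        z = flat % self.L
        y = (flat // self.L) % self.L
        x = flat // (self.L * self.L)
        return np.stack([x, y, z], axis=-1)

    def site_indices(self) -> np.ndarray:
        """Flat indices of all even-parity (FCC) sites."""
        g = np.indices((self.L,) * 3).reshape(3, -1).T
        even = g.sum(axis=1) % 2 == 0
        return self.flat_index(g[even])

    def neighbor_table(self) -> np.ndarray:
        """(L³, 12) flat neighbour indices under periodic boundaries.

        Rows are defined for every cell of the embedding cubic grid; only
        even-parity rows are meaningful (and only those are ever visited).
        """
        flat = np.arange(self.n_cells, dtype=np.int64)
        c = self.coords(flat)  # (n, 3)
        nbrs = (c[:, None, :] + NEIGHBOR_OFFSETS[None, :, :]) % self.L
        return self.flat_index(nbrs).astype(np.int64)

    def minimum_image(self, delta) -> np.ndarray:
        d = np.asarray(delta, dtype=np.int64) % self.L
        return np.where(d > self.L // 2, d - self.L, d)


def build_lattice(L: int) -> LatticeSpec:
    """Construct and sanity-check an FCC box of edge L."""
    return LatticeSpec(L)


@dataclass(frozen=True)
class ChainTopology:
    """Block sequence of one coarse-grained chain.

    ``blocks`` is a tuple of (species letter, length) pairs; the default is
    the gemini pentablock A8-B2-A6-B2-A8.
    """

    blocks: tuple[tuple[str, int], ...] = (("A", 8), ("B", 2), ("A", 6), ("B", 2), ("A", 8))

    @property
    def species(self) -> np.ndarray:
        """Per-monomer species codes (1 = A, 2 = B) in bonded order."""
        code = {"A": SPECIES_A, "B": SPECIES_B}
        return np.concatenate([np.full(n, code[s], dtype=np.int8)
                               for s, n in self.blocks])

    @property
    def n_monomers(self) -> int:
        return sum(n for _, n in self.blocks)

    def species_count(self, letter: str) -> int:
        return sum(n for s, n in self.blocks if s == letter)

    @property
    def bonded_ab_pairs(self) -> int:
        """Intra-chain bonds joining an A to a B monomer (4 for the gemini)."""
        sp = self.species
        return int(np.sum(sp[:-1] != sp[1:]))


GEMINI_PENTABLOCK = ChainTopology()


@dataclass(frozen=True)
class EnergyModel:
    """Contact-energy model ε_AB = ε_AS = ε = χkT/(z−2), all others zero."""

    chi: float = 1.0
    z: int = FCC_COORDINATION

    def epsilon_over_kT(self, tstar: float) -> float:
        """ε/(kT) at reduced temperature T* = kT/ε is simply 1/T*."""
        return 1.0 / tstar

    @property
    def contact_matrix(self) -> np.ndarray:
        """ε_ij/ε for species (S, A, B): 1 for A–B and A–S, else 0."""
        m = np.zeros((3, 3))
        m[SPECIES_A, SPECIES_B] = m[SPECIES_B, SPECIES_A] = 1.0
        m[SPECIES_A, SPECIES_SOLVENT] = m[SPECIES_SOLVENT, SPECIES_A] = 1.0
        return m


def chain_count(phi: float, spec: LatticeSpec,
                topology: ChainTopology = GEMINI_PENTABLOCK) -> int:
    """Number of chains at volume fraction φ.

    The whole-site monomer budget floor(φ·L³/2) is converted to the nearest
    whole number of chains (ties to even).  For L = 78, N = 26 this yields
    182, 365, 548, 730, 913, 1095, 1278, 1460, 1643, 1825 chains at
    φ = 0.02 … 0.20.
    """
    if not 0 < phi <= 0.3:
        raise ValueError("volume fraction must lie in (0, 0.3]")
    budget = int(np.floor(phi * spec.n_sites))
    return int(round(budget / topology.n_monomers))
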