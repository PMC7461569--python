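"""Lattice occupancy state and chain placement."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .lattice import ChainTopology, GEMINI_PENTABLOCK, LatticeSpec, chain_count

__all__ = ["LatticeState", "PlacementError", "place_chains"]


class PlacementError(RuntimeError):
    """Self-avoiding chain growth failed repeatedly (volume fraction too high)."""


@dataclass
class LatticeState:
    """Occupancy of one replica: species map, site→monomer map, positions.

    ``pos`` stores the flat cubic-grid site of every monomer with chains
    concatenated (monomer ``i`` of chain ``c`` at index ``c·N + i``); sites
    not covered by any chain are solvent.  The running reduced energy is
    kept in sync by the sweep driver.
    """

    spec: LatticeSpec
    topology: ChainTopology
    species: np.ndarray      # int8[L³]
    mono_at: np.ndarray      # int64[L³], −1 for solvent / unused parity
    pos: np.ndarray          # int64[n_chains·N]
    energy: int = 0          # running E*, see refresh_energy()

    @property
    def n_chains(self) -> int:
        return self.pos.size // self.topology.n_monomers

    @property
    def nbr(self) -> np.ndarray:
        return _neighbor_cache(self.spec)

    def chain_sites(self, c: int) -> np.ndarray:
        N = self.topology.n_monomers
        return self.pos[c * N:(c + 1) * N]

    def chain_coords(self, c: int) -> np.ndarray:
        """(N, 3) wrapped integer coordinates of chain c in bonded order."""
        return self.spec.coords(self.chain_sites(c))

    def refresh_energy(self) -> int:
        """Recount E* from scratch and store it."""
        self.energy = int(_kernels.total_energy(self.species, self.pos, self.nbr))
        return self.energy

    def copy(self) -> "LatticeState":
        return LatticeState(self.spec, self.topology, self.species.copy(),
                            self.mono_at.copy(), self.pos.copy(), self.energy)

    def check_bonds(self) -> bool:
        """All consecutive monomers of every chain at distance a√2."""
        N = self.topology.n_monomers
        for c in range(self.n_chains):
            xyz = self.chain_coords(c)
            d = self.spec.minimum_image(np.diff(xyz, axis=0))
            if not np.all((d**2).sum(axis=1) == 2):
                return False
        return True


_NBR_CACHE: dict[int, np.ndarray] = {}


def _neighbor_cache(spec: LatticeSpec) -> np.ndarray:
    tab = _NBR_CACHE.get(spec.L)
    if tab is None:
        tab = spec.neighbor_table()
        _NBR_CACHE[spec.L] = tab
    return tab


def place_chains(spec: LatticeSpec, topology: ChainTopology = GEMINI_PENTABLOCK,
                 phi: float = 0.02, seed: int = 0,
                 max_restarts: int = 200) -> LatticeState:
    """Grow self-avoiding chains on the FCC lattice at volume fraction φ.

    Each chain is grown monomer by monomer as a nearest-neighbour
    self-avoiding walk from a random empty site; a dead end restarts the
    chain.  Deterministic for a fixed seed.  Raises :class:`PlacementError`
    after ``max_restarts`` failed growths per chain (dense systems).
    """
    n_c = chain_count(phi, spec, topology)
    rng = np.random.default_rng(seed)
    nbr = _neighbor_cache(spec)
    N = topology.n_monomers
    sp_pattern = topology.species

    species = np.zeros(spec.n_cells, dtype=np.int8)
    mono_at = np.full(spec.n_cells, -1, dtype=np.int64)
    pos = np.empty(n_c * N, dtype=np.int64)
    free_even = spec.site_indices()

    for c in range(n_c):
        placed = False
        for _ in range(max_restarts):
            start = free_even[rng.integers(free_even.size)]
            if mono_at[start] != -1:
                continue
            sites = [int(start)]
            occupied = {int(start)}
            while len(sites) < N:
                cand = [int(t) for t in nbr[sites[-1]]
                        if mono_at[t] == -1 and int(t) not in occupied]
                if not cand:
                    break
                nxt = cand[rng.integers(len(cand))]
                sites.append(nxt)
                occupied.add(nxt)
            if len(sites) == N:
                idx = np.asarray(sites, dtype=np.int64)
                pos[c * N:(c + 1) * N] = idx
                species[idx] = sp_pattern
                mono_at[idx] = np.arange(c * N, (c + 1) * N, dtype=np.int64)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not grow chain {c + 1}/{n_c} after {max_restarts} restarts; "
                "reduce the volume fraction or retry with another seed")

    state = LatticeState(spec, topology, species, mono_at, pos)
    state.refresh_energy()
    return state
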