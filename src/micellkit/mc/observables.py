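"""Per-temperature observables: energy, specific heat, R_g², aggregation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .state import LatticeState

__all__ = ["MCObservables", "reduced_energy", "specific_heat",
           "mean_sq_radius_of_gyration", "unwrapped_chain_coords",
           "find_clusters", "aggregation_number"]


@dataclass
class MCObservables:
    """Collected series and means for one replica temperature."""

    tstar: float
    n_chains: int
    phi: float
    e_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    rg2_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    na_series: np.ndarray = field(default_factory=lambda: np.empty(0))
    phase_label: str = ""

    @property
    def e_per_chain(self) -> float:
        return float(np.mean(self.e_series)) / self.n_chains

    @property
    def cv(self) -> float:
        return specific_heat(self.e_series, self.tstar, self.n_chains)

    @property
    def rg2_mean(self) -> float:
        return float(np.mean(self.rg2_series))

    @property
    def na_mean(self) -> float:
        return float(np.mean(self.na_series))


def reduced_energy(state: LatticeState, include_bonded_contacts: bool = True) -> int:
    """E* of a configuration, optionally excluding bonded A–B pairs.

    The default counts every nearest-neighbour A–B/A–S pair, including the
    A–B pairs bonded within a chain; excluding them subtracts a constant
    per chain (the bonded pair count is fixed by the topology), so the two
    conventions differ only by an offset.
    """
    e = state.energy
    if not include_bonded_contacts:
        e -= state.topology.bonded_ab_pairs * state.n_chains
    return int(e)


def specific_heat(e_series, tstar: float, n_chains: int) -> float:
    """Fluctuation specific heat per chain: (⟨E*²⟩ − ⟨E*⟩²)/(n_c·T*²)."""
    e = np.asarray(e_series, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two energy samples")
    if not np.isfinite(tstar) or tstar <= 0:
        raise ValueError("T* must be positive and finite")
    return float(np.var(e) / (n_chains * tstar**2))


def unwrapped_chain_coords(state: LatticeState, c: int) -> np.ndarray:
    """(N, 3) chain coordinates unwrapped by minimum-image bond steps."""
    xyz = state.chain_coords(c).astype(np.int64)
    steps = state.spec.minimum_image(np.diff(xyz, axis=0))
    out = np.empty_like(xyz)
    out[0] = xyz[0]
    out[1:] = xyz[0] + np.cumsum(steps, axis=0)
    return out


def mean_sq_radius_of_gyration(state: LatticeState) -> float:
    """Chain-averaged R_g² about the centroid, in squared lattice units."""
    if state.n_chains < 1:
        raise ValueError("need at least one chain")
    total = 0.0
    for c in range(state.n_chains):
        xyz = unwrapped_chain_coords(state, c).astype(float)
        xyz -= xyz.mean(axis=0)
        total += float(np.mean((xyz**2).sum(axis=1)))
    return total / state.n_chains


def find_clusters(state: LatticeState) -> list[list[int]]:
    """Connected components of the chain contact graph.

    Two chains are connected when any A monomer of one is a nearest
    neighbour of any A monomer of the other.  Returns the clusters as lists
    of chain indices (singletons included), sorted by first member.
    """
    n = state.n_chains
    parent = np.arange(n, dtype=np.int64)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = _kernels.aa_contact_pairs(state.species, state.mono_at, state.pos,
                                      state.nbr, state.topology.n_monomers)
    for ci, cj in np.unique(pairs, axis=0) if pairs.size else []:
        ri, rj = find(ci), find(cj)
        if ri != rj:
            parent[ri] = rj

    groups: dict[int, list[int]] = {}
    for c in range(n):
        groups.setdefault(int(find(c)), []).append(c)
    return sorted(groups.values(), key=lambda g: g[0])


def aggregation_number(clusters: list[list[int]], weighting: str = "number") -> float:
    """Mean chains per cluster.

    ``number`` weights every cluster equally; ``weight`` weights clusters by
    their own size (Σs²/Σs), emphasising large aggregates.
    """
    if not clusters:
        return 0.0
    sizes = np.array([len(g) for g in clusters], dtype=float)
    if weighting == "number":
        return float(sizes.mean())
    if weighting == "weight":
        return float((sizes**2).sum() / sizes.sum())
    raise ValueError(f"unknown weighting {weighting!r}")
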