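"""Shared fixtures: hand-built lattice states and tiny analysis inputs."""

from __future__ import annotations

import numpy as np
import pytest

from micellkit.mc.lattice import ChainTopology, LatticeSpec
from micellkit.mc.state import LatticeState


def state_from_paths(spec: LatticeSpec, paths, pattern=None) -> LatticeState:
    """Build a LatticeState from explicit per-chain coordinate paths.

    All paths must have equal length; consecutive coordinates must be FCC
    nearest neighbours.  ``pattern`` optionally gives the per-monomer
    species letters (default: all A).
    """
    N = len(paths[0])
    if pattern is None:
        topo = ChainTopology((("A", N),))
    else:
        blocks = []
        for letter in pattern:
            if blocks and blocks[-1][0] == letter:
                blocks[-1][1] += 1
            else:
                blocks.append([letter, 1])
        topo = ChainTopology(tuple((s, n) for s, n in blocks))
    species_pattern = topo.species
    species = np.zeros(spec.n_cells, dtype=np.int8)
    mono_at = np.full(spec.n_cells, -1, dtype=np.int64)
    pos = np.empty(len(paths) * N, dtype=np.int64)
    for c, p in enumerate(paths):
        idx = spec.flat_index(np.asarray(p))
        if np.any(mono_at[idx] != -1):
            raise ValueError(f"chain {c} overlaps a previous chain")
        pos[c * N:(c + 1) * N] = idx
        species[idx] = species_pattern
        mono_at[idx] = np.arange(c * N, (c + 1) * N, dtype=np.int64)
    st = LatticeState(spec, topo, species, mono_at, pos)
    if not st.check_bonds():
        raise ValueError("paths contain non-nearest-neighbour steps")
    st.refresh_energy()
    return st


def zigzag(start, axis: int, n: int):
    """Straight FCC filament along ``axis`` (alternating transverse kicks)."""
    p = [np.asarray(start, dtype=int)]
    for i in range(n - 1):
        step = np.zeros(3, int)
        step[axis] = 1
        step[(axis + 1) % 3] = 1 if i % 2 == 0 else -1
        p.append(p[-1] + step)
    return [tuple(x) for x in p]


def compact_blob_paths(offset=(0, 0, 0)):
    """Two 4-mer chains folded into one compact, nearly isotropic cluster."""
    off = np.asarray(offset, int)
    b1 = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)]
    b2 = [(1, -1, 0), (0, -1, 1), (0, 0, 2), (1, 1, 2)]
    return [[tuple(np.asarray(p) + off) for p in b] for b in (b1, b2)]


@pytest.fixture(scope="session")
def small_spec():
    return LatticeSpec(12)
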