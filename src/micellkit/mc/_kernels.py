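"""Numba kernels for the lattice Monte Carlo engine.

State layout shared with :mod:`micellkit.mc.state`:

* ``species``  int8[L³]   — 0 solvent, 1 A, 2 B (flat cubic-grid index).
* ``mono_at``  int64[L³]  — global monomer index occupying a site, −1 if none.
* ``pos``      int64[n_c·N] — flat site of each monomer, chains concatenated.
* ``nbr``      int64[L³, 12] — periodic FCC neighbour table.

The reduced energy E* is the integer count of A–B plus A–S nearest-neighbour
contacts; a pair contributes iff exactly one member is species A.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _is_adjacent(a, b, L):
    """True if flat sites a and b are FCC nearest neighbours (min. image)."""
    az = a % L
    ay = (a // L) % L
    ax = a // (L * L)
    bz = b % L
    by = (b // L) % L
    bx = b // (L * L)
    h = L // 2
    dx = ax - bx
    if dx > h:
        dx -= L
    elif dx < -h:
        dx += L
    dy = ay - by
    if dy > h:
        dy -= L
    elif dy < -h:
        dy += L
    dz = az - bz
    if dz > h:
        dz -= L
    elif dz < -h:
        dz += L
    return dx * dx + dy * dy + dz * dz == 2


@njit(cache=True, inline="always")
def _pair(u, v):
    """Reduced contact energy of a species pair: 1 iff exactly one is A."""
    return 1 if (u == 1) != (v == 1) else 0


@njit(cache=True)
def total_energy(species, pos, nbr):
    """E* by direct count: for every A monomer, neighbours that are not A."""
    e = 0
    for m in range(pos.size):
        s = pos[m]
        if species[s] != 1:
            continue
        for k in range(12):
            if species[nbr[s, k]] != 1:
                e += 1
    return e


@njit(cache=True, inline="always")
def _local_energy(species, nbr, s, t):
    """Energy of all contacts involving sites s or t (s–t pair once)."""
    e = 0
    us = species[s]
    ut = species[t]
    for k in range(12):
        e += _pair(us, species[nbr[s, k]])
        e += _pair(ut, species[nbr[t, k]])
    # the s–t contact was counted from both ends; drop one copy
    e -= _pair(us, ut)
    return e


@njit(cache=True)
def sweep(species, mono_at, pos, nbr, L, n_chain_monomers, tstar, n_attempts, seed):
    """Metropolis single-monomer-exchange (SMA) attempts.

    Each attempt picks a uniform random monomer and one of its 12 neighbour
    sites; if that site is solvent and every bond of the monomer would stay
    a nearest-neighbour bond, the exchange is accepted with probability
    min(1, exp(−ΔE*/T*)).  ``tstar = inf`` gives the athermal limit.
    Returns (accepted count, accumulated ΔE* of accepted moves).
    """
    np.random.seed(seed)
    n_mono = pos.size
    N = n_chain_monomers
    accepted = 0
    de_sum = 0
    for _ in range(n_attempts):
        m = np.random.randint(0, n_mono)
        s = pos[m]
        t = nbr[s, np.random.randint(0, 12)]
        if mono_at[t] != -1:
            continue
        w = m % N
        if w > 0 and not _is_adjacent(pos[m - 1], t, L):
            continue
        if w < N - 1 and not _is_adjacent(pos[m + 1], t, L):
            continue
        e_before = _local_energy(species, nbr, s, t)
        sp = species[s]
        species[s] = 0
        species[t] = sp
        de = _local_energy(species, nbr, s, t) - e_before
        if de <= 0 or np.random.random() < np.exp(-de / tstar):
            mono_at[s] = -1
            mono_at[t] = m
            pos[m] = t
            accepted += 1
            de_sum += de
        else:
            species[t] = 0
            species[s] = sp
    return accepted, de_sum


@njit(cache=True)
def aa_contact_pairs(species, mono_at, pos, nbr, n_chain_monomers):
    """Inter-chain A–A nearest-neighbour contacts as (chain_i, chain_j) pairs.

    Each unordered chain pair may appear many times; callers deduplicate.
    """
    N = n_chain_monomers
    out = np.empty((pos.size * 12, 2), dtype=np.int64)
    n = 0
    for m in range(pos.size):
        s = pos[m]
        if species[s] != 1:
            continue
        ci = m // N
        for k in range(12):
            t = nbr[s, k]
            mo = mono_at[t]
            if mo == -1 or species[t] != 1:
                continue
            cj = mo // N
            if cj > ci:
                out[n, 0] = ci
                out[n, 1] = cj
                n += 1
    return out[:n]
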