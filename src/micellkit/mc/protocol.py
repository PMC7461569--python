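"""Simulation protocol: temperature ladders, parallel tempering, schedules.

A run follows the three-stage protocol used for the self-assembly phase
diagram: (i) athermal equilibration at ε/kT = 0 until the chains adopt
statistical conformations, (ii) thermal equilibration with parallel
tempering — replicas at a ladder of reduced temperatures T* = kT/ε
exchanging configurations between adjacent temperatures — and (iii) data
collection with the exchanges turned off, sampling the reduced energy at a
fixed stride and structural observables at a coarser one.

The production scale (L = 78, 72 temperatures, 3+3+2 ×10⁶ MCS) is exposed
as the ``production`` preset; the ``desk`` preset (L = 30, 12 temperatures,
10⁵+10⁵+10⁵ MCS) reproduces the qualitative phenomenology at workstation
cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .lattice import ChainTopology, GEMINI_PENTABLOCK, LatticeSpec
from .observables import (MCObservables, aggregation_number, find_clusters,
                          mean_sq_radius_of_gyration)
from .phases import PhaseThresholds, classify_phase
from .state import LatticeState, place_chains

__all__ = ["Schedule", "ReplicaLadder", "geometric_ladder", "run_sweeps",
           "parallel_tempering_sweep", "run_protocol", "PRESETS"]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class Schedule:
    """(athermal, PT-equilibration, collection) lengths in Monte Carlo steps."""

    athermal_mcs: int = 100_000
    pt_mcs: int = 100_000
    collect_mcs: int = 100_000

    def __post_init__(self):
        if min(self.athermal_mcs, self.pt_mcs, self.collect_mcs) < 0:
            raise ValueError("schedule stages must be non-negative")


@dataclass
class ReplicaLadder:
    """Replicas at strictly increasing reduced temperatures."""

    temperatures: np.ndarray
    states: list[LatticeState]
    swap_attempts: np.ndarray = field(init=False)
    swap_accepts: np.ndarray = field(init=False)
    _parity: int = 0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if len(self.states) != self.temperatures.size:
            raise ValueError("one state per temperature required")
        n_pair = max(self.temperatures.size - 1, 0)
        self.swap_attempts = np.zeros(n_pair, dtype=np.int64)
        self.swap_accepts = np.zeros(n_pair, dtype=np.int64)

    @property
    def n_replicas(self) -> int:
        return self.temperatures.size


def geometric_ladder(t_min: float = 1.0, t_max: float = 5.0, n: int = 72) -> np.ndarray:
    """Geometric ladder of reduced temperatures on [t_min, t_max]."""
    if not (0 < t_min < t_max) or n < 2:
        raise ValueError("need 0 < t_min < t_max and at least two rungs")
    return np.geomspace(t_min, t_max, n)


def run_sweeps(state: LatticeState, tstar: float, n_mcs: int,
               rng: np.random.Generator) -> float:
    """Advance a replica by ``n_mcs`` Monte Carlo steps at temperature T*.

    One MCS is one statistical attempt per monomer.  The running reduced
    energy is updated incrementally from the kernel's accepted-move sum.
    Returns the acceptance fraction.
    """
    n_attempts = n_mcs * state.pos.size
    if n_attempts == 0:
        return 0.0
    acc, de = _kernels.sweep(state.species, state.mono_at, state.pos, state.nbr,
                             state.spec.L, state.topology.n_monomers,
                             float(tstar), n_attempts,
                             int(rng.integers(_SEED_MOD)))
    state.energy += int(de)
    return acc / n_attempts


def parallel_tempering_sweep(ladder: ReplicaLadder, rng: np.random.Generator) -> None:
    """One round of adjacent-pair exchange attempts.

    Pairs of even parity and odd parity alternate between calls.  A swap of
    the configurations at T*_i < T*_j is accepted with probability
    min(1, exp((1/T*_i − 1/T*_j)·(E*_i − E*_j))) — certain when the colder
    replica carries the higher energy.
    """
    if ladder.n_replicas < 2:
        raise ValueError("parallel tempering needs at least two replicas")
    start = ladder._parity
    ladder._parity ^= 1
    for i in range(start, ladder.n_replicas - 1, 2):
        ti, tj = ladder.temperatures[i], ladder.temperatures[i + 1]
        ei, ej = ladder.states[i].energy, ladder.states[i + 1].energy
        ladder.swap_attempts[i] += 1
        log_p = (1.0 / ti - 1.0 / tj) * (ei - ej)
        if log_p >= 0 or rng.random() < np.exp(log_p):
            ladder.states[i], ladder.states[i + 1] = ladder.states[i + 1], ladder.states[i]
            ladder.swap_accepts[i] += 1


def run_protocol(spec: LatticeSpec, topology: ChainTopology = GEMINI_PENTABLOCK,
                 phi: float = 0.02, temperatures=None,
                 schedule: Schedule = Schedule(), seed: int = 0,
                 sample_stride: int = 100, swap_interval: int = 100,
                 structure_stride: int = 1000,
                 thresholds: PhaseThresholds = PhaseThresholds(),
                 frozen: bool = False,
                 return_states: bool = False):
    """Full three-stage run; returns per-temperature observables.

    Deterministic for a fixed master seed: one seed sequence spawns the
    placement, per-replica sweep and exchange streams.  ``frozen`` samples
    the initial configurations without moving (diagnostic mode).
    ``return_states`` also returns the final :class:`ReplicaLadder`.
    """
    temperatures = np.atleast_1d(np.asarray(
        geometric_ladder(n=12) if temperatures is None else temperatures, dtype=float))
    ss = np.random.SeedSequence(seed)
    n_rep = temperatures.size
    children = ss.spawn(2 * n_rep + 1)
    place_rngs = children[:n_rep]
    sweep_rngs = [np.random.default_rng(c) for c in children[n_rep:2 * n_rep]]
    pt_rng = np.random.default_rng(children[-1])

    states = [place_chains(spec, topology, phi, seed=int(c.generate_state(1)[0] % _SEED_MOD))
              for c in place_rngs]
    ladder = ReplicaLadder(temperatures, states)
    n_c = states[0].n_chains

    if not frozen:
        for r in range(n_rep):
            run_sweeps(ladder.states[r], np.inf, schedule.athermal_mcs, sweep_rngs[r])
        done = 0
        while done < schedule.pt_mcs:
            step = min(swap_interval, schedule.pt_mcs - done)
            for r in range(n_rep):
                run_sweeps(ladder.states[r], temperatures[r], step, sweep_rngs[r])
            if n_rep >= 2:
                parallel_tempering_sweep(ladder, pt_rng)
            done += step

    # collection: exchanges off, fixed-stride sampling
    n_samples = max(schedule.collect_mcs // sample_stride, 1)
    e_series = np.zeros((n_rep, n_samples))
    rg2_series = [[] for _ in range(n_rep)]
    na_series = [[] for _ in range(n_rep)]
    for k in range(n_samples):
        for r in range(n_rep):
            if not frozen:
                run_sweeps(ladder.states[r], temperatures[r], sample_stride, sweep_rngs[r])
            e_series[r, k] = ladder.states[r].energy
            if k % max(structure_stride // sample_stride, 1) == 0 or k == n_samples - 1:
                st = ladder.states[r]
                rg2_series[r].append(mean_sq_radius_of_gyration(st))
                na_series[r].append(aggregation_number(find_clusters(st)))

    out = []
    for r in range(n_rep):
        obs = MCObservables(
            tstar=float(temperatures[r]), n_chains=n_c, phi=phi,
            e_series=e_series[r],
            rg2_series=np.asarray(rg2_series[r]),
            na_series=np.asarray(na_series[r]),
            phase_label=classify_phase(ladder.states[r], thresholds=thresholds).label,
        )
        out.append(obs)
    if return_states:
        return out, ladder
    return out


#: Named run scales.  ``production`` is the full cluster-scale protocol;
#: ``desk`` reproduces the qualitative phenomenology on one CPU.
PRESETS = {
    "production": {"L": 78, "n_temperatures": 72,
              "schedule": Schedule(3_000_000, 3_000_000, 2_000_000)},
    "desk": {"L": 30, "n_temperatures": 12,
             "schedule": Schedule(100_000, 100_000, 100_000)},
}
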