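"""Monte Carlo engine: placement, energy bookkeeping, detailed balance, PT."""

import numpy as np
import pytest
from scipy.stats import chisquare

from micellkit.mc import (ChainTopology, LatticeSpec, ReplicaLadder, Schedule,
                          parallel_tempering_sweep, place_chains, run_protocol,
                          run_sweeps)
from micellkit.mc import _kernels
from micellkit.mc.state import PlacementError

from conftest import state_from_paths, zigzag


def brute_force_energy(state):
    """Independent double loop over occupied sites and their neighbours."""
    e = 0
    occupied = np.nonzero(state.mono_at >= 0)[0]
    for s in occupied:
        for t in state.nbr[s]:
            u, v = state.species[s], state.species[t]
            contact = 1 if (u == 1) != (v == 1) else 0
            if state.mono_at[t] >= 0:
                if t < s:           # occupied-occupied pairs once
                    e += contact
            else:                   # occupied-solvent pairs once (from the monomer side)
                e += contact
    return int(e)


class TestPlacement:
    def test_deterministic_for_seed(self):
        a = place_chains(LatticeSpec(16), phi=0.05, seed=3)
        b = place_chains(LatticeSpec(16), phi=0.05, seed=3)
        assert np.array_equal(a.pos, b.pos)

    def test_chains_are_valid_walks(self):
        st = place_chains(LatticeSpec(16), phi=0.08, seed=1)
        assert st.check_bonds()
        # self-avoidance: every occupied site maps to exactly one monomer
        occ, counts = np.unique(st.pos, return_counts=True)
        assert counts.max() == 1
        assert occ.size == st.pos.size

    def test_solvent_fills_the_rest(self):
        st = place_chains(LatticeSpec(16), phi=0.05, seed=2)
        assert np.count_nonzero(st.species) == st.pos.size

    def test_exhausted_retries_raise(self):
        with pytest.raises(PlacementError, match="volume fraction"):
            place_chains(LatticeSpec(6), phi=0.3, seed=0, max_restarts=0)


class TestEnergy:
    def test_all_solvent_is_zero(self, small_spec):
        st = state_from_paths(small_spec, [[(0, 0, 0), (1, 1, 0)]], pattern="BB")
        assert _kernels.total_energy(st.species, st.pos[:0], st.nbr) == 0

    def test_single_stretched_chain_vs_brute_force(self, small_spec):
        st = state_from_paths(small_spec, [zigzag((0, 0, 0), 0, 8)], pattern="AABBAABB")
        assert st.energy == brute_force_energy(st)

    def test_random_states_vs_brute_force(self):
        for seed in range(3):
            st = place_chains(LatticeSpec(12), phi=0.08, seed=seed)
            assert st.energy == brute_force_energy(st)

    def test_incremental_equals_recount_over_many_moves(self):
        """ΔE* accumulated over 10⁴ accepted moves matches a recount exactly."""
        st = place_chains(LatticeSpec(12), phi=0.08, seed=4)
        rng = np.random.default_rng(0)
        accepted = 0
        while accepted < 10_000:
            acc, de = _kernels.sweep(st.species, st.mono_at, st.pos, st.nbr,
                                     12, 26, 1.5, 5000, int(rng.integers(2**31 - 1)))
            st.energy += de
            accepted += acc
            assert st.energy == _kernels.total_energy(st.species, st.pos, st.nbr)
        assert st.check_bonds()


class TestSweep:
    def test_bonds_invariant_under_sweeps(self):
        st = place_chains(LatticeSpec(12), phi=0.08, seed=5)
        rng = np.random.default_rng(1)
        for _ in range(5):
            run_sweeps(st, 1.0, 200, rng)
            assert st.check_bonds()

    def test_athermal_limit_is_temperature_independent(self):
        """At T* = ∞ every admissible move is accepted: the trajectory is
        identical to a run at any astronomically large temperature."""
        a = place_chains(LatticeSpec(12), phi=0.06, seed=6)
        b = a.copy()
        _kernels.sweep(a.species, a.mono_at, a.pos, a.nbr, 12, 26, np.inf, 50_000, 99)
        _kernels.sweep(b.species, b.mono_at, b.pos, b.nbr, 12, 26, 1e9, 50_000, 99)
        assert np.array_equal(a.pos, b.pos)

    def test_athermal_acceptance_exceeds_cold(self):
        a = place_chains(LatticeSpec(12), phi=0.06, seed=7)
        b = a.copy()
        acc_hot, _ = _kernels.sweep(a.species, a.mono_at, a.pos, a.nbr, 12, 26,
                                    np.inf, 100_000, 3)
        acc_cold, _ = _kernels.sweep(b.species, b.mono_at, b.pos, b.nbr, 12, 26,
                                     0.5, 100_000, 3)
        assert acc_hot > acc_cold

    def test_boltzmann_sampling_matches_exact_enumeration(self):
        """A single 4-mer in a small periodic box samples energy levels with
        exact Boltzmann probabilities (χ² p > 0.01)."""
        spec = LatticeSpec(6)
        nbr = spec.neighbor_table()
        sites = spec.site_indices()
        # exhaustive enumeration of all ordered self-avoiding 4-site walks
        energies = []
        for s0 in sites:
            for s1 in nbr[s0]:
                for s2 in nbr[s1]:
                    if s2 == s0:
                        continue
                    for s3 in nbr[s2]:
                        if s3 == s0 or s3 == s1:
                            continue
                        walk = (s0, s1, s2, s3)
                        pairs = sum(
                            1 for i in range(4) for j in range(i + 1, 4)
                            if walk[j] in nbr[walk[i]])
                        energies.append(48 - 2 * pairs)  # 4 A monomers, 12 contacts each
        energies = np.asarray(energies)
        tstar = 1.0
        levels = np.unique(energies)
        weights = np.exp(-(energies - energies.min()) / tstar)
        probs = np.array([weights[energies == e].sum() for e in levels])
        probs /= probs.sum()

        st = state_from_paths(spec, [zigzag((0, 0, 0), 0, 4)])
        rng = np.random.default_rng(42)
        # the toy chain decorrelates slowly (tau_int ~ 135 sweeps); samples
        # are spaced 1000 sweeps apart so the chi-square assumption holds
        n_samp = 10_000
        counts = {int(e): 0 for e in levels}
        for _ in range(n_samp):
            _, de = _kernels.sweep(st.species, st.mono_at, st.pos, st.nbr, 6, 4,
                                   tstar, 4000, int(rng.integers(2**31 - 1)))
            st.energy += de
            counts[st.energy] += 1
        observed = np.array([counts[int(e)] for e in levels])
        _, p = chisquare(observed, probs * n_samp)
        assert p > 0.01


class TestParallelTempering:
    def _toy_ladder(self, energies, temps=(1.0, 2.0)):
        spec = LatticeSpec(12)
        states = []
        for k, e in enumerate(energies):
            st = place_chains(spec, phi=0.04, seed=k)
            st.energy = e  # forced energies for the acceptance arithmetic
            states.append(st)
        return ReplicaLadder(np.asarray(temps, float), states)

    def test_equal_energies_always_swap(self):
        lad = self._toy_ladder([100, 100])
        cold = lad.states[0]
        parallel_tempering_sweep(lad, np.random.default_rng(0))
        assert lad.states[1] is cold
        assert lad.swap_accepts[0] == 1

    def test_favourable_swap_certain(self):
        # colder replica holds the higher energy: swap probability is 1
        lad = self._toy_ladder([500, 100])
        cold = lad.states[0]
        parallel_tempering_sweep(lad, np.random.default_rng(0))
        assert lad.states[1] is cold

    def test_parity_alternates(self):
        lad = self._toy_ladder([100, 100, 100], temps=(1.0, 2.0, 3.0))
        rng = np.random.default_rng(0)
        parallel_tempering_sweep(lad, rng)
        parallel_tempering_sweep(lad, rng)
        assert lad.swap_attempts[0] == 1 and lad.swap_attempts[1] == 1

    def test_replica_marginals_match_enumeration(self):
        """With exchanges on, each rung still samples its own Boltzmann
        distribution (compared against exact enumeration per temperature)."""
        spec = LatticeSpec(6)
        nbr = spec.neighbor_table()
        sites = spec.site_indices()
        energies = []
        for s0 in sites:
            for s1 in nbr[s0]:
                for s2 in nbr[s1]:
                    if s2 == s0:
                        continue
                    for s3 in nbr[s2]:
                        if s3 == s0 or s3 == s1:
                            continue
                        walk = (s0, s1, s2, s3)
                        pairs = sum(1 for i in range(4) for j in range(i + 1, 4)
                                    if walk[j] in nbr[walk[i]])
                        energies.append(48 - 2 * pairs)
        energies = np.asarray(energies)
        levels = np.unique(energies)
        temps = (1.0, 3.0)
        states = [state_from_paths(spec, [zigzag((0, 0, 0), 0, 4)]) for _ in temps]
        lad = ReplicaLadder(np.asarray(temps), states)
        rng = np.random.default_rng(11)
        counts = np.zeros((2, levels.size), dtype=int)
        # decorrelated sampling: 1000 attempted exchanges of 1000-attempt
        # sweep blocks, one sample per 4 blocks per rung
        n_samp = 6000
        for k in range(4 * n_samp):
            for r, st in enumerate(lad.states):
                _, de = _kernels.sweep(st.species, st.mono_at, st.pos, st.nbr, 6, 4,
                                       temps[r], 1000, int(rng.integers(2**31 - 1)))
                st.energy += de
            parallel_tempering_sweep(lad, rng)
            if k % 4 == 3:
                for r, st in enumerate(lad.states):
                    counts[r, np.searchsorted(levels, st.energy)] += 1
        for r, t in enumerate(temps):
            w = np.exp(-(energies - energies.min()) / t)
            probs = np.array([w[energies == e].sum() for e in levels])
            probs /= probs.sum()
            _, p = chisquare(counts[r], probs * counts[r].sum())
            assert p > 0.01, f"T*={t}"


class TestProtocol:
    def test_frozen_schedule_constant_observables(self):
        obs = run_protocol(LatticeSpec(12), phi=0.06, temperatures=[1.5, 3.0],
                           schedule=Schedule(0, 0, 2000), seed=1, frozen=True)
        for o in obs:
            assert np.ptp(o.e_series) == 0
            assert np.ptp(o.rg2_series) == 0

    def test_bit_identical_for_same_seed(self):
        kw = dict(phi=0.06, temperatures=[1.5, 3.0],
                  schedule=Schedule(1000, 1000, 1000), seed=5)
        a = run_protocol(LatticeSpec(12), **kw)
        b = run_protocol(LatticeSpec(12), **kw)
        for oa, ob in zip(a, b):
            assert np.array_equal(oa.e_series, ob.e_series)
            assert np.array_equal(oa.na_series, ob.na_series)
            assert oa.phase_label == ob.phase_label

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            Schedule(-1, 0, 0)
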