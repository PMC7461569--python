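"""Morphology metrics and phase classification of aggregate configurations.

Each cluster of chains is unwrapped through the periodic boundaries and
characterized by three diagnostics:

* relative shape anisotropy (asphericity) κ² from the gyration-tensor
  eigenvalues — 0 for a sphere, 1 for a rod;
* percolation — whether the cluster connects to its own periodic image
  along x, y and/or z;
* branch points — occupied cells of a coarse (default 3a) grid over the
  cluster whose cell-adjacency degree is ≥ 3, a skeleton-level signature of
  Y-junctions.

Fixed, configurable threshold rules then map the diagnostics onto the
morphology labels used for the self-assembly phase diagram: micellar (M),
micellar/rod coexistence (M/R), rods turning into channels (R/CH),
three-dimensional channel networks (CH) and cylinders (C), plus
``disordered`` for fully dispersed chains.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .observables import find_clusters
from .state import LatticeState

__all__ = ["PhaseThresholds", "ClusterMetrics", "PhaseLabel", "cluster_metrics",
           "classify_phase"]


@dataclass(frozen=True)
class PhaseThresholds:
    """Threshold rules for the morphology labels (artifact choices)."""

    asphericity_elongated: float = 0.4   # κ² above which a cluster is rod-like
    branch_min: int = 2                  # skeleton branch points marking a network
    elongated_frac_mr: float = 0.10      # chain fraction in rods: M → M/R
    elongated_frac_rch: float = 0.50     # chain fraction in rods: M/R → R/CH
    cell: int = 3                        # coarse-grid edge for the skeleton


@dataclass
class ClusterMetrics:
    n_chains: int
    asphericity: float
    percolating_axes: tuple[bool, bool, bool]
    branch_points: int

    @property
    def n_percolating(self) -> int:
        return int(sum(self.percolating_axes))


@dataclass
class PhaseLabel:
    label: str
    metrics: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _cluster_sites(state: LatticeState, chains: list[int]) -> np.ndarray:
    N = state.topology.n_monomers
    return np.concatenate([state.chain_sites(c) for c in chains])


def _unwrap_cluster(state: LatticeState, sites: np.ndarray):
    """BFS unwrap of a connected site set through the periodic box.

    Returns (unwrapped coords, percolation flags per axis).  A revisit whose
    proposed unwrapped position disagrees with the stored one means the
    cluster wraps onto its own periodic image along the non-zero axes.
    """
    spec = state.spec
    nbr = state.nbr
    site_set = set(int(s) for s in sites)
    coords = {}
    perc = np.zeros(3, dtype=bool)
    start = int(sites[0])
    coords[start] = spec.coords(start).astype(np.int64)
    queue = deque([start])
    while queue:
        s = queue.popleft()
        cs = coords[s]
        ws = spec.coords(s)
        for t in nbr[s]:
            t = int(t)
            if t not in site_set:
                continue
            step = spec.minimum_image(spec.coords(t) - ws)
            proposal = cs + step
            if t in coords:
                diff = coords[t] - proposal
                perc |= diff != 0
            else:
                coords[t] = proposal
                queue.append(t)
    # chains are internally bonded, and clusters are defined by contacts, so
    # the site graph of a cluster is connected; assert to be safe
    if len(coords) != len(site_set):
        raise RuntimeError("cluster site graph unexpectedly disconnected")
    return np.array([coords[int(s)] for s in sites], dtype=np.int64), tuple(bool(x) for x in perc)


def _asphericity(xyz: np.ndarray) -> float:
    """Relative shape anisotropy κ² ∈ [0, 1] of a point set."""
    x = xyz.astype(float) - xyz.mean(axis=0)
    gyr = x.T @ x / len(x)
    lam = np.sort(np.linalg.eigvalsh(gyr))
    tr = lam.sum()
    if tr <= 0:
        return 0.0
    return float(1.5 * np.sum(lam**2) / tr**2 - 0.5)


def _branch_points(xyz: np.ndarray, cell: int) -> int:
    """Degree-≥3 nodes of the coarse occupied-cell skeleton (26-adjacency)."""
    cells = np.unique(xyz // cell, axis=0)
    cellset = set(map(tuple, cells))
    count = 0
    for c in cells:
        deg = 0
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    if (c[0] + dx, c[1] + dy, c[2] + dz) in cellset:
                        deg += 1
        if deg >= 3:
            count += 1
    return count


def cluster_metrics(state: LatticeState, chains: list[int],
                    thresholds: PhaseThresholds = PhaseThresholds()) -> ClusterMetrics:
    """Shape, percolation and branching diagnostics of one cluster."""
    sites = _cluster_sites(state, chains)
    xyz, perc = _unwrap_cluster(state, sites)
    return ClusterMetrics(
        n_chains=len(chains),
        asphericity=_asphericity(xyz),
        percolating_axes=perc,
        branch_points=_branch_points(xyz, thresholds.cell),
    )


def classify_phase(state: LatticeState, clusters: list[list[int]] | None = None,
                   thresholds: PhaseThresholds = PhaseThresholds()) -> PhaseLabel:
    """Deterministic morphology label from fixed threshold rules.

    Percolation dominates: a cluster spanning the box along ≥ 2 axes with a
    branched skeleton is a channel network (CH); spanning along one axis
    with an unbranched skeleton is cylindrical (C); a spanning but branched
    single-axis cluster is the rod/channel crossover (R/CH).  Otherwise the
    chain-weighted fraction of rod-like clusters (asphericity above the
    elongation threshold) grades M → M/R → R/CH.
    """
    if clusters is None:
        clusters = find_clusters(state)
    if not clusters:
        return PhaseLabel("disordered", [], {"reason": "no chains"})

    metrics = [cluster_metrics(state, g, thresholds) for g in clusters]
    perc = [m for m in metrics if m.n_percolating >= 1]
    diag = {"n_clusters": len(clusters)}
    if not perc and max(len(g) for g in clusters) <= 1:
        return PhaseLabel("disordered", metrics, {"reason": "no multi-chain aggregates"})
    if perc:
        best = max(perc, key=lambda m: (m.n_percolating, m.branch_points))
        diag["percolating_axes"] = best.n_percolating
        diag["branch_points"] = best.branch_points
        if best.n_percolating >= 2 and best.branch_points >= thresholds.branch_min:
            return PhaseLabel("CH", metrics, diag)
        if best.branch_points < thresholds.branch_min:
            return PhaseLabel("C", metrics, diag)
        return PhaseLabel("R/CH", metrics, diag)

    multi = [m for m in metrics if m.n_chains >= 2]
    chains_in_rods = sum(m.n_chains for m in multi
                         if m.asphericity > thresholds.asphericity_elongated)
    chains_total = sum(m.n_chains for m in multi)
    frac = chains_in_rods / chains_total if chains_total else 0.0
    diag["elongated_chain_fraction"] = frac
    if frac < thresholds.elongated_frac_mr:
        return PhaseLabel("M", metrics, diag)
    if frac < thresholds.elongated_frac_rch:
        return PhaseLabel("M/R", metrics, diag)
    return PhaseLabel("R/CH", metrics, diag)
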