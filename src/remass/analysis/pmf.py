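"""Dihedral free-energy profiles and basin states.

The potential of mean force along a periodic angle is the inverse-Boltzmann
transform of its histogram, G = -Rc T ln P, shifted so the global minimum is
zero; empty bins get G = +inf.  Basin states are carved around each local
minimum by the barrier rule: with G-dagger the maximum along the
minimum-free-energy escape path (the lower of the two directional barrier
maxima on the periodic profile), the state is the connected set of bins with
G < G-dagger - depth (depth 0.5 kcal/mol by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import constants as C

__all__ = ["PmfProfile", "StateDefinition", "pmf", "define_states",
           "state_populations", "REFERENCE_STATES"]

# Conventional alanine-dipeptide state boundaries (degrees), shipped as a
# reference configuration: each state is a list of (lo, hi) intervals on
# (-180, 180], periodic-aware (an interval with lo > hi wraps through 180).
REFERENCE_STATES = {
    "Phi1": [(168.0, -12.0)],      # phi < -12 or phi > 168, wrapping
    "Phi2": [(24.0, 108.0)],
    "Psi1": [(96.0, -144.0)],      # psi < -144 or psi > 96, wrapping
    "Psi2": [(-60.0, 48.0)],
}


@dataclass
class PmfProfile:
    angle_name: str
    edges: np.ndarray        # degrees, len n_bins + 1
    P: np.ndarray            # normalised bin probabilities
    G: np.ndarray            # kcal/mol, min-shifted, +inf on empty bins
    T: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class StateDefinition:
    name: str
    intervals: list[tuple[float, float]]   # degrees, wrap-aware
    barrier: float | None = None           # G-dagger, kcal/mol
    depth_cut: float = 0.5

    def contains(self, angles) -> np.ndarray:
        a = _wrap(np.asarray(angles, dtype=float))
        mask = np.zeros(a.shape, dtype=bool)
        for lo, hi in self.intervals:
            if lo <= hi:
                mask |= (a > lo) & (a <= hi)
            else:                           # wraps through 180/-180
                mask |= (a > lo) | (a <= hi)
        return mask


def _wrap(a):
    """Map angles to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def pmf(angles, bin_width: float = 12.0, T: float = 310.0,
        angle_name: str = "phi") -> PmfProfile:
    """Histogram PMF over (-180, 180] with periodic bins of `bin_width` deg."""
    a = _wrap(angles)
    if a.size == 0:
        raise ValueError("empty angle series")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(a, bins=edges)
    P = hist / hist.sum()
    with np.errstate(divide="ignore"):
        G = -C.KB * T * np.log(P)
    G -= G.min()
    return PmfProfile(angle_name=angle_name, edges=edges, P=P, G=G, T=T)


def _local_minima(G: np.ndarray) -> list[int]:
    n = len(G)
    out = []
    for i in range(n):
        g = G[i]
        if not np.isfinite(g):
            continue
        left, right = G[(i - 1) % n], G[(i + 1) % n]
        if g < left and g <= right:
            out.append(i)
    return out


def _directional_barrier(G: np.ndarray, start: int, step: int,
                         minima: set[int]) -> float:
    """Max G walking from `start` in direction `step` to the next minimum."""
    n = len(G)
    i = start
    barrier = G[start]
    for _ in range(n):
        i = (i + step) % n
        barrier = max(barrier, G[i])
        if i in minima:
            break
    return barrier


def define_states(profile: PmfProfile, depth: float = 0.5,
                  name_prefix: str | None = None) -> list[StateDefinition]:
    """Carve basin states from a 1D periodic PMF by the barrier-depth rule."""
    G = profile.G
    n = len(G)
    minima = _local_minima(G)
    if len(minima) < 2:
        # single-basin profile: the whole circle is one state
        return [StateDefinition(name=f"{name_prefix or profile.angle_name}1",
                                intervals=[(-180.0, 180.0)], barrier=None,
                                depth_cut=depth)]
    minset = set(minima)
    states = []
    # order states by basin depth (deepest first)
    for rank, i0 in enumerate(sorted(minima, key=lambda i: G[i]), start=1):
        up = _directional_barrier(G, i0, +1, minset - {i0})
        down = _directional_barrier(G, i0, -1, minset - {i0})
        gdag = min(up, down)
        cut = gdag - depth
        members = [i0]
        i = i0
        for _ in range(n):
            i = (i + 1) % n
            if np.isfinite(G[i]) and G[i] < cut and i not in members:
                members.append(i)
            else:
                break
        i = i0
        for _ in range(n):
            i = (i - 1) % n
            if np.isfinite(G[i]) and G[i] < cut and i not in members:
                members.insert(0, i)
            else:
                break
        intervals = _bins_to_intervals(sorted(set(members)), profile.edges)
        prefix = name_prefix or profile.angle_name
        states.append(StateDefinition(name=f"{prefix}{rank}",
                                      intervals=intervals, barrier=gdag,
                                      depth_cut=depth))
    return states


def _bins_to_intervals(bins: list[int], edges: np.ndarray) -> list[tuple[float, float]]:
    """Merge sorted bin indices (periodic) into angular intervals."""
    n = len(edges) - 1
    binset = set(bins)
    runs = []
    visited = set()
    for b in bins:
        if b in visited:
            continue
        start = b
        while (start - 1) % n in binset and (start - 1) % n != b:
            start = (start - 1) % n
            if start == b:
                break
        end = start
        run = [start]
        while (end + 1) % n in binset and (end + 1) % n != start:
            end = (end + 1) % n
            run.append(end)
        visited.update(run)
        runs.append((start, end))
    out = []
    for start, end in set(runs):
        out.append((float(edges[start]), float(edges[(end + 1) % n] if end + 1 <= n - 1 else edges[-1])))
    # wrap-around runs produce lo > hi, handled by StateDefinition.contains
    return sorted(out)


def state_populations(angles, states: list[StateDefinition]) -> dict[str, float]:
    """Occupancy fraction of each state's angular intervals."""
    a = _wrap(angles)
    if a.size == 0:
        raise ValueError("empty angle series")
    return {s.name: float(np.mean(s.contains(a))) for s in states}
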