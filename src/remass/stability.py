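"""Integrator-stability scan: find the smallest failing integration step.

An ensemble of short constant-temperature trajectories is run at each
integration step of a grid, reusing the same starting structures and noise
seeds across grid points (and across mass models) to control variance.  The
smallest step with at least one observed failure is reported as dt_f; the
largest step at which the whole ensemble survives is the recommended safe
step dt_s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import EngineConfig, Integrator
from .topology import SystemState, Topology

__all__ = ["StabilityReport", "scan_steps"]


@dataclass
class StabilityReport:
    model: str
    T: float
    dt_grid: list[float]
    failures: dict[float, int]         # dt -> number of failed trajectories
    n_traj: int
    dt_f: float | None                  # smallest dt with >= 1 failure
    dt_s: float | None                  # largest dt with zero failures

    def to_rows(self):
        return [(dt, self.failures[dt], self.n_traj) for dt in self.dt_grid]


def scan_steps(top: Topology, base: EngineConfig, T: float,
               dt_min: float, dt_max: float, dt_incr: float,
               n_traj: int, traj_steps: int,
               initial_states: list[SystemState] | None = None,
               seeds: list[int] | None = None,
               model: str = "") -> StabilityReport:
    """Sweep dt over [dt_min, dt_max] and count integrator failures.

    `initial_states` (one per trajectory, reused at every dt) and `seeds`
    pin the starting structures and noise streams so that different dt values
    and different mass models see identical initial conditions.  traj_steps
    is the per-trajectory length in steps at each dt.
    """
    grid = [round(dt_min + k * dt_incr, 10)
            for k in range(int(round((dt_max - dt_min) / dt_incr)) + 1)]
    if not grid:
        raise ValueError("empty dt grid")
    if seeds is None:
        seeds = list(range(n_traj))
    if len(seeds) != n_traj:
        raise ValueError("need one seed per trajectory")
    if initial_states is None or len(initial_states) != n_traj:
        raise ValueError("need one prepared initial state per trajectory")

    failures: dict[float, int] = {}
    for dt in grid:
        n_fail = 0
        for t in range(n_traj):
            cfg = EngineConfig(**{**base.__dict__, "dt": dt, "T": T,
                                  "seed": seeds[t]})
            rng = np.random.default_rng(np.random.SeedSequence([seeds[t], 7]))
            st = initial_states[t].copy()
            recs = Integrator(top, cfg, rng=rng).run(
                st, traj_steps, record_interval=traj_steps, store_coords=False)
            if recs and recs[-1].failed:
                n_fail += 1
        failures[dt] = n_fail

    failing = [dt for dt in grid if failures[dt] > 0]
    passing = [dt for dt in grid if failures[dt] == 0]
    return StabilityReport(model=model, T=T, dt_grid=grid, failures=failures,
                           n_traj=n_traj,
                           dt_f=min(failing) if failing else None,
                           dt_s=max(passing) if passing else None)
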