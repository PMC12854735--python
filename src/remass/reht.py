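"""Replica exchange with hybrid tempering (REHT).

Each of R replicas occupies one condition m = (T_m, T'_m, dt_m).  The solute
is fully tempered at T_m while solvent-involving interactions are scaled so
the solvent's effective temperature is T'_m <= T_m, through the hybrid
enthalpy

    H_m = E_p + (beta'_m / beta_m) (E_ps + E_s) + PV,

with beta'_m/beta_m = T_m/T'_m.  Adjacent conditions attempt a Metropolis
swap with probability omega = min(1, exp(-Delta)),

    Delta = beta_m [H_m(x_r') - H_m(x_r)] + beta_{m+1} [H_{m+1}(x_r) - H_{m+1}(x_r')],

where x_r, x_r' are the coordinates of the replicas currently at conditions
m and m+1.  Attempts alternate between even (0-1, 2-3, ...) and odd
(1-2, 3-4, ...) neighbour pairs; on acceptance the two replicas exchange
conditions and their velocities are rescaled by sqrt(T_new/T_old).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import EngineConfig, Integrator, StepResult, initialize_velocities
from .ladder import Condition, Ladder
from .topology import EnergyBreakdown, SystemState, Topology

__all__ = ["hybrid_enthalpy", "swap_delta", "SwapAttempt", "ReplicaLog", "run_reht"]


def hybrid_enthalpy(e: EnergyBreakdown, cond: Condition) -> float:
    """H_m = E_p + (T_m/T'_m)(E_ps + E_s) + PV, in kcal/mol."""
    scale = cond.beta_solv / cond.beta  # = T_m / T'_m
    return e.E_p + scale * (e.E_ps + e.E_s) + e.PV


def swap_delta(h_m_r: float, h_m_rp: float, h_mp1_r: float, h_mp1_rp: float,
               beta_m: float, beta_mp1: float) -> float:
    """Metropolis exponent for swapping the replicas at conditions m, m+1.

    Arguments are H_m and H_{m+1} evaluated on both replicas' coordinates
    (r currently at m, r' at m+1).  Antisymmetric under exchanging the two
    replicas.
    """
    return beta_m * (h_m_rp - h_m_r) + beta_mp1 * (h_mp1_r - h_mp1_rp)


@dataclass
class SwapAttempt:
    round: int
    pair: tuple[int, int]          # conditions (m, m+1)
    replicas: tuple[int, int]      # replica ids (at m, at m+1)
    delta: float
    omega: float
    rng_draw: float
    accepted: bool


@dataclass
class ReplicaLog:
    attempts: list[SwapAttempt] = field(default_factory=list)
    # walk[t][m] = replica occupying condition m after swap round t
    walk: list[list[int]] = field(default_factory=list)

    def acceptance_rate(self, m: int) -> float:
        """Fraction of accepted attempts for the neighbour pair (m, m+1)."""
        a = [s.accepted for s in self.attempts if s.pair == (m, m + 1)]
        return float(np.mean(a)) if a else float("nan")

    def check_permutation(self, R: int) -> bool:
        return all(sorted(row) == list(range(R)) for row in self.walk)


@dataclass
class RehtResult:
    log: ReplicaLog
    # per-condition demultiplexed records: condition m -> list of StepResult
    condition_records: list[list[StepResult]]
    # final replica states indexed by replica id
    replica_states: list[SystemState]
    failed: bool = False
    failure_info: tuple[int, float, float] | None = None  # (replica, dt, T)


def run_reht(top: Topology, initial_states: list[SystemState], ladder: Ladder,
             config: EngineConfig, n_swap_rounds: int, seed: int = 0,
             record_interval: int = 10, store_coords: bool = True) -> RehtResult:
    """Run the REHT protocol.

    `initial_states` holds one state per replica, replica r starting at
    condition r.  One root seed feeds fixed per-replica RNG streams plus a
    dedicated stream for the swap decisions.  Engine failure in any replica
    halts the run with the failing (replica, dt, T) identified.
    """
    R = ladder.R
    if len(initial_states) != R:
        raise ValueError(f"need {R} initial states, got {len(initial_states)}")
    rngs = [np.random.default_rng(np.random.SeedSequence([seed, 1000 + r]))
            for r in range(R)]
    swap_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    integrators = [Integrator(top, config, rng=rngs[r]) for r in range(R)]
    states = [s.copy() for s in initial_states]
    for r, st in enumerate(states):
        if st.velocities is None:
            st.velocities = initialize_velocities(top, ladder[r].T, rngs[r])

    cond_of = list(range(R))            # replica -> condition
    repl_at = list(range(R))            # condition -> replica
    log = ReplicaLog()
    cond_records: list[list[StepResult]] = [[] for _ in range(R)]
    last_energy: list[EnergyBreakdown | None] = [None] * R

    for rnd in range(n_swap_rounds):
        # MD segment for every replica at its condition
        for r in range(R):
            cond = ladder[cond_of[r]]
            recs = integrators[r].run(states[r], cond.steps_per_swap,
                                      record_interval=record_interval,
                                      store_coords=store_coords,
                                      dt=cond.dt, T=cond.T)
            if recs and recs[-1].failed:
                return RehtResult(log=log, condition_records=cond_records,
                                  replica_states=states, failed=True,
                                  failure_info=(r, cond.dt, cond.T))
            cond_records[cond.index].extend(recs)
            last_energy[r] = recs[-1].energies if recs else None

        # swap attempts: alternate even and odd neighbour pairs
        start = 0 if rnd % 2 == 0 else 1
        for m in range(start, R - 1, 2):
            r = repl_at[m]
            rp = repl_at[m + 1]
            e_r, e_rp = last_energy[r], last_energy[rp]
            if e_r is None or e_rp is None:
                continue
            cm, cmp1 = ladder[m], ladder[m + 1]
            delta = swap_delta(
                hybrid_enthalpy(e_r, cm), hybrid_enthalpy(e_rp, cm),
                hybrid_enthalpy(e_r, cmp1), hybrid_enthalpy(e_rp, cmp1),
                cm.beta, cmp1.beta)
            omega = min(1.0, float(np.exp(-delta)))
            draw = float(swap_rng.random())
            accepted = draw < omega
            log.attempts.append(SwapAttempt(round=rnd, pair=(m, m + 1),
                                            replicas=(r, rp), delta=delta,
                                            omega=omega, rng_draw=draw,
                                            accepted=accepted))
            if accepted:
                # exchange conditions; rescale velocities to the new bath
                cond_of[r], cond_of[rp] = m + 1, m
                repl_at[m], repl_at[m + 1] = rp, r
                scale_up = np.sqrt(cmp1.T / cm.T)
                states[r].velocities = states[r].velocities * scale_up
                states[rp].velocities = states[rp].velocities / scale_up
        log.walk.append(list(repl_at))

    return RehtResult(log=log, condition_records=cond_records,
                      replica_states=states)
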