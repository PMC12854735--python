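"""REHT condition schedule: temperature ladders and scaled integration steps.

Solute temperatures T_m are spaced exponentially between T_0 and T_{R-1};
solvent effective temperatures T'_m follow the same rule on their own
(narrower) range, with T'_0 = T_0.  Each condition carries an integration
step scaled as dt(T_m) = sqrt(T_0/T_m) * dt(T_0) — equal mean thermal
displacement per step at every rung — rounded to the nearest 0.1 fs.  The
number of integration steps between exchange attempts is fixed at the base
condition's value, so the wall-clock interval between attempts shrinks at the
hotter rungs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants as C

__all__ = ["Condition", "Ladder", "build_ladder", "scale_step"]


@dataclass(frozen=True)
class Condition:
    index: int
    T: float          # solute temperature, K
    T_solv: float     # solvent effective temperature, K
    dt: float         # fs
    steps_per_swap: int

    @property
    def beta(self) -> float:
        return 1.0 / (C.KB * self.T)

    @property
    def beta_solv(self) -> float:
        return 1.0 / (C.KB * self.T_solv)


@dataclass(frozen=True)
class Ladder:
    conditions: tuple[Condition, ...]

    @property
    def R(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def __getitem__(self, m: int) -> Condition:
        return self.conditions[m]


def scale_step(dt0: float, T0: float, Tm: float) -> float:
    """Temperature-scaled integration step sqrt(T0/Tm)*dt0, to 0.1 fs.

    Rounding (not flooring) to the nearest 0.1 fs: 3.5 fs at 310->430 K gives
    3.0 fs and 4.0 fs gives 3.4 fs.
    """
    if T0 <= 0 or Tm <= 0:
        raise ValueError("temperatures must be positive")
    return round(math.sqrt(T0 / Tm) * dt0, 1)


def _exponential(T0: float, Tmax: float, R: int, m: int) -> float:
    return T0 * (Tmax / T0) ** (m / (R - 1))


def build_ladder(R: int, T0: float = 310.0, Tmax: float = 430.0,
                 T0_solv: float | None = None, Tmax_solv: float = 350.0,
                 dt0: float = 1.0, swap_interval_ps: float = 2.0) -> Ladder:
    """Build the R-condition REHT schedule.

    T0_solv defaults to T0 (the base condition is untampered).  Raises if the
    solvent ladder ever exceeds the solute ladder.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    if not T0 < Tmax:
        raise ValueError("need T0 < Tmax")
    if T0_solv is None:
        T0_solv = T0
    if Tmax_solv > Tmax:
        raise ValueError("solvent ladder top must not exceed the solute ladder top")
    if dt0 <= 0:
        raise ValueError("dt0 must be positive")
    steps_per_swap = round(swap_interval_ps * 1000.0 / dt0)
    conds = []
    for m in range(R):
        Tm = _exponential(T0, Tmax, R, m)
        Tsm = _exponential(T0_solv, Tmax_solv, R, m)
        if Tsm > Tm + 1e-9:
            raise ValueError(f"condition {m}: solvent temperature {Tsm:.2f} K "
                             f"exceeds solute temperature {Tm:.2f} K")
        dt = dt0 if m == 0 else scale_step(dt0, T0, Tm)
        conds.append(Condition(index=m, T=Tm, T_solv=Tsm, dt=dt,
                               steps_per_swap=steps_per_swap))
    return Ladder(conditions=tuple(conds))
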