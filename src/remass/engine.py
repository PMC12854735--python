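"""Constrained Langevin dynamics in the NVT ensemble.

The integrator is the BAOAB splitting of underdamped Langevin dynamics, which
retains good configurational accuracy at the large integration steps that the
mass models are designed to enable.  Fixed-length bond constraints (all X-H
bonds and the three constraints of each rigid water) are enforced by
iterative SHAKE position projections inside each A half-step and RATTLE
velocity projections after every velocity update; a per-water direct variant
("settle") converges the same three-constraint system molecule by molecule.
With gamma = 0 and no constraints the scheme reduces exactly to velocity
Verlet.

Failures (non-finite values, runaway potential energy, non-converging
constraints) are recorded on the step result and truncate the trajectory;
they are never raised mid-run, because the integrator-stability scan consumes
them as data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .energy import NonbondedConfig, PairTable, compute_energies
from .topology import EnergyBreakdown, SystemState, Topology

__all__ = [
    "EngineConfig",
    "StepResult",
    "Integrator",
    "integrate",
    "count_dof",
    "detect_failure",
    "initialize_velocities",
    "kinetic_energy",
    "minimize_energy",
]


@dataclass
class EngineConfig:
    T: float                          # K
    dt: float                         # fs
    gamma: float = 5.0                # ps^-1 Langevin damping
    constraint_tol: float = 1e-8      # Å (relative, on squared lengths)
    constraint_max_iter: int = 500
    rigid_scheme: str = "rattle"      # "rattle" | "settle"
    seed: int = 0
    failure_energy_threshold: float = 1000.0  # kcal/mol per atom
    r_on: float | None = None
    r_off: float | None = None

    def nonbonded(self, box_edge: float | None) -> NonbondedConfig:
        if self.r_on is not None and self.r_off is not None:
            return NonbondedConfig(self.r_on, self.r_off)
        return NonbondedConfig.for_box(box_edge)


@dataclass
class StepResult:
    state: SystemState
    energies: EnergyBreakdown
    kinetic: float                 # kcal/mol
    failed: bool = False
    reason: str = ""


def count_dof(top: Topology) -> int:
    """Degrees of freedom: 3N minus active distance constraints.

    No centre-of-mass subtraction: the Langevin thermostat does not conserve
    the total momentum.
    """
    return 3 * top.n_atoms - len(top.constraints)


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """0.5 m v^2 summed, in kcal/mol (v in Å/fs, m in amu)."""
    return float(0.5 * np.sum(masses[:, None] * velocities ** 2) / C.KE_CONV)


def initialize_velocities(top: Topology, T: float, rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann draw at T followed by constraint velocity projection."""
    m = top.masses
    sigma = np.sqrt(C.KB * T * C.KE_CONV / m)
    v = rng.normal(size=(top.n_atoms, 3)) * sigma[:, None]
    if top.constraints:
        solver = _ConstraintSolver(top)
        v, _ = solver.project_velocities(None, v, coords_for_bonds=None)
    return v


def detect_failure(prev: StepResult | None, nxt: StepResult) -> tuple[bool, str]:
    """Failure test applied every step; the reason names the trigger."""
    if nxt.failed and nxt.reason:
        return True, nxt.reason
    x = nxt.state.coords
    if not np.isfinite(x).all():
        return True, "non-finite"
    e = nxt.energies
    if not (np.isfinite(e.E_p) and np.isfinite(e.E_ps) and np.isfinite(e.E_s)
            and np.isfinite(nxt.kinetic)):
        return True, "non-finite"
    return False, ""


class _ConstraintSolver:
    """Matrix SHAKE/RATTLE: direct dense solves of the constraint equations.

    With J the constraint Jacobian (rows +-r_k on the two atoms of
    constraint k), the RATTLE velocity projection solves the linear system
    (J M^-1 J^T) lam = -J v exactly; the SHAKE position projection iterates
    Newton steps on the same matrix built from the reference bond directions.
    The couplings between constraints sharing an atom (rigid waters, methyl
    groups) are handled exactly, so no sweeping is needed.
    """

    def __init__(self, top: Topology, tol: float = 1e-8, max_iter: int = 500,
                 scheme: str = "rattle"):
        self.i = np.array([c.i for c in top.constraints], dtype=int)
        self.j = np.array([c.j for c in top.constraints], dtype=int)
        self.d2 = np.array([c.length ** 2 for c in top.constraints])
        m = top.masses
        self.invm = 1.0 / m
        self.inv_mi = self.invm[self.i] if len(self.i) else np.empty(0)
        self.inv_mj = self.invm[self.j] if len(self.j) else np.empty(0)
        self.tol = tol
        self.max_iter = max_iter
        self.scheme = scheme
        nc = len(self.i)
        # sparsity pattern of A = J M^-1 J^T: constraint pairs sharing an atom
        rows, cols, signs, minv = [], [], [], []
        atom_map: dict[int, list[tuple[int, int]]] = {}
        for k in range(nc):
            atom_map.setdefault(self.i[k], []).append((k, +1))
            atom_map.setdefault(self.j[k], []).append((k, -1))
        for atom, entries in atom_map.items():
            for k, sk in entries:
                for l, sl in entries:
                    if k == l:
                        continue
                    rows.append(k)
                    cols.append(l)
                    signs.append(sk * sl)
                    minv.append(self.invm[atom])
        self._od_rows = np.array(rows, dtype=int)
        self._od_cols = np.array(cols, dtype=int)
        self._od_coef = np.array(signs, dtype=float) * np.array(minv)

    @property
    def n(self) -> int:
        return len(self.i)

    def _matrix(self, r: np.ndarray) -> np.ndarray:
        """A_kl = sum_shared_atoms s_k s_l m_a^-1 (r_k . r_l)."""
        nc = self.n
        a = np.zeros((nc, nc))
        a[np.arange(nc), np.arange(nc)] = (
            (self.inv_mi + self.inv_mj) * np.einsum("ij,ij->i", r, r))
        if self._od_rows.size:
            dots = np.einsum("ij,ij->i", r[self._od_rows], r[self._od_cols])
            np.add.at(a, (self._od_rows, self._od_cols), self._od_coef * dots)
        return a

    def _apply(self, arr: np.ndarray, lam: np.ndarray, r: np.ndarray) -> np.ndarray:
        """arr += M^-1 J^T lam (in place on a copy)."""
        corr = lam[:, None] * r
        out = arr.copy()
        for d in range(3):
            out[:, d] += np.bincount(self.i, weights=corr[:, d] * self.inv_mi,
                                     minlength=arr.shape[0])
            out[:, d] -= np.bincount(self.j, weights=corr[:, d] * self.inv_mj,
                                     minlength=arr.shape[0])
        return out

    def shake(self, x: np.ndarray, x_ref: np.ndarray) -> tuple[np.ndarray, bool]:
        """Project positions onto the constraint manifold.

        x_ref are the pre-move positions (already on the manifold); their
        bond vectors define the correction directions, as in classic SHAKE.
        Returns (positions, converged).
        """
        if self.n == 0:
            return x, True
        r0 = x_ref[self.i] - x_ref[self.j]
        thresh = self.tol * np.max(self.d2)
        try:
            for _ in range(self.max_iter):
                s = x[self.i] - x[self.j]
                g = np.einsum("ij,ij->i", s, s) - self.d2
                if np.max(np.abs(g)) < thresh:
                    return x, True
                # Newton step on |x_i - x_j|^2 with directions r0
                a = 2.0 * self._matrix_cross(s, r0)
                lam = np.linalg.solve(a, -g)
                x = self._apply(x, lam, r0)
        except np.linalg.LinAlgError:
            return x, False
        return x, False

    def _matrix_cross(self, s: np.ndarray, r0: np.ndarray) -> np.ndarray:
        """A_kl = sum_shared s_k s_l m_a^-1 (s_k . r0_l) (Newton Jacobian)."""
        nc = self.n
        a = np.zeros((nc, nc))
        a[np.arange(nc), np.arange(nc)] = (
            (self.inv_mi + self.inv_mj) * np.einsum("ij,ij->i", s, r0))
        if self._od_rows.size:
            dots = np.einsum("ij,ij->i", s[self._od_rows], r0[self._od_cols])
            np.add.at(a, (self._od_rows, self._od_cols), self._od_coef * dots)
        return a

    def project_velocities(self, x: np.ndarray | None, v: np.ndarray,
                           coords_for_bonds: np.ndarray | None = None
                           ) -> tuple[np.ndarray, bool]:
        """RATTLE velocity projection: zero relative velocity along bonds."""
        if self.n == 0:
            return v, True
        if coords_for_bonds is None:
            coords_for_bonds = x
        if coords_for_bonds is None:
            return v, True
        r = coords_for_bonds[self.i] - coords_for_bonds[self.j]
        rv = np.einsum("ij,ij->i", r, v[self.i] - v[self.j])
        try:
            lam = np.linalg.solve(self._matrix(r), -rv)
        except np.linalg.LinAlgError:
            return v, False
        return self._apply(v, lam, r), True


class Integrator:
    """BAOAB Langevin integrator bound to one topology."""

    def __init__(self, top: Topology, config: EngineConfig,
                 rng: np.random.Generator | None = None):
        top.validate()
        self.top = top
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.table = PairTable(top)
        self.solver = _ConstraintSolver(top, tol=config.constraint_tol,
                                        max_iter=config.constraint_max_iter,
                                        scheme=config.rigid_scheme)
        self.masses = top.masses
        self.invm = 1.0 / self.masses

    def _forces(self, state: SystemState):
        nb = self.config.nonbonded(state.box_edge)
        return compute_energies(self.top, state, nb, self.table)

    def run(self, state: SystemState, n_steps: int,
            record_interval: int = 1, store_coords: bool = True,
            dt: float | None = None, T: float | None = None) -> list[StepResult]:
        """Integrate n_steps; returns recorded StepResults (failures truncate).

        dt and T override the config values (the REHT controller moves a
        replica between conditions without rebuilding the integrator).
        """
        cfg = self.config
        dt = cfg.dt if dt is None else dt
        T = cfg.T if T is None else T
        x = state.coords.copy()
        box = state.box_edge
        if state.velocities is None:
            v = initialize_velocities(self.top, T, self.rng)
        else:
            v = state.velocities.copy()

        c1 = np.exp(-cfg.gamma * dt * 1e-3)   # gamma ps^-1, dt fs
        noise_sigma = np.sqrt((1.0 - c1 * c1) * C.KB * T * C.KE_CONV * self.invm)
        half_kick = 0.5 * dt * C.ACC_CONV * self.invm[:, None]
        half_dt = 0.5 * dt

        st = SystemState(coords=x, velocities=v, box_edge=box, time=state.time)
        breakdown, forces, finite = self._forces(st)
        records: list[StepResult] = []
        prev_result: StepResult | None = None

        for step in range(1, n_steps + 1):
            fail_reason = ""
            # B
            v = v + half_kick * forces
            v, ok = self.solver.project_velocities(x, v)
            if not ok:
                fail_reason = "constraint"
            # A
            x_ref = x
            x_unc = x + half_dt * v
            x, ok = self.solver.shake(x_unc, x_ref)
            if not ok:
                fail_reason = fail_reason or "constraint"
            if self.solver.n:
                v = v + (x - x_unc) / half_dt
            # O
            if cfg.gamma > 0.0:
                v = c1 * v + noise_sigma[:, None] * self.rng.normal(size=v.shape)
                v, ok = self.solver.project_velocities(x, v)
                if not ok:
                    fail_reason = fail_reason or "constraint"
            # A
            x_ref = x
            x_unc = x + half_dt * v
            x, ok = self.solver.shake(x_unc, x_ref)
            if not ok:
                fail_reason = fail_reason or "constraint"
            if self.solver.n:
                v = v + (x - x_unc) / half_dt
            # force evaluation + B
            st = SystemState(coords=x, velocities=v, box_edge=box,
                             time=state.time + step * dt * 1e-3)
            breakdown, forces, finite = self._forces(st)
            if not finite:
                fail_reason = fail_reason or "non-finite"
            v = v + half_kick * forces
            v, ok = self.solver.project_velocities(x, v)
            if not ok:
                fail_reason = fail_reason or "constraint"

            ek = kinetic_energy(v, self.masses)
            if (breakdown.total_potential / self.top.n_atoms
                    > cfg.failure_energy_threshold):
                fail_reason = fail_reason or "energy-threshold"
            rec_state = SystemState(
                coords=x.copy() if store_coords else x[:0].copy(),
                velocities=v.copy() if store_coords else None,
                box_edge=box, time=st.time)
            result = StepResult(state=rec_state, energies=breakdown,
                                kinetic=ek, failed=bool(fail_reason),
                                reason=fail_reason)
            failed, reason = detect_failure(prev_result, result)
            if failed:
                result.failed, result.reason = True, reason
                records.append(result)
                break
            prev_result = result
            if step % record_interval == 0 or step == n_steps:
                records.append(result)

        # write back final phase-space point
        state.coords = x
        state.velocities = v
        state.time = st.time
        return records


def integrate(top: Topology, state: SystemState, config: EngineConfig,
              n_steps: int, rng: np.random.Generator | None = None,
              record_interval: int = 1, store_coords: bool = True) -> list[StepResult]:
    """One-shot convenience wrapper around :class:`Integrator`."""
    return Integrator(top, config, rng).run(state, n_steps,
                                            record_interval=record_interval,
                                            store_coords=store_coords)


def minimize_energy(top: Topology, state: SystemState, maxiter: int = 300,
                    constraint_k: float = 2000.0, max_disp: float = 0.2
                    ) -> SystemState:
    """Relax a configuration by clamped adaptive steepest descent.

    Rigid constraints are represented by stiff harmonic restraints during the
    descent and re-projected exactly afterwards.  Per-iteration displacements
    are clamped to `max_disp` Å, which keeps the descent stable on the steep
    Lennard-Jones wall of freshly placed solvent.
    """
    nb = NonbondedConfig.for_box(state.box_edge)
    table = PairTable(top)
    ci = np.array([c.i for c in top.constraints], dtype=int)
    cj = np.array([c.j for c in top.constraints], dtype=int)
    cl = np.array([c.length for c in top.constraints])

    def energy_forces(x):
        st = SystemState(coords=x, box_edge=state.box_edge)
        eb, f, _ = compute_energies(top, st, nb, table)
        e = eb.total_potential
        if len(ci):
            d = x[ci] - x[cj]
            r = np.linalg.norm(d, axis=1)
            e += float(np.sum(constraint_k * (r - cl) ** 2))
            pair = (2.0 * constraint_k * (r - cl) / r)[:, None] * d
            np.add.at(f, ci, -pair)
            np.add.at(f, cj, pair)
        return e, f

    x = state.coords.copy()
    e, f = energy_forces(x)
    step = 1e-4
    for _ in range(maxiter):
        disp = step * f
        norms = np.linalg.norm(disp, axis=1)
        big = norms > max_disp
        if big.any():
            disp[big] *= (max_disp / norms[big])[:, None]
        e_new, f_new = energy_forces(x + disp)
        if np.isfinite(e_new) and e_new < e:
            x = x + disp
            e, f = e_new, f_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    if len(ci):
        # project back onto the constraint manifold; the stiff restraints
        # keep x close to it, so x itself supplies the bond directions
        solver = _ConstraintSolver(top)
        x, _ = solver.shake(x, x)
    return SystemState(coords=x, velocities=None, box_edge=state.box_edge,
                       time=state.time)
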