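"""Decomposed potential energy and analytic forces.

Nonbonded terms (Lennard-Jones in the epsilon/rmin convention and Coulomb)
are smoothly switched off over a window [r_on, r_off] with the standard cubic
switching function, under the minimum-image convention in a cubic box.  Every
pair term is assigned to one of three buckets by the solute/solvent identity
of its members: solute-solute (E_p, which also receives all bonded terms),
solute-solvent (E_ps) and solvent-solvent (E_s).  Forces are the exact
negative gradient of the implemented energy; non-finite results are flagged,
not raised, so the integrator's failure detection can consume them.

All terms are evaluated as flat numpy batches; `PairTable` caches the pair
list, exclusions, mixed parameters and bonded index arrays per topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .topology import EnergyBreakdown, SystemState, Topology

__all__ = ["NonbondedConfig", "PairTable", "compute_energies", "default_switching_window"]

_DEFAULT_R_ON = 8.0
_DEFAULT_R_OFF = 12.0


def default_switching_window(box_edge: float | None) -> tuple[float, float]:
    """Default switching window, shrunk proportionally for small boxes.

    The canonical window is 8-12 Å; when half the box edge is below 12 Å the
    whole window is scaled by (box/2)/12 so the cutoff never exceeds the
    minimum-image radius.
    """
    if box_edge is None:
        return (np.inf, np.inf)
    half = box_edge / 2.0
    if half >= _DEFAULT_R_OFF:
        return (_DEFAULT_R_ON, _DEFAULT_R_OFF)
    scale = half / _DEFAULT_R_OFF
    return (_DEFAULT_R_ON * scale, _DEFAULT_R_OFF * scale)


@dataclass(frozen=True)
class NonbondedConfig:
    r_on: float
    r_off: float

    @classmethod
    def for_box(cls, box_edge: float | None) -> "NonbondedConfig":
        return cls(*default_switching_window(box_edge))


class PairTable:
    """Precomputed interaction tables for one topology.

    Nonbonded exclusions: 1-2 pairs (bonds and rigid constraints), 1-3 pairs
    and all intra-water pairs; 1-4 and beyond interact at full strength.
    """

    def __init__(self, top: Topology):
        n = top.n_atoms
        self.n = n
        adj: list[set[int]] = [set() for _ in range(n)]
        for b in top.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        for c in top.constraints:
            adj[c.i].add(c.j)
            adj[c.j].add(c.i)
        excluded: set[tuple[int, int]] = set()
        for i in range(n):
            for j in adj[i]:
                excluded.add((min(i, j), max(i, j)))
                for k in adj[j]:
                    if k != i:
                        excluded.add((min(i, k), max(i, k)))
        mol = top.molecule_ids
        water = np.array([a.is_water for a in top.atoms])

        ii, jj = np.triu_indices(n, k=1)
        keep = np.ones(ii.shape, dtype=bool)
        if excluded:
            exc = np.array(sorted(excluded))
            flat = ii.astype(np.int64) * n + jj
            exc_flat = exc[:, 0].astype(np.int64) * n + exc[:, 1]
            keep &= ~np.isin(flat, exc_flat)
        keep &= ~(water[ii] & water[jj] & (mol[ii] == mol[jj]))
        self.i = ii[keep]
        self.j = jj[keep]

        eps = np.array([a.lj_epsilon for a in top.atoms])
        rmh = np.array([a.lj_rmin_half for a in top.atoms])
        q = top.charges
        self.eps_ij = np.sqrt(eps[self.i] * eps[self.j])
        self.rmin_ij = rmh[self.i] + rmh[self.j]
        self.qq_ij = C.COULOMB * q[self.i] * q[self.j]
        # bucket: 0 = solute-solute, 1 = mixed, 2 = solvent-solvent
        self.bucket = water[self.i].astype(int) + water[self.j].astype(int)

        # bonded index/parameter arrays
        self.b_i = np.array([b.i for b in top.bonds], dtype=int)
        self.b_j = np.array([b.j for b in top.bonds], dtype=int)
        self.b_k = np.array([b.k for b in top.bonds])
        self.b_r0 = np.array([b.r0 for b in top.bonds])
        self.a_i = np.array([a.i for a in top.angles], dtype=int)
        self.a_j = np.array([a.j for a in top.angles], dtype=int)
        self.a_k = np.array([a.k for a in top.angles], dtype=int)
        self.a_kth = np.array([a.k_theta for a in top.angles])
        self.a_th0 = np.array([a.theta0 for a in top.angles])
        self.d_i = np.array([d.i for d in top.dihedrals], dtype=int)
        self.d_j = np.array([d.j for d in top.dihedrals], dtype=int)
        self.d_k = np.array([d.k for d in top.dihedrals], dtype=int)
        self.d_l = np.array([d.l for d in top.dihedrals], dtype=int)
        self.d_kphi = np.array([d.k_phi for d in top.dihedrals])
        self.d_n = np.array([d.n for d in top.dihedrals])
        self.d_delta = np.array([d.delta for d in top.dihedrals])


def _switch(r2: np.ndarray, r_on: float, r_off: float):
    """Switching function S(r) and dS/dr evaluated from r^2."""
    if not np.isfinite(r_off):
        return np.ones_like(r2), np.zeros_like(r2)
    ron2, roff2 = r_on * r_on, r_off * r_off
    denom = (roff2 - ron2) ** 3
    s = np.ones_like(r2)
    ds_dr = np.zeros_like(r2)
    mid = (r2 > ron2) & (r2 < roff2)
    r2m = r2[mid]
    s[mid] = (roff2 - r2m) ** 2 * (roff2 + 2.0 * r2m - 3.0 * ron2) / denom
    r = np.sqrt(r2m)
    ds_dr[mid] = 12.0 * r * (roff2 - r2m) * (ron2 - r2m) / denom
    s[r2 >= roff2] = 0.0
    return s, ds_dr


def _mi(d, box):
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def _acc(forces, idx, vec):
    n = forces.shape[0]
    for d in range(3):
        forces[:, d] += np.bincount(idx, weights=vec[:, d], minlength=n)


def compute_energies(top: Topology, state: SystemState,
                     config: NonbondedConfig | None = None,
                     table: PairTable | None = None,
                     pressure_atm: float = 1.0):
    """Return (EnergyBreakdown, forces [kcal/mol/Å], finite flag).

    `table` may be supplied to amortise pair-list construction across many
    calls on the same topology (the MD engine does this).
    """
    if config is None:
        config = NonbondedConfig.for_box(state.box_edge)
    if table is None:
        table = PairTable(top)
    x = state.coords
    box = state.box_edge
    n = top.n_atoms
    forces = np.zeros((n, 3))
    e_bucket = np.zeros(3)   # solute-solute, mixed, solvent-solvent

    # --- nonbonded ---
    if table.i.size:
        d = _mi(x[table.i] - x[table.j], box)
        r2 = np.einsum("ij,ij->i", d, d)
        if np.isfinite(config.r_off):
            live = r2 < config.r_off ** 2
        else:
            live = slice(None)
        dl = d[live]
        r2l = r2[live]
        if r2l.size:
            with np.errstate(all="ignore"):   # blowups are flagged, not raised
                r = np.sqrt(r2l)
                inv_r = 1.0 / r
                sr6 = (table.rmin_ij[live] * inv_r) ** 6
                v_lj = table.eps_ij[live] * (sr6 * sr6 - 2.0 * sr6)
                dv_lj = table.eps_ij[live] * 12.0 * (sr6 - sr6 * sr6) * inv_r
                v_c = table.qq_ij[live] * inv_r
                dv_c = -v_c * inv_r
                s, ds = _switch(r2l, config.r_on, config.r_off)
                v = v_lj + v_c
                dv = (dv_lj + dv_c) * s + v * ds
                pairvec = (dv * inv_r)[:, None] * dl  # dV/dr * unit vector
            _acc(forces, table.i[live], -pairvec)
            _acc(forces, table.j[live], pairvec)
            np.add.at(e_bucket, table.bucket[live], v * s)

    # --- bonded (all assigned to the solute bucket) ---
    eb = 0.0
    if table.b_i.size:
        d = _mi(x[table.b_i] - x[table.b_j], box)
        r = np.linalg.norm(d, axis=1)
        eb += float(np.sum(table.b_k * (r - table.b_r0) ** 2))
        f = (-2.0 * table.b_k * (r - table.b_r0) / r)[:, None] * d
        _acc(forces, table.b_i, f)
        _acc(forces, table.b_j, -f)
    if table.a_i.size:
        eb += _angle_terms(x, table, forces, box)
    if table.d_i.size:
        eb += _dihedral_terms(x, table, forces, box)
    e_bucket[0] += eb

    pv = 0.0
    if box is not None:
        pv = pressure_atm * box ** 3 * C.ATM_A3_TO_KCALMOL
    breakdown = EnergyBreakdown(E_p=e_bucket[0], E_ps=e_bucket[1], E_s=e_bucket[2], PV=pv)
    finite = bool(np.isfinite(e_bucket).all() and np.isfinite(forces).all())
    return breakdown, forces, finite


def _angle_terms(x, t: PairTable, forces, box) -> float:
    rij = _mi(x[t.a_i] - x[t.a_j], box)
    rkj = _mi(x[t.a_k] - x[t.a_j], box)
    nij = np.linalg.norm(rij, axis=1)
    nkj = np.linalg.norm(rkj, axis=1)
    cost = np.clip(np.einsum("ij,ij->i", rij, rkj) / (nij * nkj), -1.0, 1.0)
    theta = np.arccos(cost)
    sint = np.sqrt(np.maximum(1.0 - cost * cost, 1e-12))
    dv = 2.0 * t.a_kth * (theta - t.a_th0)
    coef = (dv / sint)[:, None]
    fi = coef * (rkj / (nij * nkj)[:, None] - (cost / (nij * nij))[:, None] * rij)
    fk = coef * (rij / (nij * nkj)[:, None] - (cost / (nkj * nkj))[:, None] * rkj)
    _acc(forces, t.a_i, fi)
    _acc(forces, t.a_k, fk)
    _acc(forces, t.a_j, -(fi + fk))
    return float(np.sum(t.a_kth * (theta - t.a_th0) ** 2))


def _dihedral_terms(x, t: PairTable, forces, box) -> float:
    b1 = _mi(x[t.d_j] - x[t.d_i], box)
    b2 = _mi(x[t.d_k] - x[t.d_j], box)
    b3 = _mi(x[t.d_l] - x[t.d_k], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m = np.cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.einsum("ij,ij->i", m, n2), np.einsum("ij,ij->i", n1, n2))
    arg = t.d_n * phi - t.d_delta
    e = float(np.sum(t.d_kphi * (1.0 + np.cos(arg))))
    dv_dphi = -t.d_kphi * t.d_n * np.sin(arg)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    dphi_di = (nb2 / n1sq)[:, None] * n1
    dphi_dl = -(nb2 / n2sq)[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2)
    c32 = np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2)
    dphi_dj = -(1.0 + c12)[:, None] * dphi_di + c32[:, None] * dphi_dl
    dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
    coef = dv_dphi[:, None]
    _acc(forces, t.d_i, -coef * dphi_di)
    _acc(forces, t.d_j, -coef * dphi_dj)
    _acc(forces, t.d_k, -coef * dphi_dk)
    _acc(forces, t.d_l, -coef * dphi_dl)
    return e
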