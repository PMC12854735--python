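"""Synthetic solvated-dipeptide system builder.

Builds a 22-atom capped-alanine-like solute (CH3-CO-NH-CaH(CH3)-CO-NH-CH3,
exposing the phi and psi backbone torsions, two carbonyl-oxygen acceptors and
two amide-hydrogen donors) plus rigid three-site waters in a periodic cube.
Parameters are generic packaged values chosen for numerical robustness, not a
published force field: heavy-atom bond and angle reference values are taken
from the built geometry itself, so the constructed solute is a minimum of its
own bonded terms.
"""

from __future__ import annotations

import math

import numpy as np

from . import constants as C
from .geometry import angle_between, place_atom
from .topology import (
    AngleTerm,
    Atom,
    BondTerm,
    Constraint,
    DihedralTerm,
    SystemState,
    Topology,
)

__all__ = ["build_toy_system", "PlacementError", "build_water_topology"]

D = math.radians


class PlacementError(RuntimeError):
    """Raised when solvent cannot be placed at the requested density."""


# name -> (element, charge, lj_eps, lj_rmin_half)
_SOLUTE_NB = {
    "CAY": ("C", -0.27, 0.080, 2.00),
    "HY1": ("H", 0.09, 0.024, 1.34),
    "HY2": ("H", 0.09, 0.024, 1.34),
    "HY3": ("H", 0.09, 0.024, 1.34),
    "CY": ("C", 0.51, 0.070, 2.00),
    "OY": ("O", -0.51, 0.120, 1.70),
    "N": ("N", -0.47, 0.200, 1.85),
    "HN": ("H", 0.31, 0.046, 0.2245),
    "CA": ("C", 0.07, 0.056, 2.01),
    "HA": ("H", 0.09, 0.022, 1.32),
    "CB": ("C", -0.27, 0.078, 2.05),
    "HB1": ("H", 0.09, 0.024, 1.34),
    "HB2": ("H", 0.09, 0.024, 1.34),
    "HB3": ("H", 0.09, 0.024, 1.34),
    "C": ("C", 0.51, 0.070, 2.00),
    "O": ("O", -0.51, 0.120, 1.70),
    "NT": ("N", -0.47, 0.200, 1.85),
    "HNT": ("H", 0.31, 0.046, 0.2245),
    "CAT": ("C", -0.11, 0.080, 2.00),
    "HT1": ("H", 0.09, 0.024, 1.34),
    "HT2": ("H", 0.09, 0.024, 1.34),
    "HT3": ("H", 0.09, 0.024, 1.34),
}

_MASS = {"C": 12.011, "O": 15.9994, "N": 14.007, "H": 1.0080}

# covalent bonds of the solute; X-H bonds become rigid constraints
_SOLUTE_BONDS = [
    ("CAY", "HY1"), ("CAY", "HY2"), ("CAY", "HY3"),
    ("CAY", "CY"), ("CY", "OY"), ("CY", "N"),
    ("N", "HN"), ("N", "CA"), ("CA", "HA"), ("CA", "CB"),
    ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3"),
    ("CA", "C"), ("C", "O"), ("C", "NT"),
    ("NT", "HNT"), ("NT", "CAT"),
    ("CAT", "HT1"), ("CAT", "HT2"), ("CAT", "HT3"),
]

_BOND_K = 300.0      # kcal/mol/Å^2 (heavy-heavy flexible bonds)
_ANGLE_K = 45.0      # kcal/mol/rad^2

# cosine torsions: (a, b, c, d, k_phi kcal/mol, n, delta rad)
_SOLUTE_DIHEDRALS = [
    ("CY", "N", "CA", "C", 1.0, 3, 0.0),        # phi
    ("N", "CA", "C", "NT", 0.8, 3, 0.0),        # psi
    ("CAY", "CY", "N", "CA", 8.0, 2, math.pi),  # omega (planar amide)
    ("CA", "C", "NT", "CAT", 8.0, 2, math.pi),  # omega'
]


def _solute_coords(phi: float = D(-80.0), psi: float = D(150.0)) -> dict[str, np.ndarray]:
    """Idealised solute geometry from internal coordinates."""
    x: dict[str, np.ndarray] = {}
    x["CAY"] = np.zeros(3)
    x["CY"] = np.array([1.52, 0.0, 0.0])
    # OY in the xy plane
    ang = D(121.0)
    x["OY"] = x["CY"] + 1.23 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    p = place_atom
    x["N"] = p(x["OY"], x["CAY"], x["CY"], 1.335, D(116.0), math.pi)
    x["HN"] = p(x["CAY"], x["CY"], x["N"], 1.01, D(119.0), 0.0)
    x["CA"] = p(x["CAY"], x["CY"], x["N"], 1.45, D(122.0), math.pi)
    x["C"] = p(x["CY"], x["N"], x["CA"], 1.52, D(111.0), phi)
    x["CB"] = p(x["CY"], x["N"], x["CA"], 1.53, D(110.5), phi + D(122.0))
    x["HA"] = p(x["CY"], x["N"], x["CA"], 1.09, D(108.0), phi - D(119.0))
    x["O"] = p(x["N"], x["CA"], x["C"], 1.23, D(121.0), psi + math.pi)
    x["NT"] = p(x["N"], x["CA"], x["C"], 1.335, D(116.0), psi)
    x["HNT"] = p(x["CA"], x["C"], x["NT"], 1.01, D(119.0), 0.0)
    x["CAT"] = p(x["CA"], x["C"], x["NT"], 1.45, D(122.0), math.pi)
    for i, name in enumerate(("HY1", "HY2", "HY3")):
        x[name] = p(x["N"], x["CY"], x["CAY"], 1.09, D(109.5), D(60.0 + 120.0 * i))
    for i, name in enumerate(("HB1", "HB2", "HB3")):
        x[name] = p(x["N"], x["CA"], x["CB"], 1.09, D(109.5), D(60.0 + 120.0 * i))
    for i, name in enumerate(("HT1", "HT2", "HT3")):
        x[name] = p(x["C"], x["NT"], x["CAT"], 1.09, D(109.5), D(60.0 + 120.0 * i))
    return x


def _angle_triplets(bond_pairs: list[tuple[int, int]], n_atoms: int) -> list[tuple[int, int, int]]:
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bond_pairs:
        adj[i].add(j)
        adj[j].add(i)
    out = []
    for j in range(n_atoms):
        nbrs = sorted(adj[j])
        for ii in range(len(nbrs)):
            for kk in range(ii + 1, len(nbrs)):
                out.append((nbrs[ii], j, nbrs[kk]))
    return out


def build_solute(phi: float = D(-80.0), psi: float = D(150.0)) -> tuple[Topology, np.ndarray]:
    """Build the 22-atom capped-alanine-like solute (vacuum)."""
    coords_map = _solute_coords(phi, psi)
    names = list(_SOLUTE_NB)
    index = {n: i for i, n in enumerate(names)}
    coords = np.array([coords_map[n] for n in names])

    atoms = []
    for n in names:
        el, q, eps, rmh = _SOLUTE_NB[n]
        atoms.append(Atom(name=n, element=el, mass=_MASS[el], charge=q,
                          lj_epsilon=eps, lj_rmin_half=rmh, molecule_id=0,
                          is_hydrogen=(el == "H"), is_water=False,
                          is_solute_heavy=(el != "H")))

    bonds: list[BondTerm] = []
    constraints: list[Constraint] = []
    bond_pairs: list[tuple[int, int]] = []
    for a, b in _SOLUTE_BONDS:
        i, j = index[a], index[b]
        bond_pairs.append((i, j))
        r = float(np.linalg.norm(coords[i] - coords[j]))
        if atoms[i].is_hydrogen or atoms[j].is_hydrogen:
            constraints.append(Constraint(i, j, r))
        else:
            bonds.append(BondTerm(i, j, _BOND_K, r))

    angles = [
        AngleTerm(i, j, k, _ANGLE_K, angle_between(coords[i], coords[j], coords[k]))
        for i, j, k in _angle_triplets(bond_pairs, len(atoms))
    ]
    dihedrals = [
        DihedralTerm(index[a], index[b], index[c], index[d], kphi, n, delta)
        for a, b, c, d, kphi, n, delta in _SOLUTE_DIHEDRALS
    ]
    top = Topology(atoms=atoms, bonds=bonds, angles=angles,
                   dihedrals=dihedrals, constraints=constraints)
    top.validate()
    return top, coords


def _water_template() -> np.ndarray:
    """O, H1, H2 of one rigid water, O at origin, in the xz plane."""
    half = D(C.WATER_ANGLE) / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [C.WATER_OH * math.sin(half), 0.0, C.WATER_OH * math.cos(half)],
        [-C.WATER_OH * math.sin(half), 0.0, C.WATER_OH * math.cos(half)],
    ])


def _water_atoms(mol_id: int) -> list[Atom]:
    o = Atom(name="OH2", element="O", mass=C.WATER_O_MASS, charge=C.WATER_O_CHARGE,
             lj_epsilon=C.WATER_O_EPS, lj_rmin_half=C.WATER_O_RMIN_HALF,
             molecule_id=mol_id, is_hydrogen=False, is_water=True)
    hs = [Atom(name=f"H{i}", element="H", mass=C.WATER_H_MASS, charge=C.WATER_H_CHARGE,
               lj_epsilon=C.WATER_H_EPS, lj_rmin_half=C.WATER_H_RMIN_HALF,
               molecule_id=mol_id, is_hydrogen=True, is_water=True)
          for i in (1, 2)]
    return [o] + hs


def _water_constraints(offset: int) -> list[Constraint]:
    return [
        Constraint(offset, offset + 1, C.WATER_OH),
        Constraint(offset, offset + 2, C.WATER_OH),
        Constraint(offset + 1, offset + 2, C.WATER_HH),
    ]


def build_water_topology(n_waters: int = 1, first_mol_id: int = 0) -> Topology:
    """Topology of rigid three-site waters only (no solute)."""
    atoms: list[Atom] = []
    constraints: list[Constraint] = []
    for w in range(n_waters):
        atoms.extend(_water_atoms(first_mol_id + w))
        constraints.extend(_water_constraints(3 * w))
    top = Topology(atoms=atoms, constraints=constraints)
    top.validate()
    return top


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_toy_system(n_waters: int, box_edge: float | None = None,
                     seed: int = 0, min_dist: float = 1.5,
                     max_retries: int = 2000) -> tuple[Topology, SystemState]:
    """Build the solvated toy system: solute + n_waters rigid waters.

    Water oxygens are proposed uniformly in the cube and a whole water is
    accepted only if none of its atoms comes within `min_dist` Å (minimum
    image) of an already-placed atom.  Deterministic for a fixed seed.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    top, solute_coords = build_solute()
    if n_waters == 0 and box_edge is None:
        return top, SystemState(coords=solute_coords, box_edge=None)
    if box_edge is None:
        raise ValueError("box_edge required when placing solvent")

    rng = np.random.default_rng(seed)
    # centre the solute in the box
    coords = solute_coords - solute_coords.mean(axis=0) + box_edge / 2.0
    all_coords = [coords]
    placed = coords.copy()
    tmpl = _water_template()

    for w in range(n_waters):
        ok = False
        for _ in range(max_retries):
            o_pos = rng.uniform(0.0, box_edge, size=3)
            wat = tmpl @ _random_rotation(rng).T + o_pos
            d = placed[None, :, :] - wat[:, None, :]
            d -= box_edge * np.round(d / box_edge)
            if np.min(np.linalg.norm(d, axis=-1)) >= min_dist:
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place water {w + 1}/{n_waters} in a {box_edge} Å box "
                f"after {max_retries} retries: requested density too high for "
                f"minimum separation {min_dist} Å"
            )
        offset = top.n_atoms
        top.atoms.extend(_water_atoms(mol_id=w + 1))
        top.constraints.extend(_water_constraints(offset))
        all_coords.append(wat)
        placed = np.vstack([placed, wat])

    top.validate()
    state = SystemState(coords=np.vstack(all_coords), box_edge=box_edge)
    return top, state
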