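"""Molecular data model: atoms, topology, system state, energy breakdown.

The topology is deliberately self-contained (parameters live on the bonded
terms, not in a separate force-field file): mass fields are freely editable,
which is what the mass-model transforms rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "Constraint",
    "Topology",
    "SystemState",
    "EnergyBreakdown",
]


@dataclass
class Atom:
    """One atom: identity, mass, charge and Lennard-Jones parameters."""

    name: str
    element: str
    mass: float                 # amu
    charge: float               # e
    lj_epsilon: float = 0.0     # kcal/mol
    lj_rmin_half: float = 0.0   # Å
    molecule_id: int = 0
    is_hydrogen: bool = False
    is_water: bool = False
    is_solute_heavy: bool = False


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k: float    # kcal/mol/Å^2, V = k (r - r0)^2
    r0: float   # Å


@dataclass(frozen=True)
class AngleTerm:
    # i-j-k with j the central atom
    i: int
    j: int
    k: int
    k_theta: float    # kcal/mol/rad^2, V = k_theta (theta - theta0)^2
    theta0: float     # radians


@dataclass(frozen=True)
class DihedralTerm:
    i: int
    j: int
    k: int
    l: int
    k_phi: float      # kcal/mol, V = k_phi (1 + cos(n phi - delta))
    n: int
    delta: float      # radians


@dataclass(frozen=True)
class Constraint:
    i: int
    j: int
    length: float     # Å


@dataclass
class Topology:
    """Atoms plus bonded terms, constraints and the solute/solvent split."""

    atoms: list[Atom]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)  # applied mass models

    # -- derived views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms])

    @property
    def solute_ids(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_water], dtype=int)

    @property
    def solvent_ids(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_water], dtype=int)

    def molecules(self) -> dict[int, list[int]]:
        """Partition of atom indices by molecule id."""
        out: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.molecule_id, []).append(i)
        return out

    def molecular_mass(self, mol_id: int) -> float:
        return sum(self.atoms[i].mass for i in self.molecules()[mol_id])

    def total_mass(self) -> float:
        return float(sum(a.mass for a in self.atoms))

    def bonded_hydrogens(self) -> dict[int, list[int]]:
        """Map heavy-atom index -> indices of its covalently bound hydrogens.

        Both plain bonds and rigid constraints count as covalent pairing.
        """
        out: dict[int, list[int]] = {}
        pairs = [(b.i, b.j) for b in self.bonds] + [(c.i, c.j) for c in self.constraints]
        for i, j in pairs:
            hi, hj = self.atoms[i].is_hydrogen, self.atoms[j].is_hydrogen
            if hi and not hj:
                out.setdefault(j, []).append(i)
            elif hj and not hi:
                out.setdefault(i, []).append(j)
        return out

    def copy(self) -> "Topology":
        return Topology(
            atoms=[replace(a) for a in self.atoms],
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=list(self.dihedrals),
            constraints=list(self.constraints),
            provenance=list(self.provenance),
        )

    def validate(self) -> None:
        n = self.n_atoms
        for terms, arity in ((self.bonds, 2), (self.angles, 3), (self.dihedrals, 4), (self.constraints, 2)):
            for t in terms:
                idx = (t.i, t.j) if arity == 2 else (t.i, t.j, t.k) if arity == 3 else (t.i, t.j, t.k, t.l)
                if not all(0 <= x < n for x in idx):
                    raise ValueError(f"index tuple {idx} out of range for {n} atoms")
        for a in self.atoms:
            if not a.mass > 0:
                raise ValueError(f"non-positive mass on atom {a.name}")


@dataclass
class SystemState:
    """Coordinates (Å), velocities (Å/fs), cubic periodic box and clock."""

    coords: np.ndarray
    velocities: np.ndarray | None = None
    box_edge: float | None = None   # Å; None = vacuum, no PBC
    time: float = 0.0               # ps

    def copy(self) -> "SystemState":
        return SystemState(
            coords=self.coords.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            box_edge=self.box_edge,
            time=self.time,
        )


@dataclass
class EnergyBreakdown:
    """Decomposed potential energy, kcal/mol.

    E_p  — solute-solute (bonded + nonbonded)
    E_ps — solute-solvent nonbonded
    E_s  — solvent-solvent nonbonded
    PV   — pressure-volume term at the fixed box volume
    """

    E_p: float
    E_ps: float
    E_s: float
    PV: float = 0.0

    @property
    def total_potential(self) -> float:
        return self.E_p + self.E_ps + self.E_s
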