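"""File I/O: PSF (X-PLOR dialect), PDB, multi-frame XYZ, DCD, TSV tables.

The PSF reader/writer treats the mass column as free data: any positive mass
parses, with no element-based gating (a water oxygen of 0.743963 amu is as
valid as 15.9994), which is exactly the semantics the mass models need.
PSF carries connectivity, masses and charges only; force-field parameters
and rigid constraints live in the packaged builder.

PDB and DCD go through MDAnalysis; XYZ is written directly at full float
precision so trajectory round-trips are lossless to well below 1e-6 Å.
"""

from __future__ import annotations

import numpy as np

from .topology import Atom, BondTerm, SystemState, Topology

__all__ = [
    "write_psf", "read_psf", "write_pdb", "read_pdb",
    "write_xyz_traj", "read_xyz_traj", "write_dcd", "write_energy_tsv",
]


class PsfParseError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


# ---------------------------------------------------------------- PSF ----

def write_psf(top: Topology, path) -> None:
    """Write an X-PLOR-dialect PSF (NATOM/NBOND/NTHETA/NPHI sections).

    Rigid constraints are emitted as bonds (they are covalent bonds); the
    molecule id becomes the residue id, waters get resname TIP3.
    """
    lines = ["PSF", "", "       1 !NTITLE", " REMARKS generated by remass", ""]
    lines.append(f"{top.n_atoms:8d} !NATOM")
    for idx, a in enumerate(top.atoms, start=1):
        resname = "TIP3" if a.is_water else "ALA"
        seg = "WAT" if a.is_water else "PEPT"
        lines.append(
            f"{idx:8d} {seg:<4s} {a.molecule_id + 1:<4d} {resname:<4s} "
            f"{a.name:<4s} {a.name:<4s} {a.charge:12.6f}  {a.mass:12.6f} {0:11d}"
        )
    pairs = [(b.i, b.j) for b in top.bonds] + [(c.i, c.j) for c in top.constraints]
    lines.append("")
    lines.append(f"{len(pairs):8d} !NBOND: bonds")
    lines.extend(_index_rows(pairs, tuples_per_line=4))
    angles = [(a.i, a.j, a.k) for a in top.angles]
    lines.append("")
    lines.append(f"{len(angles):8d} !NTHETA: angles")
    lines.extend(_index_rows(angles, tuples_per_line=3))
    dihedrals = [(d.i, d.j, d.k, d.l) for d in top.dihedrals]
    lines.append("")
    lines.append(f"{len(dihedrals):8d} !NPHI: dihedrals")
    lines.extend(_index_rows(dihedrals, tuples_per_line=2))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _index_rows(tuples, tuples_per_line):
    if not tuples:
        return []
    flat = [i + 1 for t in tuples for i in t]   # PSF is 1-based
    per_line = tuples_per_line * len(tuples[0])
    return ["".join(f"{v:8d}" for v in flat[k:k + per_line])
            for k in range(0, len(flat), per_line)]


def read_psf(path) -> Topology:
    """Parse an X-PLOR PSF into a Topology (atoms + bond connectivity).

    Masses are accepted verbatim (no 14-18 amu oxygen gate or <1 amu Drude
    interpretation); LJ parameters are left zeroed, rigid constraints empty.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw or not raw[0].startswith("PSF"):
        raise PsfParseError(path, 1, "missing PSF header")

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    i = 0
    n = len(raw)
    while i < n:
        line = raw[i]
        if "!NATOM" in line:
            try:
                natom = int(line.split("!")[0])
            except ValueError:
                raise PsfParseError(path, i + 1, "malformed !NATOM count")
            for k in range(natom):
                i += 1
                if i >= n:
                    raise PsfParseError(path, i, f"expected {natom} atom lines")
                parts = raw[i].split()
                if len(parts) < 8:
                    raise PsfParseError(path, i + 1,
                                        f"atom line has {len(parts)} fields, need >= 8")
                try:
                    resid = int(parts[2])
                    charge = float(parts[6])
                    mass = float(parts[7])
                except ValueError as err:
                    raise PsfParseError(path, i + 1, f"bad numeric field: {err}")
                name = parts[4]
                resname = parts[3]
                is_water = resname.upper() in ("TIP3", "TIP3P", "HOH", "WAT", "SPC")
                element = name[0].upper()
                atoms.append(Atom(name=name, element=element, mass=mass,
                                  charge=charge, molecule_id=resid - 1,
                                  is_hydrogen=element == "H",
                                  is_water=is_water,
                                  is_solute_heavy=(not is_water and element != "H")))
            if len(atoms) != natom:
                raise PsfParseError(path, i + 1,
                                    f"atom count mismatch: header {natom}, read {len(atoms)}")
        elif "!NBOND" in line:
            try:
                nbond = int(line.split("!")[0])
            except ValueError:
                raise PsfParseError(path, i + 1, "malformed !NBOND count")
            vals: list[int] = []
            while len(vals) < 2 * nbond:
                i += 1
                if i >= n:
                    raise PsfParseError(path, i,
                                        f"expected {nbond} bonds, found {len(vals) // 2}")
                try:
                    vals.extend(int(v) for v in raw[i].split())
                except ValueError as err:
                    raise PsfParseError(path, i + 1, f"bad bond index: {err}")
            if len(vals) != 2 * nbond:
                raise PsfParseError(path, i + 1,
                                    f"bond count mismatch: header {nbond}, read {len(vals) // 2}")
            bonds = [(vals[2 * k] - 1, vals[2 * k + 1] - 1) for k in range(nbond)]
        i += 1

    if not atoms:
        raise PsfParseError(path, len(raw), "no !NATOM section found")
    top = Topology(atoms=atoms,
                   bonds=[BondTerm(i_, j_, 0.0, 0.0) for i_, j_ in bonds])
    top.validate()
    return top


# ---------------------------------------------------------------- PDB ----

def write_pdb(top: Topology, state: SystemState, path) -> None:
    """Coordinates-only PDB via MDAnalysis."""
    import MDAnalysis as mda
    import warnings

    n = top.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in top.atoms])
    u.add_TopologyAttr("elements", [a.element for a in top.atoms])
    u.add_TopologyAttr("resnames", ["TIP3" if a.is_water else "ALA" for a in top.atoms])
    u.atoms.positions = state.coords
    if state.box_edge is not None:
        u.dimensions = [state.box_edge] * 3 + [90.0] * 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_pdb(path) -> np.ndarray:
    """Coordinates (Å) from a PDB file."""
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        return u.atoms.positions.astype(float).copy()


# ---------------------------------------------------------------- XYZ ----

def write_xyz_traj(frames, path, names=None, comment="frame") -> None:
    """Multi-frame XYZ at full precision (round-trips below 1e-6 Å)."""
    with open(path, "w") as fh:
        for fi, x in enumerate(frames):
            x = np.asarray(x, dtype=float)
            fh.write(f"{len(x)}\n{comment} {fi}\n")
            for k, row in enumerate(x):
                nm = names[k] if names is not None else "X"
                fh.write(f"{nm:<4s} {row[0]:.10f} {row[1]:.10f} {row[2]:.10f}\n")


def read_xyz_traj(path) -> list[np.ndarray]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        block = lines[i + 2:i + 2 + nat]
        if len(block) != nat:
            raise ValueError(f"{path}:{i + 1}: truncated frame")
        frames.append(np.array([[float(v) for v in ln.split()[1:4]] for ln in block]))
        i += 2 + nat
    return frames


def write_dcd(frames, path, box_edge: float | None = None) -> None:
    """Optional binary DCD trajectory via MDAnalysis."""
    import MDAnalysis as mda

    frames = [np.asarray(f, dtype=np.float32) for f in frames]
    n = frames[0].shape[0]
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n) as w:
        for f in frames:
            u.atoms.positions = f
            if box_edge is not None:
                u.dimensions = [box_edge] * 3 + [90.0] * 3
            w.write(u.atoms)


# ---------------------------------------------------------------- TSV ----

def write_energy_tsv(records, path) -> None:
    """Sidecar per-frame energy table (tab-separated)."""
    import pandas as pd

    rows = [{
        "time_ps": r.state.time,
        "E_p": r.energies.E_p,
        "E_ps": r.energies.E_ps,
        "E_s": r.energies.E_s,
        "PV": r.energies.PV,
        "E_k": r.kinetic,
        "failed": int(r.failed),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
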