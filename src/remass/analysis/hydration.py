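"""Hydration probes: hydrogen bonds, radial distribution, solvation shell.

Geometric hydrogen-bond criterion: donor-acceptor distance strictly below
4 Å and donor-hydrogen-acceptor angle strictly above 150 degrees, with
minimum-image distances.  The first solvation shell counts water molecules
whose oxygen lies within 3.75 Å of any solute heavy atom, each water once.
"""

from __future__ import annotations

import numpy as np

from ..geometry import min_image

__all__ = ["hydrogen_bonds", "rdf", "solvation_count"]

HB_DIST = 4.0       # Å, strict <
HB_ANGLE = 150.0    # degrees, strict >
SHELL_CUT = 3.75    # Å


def hydrogen_bonds(coords, donors, hydrogens, acceptors,
                   box_edge: float | None = None,
                   dist_cut: float = HB_DIST,
                   angle_cut: float = HB_ANGLE) -> int:
    """Count (D, H, A) triplets satisfying the geometric criterion.

    `donors` and `hydrogens` are parallel index lists (the covalent D-H
    pairing); `acceptors` is an index list.  A donor with several hydrogens
    appears once per hydrogen.
    """
    x = np.asarray(coords, dtype=float)
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.shape != hydrogens.shape:
        raise ValueError("donors and hydrogens must pair one-to-one")
    count = 0
    cos_cut = np.cos(np.radians(angle_cut))
    for d, h in zip(donors, hydrogens):
        da = min_image(x[acceptors] - x[d], box_edge)
        dist = np.linalg.norm(da, axis=1)
        close = dist < dist_cut
        if not close.any():
            continue
        hd = min_image(x[d] - x[h], box_edge)
        ha = min_image(x[acceptors[close]] - x[h], box_edge)
        cosang = (ha @ hd) / (np.linalg.norm(ha, axis=1) * np.linalg.norm(hd))
        # angle > 150 deg <=> cos(angle) < cos(150 deg)
        count += int(np.sum(cosang < cos_cut))
    return count


def rdf(frames, ref_atoms, target_atoms, box_edge: float,
        dr: float = 0.1, r_max: float | None = None):
    """Radial distribution function g(r) of targets around reference atoms.

    Normalised by the ideal-gas expectation at the bulk target number density
    (n_targets / box volume), averaged over reference atoms and frames.
    Returns (bin centres, g).
    """
    if r_max is None:
        r_max = box_edge / 2.0
    if r_max > box_edge / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the box edge")
    ref_atoms = np.asarray(ref_atoms, dtype=int)
    target_atoms = np.asarray(target_atoms, dtype=int)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(len(edges) - 1)
    n_frames = 0
    for x in frames:
        x = np.asarray(x, dtype=float)
        d = x[target_atoms][None, :, :] - x[ref_atoms][:, None, :]
        d -= box_edge * np.round(d / box_edge)
        dist = np.linalg.norm(d, axis=-1).ravel()
        # drop self pairs if index sets overlap
        dist = dist[dist > 1e-9]
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames")
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = len(target_atoms) / box_edge ** 3
    ideal = shell_vol * rho * len(ref_atoms) * n_frames
    g = counts / ideal
    return centers, g


def solvation_count(coords, solute_heavy, water_oxygens,
                    box_edge: float | None = None,
                    cut: float = SHELL_CUT) -> int:
    """Number of waters whose O is within `cut` of any solute heavy atom."""
    x = np.asarray(coords, dtype=float)
    solute_heavy = np.asarray(solute_heavy, dtype=int)
    water_oxygens = np.asarray(water_oxygens, dtype=int)
    if water_oxygens.size == 0:
        return 0
    d = x[water_oxygens][:, None, :] - x[solute_heavy][None, :, :]
    if box_edge is not None:
        d -= box_edge * np.round(d / box_edge)
    dist = np.linalg.norm(d, axis=-1)
    return int(np.sum(np.any(dist < cut, axis=1)))
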