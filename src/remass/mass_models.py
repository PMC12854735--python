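"""Mass-acceleration models: hydrogen mass repartitioning and light water.

Three families of mass edits on a topology:

* HMR(k) — every hydrogen's mass is multiplied by k and the gained mass is
  subtracted from the heavy atom it is covalently bound to, so every
  molecule's total mass is conserved exactly.  k = 1, 2, 3 are conventionally
  named HMR1 (the unmodified reference), HMR2 and HMR3.
* LW — the light-water model (TIP3P-F masses): water hydrogens become
  0.186496 amu and water oxygens 0.743963 amu, making a water molecule
  1.116955 amu, ~16x lighter than standard water.  The solute is untouched.
* hLW — hybrid light water: the LW masses scaled up by 4 (water molecule
  4.46782 amu) combined with HMR(k=3) on the solute, which permits HMR3-sized
  integration steps.

Each transform refuses to run twice on the same topology (tracked through
the topology's provenance list) and re-validates that constrained waters
remain well-posed (positive masses) afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import constants as C
from .topology import Topology

__all__ = ["MassModelSpec", "apply_hmr", "apply_lw", "apply_hlw", "apply_model", "MODEL_NAMES"]

MODEL_NAMES = ("hmr1", "hmr2", "hmr3", "lw", "hlw")


@dataclass(frozen=True)
class MassModelSpec:
    """Summary of the packaged mass-model constants."""

    kind: str                        # HMR | LW | hLW
    hmr_factor: int = 1
    lw_h_mass: float = C.LW_H_MASS
    lw_o_mass: float = C.LW_O_MASS
    hlw_water_scale: float = C.HLW_WATER_SCALE
    hlw_solute_factor: int = C.HLW_SOLUTE_K


class MassModelError(ValueError):
    """Raised when a mass transform would produce an unphysical topology."""


def _check_not_applied(top: Topology) -> None:
    if top.provenance:
        raise MassModelError(
            f"mass model already applied ({'+'.join(top.provenance)}); "
            "transforms must start from the pristine topology"
        )


def _validate_waters(top: Topology) -> None:
    for a in top.atoms:
        if a.mass <= 0:
            raise MassModelError(f"atom {a.name} ended with non-positive mass {a.mass}")


def apply_hmr(top: Topology, k: int | float, _solute_only: bool = False,
              _tag: str | None = None) -> Topology:
    """Repartition hydrogen masses by a factor k, conserving molecular mass.

    Every hydrogen's mass becomes k x its original value; the heavy atom each
    hydrogen is bound to loses the total mass its hydrogens gained.  Raises
    if any heavy atom would end up lighter than one of its own hydrogens
    (the over-repartitioning guard for methyl carbons).
    """
    if k < 1:
        raise MassModelError("repartitioning factor k must be >= 1")
    _check_not_applied(top)
    out = top.copy()
    tag = _tag if _tag is not None else f"HMR{k:g}"
    if k == 1:
        out.provenance.append(tag)
        return out

    h_of = out.bonded_hydrogens()
    # verify the precondition: each hydrogen bound to exactly one heavy atom
    seen: dict[int, int] = {}
    for heavy, hs in h_of.items():
        for h in hs:
            seen[h] = seen.get(h, 0) + 1
    for i, a in enumerate(out.atoms):
        if a.is_hydrogen and (_solute_only is False or not a.is_water):
            if seen.get(i, 0) != 1:
                raise MassModelError(
                    f"hydrogen {a.name} (index {i}) bound to {seen.get(i, 0)} heavy atoms"
                )

    gains: dict[int, float] = {}
    for i, a in enumerate(out.atoms):
        if not a.is_hydrogen:
            continue
        if _solute_only and a.is_water:
            continue
        gain = (k - 1.0) * a.mass
        heavy = next(hv for hv, hs in h_of.items() if i in hs)
        gains[heavy] = gains.get(heavy, 0.0) + gain
        a.mass *= k
    for heavy, gained in gains.items():
        new_mass = out.atoms[heavy].mass - gained
        h_masses = [out.atoms[h].mass for h in h_of[heavy]
                    if not (_solute_only and out.atoms[h].is_water)]
        if h_masses and new_mass <= max(h_masses):
            raise MassModelError(
                f"repartitioning with k={k} would leave heavy atom "
                f"{out.atoms[heavy].name} at {new_mass:.3f} amu, not heavier than "
                f"its hydrogens ({max(h_masses):.3f} amu)"
            )
        out.atoms[heavy].mass = new_mass
    _validate_waters(out)
    out.provenance.append(tag)
    return out


def apply_lw(top: Topology, water_scale: float = 1.0, _tag: str = "LW") -> Topology:
    """Assign light-water (TIP3P-F) masses to all waters; solute untouched."""
    _check_not_applied(top)
    out = top.copy()
    n_water = 0
    for a in out.atoms:
        if not a.is_water:
            continue
        n_water += 1
        a.mass = (C.LW_H_MASS if a.is_hydrogen else C.LW_O_MASS) * water_scale
    if n_water == 0:
        raise MassModelError("topology contains no water molecules")
    _validate_waters(out)
    out.provenance.append(_tag)
    return out


def apply_hlw(top: Topology) -> Topology:
    """Hybrid light water: 4x LW water masses plus HMR(k=3) on the solute."""
    _check_not_applied(top)
    out = apply_lw(top, water_scale=C.HLW_WATER_SCALE, _tag="hLW")
    out.provenance.pop()  # re-tag once at the end
    out = apply_hmr(out, C.HLW_SOLUTE_K, _solute_only=True, _tag="hLW")
    return out


def apply_model(top: Topology, name: str) -> Topology:
    """Apply a mass model by its conventional name (hmr1/hmr2/hmr3/lw/hlw)."""
    name = name.lower()
    if name not in MODEL_NAMES:
        raise MassModelError(f"unknown mass model {name!r}; choose from {MODEL_NAMES}")
    if name.startswith("hmr"):
        return apply_hmr(top, int(name[3:]))
    if name == "lw":
        return apply_lw(top)
    return apply_hlw(top)
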