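"""Side-chain construction from internal coordinates and rotamers."""

from __future__ import annotations

import numpy as np

from neomhc.chemdata import (CB_ANGLE, CB_BOND, CB_TORSION, N_CHI,
                             ROTAMER_LIBRARY, SIDECHAIN_TOPOLOGY,
                             atom_element)
from neomhc.geometry import place_atom
from neomhc.structure import Atom, Residue


def build_sidechain(backbone: dict[str, np.ndarray], resname: str,
                    chis: tuple[float, ...]) -> dict[str, np.ndarray]:
    """Heavy side-chain atom coordinates for ``resname`` on the given
    backbone (needs N, CA, C), with the supplied chi angles."""
    if resname not in SIDECHAIN_TOPOLOGY:
        raise KeyError(f"no side-chain topology for {resname!r}")
    if len(chis) != N_CHI[resname]:
        raise ValueError(
            f"{resname} takes {N_CHI[resname]} chi angles, got {len(chis)}")
    coords: dict[str, np.ndarray] = dict(backbone)
    if resname != "GLY":
        coords["CB"] = place_atom(coords["C"], coords["N"], coords["CA"],
                                  CB_BOND, CB_ANGLE, CB_TORSION)
    for name, (ra, rb, rc), bond, angle, tspec in SIDECHAIN_TOPOLOGY[resname]:
        if tspec[0] == "chi":
            _, k, offset = tspec
            torsion = chis[k - 1] + offset
        else:
            torsion = tspec[1]
        coords[name] = place_atom(coords[ra], coords[rb], coords[rc],
                                  bond, angle, torsion)
    return {k: v for k, v in coords.items() if k not in ("N", "CA", "C", "O")}


def most_probable_rotamer(resname: str) -> tuple[float, ...]:
    return ROTAMER_LIBRARY[resname][0][0]


def build_residue(backbone: dict[str, np.ndarray], resname: str, resseq: int,
                  chis: tuple[float, ...] | None = None) -> Residue:
    """Full heavy-atom Residue from backbone coordinates and a rotamer
    (most probable when ``chis`` is None)."""
    if chis is None:
        chis = most_probable_rotamer(resname)
    res = Residue(name=resname, resseq=resseq)
    for name in ("N", "CA", "C", "O"):
        res.atoms.append(Atom(name=name, element=atom_element(name),
                              coord=np.asarray(backbone[name], dtype=float)))
    for name, coord in build_sidechain(
            {k: np.asarray(backbone[k], dtype=float)
             for k in ("N", "CA", "C")}, resname, chis).items():
        res.atoms.append(Atom(name=name, element=atom_element(name),
                              coord=coord))
    return res


def set_rotamer(residue: Residue, chis: tuple[float, ...]) -> None:
    """Rebuild the residue's side chain in place with new chi angles.

    Backbone atoms are untouched; the atom list keeps backbone first."""
    backbone = {}
    for name in ("N", "CA", "C"):
        atom = residue.atom(name)
        if atom is None:
            raise ValueError(
                f"residue {residue.name}{residue.resseq} lacks backbone "
                f"atom {name}")
        backbone[name] = atom.coord
    new_coords = build_sidechain(backbone, residue.name, chis)
    kept = [a for a in residue.atoms if a.name in ("N", "CA", "C", "O")]
    for name, coord in new_coords.items():
        kept.append(Atom(name=name, element=atom_element(name), coord=coord))
    residue.atoms = kept


def mutate_residue(residue: Residue, new_resname: str,
                   chis: tuple[float, ...] | None = None) -> Residue:
    """Replace the residue type in place, rebuilding the side chain from
    the most probable (or supplied) rotamer. Backbone is preserved."""
    residue.name = new_resname
    if chis is None:
        chis = most_probable_rotamer(new_resname)
    set_rotamer(residue, chis)
    return residue


def sidechain_reach(resname: str, chis: tuple[float, ...]) -> float:
    """Maximum heavy-atom distance from CA for a rotamer, on an ideal
    backbone; used to reason about pocket occlusion in fixtures."""
    backbone = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
        "C": np.array([2.009, 1.423, 0.0]),
    }
    coords = build_sidechain(backbone, resname, chis)
    if not coords:
        return 0.0
    ca = backbone["CA"]
    return max(float(np.linalg.norm(c - ca)) for c in coords.values())
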