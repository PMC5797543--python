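"""Quantitative structure comparison.

Superposition/RMSD (Kabsch), named-atom displacement after frame fitting,
Shrake-Rupley solvent-accessible surface areas and buried surface area,
distance-based polar/hydrophobic contact counts, and phi/psi-based
3_10-helix classification.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import cdist

from neomhc.chemdata import APOLAR_RESIDUES, VDW_RADII
from neomhc.geometry import dihedral
from neomhc.structure import Atom, Chain, Residue, StructureModel

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


# --- selections ----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Selection:
    """Atom selection: one chain, optional residue range and atom subset.

    ``atoms`` may be None (all atoms), "backbone", or an explicit tuple of
    atom names.
    """

    chain: str
    res_min: int | None = None
    res_max: int | None = None
    atoms: tuple[str, ...] | str | None = None

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse "A", "A:1-180" or "A:1-180:backbone"."""
        parts = text.split(":")
        chain = parts[0]
        res_min = res_max = None
        atoms = None
        if len(parts) > 1 and parts[1]:
            lo, _, hi = parts[1].partition("-")
            res_min, res_max = int(lo), int(hi or lo)
        if len(parts) > 2 and parts[2]:
            atoms = parts[2] if parts[2] == "backbone" else tuple(
                parts[2].split(","))
        return cls(chain, res_min, res_max, atoms)

    def _atom_ok(self, name: str) -> bool:
        if self.atoms is None:
            return True
        if self.atoms == "backbone":
            return name in BACKBONE_ATOMS
        return name in self.atoms

    def matches(self, chain_id: str, resseq: int, atom_name: str) -> bool:
        if chain_id != self.chain:
            return False
        if self.res_min is not None and resseq < self.res_min:
            return False
        if self.res_max is not None and resseq > self.res_max:
            return False
        return self._atom_ok(atom_name)


AtomKey = tuple[str, int, str, str]  # chain, resseq, icode, atom name


def select_atoms(model: StructureModel, selections: "list[Selection] | Selection"
                 ) -> dict[AtomKey, Atom]:
    if isinstance(selections, Selection):
        selections = [selections]
    picked: dict[AtomKey, Atom] = {}
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                for sel in selections:
                    if sel.matches(chain.id, res.resseq, atom.name):
                        picked[(chain.id, res.resseq, res.icode,
                                atom.name)] = atom
                        break
    return picked


# --- superposition -------------------------------------------------------


@dataclasses.dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_move: np.ndarray,
                     coords_ref: np.ndarray) -> Superposition:
    """Least-squares rigid transform taking ``coords_move`` onto
    ``coords_ref`` (proper rotation only)."""
    move = np.asarray(coords_move, dtype=float)
    ref = np.asarray(coords_ref, dtype=float)
    if move.shape != ref.shape:
        raise ValueError("coordinate sets must have matching shapes")
    if move.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs")
    mc = move.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (move - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = rc - rot @ mc
    moved = move @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def _paired_coords(model_a: StructureModel, model_b: StructureModel,
                   selection: list[Selection] | Selection,
                   ) -> tuple[np.ndarray, np.ndarray, list[AtomKey]]:
    atoms_a = select_atoms(model_a, selection)
    atoms_b = select_atoms(model_b, selection)
    keys = [k for k in atoms_a if k in atoms_b]
    unpaired = (set(atoms_a) | set(atoms_b)) - set(keys)
    if unpaired:
        logger.warning("dropping %d unpairable atoms", len(unpaired))
    if not keys:
        raise ValueError("no pairable atoms in selection")
    a = np.array([atoms_a[k].coord for k in keys])
    b = np.array([atoms_b[k].coord for k in keys])
    return a, b, keys


def selection_rmsd(model_a: StructureModel, model_b: StructureModel,
                   frame: list[Selection] | Selection,
                   measure: list[Selection] | Selection) -> float:
    """Superpose on ``frame`` atoms, report RMSD over ``measure`` atoms
    without refitting. Atoms pair by (chain, resseq, icode, name)."""
    fa, fb, _ = _paired_coords(model_a, model_b, frame)
    sup = kabsch_superpose(fa, fb)
    ma, mb, _ = _paired_coords(model_a, model_b, measure)
    moved = sup.apply(ma)
    return float(np.sqrt(np.mean(np.sum((moved - mb) ** 2, axis=1))))


def atom_displacement(model_a: StructureModel, model_b: StructureModel,
                      frame: list[Selection] | Selection,
                      chain: str, resseq: int, atom_name: str) -> float:
    """Distance between one atom's positions after frame superposition."""
    fa, fb, _ = _paired_coords(model_a, model_b, frame)
    sup = kabsch_superpose(fa, fb)

    def find(model: StructureModel) -> np.ndarray:
        res = model.chain(chain).residue(resseq)
        if res is None or res.atom(atom_name) is None:
            raise ValueError(f"atom {chain}:{resseq}:{atom_name} missing")
        return res.atom(atom_name).coord

    moved = sup.apply(find(model_a)[None, :])[0]
    return float(np.linalg.norm(moved - find(model_b)))


# --- surface areas -------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


@dataclasses.dataclass
class SasaResult:
    areas: np.ndarray  # per atom, A^2
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def sasa_from_arrays(coords: np.ndarray, radii: np.ndarray,
                     probe: float = 1.4, n_points: int = 960) -> SasaResult:
    """Shrake-Rupley numeric accessible surface, deterministic for a fixed
    point count."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    pts = _sphere_points(n_points)
    expanded = radii + probe
    areas = np.zeros(len(coords))
    # neighbour lists
    d = cdist(coords, coords)
    for i in range(len(coords)):
        ri = expanded[i]
        neigh = np.nonzero((d[i] < ri + expanded) & (d[i] > 0))[0]
        surface = coords[i] + ri * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            accessible &= (np.linalg.norm(surface - coords[j], axis=1)
                           >= expanded[j])
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ri ** 2 * accessible.sum() / n_points
    return SasaResult(areas=areas, probe=probe, n_points=n_points)


def _atom_radii(atoms: list[Atom]) -> np.ndarray:
    radii = []
    for a in atoms:
        el = a.element if a.element in VDW_RADII else None
        if el is None:
            raise ValueError(f"no vdW radius for element {a.element!r}")
        radii.append(VDW_RADII[el])
    return np.array(radii)


def sasa(model: StructureModel, selection: list[Selection] | Selection | None
         = None, probe: float = 1.4, n_points: int = 960) -> SasaResult:
    if selection is None:
        atoms = [a for _, _, a in model.iter_atoms()]
    else:
        atoms = list(select_atoms(model, selection).values())
    if not atoms:
        raise ValueError("empty selection for SASA")
    coords = np.array([a.coord for a in atoms])
    return sasa_from_arrays(coords, _atom_radii(atoms), probe, n_points)


def buried_surface_area(model: StructureModel,
                        sel_a: list[Selection] | Selection,
                        sel_b: list[Selection] | Selection,
                        probe: float = 1.4, n_points: int = 960) -> float:
    """BSA = SASA(A) + SASA(B) - SASA(A u B); symmetric in A and B."""
    atoms_a = select_atoms(model, sel_a)
    atoms_b = select_atoms(model, sel_b)
    overlap = set(atoms_a) & set(atoms_b)
    if overlap:
        raise ValueError(f"selections overlap on {len(overlap)} atoms")
    la, lb = list(atoms_a.values()), list(atoms_b.values())
    ca = np.array([a.coord for a in la]).reshape(-1, 3)
    cb = np.array([a.coord for a in lb]).reshape(-1, 3)
    ra, rb = _atom_radii(la), _atom_radii(lb)
    s_a = sasa_from_arrays(ca, ra, probe, n_points).total
    s_b = sasa_from_arrays(cb, rb, probe, n_points).total
    s_ab = sasa_from_arrays(np.vstack([ca, cb]), np.concatenate([ra, rb]),
                            probe, n_points).total
    return s_a + s_b - s_ab


# --- contacts ------------------------------------------------------------


@dataclasses.dataclass
class Contact:
    atom_a: AtomKey
    atom_b: AtomKey
    distance: float
    kind: str  # polar | hydrophobic


def contacts(model: StructureModel,
             sel_a: list[Selection] | Selection,
             sel_b: list[Selection] | Selection,
             polar_cutoff: float = 3.5,
             hydrophobic_cutoff: float = 4.5) -> list[Contact]:
    """Distance-based interface contacts.

    polar: N/O vs N/O pairs within ``polar_cutoff``; hydrophobic: C vs C
    pairs, both atoms either side-chain carbons or carbons of apolar
    residues, within ``hydrophobic_cutoff``. This typing is a documented
    simplification; counts are reported, not asserted against any
    published table.
    """
    atoms_a = select_atoms(model, sel_a)
    atoms_b = select_atoms(model, sel_b)
    if set(atoms_a) & set(atoms_b):
        raise ValueError("contact selections must be disjoint")

    def hydrophobic_ok(key: AtomKey, atom: Atom, resname: str) -> bool:
        if atom.element != "C":
            return False
        return resname in APOLAR_RESIDUES or key[3] not in BACKBONE_ATOMS

    resnames = {}
    for chain in model.chains:
        for res in chain.residues:
            resnames[(chain.id, res.resseq, res.icode)] = res.name

    out: list[Contact] = []
    items_b = list(atoms_b.items())
    cb = np.array([a.coord for _, a in items_b]).reshape(-1, 3)
    for key_a, atom_a in atoms_a.items():
        d = np.linalg.norm(cb - atom_a.coord, axis=1)
        for (key_b, atom_b), dist in zip(items_b, d):
            if (atom_a.element in ("N", "O") and atom_b.element in ("N", "O")
                    and dist <= polar_cutoff):
                out.append(Contact(key_a, key_b, float(dist), "polar"))
            elif (dist <= hydrophobic_cutoff
                    and hydrophobic_ok(key_a, atom_a, resnames[key_a[:3]])
                    and hydrophobic_ok(key_b, atom_b, resnames[key_b[:3]])):
                out.append(Contact(key_a, key_b, float(dist), "hydrophobic"))
    return out


def contact_counts(contact_list: list[Contact]) -> dict[str, int]:
    counts = {"polar": 0, "hydrophobic": 0}
    for c in contact_list:
        counts[c.kind] += 1
    return counts


# --- dihedrals and 3_10 classification ----------------------------------


THREE_TEN_PHI = (-90.0, -40.0)
THREE_TEN_PSI = (-45.0, 0.0)
ALPHA_PHI = (-100.0, -30.0)
ALPHA_PSI = (-80.0, -5.0)
BETA_PHI = (-180.0, -45.0)
BETA_PSI = (90.0, 180.0)


@dataclasses.dataclass
class DihedralRecord:
    resseq: int
    resname: str
    phi: float | None
    psi: float | None
    ss_class: str  # 3_10 | alpha | beta | other | absent


def phi_psi(model: StructureModel, chain_id: str) -> list[DihedralRecord]:
    """Backbone phi/psi per residue; termini and residues with missing
    backbone atoms are marked absent."""
    chain = model.chain(chain_id)
    records = []
    residues = chain.residues
    for i, res in enumerate(residues):
        def bb(r: Residue, name: str):
            a = r.atom(name)
            return None if a is None else a.coord

        phi = psi = None
        n, ca, c = bb(res, "N"), bb(res, "CA"), bb(res, "C")
        complete = n is not None and ca is not None and c is not None
        if i > 0 and complete:
            prev_c = bb(residues[i - 1], "C")
            if prev_c is not None:
                phi = dihedral(prev_c, n, ca, c)
        if i + 1 < len(residues) and complete:
            next_n = bb(residues[i + 1], "N")
            if next_n is not None:
                psi = dihedral(n, ca, c, next_n)
        records.append(DihedralRecord(
            resseq=res.resseq, resname=res.name, phi=phi, psi=psi,
            ss_class=_classify(phi, psi)))
    return records


def _in(window: tuple[float, float], value: float) -> bool:
    return window[0] <= value <= window[1]


def _classify(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "absent"
    if _in(THREE_TEN_PHI, phi) and _in(THREE_TEN_PSI, psi):
        return "3_10"
    if _in(ALPHA_PHI, phi) and _in(ALPHA_PSI, psi):
        return "alpha"
    if _in(BETA_PHI, phi) and _in(BETA_PSI, psi):
        return "beta"
    return "other"


def classify_310(records: list[DihedralRecord],
                 run_length: int = 3) -> list[tuple[int, int]]:
    """Maximal runs of >= run_length residues in the 3_10 phi/psi window,
    as (first resseq, last resseq) spans."""
    spans = []
    run: list[int] = []
    for rec in records:
        if rec.ss_class == "3_10":
            run.append(rec.resseq)
        else:
            if len(run) >= run_length:
                spans.append((run[0], run[-1]))
            run = []
    if len(run) >= run_length:
        spans.append((run[0], run[-1]))
    return spans
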