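"""Hierarchical structure model and PDB I/O.

The in-memory model is deliberately small: ordered chains of ordered
residues of atoms, with coordinates in Angstrom and residue numbering taken
verbatim from the source file. Parsing and writing are backed by gemmi;
this module layers the toolkit's policies on top: highest-occupancy altloc
selection (ties break to the first encountered), HETATM/water records
skipped, duplicate atom identities rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised for malformed or inconsistent PDB input."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""
    serial: int = 0

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(),
                    self.occupancy, self.bfactor, self.altloc, self.serial)


@dataclasses.dataclass
class Residue:
    name: str  # 3-letter code
    resseq: int
    icode: str = ""
    atoms: list[Atom] = dataclasses.field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple[int, str]:
        return (self.resseq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.name, self.resseq, self.icode,
                       [a.copy() for a in self.atoms])


@dataclasses.dataclass
class Chain:
    id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue(self, resseq: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.resseq == resseq and r.icode == icode:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclasses.dataclass
class StructureModel:
    chains: list[Chain] = dataclasses.field(default_factory=list)
    source: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.source or 'structure'}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def coords(self) -> np.ndarray:
        pts = [a.coord for _, _, a in self.iter_atoms()]
        return np.array(pts, dtype=float).reshape(-1, 3)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def copy(self) -> "StructureModel":
        return StructureModel([c.copy() for c in self.chains], self.source)


def _validate_atom_lines(path: Path) -> None:
    # gemmi tolerates some malformed records; reject them up front with a
    # line number so failures are actionable.
    seen: set[tuple[str, str, str, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated ATOM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}:{lineno}: bad coordinate field ({exc})"
                ) from None
            if line.startswith("ATOM  "):
                resname = line[17:20].strip()
                if resname == "HOH":
                    continue
                ident = (line[21], line[22:27], line[12:16].strip(),
                         line[16], resname)
                if ident in seen:
                    raise PDBParseError(
                        f"{path}:{lineno}: duplicate atom "
                        f"(chain {line[21]!r}, residue {line[22:27].strip()!r}, "
                        f"atom {line[12:16].strip()!r}, altloc {line[16]!r})"
                    )
                seen.add(ident)


def read_pdb(path: str | Path, keep_hetero: bool = False) -> StructureModel:
    """Read ATOM records into a StructureModel.

    HETATM records and waters are skipped unless ``keep_hetero``. Alternate
    locations are collapsed to the highest-occupancy conformer (first wins
    on ties). Residue numbering and insertion codes are kept verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_atom_lines(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if not st or not st[0]:
        raise PDBParseError(f"{path}: no atoms parsed")
    st.setup_entities()
    model = StructureModel(source=str(path))
    for gchain in st[0]:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.name == "HOH":
                continue
            is_standard = gres.name in THREE_TO_ONE
            if not is_standard and not keep_hetero:
                continue
            res = Residue(
                name=gres.name,
                resseq=gres.seqid.num,
                icode=(gres.seqid.icode or " ").strip(),
            )
            best: dict[str, Atom] = {}
            for ga in gres:
                atom = Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    bfactor=ga.b_iso,
                    altloc=(ga.altloc or "").strip(),
                    serial=ga.serial,
                )
                prev = best.get(ga.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    best[ga.name] = atom
            res.atoms = list(best.values())
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise PDBParseError(f"{path}: no polymer atoms after filtering")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-width PDB ATOM/TER/END records via gemmi."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.resseq, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                ga.b_iso = atom.bfactor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))
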