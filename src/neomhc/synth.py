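"""Seeded synthetic fixtures for every input class the toolkit consumes.

Every generator is a pure function of its arguments (same seed, same
bytes) and returns machine-readable planted truth alongside the data, so
tests never re-derive labels by hand.

The micro-groove deserves a note: it is an idealised, deliberately tiny
peptide/MHC-like complex -- a 9-mer peptide in an extended conformation
(phi -120, psi +120) flanked by two short ideal alpha-helices ("walls")
and two extended strands below ("floor"), all built from ideal bond
geometry and placed numerically so the walls and floor sit at van der
Waals contact distance from the peptide. It runs the full model-pool
screen in seconds and is the default test substrate for the threading
protocol. With ``occlude_pocket_b=True`` an additional shell of fixed
scaffold atoms is placed around the second peptide position so that every
bundled arginine rotamer clashes while glutamine still fits -- a geometric
caricature of a B pocket that accepts Gln but excludes the longer Arg
side chain.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from neomhc.biophys import MeltCurve, simulate_melt_curve
from neomhc.chemdata import ROTAMER_LIBRARY, VDW_RADII, atom_element
from neomhc.geometry import build_backbone, rotation_matrix
from neomhc.sequences import SequenceRecord
from neomhc.sidechain import build_residue, build_sidechain
from neomhc.structure import (Atom, Chain, ONE_TO_THREE, Residue,
                              StructureModel)
from neomhc.variants import VariantRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CALLERS = ("mutect", "muse", "radia", "sniper", "strelka")


# --- variant sets --------------------------------------------------------


@dataclasses.dataclass
class PlantedVariant:
    record: VariantRecord
    label: str  # clean | oxog | low_af | unexpressed
    expected_kept: bool
    expected_stage: str  # passed | oxog | expression


def make_variant_set(seed: int, n: int = 100,
                     oxog_fraction: float = 0.2,
                     low_af_fraction: float = 0.1,
                     unexpressed_fraction: float = 0.1
                     ) -> list[PlantedVariant]:
    """Variant set with planted, unambiguous filter-chain cases.

    * oxog: alt reads solely in one mate (alternating read 1 / read 2),
      OxoG-consistent substitution, otherwise clean -> dropped at the
      artifact stage.
    * low_af: allele fraction < 0.1 with zero RNA alt reads, both mates
      supporting -> dropped at the artifact stage (low-AF clause).
    * unexpressed: gene expression 0, otherwise clean -> dropped at the
      expression stage.
    * clean: passes everything (allele fraction >= 0.15, both mates, RNA
      alt evidence, expressed gene, at most two caller rejections).
    """
    if oxog_fraction + low_af_fraction + unexpressed_fraction > 1.0:
        raise ValueError("planted fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_oxog = round(n * oxog_fraction)
    n_lowaf = round(n * low_af_fraction)
    n_unexpr = round(n * unexpressed_fraction)
    labels = (["oxog"] * n_oxog + ["low_af"] * n_lowaf
              + ["unexpressed"] * n_unexpr)
    labels += ["clean"] * (n - len(labels))
    out = []
    for i, label in enumerate(labels):
        pos = 10_000 + i * 100
        # caller statuses: clean-ish consensus for every planted class
        n_reject = int(rng.integers(0, 3))
        rejected = set(rng.choice(len(_CALLERS), size=n_reject,
                                  replace=False))
        status = {c: ("rejected" if j in rejected else "accepted")
                  for j, c in enumerate(_CALLERS)}
        gene = f"GENE{i:03d}"
        tx = (f"TX{i:03d}.1",)
        common = dict(chrom="chr1", pos=pos, caller_status=status,
                      gene_id=gene, transcript_ids=tx,
                      protein_pos=int(rng.integers(20, 180)))
        if label == "oxog":
            ref, alt = ("C", "A") if i % 2 == 0 else ("G", "T")
            read1_only = i % 4 < 2
            rec = VariantRecord(
                ref_base=ref, alt_base=alt,
                allele_fraction=float(rng.uniform(0.15, 0.4)),
                alt_read1_count=int(rng.integers(3, 20)) if read1_only else 0,
                alt_read2_count=0 if read1_only else int(rng.integers(3, 20)),
                rna_depth=int(rng.integers(10, 60)),
                rna_alt_count=int(rng.integers(3, 15)),
                rna_spanning_reads=0,
                gene_expression=float(rng.uniform(5, 50)),
                ref_aa="A", alt_aa="V", **common)
            out.append(PlantedVariant(rec, label, False, "oxog"))
        elif label == "low_af":
            rec = VariantRecord(
                ref_base="A", alt_base="G",
                allele_fraction=float(rng.uniform(0.02, 0.09)),
                alt_read1_count=int(rng.integers(2, 8)),
                alt_read2_count=int(rng.integers(2, 8)),
                rna_depth=int(rng.integers(10, 60)),
                rna_alt_count=0, rna_spanning_reads=0,
                gene_expression=float(rng.uniform(5, 50)),
                ref_aa="K", alt_aa="E", **common)
            out.append(PlantedVariant(rec, label, False, "oxog"))
        elif label == "unexpressed":
            rec = VariantRecord(
                ref_base="T", alt_base="C",
                allele_fraction=float(rng.uniform(0.2, 0.5)),
                alt_read1_count=int(rng.integers(3, 15)),
                alt_read2_count=int(rng.integers(3, 15)),
                rna_depth=int(rng.integers(5, 30)),
                rna_alt_count=int(rng.integers(1, 10)),
                rna_spanning_reads=0,
                gene_expression=0.0,
                ref_aa="S", alt_aa="F", **common)
            out.append(PlantedVariant(rec, label, False, "expression"))
        else:
            rec = VariantRecord(
                ref_base="G", alt_base="A",
                allele_fraction=float(rng.uniform(0.15, 0.6)),
                alt_read1_count=int(rng.integers(3, 20)),
                alt_read2_count=int(rng.integers(3, 20)),
                rna_depth=int(rng.integers(15, 80)),
                rna_alt_count=int(rng.integers(3, 25)),
                rna_spanning_reads=int(rng.integers(0, 5)),
                gene_expression=float(rng.uniform(5, 80)),
                ref_aa="R", alt_aa="Q", **common)
            out.append(PlantedVariant(rec, label, True, "passed"))
    return out


# --- proteins ------------------------------------------------------------


def make_protein_with_mutation(seed: int, length: int = 100,
                               mut_pos: int = 50
                               ) -> tuple[str, str, str, str]:
    """Random protein with a planted missense change.

    Returns (reference sequence, mutant sequence, ref_aa, alt_aa)."""
    if not (1 <= mut_pos <= length):
        raise ValueError("mut_pos outside protein")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AA20), size=length))
    ref_aa = seq[mut_pos - 1]
    alt_aa = str(rng.choice([a for a in AA20 if a != ref_aa]))
    mutant = seq[:mut_pos - 1] + alt_aa + seq[mut_pos:]
    return seq, mutant, ref_aa, alt_aa


# --- allele families -----------------------------------------------------


def make_allele_family(seed: int, ref_seq: str, n_alleles: int = 20,
                       mutation_rate: float = 0.1,
                       conserved_positions: tuple[int, ...] = ()
                       ) -> list[SequenceRecord]:
    """Family of sequences derived from ``ref_seq`` by point substitution
    at rate ``mutation_rate`` everywhere except the 1-based
    ``conserved_positions``, which stay identical across the family."""
    for p in conserved_positions:
        if not (1 <= p <= len(ref_seq)):
            raise ValueError(f"conserved position {p} outside sequence")
    rng = np.random.default_rng(seed)
    conserved = set(conserved_positions)
    records = []
    for i in range(n_alleles):
        letters = list(ref_seq)
        for j in range(len(letters)):
            if (j + 1) in conserved:
                continue
            if rng.random() < mutation_rate:
                letters[j] = str(rng.choice(
                    [a for a in AA20 if a != letters[j]]))
        records.append(SequenceRecord(id=f"allele-{i + 1:03d}",
                                      residues="".join(letters)))
    return records


# --- micro-groove --------------------------------------------------------

PEPTIDE_SEQ = "AQDIYRASY"
WALL_SEQ = "LSYL"  # short helical wall segments
FLOOR_SEQ = "T"  # single-residue floor pads
WALL_CLEARANCE = 3.2  # A, min heavy-atom distance wall -> placed atoms
FLOOR_CLEARANCE = 3.2
CAGE_RADIUS = 7.4  # A, occlusion shell around peptide position 2 CA
CAGE_SPACING = 1.6
CAGE_KEEPOUT = 3.6  # no shell atom closer than this to existing atoms


def _chain_from_sequence(seq: str, phi: float, psi: float, chain_id: str,
                         first_resseq: int) -> tuple[Chain, np.ndarray]:
    """Ideal-geometry chain with greedy clash-avoiding rotamer choice:
    each residue (N to C) takes the library rotamer with the least vdW
    overlap against everything already built (probability breaks ties)."""
    backbone = build_backbone(len(seq), [phi] * len(seq), [psi] * len(seq))
    chain = Chain(id=chain_id)
    placed: list[np.ndarray] = []
    placed_radii: list[float] = []
    for bb in backbone:
        for name in ("N", "CA", "C", "O"):
            placed.append(bb[name])
            placed_radii.append(VDW_RADII["N" if name == "N"
                                          else "O" if name == "O" else "C"])
    placed_arr = np.array(placed)
    radii_arr = np.array(placed_radii)
    for i, (aa, bb) in enumerate(zip(seq, backbone)):
        resname = ONE_TO_THREE[aa]
        best = None
        for chis, prob in ROTAMER_LIBRARY[resname]:
            sc = build_sidechain({k: bb[k] for k in ("N", "CA", "C")},
                                 resname, chis)
            overlap = 0.0
            for name, coord in sc.items():
                r_self = VDW_RADII.get(atom_element(name), VDW_RADII["C"])
                d = np.linalg.norm(placed_arr - coord, axis=1)
                limit = r_self + radii_arr - 0.4
                # ignore the residue's own backbone (bonded geometry)
                own = slice(4 * i, 4 * i + 4)
                mask = d < limit
                mask[own] = False
                overlap += float(np.sum((limit - d)[mask]))
            score = (overlap, -prob)
            if best is None or score < best[0]:
                best = (score, chis)
        chain.residues.append(
            build_residue(bb, resname, first_resseq + i, chis=best[1]))
        sc_coords = [a.coord for a in chain.residues[-1].atoms
                     if a.name not in ("N", "CA", "C", "O")]
        if sc_coords:
            sc_radii = [VDW_RADII.get(a.element, VDW_RADII["C"])
                        for a in chain.residues[-1].atoms
                        if a.name not in ("N", "CA", "C", "O")]
            placed_arr = np.vstack([placed_arr, np.array(sc_coords)])
            radii_arr = np.concatenate([radii_arr, np.array(sc_radii)])
    coords = np.array([a.coord for r in chain.residues for a in r.atoms])
    return chain, coords


def _chain_coords(chain: Chain) -> np.ndarray:
    return np.array([a.coord for r in chain.residues for a in r.atoms])


def _transform_chain(chain: Chain, rot: np.ndarray, trans: np.ndarray
                     ) -> None:
    for r in chain.residues:
        for a in r.atoms:
            a.coord = rot @ a.coord + trans


def _align_axis_to_x(chain: Chain) -> None:
    cas = np.array([r.atom("CA").coord for r in chain.residues])
    if len(cas) < 2:
        centroid = _chain_coords(chain).mean(axis=0)
        _transform_chain(chain, np.eye(3), -centroid)
        return
    v = cas[-1] - cas[0]
    v = v / np.linalg.norm(v)
    x = np.array([1.0, 0.0, 0.0])
    axis = np.cross(v, x)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        rot = np.eye(3)
    else:
        angle = np.degrees(np.arccos(np.clip(np.dot(v, x), -1.0, 1.0)))
        rot = rotation_matrix(axis / norm, angle)
    centroid = _chain_coords(chain).mean(axis=0)
    _transform_chain(chain, rot, -rot @ centroid)


def _place_at_clearance(chain: Chain, direction: np.ndarray,
                        avoid_coords: np.ndarray, target: float) -> None:
    """Translate the rigid chain along ``direction`` until its minimum
    heavy-atom distance to ``avoid_coords`` equals ``target`` (bisection)."""
    direction = direction / np.linalg.norm(direction)
    base = _chain_coords(chain)

    def min_dist(t: float) -> float:
        c = base + t * direction
        diff = c[:, None, :] - avoid_coords[None, :, :]
        return float(np.sqrt((diff ** 2).sum(-1)).min())

    lo, hi = 0.0, 80.0
    if min_dist(lo) > target:
        # start outside: move towards the peptide instead
        lo, hi = -80.0, 0.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if min_dist(mid) < target:
                hi = mid
            else:
                lo = mid
        _transform_chain(chain, np.eye(3), lo * direction)
        return
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    _transform_chain(chain, np.eye(3), hi * direction)


def _fibonacci_shell(center: np.ndarray, radius: float,
                     spacing: float) -> np.ndarray:
    n = max(8, int(np.ceil(4.0 * np.pi * radius ** 2 / spacing ** 2)))
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    pts = np.column_stack([np.sin(phi) * np.cos(theta),
                           np.sin(phi) * np.sin(theta),
                           np.cos(phi)])
    return center + radius * pts


def make_micro_groove(seed: int = 0, occlude_pocket_b: bool = False,
                      full: bool = False) -> StructureModel:
    """Idealised micro peptide/MHC-like complex.

    Chain A is the MHC-like heavy chain (two helix walls, two floor
    strands; ~46 residues), chain C the 9-mer peptide. ``full`` adds a
    mock light chain (chain B) and a heavy-chain segment numbered beyond
    180, both far from the groove, to exercise trimming.
    ``occlude_pocket_b`` adds the arginine-excluding scaffold shell around
    peptide position 2 (single-atom glycine residues numbered from 500).
    The ``seed`` is accepted for interface uniformity; the construction is
    fully deterministic.
    """
    del seed  # deterministic by construction
    pep_chain, _ = _chain_from_sequence(PEPTIDE_SEQ, -120.0, 120.0, "C", 1)
    _align_axis_to_x(pep_chain)
    pep_coords = _chain_coords(pep_chain)

    heavy = Chain(id="A")
    placed = pep_coords
    # floor pads below the peptide (placed against the peptide only),
    # then helix wall segments flanking both sides (placed against
    # everything already present); each part slides along its approach
    # direction until it reaches van der Waals contact
    parts = []
    resseq = 1
    for x in (-12.0, -6.0, 0.0, 6.0, 12.0):
        parts.append((FLOOR_SEQ, -120.0, 120.0, resseq,
                      (x, 0.0, 0.0), (0, 0, -1), FLOOR_CLEARANCE, "pep"))
        resseq += 10
    for x in (-8.0, 8.0):
        for ysign in (1.0, -1.0):
            parts.append((WALL_SEQ, -57.0, -47.0, resseq,
                          (x, 0.0, 2.0), (0, ysign, 0), WALL_CLEARANCE,
                          "union"))
            resseq += 10
    for seq, phi, psi, first, offset, approach, clearance, mode in parts:
        part, _ = _chain_from_sequence(seq, phi, psi, "A", first)
        _align_axis_to_x(part)
        _transform_chain(part, np.eye(3), np.array(offset, dtype=float))
        avoid = pep_coords if mode == "pep" else placed
        _place_at_clearance(part, np.array(approach, dtype=float), avoid,
                            clearance)
        heavy.residues.extend(part.residues)
        placed = np.vstack([placed, _chain_coords(part)])

    if occlude_pocket_b:
        # occlusion shell: positively charged amine-like pseudo-atoms
        # (lysine NZ) centred on the second peptide position, modelling a
        # pocket that sterically and electrostatically excludes the long
        # charged Arg side chain while neutral Gln still fits
        ca2 = pep_chain.residues[1].atom("CA").coord
        shell = _fibonacci_shell(ca2, CAGE_RADIUS, CAGE_SPACING)
        existing = np.vstack([pep_coords, _chain_coords(heavy)])
        resseq = 500
        for pt in shell:
            if np.linalg.norm(existing - pt, axis=1).min() < CAGE_KEEPOUT:
                continue
            res = Residue(name="LYS", resseq=resseq)
            res.atoms.append(Atom(name="NZ", element="N", coord=pt.copy()))
            heavy.residues.append(res)
            resseq += 1

    chains = [heavy, pep_chain]
    if full:
        # mock light chain far below the groove
        light, _ = _chain_from_sequence("AEAEAEAEAE", -57.0, -47.0, "B", 1)
        _align_axis_to_x(light)
        _transform_chain(light, np.eye(3), np.array([0.0, 0.0, -30.0]))
        chains.insert(1, light)
        # mock membrane-proximal segment numbered beyond the groove domain
        distal, _ = _chain_from_sequence("GDGDGDGDGD", -120.0, 120.0,
                                         "A", 181)
        _align_axis_to_x(distal)
        _transform_chain(distal, np.eye(3), np.array([40.0, 0.0, 0.0]))
        heavy.residues.extend(distal.residues)
    return StructureModel(chains=chains, source="micro-groove")


def micro_groove_heavy_sequence(model: StructureModel) -> str:
    return model.chain("A").sequence()


# --- melt curves ---------------------------------------------------------


def make_melt_curves(seed: int,
                     params: list[tuple[float, float, float, float]],
                     noise_sd: float = 0.0) -> list[MeltCurve]:
    """One synthetic curve per (f_min, f_max, tm, k) tuple; sub-seeds are
    drawn deterministically from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(len(params))
    return [simulate_melt_curve(*p, noise_sd=noise_sd, seed=int(s))
            for p, s in zip(params, seeds)]
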