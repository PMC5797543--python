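"""Bundled chemical reference data.

Residue masses (standard IUPAC average and monoisotopic residue-mass
tables), element van der Waals radii, polar/charge classifications, and a
compact side-chain geometry layer: per-residue internal-coordinate
topologies (heavy atoms only, Engh & Huber-style bond lengths/angles) plus
a small backbone-independent rotamer library (<= 8 rotamers per type,
modal chi values). The library is deliberately tiny for reproducibility;
richer libraries can be plugged in wherever a ``rotamers`` mapping is
accepted.
"""

from __future__ import annotations

# --- masses (Da) ---------------------------------------------------------

WATER_AVERAGE = 18.01528
WATER_MONO = 18.010565

RESIDUE_MASS_AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

RESIDUE_MASS_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# --- elements ------------------------------------------------------------

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

LJ_WELL_DEPTH = {"C": 0.12, "N": 0.16, "O": 0.16, "S": 0.20, "H": 0.02}

# --- atom classifications -----------------------------------------------

# side-chain heavy atoms bearing polar hydrogens (donors) / lone pairs
# (acceptors); backbone N is always a donor, backbone O an acceptor
HB_DONOR_ATOMS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"), ("TRP", "NE1"), ("HIS", "ND1"), ("HIS", "NE2"),
}
HB_ACCEPTOR_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}

# formal charges spread over the terminal atoms of ionisable side chains
PARTIAL_CHARGES = {
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("LYS", "NZ"): 1.0,
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
}

APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO",
                   "GLY"}


def atom_element(atom_name: str) -> str:
    """Element from a heavy-atom PDB name (first letter after digits)."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


# --- side-chain internal coordinates ------------------------------------

# Each entry: (atom, (ref_a, ref_b, ref_c), bond, angle, torsion_spec)
# where the new atom bonds ref_c, ``angle`` is ref_b/ref_c/new and the
# torsion ref_a-ref_b-ref_c-new is either ("chi", k, offset_deg) or
# ("fixed", deg). CB placement (common to all non-Gly types) is handled by
# the builder with torsion C-N-CA-CB fixed at the L-configuration value.

CB_TORSION = -122.6  # dihedral C-N-CA-CB for L-amino acids
CB_BOND = 1.530
CB_ANGLE = 110.5  # N-CA-CB

_CHI = lambda k, off=0.0: ("chi", k, off)  # noqa: E731
_FIX = lambda deg: ("fixed", deg)  # noqa: E731

SIDECHAIN_TOPOLOGY: dict[str, list] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, _CHI(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, _CHI(1))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, _CHI(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _CHI(1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.521, 110.5, _CHI(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _CHI(1, 122.0))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, _CHI(1)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _CHI(2)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _CHI(2, 122.0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, _CHI(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _CHI(1, -122.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _CHI(2))],
    "MET": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI(1)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _CHI(2)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _CHI(3))],
    "PRO": [("CG", ("N", "CA", "CB"), 1.492, 104.5, _FIX(-28.0)),
            ("CD", ("CA", "CB", "CG"), 1.503, 106.1, _FIX(38.0))],
    "PHE": [("CG", ("N", "CA", "CB"), 1.502, 113.8, _CHI(1)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _CHI(2)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _CHI(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.0, _FIX(180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.0, _FIX(180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, _FIX(0.0))],
    "TYR": [("CG", ("N", "CA", "CB"), 1.502, 113.8, _CHI(1)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _CHI(2)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _CHI(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.0, _FIX(180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.0, _FIX(180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, _FIX(0.0)),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, _FIX(180.0))],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.6, _CHI(1)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _CHI(2)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, _CHI(2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, _FIX(180.0)),
            ("CE2", ("CG", "CD1", "NE1"), 1.370, 109.0, _FIX(0.0)),
            ("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, _FIX(180.0)),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, _FIX(180.0)),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, _FIX(180.0)),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, _FIX(0.0))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _CHI(1)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _CHI(2)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _CHI(2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _CHI(1)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _CHI(2)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _CHI(2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _CHI(2)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _CHI(3)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _CHI(3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _CHI(2)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _CHI(3)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _CHI(3, 180.0))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _CHI(2)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, _CHI(3)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _CHI(4))],
    "ARG": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _CHI(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _CHI(2)),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _CHI(3)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, _CHI(4)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, _FIX(180.0)),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, _FIX(0.0))],
    "HIS": [("CG", ("N", "CA", "CB"), 1.497, 113.8, _CHI(1)),
            ("ND1", ("CA", "CB", "CG"), 1.371, 122.7, _CHI(2)),
            ("CD2", ("CA", "CB", "CG"), 1.356, 131.2, _CHI(2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.319, 109.0, _FIX(180.0)),
            ("NE2", ("CG", "ND1", "CE1"), 1.374, 111.7, _FIX(0.0))],
}

N_CHI = {
    "GLY": 0, "ALA": 0, "PRO": 0, "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "TRP": 2, "ASP": 2, "ASN": 2,
    "HIS": 2, "MET": 3, "GLU": 3, "GLN": 3, "LYS": 4, "ARG": 4,
}


def _norm(rotamers: list[tuple[tuple[float, ...], float]]
          ) -> list[tuple[tuple[float, ...], float]]:
    total = sum(p for _, p in rotamers)
    return [(chis, p / total) for chis, p in rotamers]


# Backbone-independent modal rotamers (chi tuples in degrees, prior
# probability). Ordered by decreasing probability; the first entry is the
# "most probable rotamer" used at threading time.
ROTAMER_LIBRARY: dict[str, list[tuple[tuple[float, ...], float]]] = {
    "GLY": [((), 1.0)],
    "ALA": [((), 1.0)],
    "PRO": [((), 1.0)],
    "SER": _norm([((-65.0,), 0.45), ((62.0,), 0.30), ((180.0,), 0.25)]),
    "CYS": _norm([((-65.0,), 0.50), ((-177.0,), 0.30), ((63.0,), 0.20)]),
    "THR": _norm([((-60.0,), 0.45), ((60.0,), 0.45), ((180.0,), 0.10)]),
    "VAL": _norm([((175.0,), 0.60), ((-60.0,), 0.25), ((63.0,), 0.15)]),
    "LEU": _norm([((-65.0, 175.0), 0.55), ((177.0, 62.0), 0.30),
                  ((-85.0, 65.0), 0.15)]),
    "ILE": _norm([((-65.0, 170.0), 0.60), ((-57.0, -60.0), 0.20),
                  ((62.0, 170.0), 0.20)]),
    "MET": _norm([((-65.0, 180.0, 75.0), 0.30), ((-65.0, 180.0, 180.0), 0.25),
                  ((180.0, 180.0, 180.0), 0.25), ((-65.0, -65.0, -70.0), 0.20)]),
    "PHE": _norm([((-65.0, 90.0), 0.50), ((180.0, 80.0), 0.35),
                  ((62.0, 90.0), 0.15)]),
    "TYR": _norm([((-65.0, 90.0), 0.50), ((180.0, 80.0), 0.35),
                  ((62.0, 90.0), 0.15)]),
    "TRP": _norm([((-65.0, 100.0), 0.40), ((180.0, -105.0), 0.35),
                  ((62.0, -90.0), 0.25)]),
    "ASP": _norm([((-70.0, -15.0), 0.50), ((-170.0, 10.0), 0.30),
                  ((62.0, -10.0), 0.20)]),
    "ASN": _norm([((-65.0, -20.0), 0.45), ((-170.0, 30.0), 0.30),
                  ((62.0, -75.0), 0.25)]),
    "HIS": _norm([((-65.0, -70.0), 0.45), ((180.0, 60.0), 0.30),
                  ((62.0, -75.0), 0.25)]),
    "GLU": _norm([((-65.0, 180.0, -10.0), 0.40), ((180.0, 180.0, 0.0), 0.35),
                  ((-60.0, -60.0, -20.0), 0.25)]),
    "GLN": _norm([((-65.0, 180.0, 0.0), 0.35), ((180.0, 180.0, 0.0), 0.30),
                  ((180.0, 65.0, 0.0), 0.20), ((-60.0, -60.0, -40.0), 0.15)]),
    "LYS": _norm([((-65.0, 180.0, 180.0, 180.0), 0.40),
                  ((180.0, 180.0, 180.0, 180.0), 0.35),
                  ((-60.0, -60.0, 180.0, 180.0), 0.25)]),
    "ARG": _norm([((-65.0, 180.0, 180.0, 180.0), 0.20),
                  ((180.0, 180.0, 180.0, 180.0), 0.15),
                  ((-65.0, 180.0, 65.0, 85.0), 0.12),
                  ((-65.0, 180.0, 180.0, -85.0), 0.12),
                  ((180.0, 65.0, 65.0, 85.0), 0.10),
                  ((-60.0, -60.0, 180.0, 180.0), 0.11),
                  ((62.0, 180.0, 180.0, 180.0), 0.10),
                  ((180.0, 180.0, 65.0, 85.0), 0.10)]),
}
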