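"""Internal-coordinate geometry: dihedrals, atom placement, chain building.

Atom placement uses the natural-extension reference frame (NeRF): a new
atom D bonded to C is positioned from the chain A-B-C given the C-D bond
length, the B-C-D bond angle and the A-B-C-D torsion. Peptide chains are
built with standard heavy-atom bond lengths/angles and caller-supplied
phi/psi (omega fixed trans), which is what both the synthetic micro-groove
fixture and the dihedral-classification tests rely on.
"""

from __future__ import annotations

import math

import numpy as np


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    return math.degrees(math.atan2(y, x))


def bond_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in degrees."""
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom D bonded to C.

    ``bond`` = |C-D| in Angstrom, ``angle`` = B-C-D in degrees,
    ``torsion`` = A-B-C-D in degrees.
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


# Engh & Huber-style ideal backbone geometry (Angstrom, degrees)
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
OMEGA = 180.0


def build_backbone(n_res: int, phi: list[float], psi: list[float]
                   ) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O backbone coordinates for ``n_res`` residues.

    ``phi[i]`` and ``psi[i]`` are the torsions at residue i (0-based);
    phi[0] and psi[-1] are still consumed for atom placement even though
    they are undefined as observables. Omega is fixed trans.
    """
    if len(phi) != n_res or len(psi) != n_res:
        raise ValueError("phi/psi lists must have one entry per residue")
    residues: list[dict[str, np.ndarray]] = []
    # seed first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([N_CA, 0.0, 0.0])
    ang = math.radians(ANG_N_CA_C)
    c0 = ca0 + CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       C_N, ANG_CA_C_N, psi[i - 1])
        ca = place_atom(prev["CA"], prev["C"], n,
                        N_CA, ANG_C_N_CA, OMEGA)
        c = place_atom(prev["C"], n, ca,
                       CA_C, ANG_N_CA_C, phi[i])
        residues.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next residue's N around the CA-C axis,
    # i.e. torsion N-CA-C-O = psi + 180
    for i, res in enumerate(residues):
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              C_O, ANG_CA_C_O, psi[i] + 180.0)
    return residues


def backbone_phi_psi(residues: list[dict[str, np.ndarray]]
                     ) -> list[tuple[float | None, float | None]]:
    """Observable (phi, psi) per residue; None at chain termini."""
    out: list[tuple[float | None, float | None]] = []
    for i in range(len(residues)):
        phi = psi = None
        if i > 0:
            phi = dihedral(residues[i - 1]["C"], residues[i]["N"],
                           residues[i]["CA"], residues[i]["C"])
        if i + 1 < len(residues):
            psi = dihedral(residues[i]["N"], residues[i]["CA"],
                           residues[i]["C"], residues[i + 1]["N"])
        out.append((phi, psi))
    return out


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])
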