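"""Internal-coordinate geometry: torsions, atom placement, ideal backbones.

The backbone builder uses standard peptide bond lengths and angles and places
atoms by the natural extension reference frame (NeRF) construction, so toy
chains have correct Cα–Cα spacing (3.8 Å) and, for the α-helical torsions
(φ, ψ) = (−57°, −47°), the canonical 1.5 Å rise and ~100° twist per residue.
"""

from __future__ import annotations

import numpy as np

from .core import ATOMIC_MASSES, StructureModel

__all__ = ["dihedral_angle", "place_atom", "build_backbone", "random_rotation"]

# ideal peptide geometry (Engh–Huber style averages)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position d with |cd| = bond, ∠(b,c,d) = angle, torsion(a,b,c,d) = dihedral."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms for placement")
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   omega: float = OMEGA_TRANS) -> StructureModel:
    """Build an all-trans peptide backbone (N, CA, C, O per residue).

    ``phi[0]`` is unused (no preceding carbonyl); arrays must share length
    n_residues ≥ 2.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res or n_res < 2:
        raise ValueError("phi and psi must share length >= 2")
    coords = {}
    coords[(0, "N")] = np.zeros(3)
    coords[(0, "CA")] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        n_i, ca_i, c_i = coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")]
        coords[(i, "O")] = place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O,
                                      psi[i] + 180.0)
        if i + 1 >= n_res:
            break
        n_next = place_atom(n_i, ca_i, c_i, BOND_C_N, ANGLE_CA_C_N, psi[i])
        ca_next = place_atom(ca_i, c_i, n_next, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_next = place_atom(c_i, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C,
                            phi[i + 1])
        coords[(i + 1, "N")] = n_next
        coords[(i + 1, "CA")] = ca_next
        coords[(i + 1, "C")] = c_next

    names, elements, resids, xyz = [], [], [], []
    for i in range(n_res):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            names.append(name)
            elements.append(el)
            resids.append(i + 1)
            xyz.append(coords[(i, name)])
    return StructureModel(
        atom_names=names,
        elements=elements,
        resids=resids,
        resnames=["ALA"] * len(names),
        chain_ids=["A"] * len(names),
        masses=[ATOMIC_MASSES[e] for e in elements],
        coords=np.asarray(xyz),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A proper rotation matrix drawn uniformly (Haar) via quaternions."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
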