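"""Coarse secondary-structure classification (H / E / C).

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
energy  E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332 kcal/mol,
a bond being assigned when E < −0.5 kcal/mol. Amide hydrogens are
reconstructed from N, Cα and the preceding carbonyl carbon, so models
without hydrogens work. α-helix (H) comes from consecutive i→i+4 bond
turns, strand (E) from parallel/antiparallel bridge ladders, everything
else is coil (C). The full 8-state alphabet (3₁₀/π helices, bends, ...) is
deliberately out of scope: only coarse content over time is reported.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Ensemble, StructureModel

__all__ = ["classify_secondary_structure", "ss_fractions"]

KS_COUPLING = 0.084 * 332.0      # kcal/mol·Å
KS_BOND_ENERGY = -0.5            # kcal/mol
NH_BOND_LENGTH = 1.01            # Å


def _backbone_table(frame: StructureModel) -> tuple[list[dict], list[int]]:
    """Per-residue backbone coordinates in chain order."""
    residues: list[dict] = []
    resids: list[int] = []
    key = None
    for i in range(frame.n_atoms):
        if frame.is_hetatm[i]:
            continue
        k = (str(frame.chain_ids[i]), int(frame.resids[i]))
        if k != key:
            residues.append({"chain": k[0]})
            resids.append(k[1])
            key = k
        name = str(frame.atom_names[i])
        if name in ("N", "CA", "C", "O"):
            residues[-1][name] = frame.coords[i]
    return residues, resids


def _place_amide_h(res: dict, prev: dict | None) -> np.ndarray | None:
    if prev is None or "C" not in prev or "N" not in res or "CA" not in res:
        return None
    n, ca, c_prev = res["N"], res["CA"], prev["C"]
    d1 = n - c_prev
    d2 = n - ca
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    bis = d1 + d2
    nb = np.linalg.norm(bis)
    if nb < 1e-8:
        return None
    return n + NH_BOND_LENGTH * bis / nb


def _hbond_matrix(residues: list[dict]) -> np.ndarray:
    """bond[i, j]: N-H of residue i donates to C=O of residue j."""
    n = len(residues)
    bond = np.zeros((n, n), dtype=bool)
    hs: list[np.ndarray | None] = []
    for i, res in enumerate(residues):
        prev = residues[i - 1] if i > 0 and residues[i - 1]["chain"] == res["chain"] else None
        hs.append(_place_amide_h(res, prev))
    for i, res in enumerate(residues):
        h = hs[i]
        if h is None or "N" not in res:
            continue
        n_i = res["N"]
        for j, other in enumerate(residues):
            if abs(i - j) < 2 or "C" not in other or "O" not in other:
                continue
            c, o = other["C"], other["O"]
            r_on = np.linalg.norm(o - n_i)
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - n_i)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clash; no physical bond energy
            e = KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            bond[i, j] = e < KS_BOND_ENERGY
    return bond


def classify_secondary_structure(frame: StructureModel) -> np.ndarray:
    """Per-residue labels in {'H', 'E', 'C'} for one structure.

    Residues missing backbone atoms are marked C with a warning.
    """
    residues, _ = _backbone_table(frame)
    n = len(residues)
    labels = np.full(n, "C", dtype="U1")
    incomplete = [i for i, r in enumerate(residues)
                  if not all(k in r for k in ("N", "CA", "C", "O"))]
    if incomplete:
        warnings.warn(f"{len(incomplete)} residues missing backbone atoms; "
                      "marked coil", stacklevel=2)
    bond = _hbond_matrix(residues)
    # i -> i+4 turns: acceptor i, donor i+4
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        turn4[i] = bond[i + 4, i]
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            helix[i:i + 4] = True
    # bridges (Kabsch–Sander parallel / antiparallel patterns)
    strand = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (bond[j, i - 1] and bond[i + 1, j]) or \
                       (bond[i, j - 1] and bond[j + 1, i])
            anti = (bond[i, j] and bond[j, i]) or \
                   (bond[j + 1, i - 1] and bond[i + 1, j - 1])
            if parallel or anti:
                strand[i] = strand[j] = True
    labels[strand] = "E"
    labels[helix] = "H"   # helix wins over strand, per DSSP priority
    for i in incomplete:
        labels[i] = "C"
    return labels


def ss_fractions(ens: Ensemble) -> dict[str, np.ndarray]:
    """Fractions of H, E and C per frame (each frame's fractions sum to 1)."""
    out = {"H": [], "E": [], "C": []}
    for i in range(ens.n_frames):
        labels = classify_secondary_structure(ens.frame(i))
        n = len(labels)
        for k in out:
            out[k].append((labels == k).sum() / n)
    return {k: np.asarray(v) for k, v in out.items()}
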