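"""Ligand-centric analyses: pocket distance, interaction fingerprints,
Tanimoto similarity and persistence timelines.

Fingerprint bits are (residue, interaction class) pairs — the residue-level
annotation a per-frame interaction diagram or persistence timeline uses —
rather than chemical substructure keys. Classes and default cutoffs:

* ``any_contact``  — heavy-atom minimum distance ≤ 4.5 Å;
* ``hydrophobic``  — carbon–carbon minimum distance ≤ 4.0 Å;
* ``hbond_donor`` / ``hbond_acceptor`` — the geometric hydrogen-bond
  predicate (donor on the protein / on the ligand respectively).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Ensemble, SelectionMask, StructureModel
from .hbonds import ANGLE_CUT_DEFAULT, D_CUT_DEFAULT, hbond_count
from .superpose import ProfileSeries

__all__ = [
    "FingerprintSeries", "InteractionTimeline", "pocket_center_distance",
    "frame_fingerprint", "fingerprint_series", "tanimoto_matrix",
    "interaction_timeline", "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = {"any_contact": 4.5, "hydrophobic": 4.0,
                   "hbond_distance": D_CUT_DEFAULT,
                   "hbond_angle": ANGLE_CUT_DEFAULT}
_CLASSES = ("any_contact", "hydrophobic", "hbond_donor", "hbond_acceptor")


@dataclass
class FingerprintSeries:
    """Per-frame interaction bit vectors with stable bit definitions."""

    bit_definitions: list[tuple[int, str]]   # (residue, interaction class)
    bits: np.ndarray                         # (M, B) in {0, 1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[1] != len(self.bit_definitions):
            raise ValueError("bits must be (M, B) matching bit_definitions")
        if len(self.bit_definitions) < 1:
            raise ValueError("at least one bit required")
        if np.any(self.bits > 1):
            raise ValueError("bits must be 0/1")


@dataclass
class InteractionTimeline:
    """Occupancy and run-length encoding per (residue, class) bit."""

    entries: dict      # (residue, class) -> {occupancy, runs, longest_run}
    n_frames: int
    ranking: list      # residues sorted by total contact occupancy, descending


def pocket_center_distance(ens: Ensemble, ligand: SelectionMask,
                           pocket_residues: SelectionMask) -> ProfileSeries:
    """Distance (Å) between the ligand centroid and the pocket Cα centroid."""
    if len(ligand) == 0 or len(pocket_residues) == 0:
        raise ValueError("empty selection")
    topo = ens.topology
    ca = topo.atom_names[pocket_residues.indices] == "CA"
    pocket_idx = pocket_residues.indices[ca] if ca.any() else pocket_residues.indices
    lig = ens.frames[:, ligand.indices].mean(axis=1)
    poc = ens.frames[:, pocket_idx].mean(axis=1)
    vals = np.linalg.norm(lig - poc, axis=1)
    return ProfileSeries(kind="pocket_distance", values=vals, times=ens.times,
                         unit="angstrom")


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a[:, None] - b[None]) ** 2).sum(axis=-1).min()))


def frame_fingerprint(frame: StructureModel, ligand: SelectionMask,
                      protein: SelectionMask,
                      cutoffs: dict | None = None,
                      residues: np.ndarray | None = None,
                      classes: tuple[str, ...] = _CLASSES
                      ) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """One interaction bit vector for a single frame.

    Returns (bits, bit_definitions); ``residues`` fixes the residue set (and
    order) so fingerprints are comparable across frames.
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)
    lig_idx = ligand.indices
    prot_idx = protein.indices
    lig_xyz = frame.coords[lig_idx]
    if residues is None:
        residues = np.unique(frame.resids[prot_idx])
    defs = [(int(r), c) for r in residues for c in classes]
    bits = np.zeros(len(defs), dtype=np.uint8)
    lig_carbon = np.char.upper(frame.elements[lig_idx]) == "C"
    lig_polar = np.isin(np.char.upper(frame.elements[lig_idx]), ["N", "O"])
    b = 0
    for r in residues:
        res_idx = prot_idx[frame.resids[prot_idx] == r]
        res_xyz = frame.coords[res_idx]
        dmin = _min_dist(res_xyz, lig_xyz)
        if dmin < 0.5:
            warnings.warn(f"residue {r}: ligand-protein clash (d={dmin:.2f} Å)",
                          stacklevel=2)
        for c in classes:
            hit = False
            if c == "any_contact":
                hit = dmin <= cut["any_contact"]
            elif c == "hydrophobic":
                res_c = res_xyz[np.char.upper(frame.elements[res_idx]) == "C"]
                if len(res_c) and lig_carbon.any():
                    hit = _min_dist(res_c, lig_xyz[lig_carbon]) <= cut["hydrophobic"]
            elif c == "hbond_donor":
                # protein N/O donates to ligand N/O
                res_pol = res_idx[np.isin(np.char.upper(frame.elements[res_idx]),
                                          ["N", "O"])]
                if len(res_pol) and lig_polar.any():
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        hit = hbond_count(
                            frame, SelectionMask(np.sort(res_pol)),
                            SelectionMask(np.sort(lig_idx[lig_polar])),
                            cut["hbond_distance"], cut["hbond_angle"]) > 0
            elif c == "hbond_acceptor":
                res_pol = res_idx[np.isin(np.char.upper(frame.elements[res_idx]),
                                          ["N", "O"])]
                if len(res_pol) and lig_polar.any():
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        hit = hbond_count(
                            frame, SelectionMask(np.sort(lig_idx[lig_polar])),
                            SelectionMask(np.sort(res_pol)),
                            cut["hbond_distance"], cut["hbond_angle"]) > 0
            bits[b] = hit
            b += 1
    return bits, defs


def fingerprint_series(ens: Ensemble, ligand: SelectionMask,
                       protein: SelectionMask, cutoffs: dict | None = None,
                       classes: tuple[str, ...] = _CLASSES) -> FingerprintSeries:
    """Fingerprints for every frame, with a stable bit layout."""
    residues = np.unique(ens.topology.resids[protein.indices])
    rows = []
    defs = None
    for i in range(ens.n_frames):
        bits, defs = frame_fingerprint(ens.frame(i), ligand, protein, cutoffs,
                                       residues, classes)
        rows.append(bits)
    return FingerprintSeries(bit_definitions=defs, bits=np.asarray(rows))


def tanimoto_matrix(fp: FingerprintSeries, stride: int = 1) -> np.ndarray:
    """Pairwise Tanimoto similarity of frame fingerprints.

    T(a, b) = |a∧b| / |a∨b|; two all-zero fingerprints are defined as
    identical (T = 1), which is logged when it happens.
    """
    bits = fp.bits[::stride].astype(bool)
    if not bits.any():
        warnings.warn("all fingerprints empty; Tanimoto matrix is all ones",
                      stacklevel=2)
    inter = (bits[:, None] & bits[None]).sum(axis=2).astype(float)
    union = (bits[:, None] | bits[None]).sum(axis=2).astype(float)
    empty_pair = union == 0
    if empty_pair.any() and bits.any():
        warnings.warn("empty-fingerprint pairs present; their Tanimoto set to 1",
                      stacklevel=2)
    union[empty_pair] = 1.0
    inter[empty_pair] = 1.0
    return inter / union


def interaction_timeline(fp: FingerprintSeries) -> InteractionTimeline:
    """Run-length encoding, occupancy and residue ranking per bit."""
    m, nbits = fp.bits.shape
    entries = {}
    per_res: dict[int, float] = {}
    for b, (res, cls) in enumerate(fp.bit_definitions):
        col = fp.bits[:, b].astype(bool)
        runs = []
        start = None
        for t in range(m):
            if col[t] and start is None:
                start = t
            elif not col[t] and start is not None:
                runs.append((start, t - start))
                start = None
        if start is not None:
            runs.append((start, m - start))
        occ = col.mean()
        entries[(res, cls)] = {
            "occupancy": float(occ),
            "runs": runs,
            "longest_run": max((l for _, l in runs), default=0),
        }
        if cls == "any_contact":
            per_res[res] = per_res.get(res, 0.0) + float(occ)
    ranking = sorted(per_res, key=lambda r: (-per_res[r], r))
    return InteractionTimeline(entries=entries, n_frames=m, ranking=ranking)
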