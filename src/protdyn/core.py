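"""Core containers for structures, conformational ensembles and atom selections.

Unit conventions used throughout the package:

* coordinates and distances in angstrom (Å),
* times in nanoseconds (ns),
* masses in dalton (Da),
* residue indices 1-based and sequential per chain (author numbering from the
  source file is retained as metadata for reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructureModel",
    "Ensemble",
    "SelectionMask",
    "ATOMIC_MASSES",
    "VDW_RADII",
    "guess_element",
]

#: Atomic masses (Da) for elements that occur in protein/ligand systems.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "SE": 78.971,
}

#: Bondi van der Waals radii (Å), used by the solvent-accessibility routine.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 2.00, "MN": 2.00, "SE": 1.90,
}


def guess_element(atom_name: str) -> str:
    """Guess the element symbol from a PDB-style atom name.

    Follows the usual heuristic: strip digits, try the two-letter symbol
    first (Cl, Br, ...), fall back to the first letter.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot guess element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in ATOMIC_MASSES and two not in {"CA", "CL", "NA", "MG", "SE"}:
        return two
    # Two-letter symbols only when the name is clearly not a protein atom
    # name: 'CA' in a protein is a Cα carbon, not calcium.
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE"} and len(stripped) == 2:
        return two
    one = stripped[0].upper()
    if one in ATOMIC_MASSES:
        return one
    raise ValueError(f"unknown element for atom name {atom_name!r}")


def _as_str_array(values: Iterable[str]) -> np.ndarray:
    return np.asarray(list(values), dtype="U6")


@dataclass
class StructureModel:
    """One set of atoms: names, elements, residues, chains, masses, coordinates.

    ``resids`` are 1-based and sequential per chain; ``author_resids`` keeps
    the numbering of the source file (e.g. SER289 in the human PPARG ligand
    binding domain) for reporting. HETATM ligand atoms live in the same model,
    flagged by ``is_hetatm``, so ligand analyses reuse the same machinery.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chain_ids: np.ndarray
    masses: np.ndarray
    coords: np.ndarray
    author_resids: np.ndarray | None = None
    is_hetatm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_names = _as_str_array(self.atom_names)
        self.elements = _as_str_array(self.elements)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = _as_str_array(self.resnames)
        self.chain_ids = _as_str_array(self.chain_ids)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.n_atoms
        if n < 1:
            raise ValueError("StructureModel requires at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        for arr, name in ((self.elements, "elements"), (self.resids, "resids"),
                          (self.resnames, "resnames"), (self.chain_ids, "chain_ids"),
                          (self.masses, "masses")):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_atoms {n}")
        if self.author_resids is None:
            self.author_resids = self.resids.copy()
        else:
            self.author_resids = np.asarray(self.author_resids, dtype=int)
        if self.is_hetatm is None:
            self.is_hetatm = np.zeros(n, dtype=bool)
        else:
            self.is_hetatm = np.asarray(self.is_hetatm, dtype=bool)
        # residue indices non-decreasing within each chain
        for chain in np.unique(self.chain_ids):
            r = self.resids[self.chain_ids == chain]
            if np.any(np.diff(r) < 0):
                raise ValueError(f"residue indices decrease within chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered (chain, resid) pairs, one per residue."""
        keys: list[tuple[str, int]] = []
        for c, r in zip(self.chain_ids, self.resids):
            if not keys or keys[-1] != (c, r):
                keys.append((str(c), int(r)))
        return keys

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """A copy of this model carrying different coordinates."""
        return replace(self, coords=np.asarray(coords, dtype=float))

    def subset(self, mask: "SelectionMask") -> "StructureModel":
        idx = mask.indices
        return StructureModel(
            atom_names=self.atom_names[idx],
            elements=self.elements[idx],
            resids=self.resids[idx],
            resnames=self.resnames[idx],
            chain_ids=self.chain_ids[idx],
            masses=self.masses[idx],
            coords=self.coords[idx],
            author_resids=self.author_resids[idx],
            is_hetatm=self.is_hetatm[idx],
        )


@dataclass
class Ensemble:
    """M frames × N atoms × 3 coordinates (Å) with frame times (ns).

    The universal carrier for MD trajectories and multi-model PDB sets alike.
    """

    topology: StructureModel
    frames: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (M, N, 3)")
        m, n, _ = self.frames.shape
        if m < 1:
            raise ValueError("ensemble needs at least one frame")
        if n != self.topology.n_atoms:
            raise ValueError(
                f"frames carry {n} atoms but topology has {self.topology.n_atoms}")
        if self.times is None:
            self.times = np.arange(m, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (m,):
                raise ValueError("times length must equal number of frames")
            if m > 1 and np.any(np.diff(self.times) <= 0):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])

    def subset(self, mask: "SelectionMask") -> "Ensemble":
        return Ensemble(
            topology=self.topology.subset(mask),
            frames=self.frames[:, mask.indices, :],
            times=self.times.copy(),
        )


@dataclass(frozen=True)
class SelectionMask:
    """An ordered set of atom positions into a StructureModel.

    Positions are stored 0-based (numpy convention); they are unique, sorted
    and within ``[0, N)``.
    """

    indices: np.ndarray
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if len(idx) and (np.any(np.diff(idx) <= 0)):
            raise ValueError("indices must be strictly increasing (unique, sorted)")
        if len(idx) and idx[0] < 0:
            raise ValueError("indices must be non-negative")
        if self.n_atoms is not None and len(idx) and idx[-1] >= self.n_atoms:
            raise ValueError("index out of range for model")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def union(self, other: "SelectionMask") -> "SelectionMask":
        return SelectionMask(np.union1d(self.indices, other.indices),
                             self.n_atoms or other.n_atoms)

    def intersection(self, other: "SelectionMask") -> "SelectionMask":
        return SelectionMask(np.intersect1d(self.indices, other.indices),
                             self.n_atoms or other.n_atoms)

    @classmethod
    def from_bool(cls, mask: Sequence[bool]) -> "SelectionMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(np.flatnonzero(mask), n_atoms=len(mask))
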