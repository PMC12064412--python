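"""Kabsch superposition and per-trajectory structural statistics.

RMSD is computed on backbone atoms by default and RMSF on Cα atoms, the
usual choices when comparing liganded and unliganded runs of the same
protein; the reference frame for RMSD is the first frame unless one is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble, SelectionMask, StructureModel

__all__ = [
    "ProfileSeries", "ResidueProfile", "kabsch_superpose", "superpose_ensemble",
    "rmsd_series", "rmsf_profile", "radius_of_gyration",
]


@dataclass
class ProfileSeries:
    """A per-frame scalar series with units (rmsd/rg in Å, sasa in Å², ...)."""

    kind: str
    values: np.ndarray
    times: np.ndarray
    unit: str = ""
    labels: list[str] | None = None   # for multi-column series (e.g. Rg axes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise ValueError("values and times must have equal length")


@dataclass
class ResidueProfile:
    """A per-residue profile (e.g. RMSF in Å or a secondary-structure fraction)."""

    residue_index: np.ndarray
    value: np.ndarray
    kind: str = "rmsf"
    unit: str = "angstrom"

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.residue_index) != len(self.value):
            raise ValueError("one value per residue required")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``mobile @ rotation.T + translation ≈ reference``; the rotation is proper
    (det +1, reflections corrected) and the RMSD is the minimized
    (weighted) value in Å.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    a = mobile - mc
    b = reference - rc
    h = (w[:, None] * a).T @ b
    if np.linalg.matrix_rank(h) < 2:
        raise ValueError("degenerate geometry: correlation matrix rank < 2")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    rotated = a @ rot.T
    rmsd = float(np.sqrt((w[:, None] * (rotated - b) ** 2).sum()))
    trans = rc - mc @ rot.T
    return rot, trans, rmsd


def superpose_ensemble(ens: Ensemble, selection: SelectionMask | None = None,
                       reference: np.ndarray | None = None,
                       iterations: int = 3) -> Ensemble:
    """Superpose every frame onto the (iterated) mean structure.

    The fit uses ``selection`` atoms (default: all) but transforms all atoms.
    With ``reference`` given, a single pass onto it is done instead.
    """
    idx = selection.indices if selection is not None else slice(None)
    frames = ens.frames.copy()
    if reference is not None:
        targets = [np.asarray(reference, dtype=float)]
        rounds = 1
    else:
        targets = None
        rounds = iterations
    for _ in range(rounds):
        target = targets[0] if targets is not None else frames[:, idx].mean(axis=0)
        for k in range(len(frames)):
            rot, trans, _ = kabsch_superpose(frames[k, idx], target)
            frames[k] = frames[k] @ rot.T + trans
    return Ensemble(topology=ens.topology, frames=frames, times=ens.times.copy())


def rmsd_series(ens: Ensemble, selection: SelectionMask,
                reference: np.ndarray | None = None) -> ProfileSeries:
    """Per-frame Kabsch-minimized RMSD to a reference (default: first frame)."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    sub = ens.frames[:, selection.indices]
    ref = sub[0] if reference is None else np.asarray(reference, dtype=float)
    vals = np.array([kabsch_superpose(f, ref)[2] for f in sub])
    return ProfileSeries(kind="rmsd", values=vals, times=ens.times, unit="angstrom")


def rmsf_profile(ens: Ensemble, selection: SelectionMask,
                 presuperposed: bool = False) -> ResidueProfile:
    """Per-residue root-mean-square fluctuation about the mean structure.

    Frames are first superposed onto their iterated mean (3 rounds) on the
    selection, unless ``presuperposed``. Residues contributing several
    selected atoms report the square root of the mean of their atoms' MSF.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    if len(selection) == 0:
        raise ValueError("empty selection")
    work = ens if presuperposed else superpose_ensemble(ens, selection)
    sub = work.frames[:, selection.indices]
    mean = sub.mean(axis=0)
    msf = ((sub - mean[None]) ** 2).sum(axis=2).mean(axis=0)  # per atom
    resids = work.topology.resids[selection.indices]
    uniq = np.unique(resids)
    per_res = np.array([msf[resids == r].mean() for r in uniq])
    return ResidueProfile(residue_index=uniq, value=np.sqrt(per_res), kind="rmsf")


def radius_of_gyration(ens: Ensemble, selection: SelectionMask | None = None,
                       per_axis: bool = False) -> ProfileSeries:
    """Mass-weighted radius of gyration per frame, optionally per axis.

    The per-axis convention is the one used by gmx gyrate: Rg_x collects the
    spread in the *other two* coordinates, so a flat ring in the xy-plane has
    Rg_z → ring radius.
    """
    idx = selection.indices if selection is not None else np.arange(ens.n_atoms)
    if len(idx) == 0:
        raise ValueError("empty selection")
    m = ens.topology.masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    xyz = ens.frames[:, idx]
    com = (m[None, :, None] * xyz).sum(axis=1) / total
    d = xyz - com[:, None]
    sq = m[None, :, None] * d ** 2  # (M, n, 3)
    if per_axis:
        tot = sq.sum(axis=(1, 2))
        per = np.sqrt((tot[:, None] - sq.sum(axis=1)) / total)  # drop own axis
        return ProfileSeries(kind="rg_axis", values=per, times=ens.times,
                             unit="angstrom", labels=["Rg_x", "Rg_y", "Rg_z"])
    vals = np.sqrt(sq.sum(axis=(1, 2)) / total)
    return ProfileSeries(kind="rg", values=vals, times=ens.times, unit="angstrom")
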