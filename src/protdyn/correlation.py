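"""Correlated-motion and contact analyses.

* :func:`dccm` — the dynamic cross-correlation matrix
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩) of per-residue displacement
  vectors about the mean structure (frames superposed first);
* :func:`distance_matrices` — mean inter-residue distance, contact
  occupancy, and the mean (normalized) formation time of contact events;
* :func:`rdcm` — the residue distance correlation matrix: the Pearson
  correlation over time between per-residue mean-distance series
  s_i(t) = mean_j d_ij(t);
* :func:`windowed_pearson` — DCCMs within sliding windows;
* :func:`helix_distance_report` — per-segment-pair mean Cα distance trends
  (e.g. helix H10 against the rest of the fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Ensemble, SelectionMask
from .superpose import superpose_ensemble

__all__ = [
    "CorrelationMatrix", "ContactSummary", "dccm", "dccm_from_covariance",
    "distance_matrices", "rdcm", "windowed_pearson", "helix_distance_report",
]

CONTACT_CUTOFF_DEFAULT = 8.0   # Å, Cα–Cα


@dataclass
class CorrelationMatrix:
    """Symmetric per-residue matrix in [−1, 1] with unit diagonal."""

    labels: np.ndarray
    values: np.ndarray
    kind: str = "dccm"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.values)) > 1 + 1e-8:
            raise ValueError("entries must lie in [-1, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("entries must be finite")


@dataclass
class ContactSummary:
    """Mean distance (Å), occupancy in [0,1] and normalized formation time."""

    labels: np.ndarray
    mean_distance: np.ndarray
    occupancy: np.ndarray
    formation_time: np.ndarray   # NaN where never in contact
    cutoff: float


def _residue_coords(ens: Ensemble, selection: SelectionMask) -> tuple[np.ndarray, np.ndarray]:
    """(M, R, 3) one point per residue (mean of selected atoms) + labels."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    idx = selection.indices
    resids = ens.topology.resids[idx]
    uniq = np.unique(resids)
    sub = ens.frames[:, idx]
    out = np.empty((ens.n_frames, len(uniq), 3))
    for k, r in enumerate(uniq):
        out[:, k] = sub[:, resids == r].mean(axis=1)
    return out, uniq


def dccm(ens: Ensemble, selection: SelectionMask,
         presuperposed: bool = False) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the selected residues."""
    if ens.n_frames < 10:
        raise ValueError("need at least 10 frames for a stable DCCM")
    work = ens if presuperposed else superpose_ensemble(ens, selection)
    xyz, labels = _residue_coords(work, selection)
    d = xyz - xyz.mean(axis=0, keepdims=True)
    inner = np.einsum("mik,mjk->ij", d, d) / len(d)
    var = np.diag(inner).copy()
    zero = var <= 1e-30
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance residues; "
                      "their correlations set to 0", stacklevel=2)
        var[zero] = 1.0
    c = inner / np.sqrt(np.outer(var, var))
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    return CorrelationMatrix(labels=labels, values=c, kind="dccm")


def dccm_from_covariance(cov: np.ndarray,
                         labels: np.ndarray | None = None) -> CorrelationMatrix:
    """Analytic DCCM from a 3N×3N positional covariance matrix.

    C_ij = tr(Σ_ij) / √(tr(Σ_ii) tr(Σ_jj)) over the 3×3 blocks — the exact
    counterpart of the sample DCCM, useful both for elastic-network
    predictions and as an oracle for sampled ensembles.
    """
    cov = np.asarray(cov, dtype=float)
    n3 = cov.shape[0]
    if cov.shape != (n3, n3) or n3 % 3:
        raise ValueError("covariance must be 3N x 3N")
    n = n3 // 3
    blocks = cov.reshape(n, 3, n, 3)
    inner = np.einsum("ikjk->ij", blocks)
    var = np.diag(inner)
    c = inner / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    if labels is None:
        labels = np.arange(1, n + 1)
    return CorrelationMatrix(labels=labels,
                             values=np.clip((c + c.T) / 2, -1, 1), kind="dccm")


def _pairwise_distances(xyz: np.ndarray) -> np.ndarray:
    diff = xyz[:, :, None, :] - xyz[:, None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def distance_matrices(ens: Ensemble, selection: SelectionMask,
                      contact_cutoff: float = CONTACT_CUTOFF_DEFAULT) -> ContactSummary:
    """Mean-distance, occupancy and formation-time matrices.

    Occupancy is the fraction of frames with d_ij ≤ cutoff. A formation event
    is a no-contact→contact transition (a contact present in frame 1 counts
    as an event at frame 1); formation time is the mean event frame index
    divided by M, so values live in (0, 1] independent of trajectory length.
    Pairs never in contact get NaN.
    """
    if contact_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz, labels = _residue_coords(ens, selection)
    m = len(xyz)
    d = _pairwise_distances(xyz)
    contact = d <= contact_cutoff
    mean_d = d.mean(axis=0)
    occ = contact.mean(axis=0)
    np.fill_diagonal(occ, 1.0)
    prev = np.zeros_like(contact[0])
    event_sum = np.zeros(occ.shape)
    event_count = np.zeros(occ.shape)
    for t in range(m):
        formed = contact[t] & ~prev
        event_sum += formed * (t + 1)
        event_count += formed
        prev = contact[t]
    with np.errstate(invalid="ignore", divide="ignore"):
        formation = np.where(event_count > 0, event_sum / event_count / m, np.nan)
    np.fill_diagonal(formation, 1.0 / m)
    return ContactSummary(labels=labels, mean_distance=mean_d, occupancy=occ,
                          formation_time=formation, cutoff=contact_cutoff)


def rdcm(ens: Ensemble, selection: SelectionMask) -> CorrelationMatrix:
    """Residue distance correlation matrix.

    For each residue i, s_i(t) is its mean distance to all other selected
    residues at frame t; entries are the Pearson correlation of s_i and s_j
    over time. Being built from internal distances, it needs no
    superposition. Constant series get zero off-diagonal correlations.
    """
    if ens.n_frames < 10:
        raise ValueError("need at least 10 frames for a stable RDCM")
    xyz, labels = _residue_coords(ens, selection)
    d = _pairwise_distances(xyz)
    r = d.shape[1]
    s = d.sum(axis=2) / (r - 1)          # (M, R) mean distance to others
    s = s - s.mean(axis=0, keepdims=True)
    var = (s ** 2).mean(axis=0)
    zero = var <= 1e-30
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant distance series; rows zeroed",
                      stacklevel=2)
        var[zero] = 1.0
    c = (s.T @ s) / len(s) / np.sqrt(np.outer(var, var))
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    return CorrelationMatrix(labels=labels, values=c, kind="rdcm")


def windowed_pearson(ens: Ensemble, selection: SelectionMask,
                     window: int, stride: int | None = None) -> list[CorrelationMatrix]:
    """DCCM within sliding windows [k·stride, k·stride + window)."""
    if window > ens.n_frames:
        raise ValueError("window longer than trajectory")
    if window < 10:
        warnings.warn("window < 10 frames gives unstable correlation estimates",
                      stacklevel=2)
    stride = stride or window
    out = []
    start = 0
    while start + window <= ens.n_frames:
        sub = Ensemble(topology=ens.topology,
                       frames=ens.frames[start:start + window],
                       times=ens.times[start:start + window])
        out.append(dccm(sub, selection))
        start += stride
    return out


def helix_distance_report(ens: Ensemble, segments: dict[str, tuple[int, int]],
                          selection: SelectionMask | None = None) -> dict:
    """Mean inter-segment Cα distance per frame and its time trend.

    ``segments`` maps names (e.g. "H10") to inclusive residue ranges; ranges
    must not overlap. For each unordered pair the per-frame mean pairwise
    distance between the segments' residues is reported along with the sign
    of its least-squares slope over time (0 when |slope| is below the
    noise floor estimated from the residual scatter).
    """
    from .select import select as _select

    names = list(segments)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            lo1, hi1 = segments[names[a]]
            lo2, hi2 = segments[names[b]]
            if max(lo1, lo2) <= min(hi1, hi2):
                raise ValueError(f"segments {names[a]} and {names[b]} overlap")
    if selection is None:
        selection = _select(ens.topology, "calpha")
    xyz, labels = _residue_coords(ens, selection)
    label_pos = {int(r): k for k, r in enumerate(labels)}
    report = {}
    t = ens.times
    tc = t - t.mean()
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            pos1 = [label_pos[r] for r in range(segments[names[a]][0],
                                               segments[names[a]][1] + 1)
                    if r in label_pos]
            pos2 = [label_pos[r] for r in range(segments[names[b]][0],
                                               segments[names[b]][1] + 1)
                    if r in label_pos]
            if not pos1 or not pos2:
                raise ValueError("segment covers no selected residues")
            diff = xyz[:, pos1, None, :] - xyz[:, None, pos2, :]
            series = np.sqrt((diff ** 2).sum(axis=-1)).mean(axis=(1, 2))
            slope = float((tc * (series - series.mean())).sum() / (tc ** 2).sum())
            resid = series - series.mean() - slope * tc
            noise = 2.0 * resid.std() / np.sqrt((tc ** 2).sum())  # ~2 SE of slope
            sign = 0 if abs(slope) <= noise else int(np.sign(slope))
            report[(names[a], names[b])] = {
                "series": series, "slope": slope, "trend": sign}
    return report
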