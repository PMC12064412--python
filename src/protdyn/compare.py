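"""Cross-ensemble and cross-structure comparison.

Subspace similarity between two sets of collective motions:

* RMSIP(d) = √( (1/d) Σᵢ Σⱼ (vᵢ·wⱼ)² )  over the top d modes of each set;
* covariance overlap
  Ω = 1 − √( (Σλᵢ + Σμᵢ − 2 ΣᵢΣⱼ √(λᵢ μⱼ) (vᵢ·wⱼ)²) / (Σλᵢ + Σμᵢ) ).

Both live in [0, 1], are symmetric, and are invariant to eigenvector sign
flips. Similarity matrices over a structure family feed average-linkage
hierarchical clustering (distance 1 − similarity), and partitions are scored
against external labels (e.g. species taxonomy) with the adjusted Rand
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .core import SelectionMask, StructureModel
from .correlation import CorrelationMatrix
from .modes import ModeSet
from .superpose import ResidueProfile, kabsch_superpose

__all__ = [
    "SimilarityMatrix", "DendrogramTree", "rmsip", "covariance_overlap",
    "consensus_dccm", "fluctuation_peaks", "hierarchical_cluster",
    "compare_partitions", "deduplicate_by_rmsd", "similarity_matrix",
]


@dataclass
class SimilarityMatrix:
    """K×K similarity (or RMSD distance) matrix over labelled structures."""

    labels: list[str]
    values: np.ndarray
    metric: str = "rmsip"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        expected_diag = 0.0 if self.metric == "rmsd" else 1.0
        if not np.allclose(np.diag(self.values), expected_diag, atol=1e-6):
            raise ValueError(f"diagonal must be {expected_diag} for {self.metric}")


@dataclass
class DendrogramTree:
    """Average-linkage merge tree (scipy linkage encoding) with leaf labels."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def flat_clusters(self, k: int | None = None,
                      height: float | None = None) -> np.ndarray:
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k or height")
        if k is not None:
            return fcluster(self.linkage_matrix, k, criterion="maxclust")
        return fcluster(self.linkage_matrix, height, criterion="distance")

    def to_newick(self) -> str:
        n = len(self.labels)
        nodes: dict[int, tuple[str, float]] = {
            i: (self.labels[i], 0.0) for i in range(n)}
        for row_idx, (a, b, h, _) in enumerate(self.linkage_matrix):
            sa, ha = nodes[int(a)]
            sb, hb = nodes[int(b)]
            branch_a = h - ha
            branch_b = h - hb
            nodes[n + row_idx] = (
                f"({sa}:{branch_a:.6g},{sb}:{branch_b:.6g})", h)
        root, _ = nodes[n + len(self.linkage_matrix) - 1]
        return root + ";"


def rmsip(modes_a: ModeSet, modes_b: ModeSet, d: int = 10) -> float:
    """Root mean square inner product of the top-d subspaces, in [0, 1]."""
    if modes_a.n_features != modes_b.n_features:
        raise ValueError("mode sets live in different feature dimensions")
    d = min(d, modes_a.n_modes, modes_b.n_modes)
    if d < 1:
        raise ValueError("no modes to compare")
    v = modes_a.vectors[:, :d]
    w = modes_b.vectors[:, :d]
    return float(np.sqrt(((v.T @ w) ** 2).sum() / d))


def covariance_overlap(modes_a: ModeSet, modes_b: ModeSet, d: int = 10) -> float:
    """Spectrum-weighted subspace overlap Ω over the top d modes, in [0, 1]."""
    if modes_a.n_features != modes_b.n_features:
        raise ValueError("mode sets live in different feature dimensions")
    d = min(d, modes_a.n_modes, modes_b.n_modes)
    lam = modes_a.eigenvalues[:d]
    mu = modes_b.eigenvalues[:d]
    if np.any(lam < 0) or np.any(mu < 0):
        raise ValueError("eigenvalues must be non-negative")
    v = modes_a.vectors[:, :d]
    w = modes_b.vectors[:, :d]
    cross = (np.sqrt(np.outer(lam, mu)) * (v.T @ w) ** 2).sum()
    total = lam.sum() + mu.sum()
    if total <= 0:
        raise ValueError("both spectra are zero")
    val = 1.0 - np.sqrt(max(total - 2 * cross, 0.0) / total)
    return float(np.clip(val, 0.0, 1.0))


def consensus_dccm(matrices: list[CorrelationMatrix]
                   ) -> tuple[CorrelationMatrix, np.ndarray]:
    """Element-wise mean DCCM and the per-cell sign agreement fraction."""
    if not matrices:
        raise ValueError("no matrices supplied")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if not np.array_equal(m.labels, labels):
            raise ValueError("matrices must share labels")
    stack = np.stack([m.values for m in matrices])
    mean = stack.mean(axis=0)
    sign = np.sign(mean)
    agree = np.where(sign == 0, 0.5,
                     (np.sign(stack) == sign[None]).mean(axis=0))
    np.fill_diagonal(mean, 1.0)
    consensus = CorrelationMatrix(labels=labels,
                                  values=np.clip(mean, -1, 1), kind="consensus")
    return consensus, agree


def fluctuation_peaks(profile: ResidueProfile, core_mask: SelectionMask | None = None,
                      min_prominence: float = 0.2,
                      terminal_fraction: float = 0.05) -> list[tuple[int, float]]:
    """Prominent local maxima of a fluctuation profile, termini excluded.

    The first and last ``terminal_fraction`` of residues are dropped (chain
    ends always fluctuate); remaining peaks need prominence at least
    ``min_prominence`` × profile maximum. Returned ordered by height.
    """
    vals = profile.value
    n = len(vals)
    if n < 5:
        raise ValueError("profile too short for peak analysis")
    skip = max(1, int(np.ceil(n * terminal_fraction)))
    core = np.zeros(n, dtype=bool)
    core[skip:n - skip] = True
    if core_mask is not None:
        allowed = np.zeros(n, dtype=bool)
        allowed[core_mask.indices] = True
        core &= allowed
    if not core.any():
        raise ValueError("empty core after terminal exclusion")
    prominence = min_prominence * vals.max()
    idx, props = find_peaks(vals, prominence=prominence)
    peaks = [(int(profile.residue_index[i]), float(vals[i]))
             for i in idx if core[i]]
    peaks.sort(key=lambda p: -p[1])
    return peaks


def hierarchical_cluster(sim: SimilarityMatrix,
                         linkage_method: str = "average") -> DendrogramTree:
    """Average-linkage clustering on 1 − similarity (or raw RMSD distance).

    Leaf order is made deterministic by sorting labels lexicographically
    before linkage, which also fixes tie-breaks.
    """
    if np.any(~np.isfinite(sim.values)):
        raise ValueError("similarity matrix contains NaN/inf")
    order = np.argsort(np.asarray(sim.labels, dtype=object))
    labels = [sim.labels[i] for i in order]
    vals = sim.values[np.ix_(order, order)]
    dist = vals if sim.metric == "rmsd" else 1.0 - vals
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    return DendrogramTree(linkage_matrix=z, labels=labels)


def compare_partitions(clusters, taxonomy) -> float:
    """Adjusted Rand index between two labelings, in [−1, 1].

    Degenerate single-class cases: 1 when both are single-class, else 0
    (with a warning) — the permutation-model expectation is undefined there.
    """
    a = np.asarray(clusters)
    b = np.asarray(taxonomy)
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    na, nb = len(np.unique(a)), len(np.unique(b))
    if na == 1 or nb == 1:
        if na == nb == 1:
            return 1.0
        warnings.warn("single-class labeling; ARI defined as 0", stacklevel=2)
        return 0.0
    return float(adjusted_rand_score(a, b))


def deduplicate_by_rmsd(structures: list[StructureModel], cutoff: float = 0.19,
                        unit: str = "nm") -> list[int]:
    """Greedy redundancy filter: keep a structure iff its minimum RMSD to all
    previously kept structures exceeds the cutoff.

    Returns the retained indices (input order). The cutoff is interpreted in
    ``unit`` ("nm" or "angstrom"); 0.19 nm = 1.9 Å.
    """
    if unit == "nm":
        cutoff_a = cutoff * 10.0
    elif unit in ("angstrom", "A"):
        cutoff_a = cutoff
    else:
        raise ValueError(f"unknown unit {unit!r}")
    kept: list[int] = []
    for i, s in enumerate(structures):
        ok = True
        for j in kept:
            ref = structures[j]
            if ref.n_atoms != s.n_atoms:
                raise ValueError("structures differ in size; supply a "
                                 "residue correspondence and subset first")
            _, _, r = kabsch_superpose(s.coords, ref.coords)
            if r <= cutoff_a:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


def similarity_matrix(mode_sets: list[ModeSet], labels: list[str],
                      metric: str = "rmsip", d: int = 10) -> SimilarityMatrix:
    """Pairwise RMSIP or covariance-overlap matrix over a structure family."""
    k = len(mode_sets)
    vals = np.eye(k)
    fn = rmsip if metric == "rmsip" else covariance_overlap
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = fn(mode_sets[i], mode_sets[j], d)
    return SimilarityMatrix(labels=list(labels), values=vals, metric=metric)
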