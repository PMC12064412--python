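"""PCA, dihedral PCA, tICA and free-energy landscapes.

Features are plain M × F matrices; helpers build them from ensembles
(superposed Cartesian coordinates or sin/cos-embedded backbone torsions).
Free-energy landscapes are G(bin) = −kT ln(P(bin)/P_max) over a 2D
projection, in kT internally and optionally kJ/mol at a given temperature
(default 300 K — a conventional simulation temperature, configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Ensemble, SelectionMask
from .geometry import dihedral_angle
from .modes import ModeSet
from .superpose import superpose_ensemble

__all__ = [
    "pca", "cartesian_features", "dihedral_features", "tica", "fel",
    "project_external", "FreeEnergyLandscape", "TICAResult",
]

KB_KJ_PER_MOL_K = 0.008314462618


def cartesian_features(ens: Ensemble, selection: SelectionMask | None = None,
                       superpose: bool = True) -> np.ndarray:
    """Flattened (M, 3N) coordinates, superposed onto the iterated mean."""
    work = superpose_ensemble(ens, selection) if superpose else ens
    frames = work.frames if selection is None else work.frames[:, selection.indices]
    return frames.reshape(len(frames), -1)


def dihedral_features(ens: Ensemble) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """(cos, sin) embedding of backbone φ/ψ torsions, periodicity-safe.

    Returns the M × F feature matrix and the feature labels
    [(resid, "phi"), ...] with two columns (cos, sin) per torsion. Chain
    termini without a full 4-atom torsion are skipped.
    """
    topo = ens.topology
    pos: dict[tuple[int, str], int] = {}
    for i in range(topo.n_atoms):
        if topo.is_hetatm[i]:
            continue
        name = str(topo.atom_names[i])
        if name in ("N", "CA", "C"):
            pos[(int(topo.resids[i]), name)] = i
    resids = sorted({r for r, _ in pos})
    torsions: list[tuple[int, str, tuple[int, int, int, int]]] = []
    for r in resids:
        # φ(r): C(r-1), N(r), CA(r), C(r)
        if all(k in pos for k in [(r - 1, "C"), (r, "N"), (r, "CA"), (r, "C")]):
            torsions.append((r, "phi", (pos[(r - 1, "C")], pos[(r, "N")],
                                        pos[(r, "CA")], pos[(r, "C")])))
        # ψ(r): N(r), CA(r), C(r), N(r+1)
        if all(k in pos for k in [(r, "N"), (r, "CA"), (r, "C"), (r + 1, "N")]):
            torsions.append((r, "psi", (pos[(r, "N")], pos[(r, "CA")],
                                        pos[(r, "C")], pos[(r + 1, "N")])))
    if not torsions:
        raise ValueError("no complete backbone torsions found")
    m = ens.n_frames
    feats = np.empty((m, 2 * len(torsions)))
    for k, (_, _, (a, b, c, d)) in enumerate(torsions):
        ang = np.array([dihedral_angle(ens.frames[t, a], ens.frames[t, b],
                                       ens.frames[t, c], ens.frames[t, d])
                        for t in range(m)])
        rad = np.radians(ang)
        feats[:, 2 * k] = np.cos(rad)
        feats[:, 2 * k + 1] = np.sin(rad)
    labels = [(r, which) for r, which, _ in torsions]
    return feats, labels


def pca(features: np.ndarray, n_components: int | None = None,
        feature_kind: str = "cartesian") -> tuple[ModeSet, np.ndarray]:
    """PCA of a feature matrix; returns the ModeSet and the projections.

    Components carry the sign convention that their largest-magnitude loading
    is positive. Requesting more components than the rank truncates with a
    warning.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("features must be (M >= 2, F)")
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD is numerically preferable to forming the covariance
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s ** 2 / len(x)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    d = n_components if n_components is not None else rank
    if d > rank:
        warnings.warn(f"requested {d} components but rank is {rank}; truncated",
                      stacklevel=2)
        d = rank
    vecs = vt[:d].T
    for k in range(d):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    modes = ModeSet(mean=mean, vectors=vecs, eigenvalues=eigvals[:d],
                    feature_kind=feature_kind)
    return modes, xc @ vecs


@dataclass
class TICAResult:
    """tICA modes with eigenvalues λ ∈ [−1, 1] and implied timescales."""

    modes: ModeSet
    lag: int
    autocorrelations: np.ndarray      # generalized eigenvalues, |λ| ordered
    timescales: np.ndarray            # −lag/ln λ for λ in (0, 1), else NaN
    ridge: float = 0.0


def tica(features: np.ndarray, lag: int, n_components: int | None = None,
         feature_kind: str = "cartesian") -> tuple[TICAResult, np.ndarray]:
    """Time-lagged independent component analysis.

    Solves C(τ) v = λ C(0) v with the symmetrized estimator
    ½(C(τ) + C(τ)ᵀ); components are ordered by |λ|. A singular C(0) is
    regularized with a small logged ridge. Returns the result object and the
    projections of the input onto the components.
    """
    x = np.asarray(features, dtype=float)
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    m, f = x.shape
    if m - lag < 2:
        raise ValueError("not enough frames for this lag")
    if m - lag < f:
        warnings.warn("fewer lagged pairs than features; estimates unstable",
                      stacklevel=2)
    xc = x - x.mean(axis=0)
    a, b = xc[:-lag], xc[lag:]
    c0 = (a.T @ a + b.T @ b) / (2 * (m - lag))
    ct = (a.T @ b + b.T @ a) / (2 * (m - lag))
    ridge = 0.0
    eps = 1e-10 * max(np.trace(c0) / f, 1.0)
    if np.linalg.matrix_rank(c0) < f or np.linalg.cond(c0) > 1e10:
        ridge = 1e-6 * np.trace(c0) / f
        warnings.warn(f"singular lagged covariance; ridge {ridge:.3e} added",
                      stacklevel=2)
    c0r = c0 + (ridge + eps) * np.eye(f)
    from scipy.linalg import eigh
    lam, vec = eigh(ct, c0r)
    order = np.argsort(-np.abs(lam))
    lam, vec = lam[order], vec[:, order]
    d = n_components if n_components is not None else f
    d = min(d, f)
    lam, vec = lam[:d], vec[:, :d]
    # orthonormalize the retained components for ModeSet storage (the raw
    # generalized eigenvectors are C0-orthogonal, not Euclidean-orthogonal)
    q, _ = np.linalg.qr(vec)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where((lam > 0) & (lam < 1), -lag / np.log(lam), np.nan)
    modes = ModeSet(mean=x.mean(axis=0), vectors=q,
                    eigenvalues=np.abs(lam), feature_kind=feature_kind)
    proj = xc @ vec
    return TICAResult(modes=modes, lag=lag, autocorrelations=lam,
                      timescales=ts, ridge=ridge), proj


@dataclass
class FreeEnergyLandscape:
    """G = −kT ln(P/P_max) over a 2D projection; NaN where unsampled."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    g_kt: np.ndarray                         # (nx, ny), min over occupied = 0
    minima: list = field(default_factory=list)  # dicts: bin, g_kt, frame, time
    axis_labels: tuple[str, str] = ("PC1", "PC2")
    temperature: float | None = None

    @property
    def g_kj_per_mol(self) -> np.ndarray:
        t = self.temperature if self.temperature is not None else 300.0
        return self.g_kt * KB_KJ_PER_MOL_K * t


def fel(projections: np.ndarray, n_bins: int = 32,
        temperature: float = 300.0, times: np.ndarray | None = None,
        axis_labels: tuple[str, str] = ("PC1", "PC2")) -> FreeEnergyLandscape:
    """Free-energy landscape over a 2D projection.

    Minima are local minima of G over occupied bins under the 8-neighbour
    rule; each reports its most central frame (closest to the bin's occupied
    centroid) and that frame's time, the convention used when quoting
    "minimum energy states at ... ns".
    """
    p = np.asarray(projections, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("projections must be (M, 2)")
    if len(p) < 100:
        raise ValueError("need at least 100 samples for a landscape")
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    counts, ex, ey = np.histogram2d(p[:, 0], p[:, 1], bins=n_bins)
    if (counts > 0).sum() <= 1:
        warnings.warn("all samples fall in one bin; landscape degenerate",
                      stacklevel=2)
    with np.errstate(divide="ignore"):
        g = -np.log(counts / counts.max())
    g[counts == 0] = np.nan
    minima = []
    nx, ny = g.shape
    ix = np.clip(np.searchsorted(ex, p[:, 0], side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(ey, p[:, 1], side="right") - 1, 0, ny - 1)
    for i in range(nx):
        for j in range(ny):
            if np.isnan(g[i, j]):
                continue
            neigh = [(a, b) for a in range(max(0, i - 1), min(nx, i + 2))
                     for b in range(max(0, j - 1), min(ny, j + 2))
                     if (a, b) != (i, j) and not np.isnan(g[a, b])]
            if any(g[a, b] < g[i, j] for a, b in neigh):
                continue
            # plateau tie-break: keep only the first bin (scan order) of a
            # flat neighbourhood, so equal-count adjacent bins yield one minimum
            if any(g[a, b] == g[i, j] and (a, b) < (i, j) for a, b in neigh):
                continue
            members = np.flatnonzero((ix == i) & (iy == j))
            centroid = p[members].mean(axis=0)
            rep = members[np.argmin(((p[members] - centroid) ** 2).sum(axis=1))]
            minima.append({
                "bin": (i, j), "g_kt": float(g[i, j]), "frame": int(rep),
                "time": float(times[rep]) if times is not None else float(rep),
            })
    minima.sort(key=lambda m: m["g_kt"])
    return FreeEnergyLandscape(edges_x=ex, edges_y=ey, g_kt=g, minima=minima,
                               axis_labels=axis_labels, temperature=temperature)


def project_external(modes: ModeSet, features: np.ndarray,
                     feature_kind: str | None = None) -> np.ndarray:
    """Project external features onto stored modes (centered by their mean)."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != modes.n_features:
        raise ValueError(
            f"features must be (M', {modes.n_features}), got {x.shape}")
    if feature_kind is not None and feature_kind != modes.feature_kind:
        raise ValueError(
            f"feature kind {feature_kind!r} != modes' {modes.feature_kind!r}")
    return (x - modes.mean) @ modes.vectors
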