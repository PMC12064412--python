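"""Elastic network models (GNM and ANM) over Cα (or bead) contact topologies.

A Gaussian network model (GNM) builds the Kirchhoff (graph Laplacian) matrix
of the Cα contact graph; an anisotropic network model (ANM) builds the 3N×3N
Hessian of a uniform-spring network. Mean-square fluctuations are proportional
to the diagonal (GNM) or the 3×3 block traces (ANM) of the pseudo-inverse.
Retained modes are exposed as a :class:`~protdyn.modes.ModeSet` whose
variances are the inverse stiffness eigenvalues, so elastic modes plug into
the same subspace-similarity machinery (RMSIP, covariance overlap) as PCA
modes from a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .core import SelectionMask, StructureModel
from .modes import ModeSet

__all__ = ["ElasticNetworkModel", "enm_modes", "build_kirchhoff", "build_hessian"]

GNM_CUTOFF_DEFAULT = 7.3
ANM_CUTOFF_DEFAULT = 13.0
_ZERO_TOL = 1e-8


class ConnectivityError(ValueError):
    """The contact graph is disconnected at the chosen cutoff."""


def build_kirchhoff(coords: np.ndarray, cutoff: float, gamma: float = 1.0) -> np.ndarray:
    """GNM Kirchhoff matrix: −γ for contacts within cutoff, degree on diagonal."""
    d = squareform(pdist(coords))
    contact = (d <= cutoff) & ~np.eye(len(coords), dtype=bool)
    k = -gamma * contact.astype(float)
    np.fill_diagonal(k, -k.sum(axis=1))
    return k


def build_hessian(coords: np.ndarray, cutoff: float, gamma: float = 1.0) -> np.ndarray:
    """ANM Hessian: per contact, −γ (r̂ r̂ᵀ) off-diagonal blocks."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    d = squareform(pdist(coords))
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > cutoff or d[i, j] == 0:
                continue
            rij = coords[j] - coords[i]
            block = gamma * np.outer(rij, rij) / (rij @ rij)
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = -block
            h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = -block
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
            h[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
    return h


def _check_connected(coords: np.ndarray, cutoff: float) -> None:
    d = squareform(pdist(coords))
    adj = (d <= cutoff) & ~np.eye(len(coords), dtype=bool)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ConnectivityError(
            f"contact graph has {n_comp} components at cutoff {cutoff} Å")


@dataclass
class ElasticNetworkModel:
    """Eigensystem of a GNM Kirchhoff or ANM Hessian, zero modes excluded."""

    kind: str
    cutoff: float
    gamma: float
    modes: ModeSet                  # variances = 1/stiffness, softest first
    stiffness: np.ndarray           # stiffness eigenvalues matching modes
    fluctuations: np.ndarray        # per-residue MSF (arbitrary units / γ)
    n_zero_modes: int

    @property
    def n_residues(self) -> int:
        return len(self.fluctuations)


def enm_modes(model: StructureModel, kind: str = "anm",
              cutoff: float | None = None, n_modes: int | None = None,
              selection: SelectionMask | None = None,
              gamma: float = 1.0) -> ElasticNetworkModel:
    """Build and diagonalize an elastic network over the model's Cα atoms.

    ``selection`` overrides the default Cα selection (models without CA atoms,
    e.g. bead chains, fall back to all atoms). A connected contact graph has
    exactly one zero mode for GNM and six for ANM; anything else raises.
    """
    kind = kind.lower()
    if kind not in ("gnm", "anm"):
        raise ValueError(f"kind must be 'gnm' or 'anm', got {kind!r}")
    if cutoff is None:
        cutoff = GNM_CUTOFF_DEFAULT if kind == "gnm" else ANM_CUTOFF_DEFAULT
    if selection is not None:
        sub = model.subset(selection)
    else:
        ca = model.atom_names == "CA"
        sub = model.subset(SelectionMask.from_bool(ca)) if ca.any() else model
    coords = sub.coords
    n = len(coords)
    _check_connected(coords, cutoff)
    expected_zero = 1 if kind == "gnm" else 6
    mat = (build_kirchhoff if kind == "gnm" else build_hessian)(coords, cutoff, gamma)
    evals, evecs = np.linalg.eigh(mat)
    scale = max(evals.max(), 1.0)
    zero = evals < _ZERO_TOL * scale
    if zero.sum() < expected_zero:
        raise ConnectivityError(
            f"{kind.upper()} expected {expected_zero} zero modes, found {int(zero.sum())}")
    if zero.sum() > expected_zero:
        # connected graph, yet extra zero-energy (mechanism) modes: possible
        # for sparse/collinear contact geometries; exclude them like the
        # rigid-body modes
        import warnings
        warnings.warn(
            f"{int(zero.sum()) - expected_zero} internal mechanism modes "
            "excluded beyond the rigid-body modes", stacklevel=2)
    keep = ~zero
    stiff = evals[keep]
    vecs = evecs[:, keep]
    if n_modes is not None:
        stiff = stiff[:n_modes]
        vecs = vecs[:, :n_modes]
    # MSF from the full pseudo-inverse (all retained modes, not truncated)
    inv = evecs[:, ~zero] / evals[~zero]
    pinv = inv @ evecs[:, ~zero].T
    if kind == "gnm":
        fluct = np.diag(pinv).copy()
    else:
        fluct = np.array([np.trace(pinv[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                          for i in range(n)])
    mode_set = ModeSet(mean=coords.ravel() if kind == "anm" else np.zeros(n),
                       vectors=vecs, eigenvalues=1.0 / stiff,
                       feature_kind="cartesian" if kind == "anm" else "gnm")
    return ElasticNetworkModel(kind=kind, cutoff=cutoff, gamma=gamma,
                               modes=mode_set, stiffness=stiff,
                               fluctuations=fluct,
                               n_zero_modes=expected_zero)
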