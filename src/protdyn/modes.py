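"""Orthonormal mode sets: the common currency of PCA, tICA and elastic models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModeSet"]


@dataclass
class ModeSet:
    """Orthonormal displacement (or feature) eigenvectors with variances.

    ``vectors`` holds D orthonormal columns of length F; ``eigenvalues`` are
    the associated variances (feature units²), non-increasing and ≥ 0.
    ``feature_kind`` records the feature space (cartesian / dihedral /
    distance) so projections cannot silently mix spaces.
    """

    mean: np.ndarray
    vectors: np.ndarray
    eigenvalues: np.ndarray
    feature_kind: str = "cartesian"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be an F x D matrix")
        f, d = self.vectors.shape
        if self.mean.shape != (f,):
            raise ValueError("mean length must match vector dimension")
        if self.eigenvalues.shape != (d,):
            raise ValueError("one eigenvalue per mode required")
        gram = self.vectors.T @ self.vectors
        if not np.allclose(gram, np.eye(d), atol=1e-8):
            raise ValueError("mode vectors must be orthonormal")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        self.eigenvalues = np.clip(self.eigenvalues, 0.0, None)
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_features(self) -> int:
        return self.vectors.shape[0]

    def truncated(self, d: int) -> "ModeSet":
        d = min(d, self.n_modes)
        return ModeSet(self.mean, self.vectors[:, :d], self.eigenvalues[:d],
                       self.feature_kind)
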