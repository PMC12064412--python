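"""Shrake–Rupley solvent-accessible surface area.

Test points are distributed on each atom's solvent-expanded sphere
(radius + probe) with a Fibonacci (golden-spiral) lattice; a point is
accessible when it lies outside every neighbour's expanded sphere. Per-atom
SASA is the accessible fraction times the expanded-sphere area.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import VDW_RADII, Ensemble, SelectionMask, StructureModel
from .superpose import ProfileSeries

__all__ = ["shrake_rupley", "sasa_series"]

PROBE_DEFAULT = 1.4
N_POINTS_DEFAULT = 960


def _sphere_points(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _radii_for(model: StructureModel) -> np.ndarray:
    radii = np.empty(model.n_atoms)
    for k, el in enumerate(model.elements):
        try:
            radii[k] = VDW_RADII[str(el).upper()]
        except KeyError:
            raise ValueError(f"no van der Waals radius for element {el!r}") from None
    return radii


def shrake_rupley(model: StructureModel, probe: float = PROBE_DEFAULT,
                  n_points: int = N_POINTS_DEFAULT,
                  selection: SelectionMask | None = None
                  ) -> tuple[np.ndarray, float]:
    """Per-atom SASA (Å²) and the total, for one structure."""
    idx = selection.indices if selection is not None else np.arange(model.n_atoms)
    coords = model.coords[idx]
    radii = _radii_for(model)[idx] + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom = np.zeros(len(idx))
    for k in range(len(idx)):
        pts = coords[k] + radii[k] * unit
        neighbours = tree.query_ball_point(coords[k], radii[k] + rmax)
        neighbours = [j for j in neighbours if j != k]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        per_atom[k] = accessible.mean() * 4 * np.pi * radii[k] ** 2
    return per_atom, float(per_atom.sum())


def sasa_series(ens: Ensemble, probe: float = PROBE_DEFAULT,
                n_points: int = N_POINTS_DEFAULT,
                selection: SelectionMask | None = None) -> ProfileSeries:
    """Total SASA per frame over an ensemble."""
    vals = []
    for i in range(ens.n_frames):
        _, total = shrake_rupley(ens.frame(i), probe, n_points, selection)
        vals.append(total)
    return ProfileSeries(kind="sasa", values=np.asarray(vals), times=ens.times,
                         unit="angstrom^2")
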