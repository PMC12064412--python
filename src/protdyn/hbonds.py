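"""Geometric hydrogen-bond detection.

A bond is counted when the donor–acceptor heavy-atom distance is at most
``d_cut`` (default 3.5 Å) and the donor-H···acceptor angle is at least
``angle_cut`` (default 120°). The donor's hydrogen is any H within 1.2 Å of
the donor heavy atom; in hydrogen-free models the angle criterion cannot be
evaluated and a distance-only fallback is used (logged once via warnings).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .core import Ensemble, SelectionMask, StructureModel
from .superpose import ProfileSeries

__all__ = ["hbond_count", "hbond_series"]

D_CUT_DEFAULT = 3.5
ANGLE_CUT_DEFAULT = 120.0
H_COVALENT_CUT = 1.2


def _bonded_hydrogens(model: StructureModel, donor_idx: np.ndarray) -> dict[int, list[int]]:
    h_idx = np.flatnonzero(np.char.upper(model.elements) == "H")
    out: dict[int, list[int]] = {int(i): [] for i in donor_idx}
    if len(h_idx) == 0:
        return out
    tree = cKDTree(model.coords[h_idx])
    for i in donor_idx:
        near = tree.query_ball_point(model.coords[i], H_COVALENT_CUT)
        out[int(i)] = [int(h_idx[j]) for j in near]
    return out


def hbond_count(frame: StructureModel, donors: SelectionMask,
                acceptors: SelectionMask, d_cut: float = D_CUT_DEFAULT,
                angle_cut: float = ANGLE_CUT_DEFAULT) -> int:
    """Count donor→acceptor hydrogen bonds in a single structure."""
    if len(donors) == 0 or len(acceptors) == 0:
        warnings.warn("no donors or acceptors selected; hydrogen-bond count is 0",
                      stacklevel=2)
        return 0
    coords = frame.coords
    hydrogens = _bonded_hydrogens(frame, donors.indices)
    have_h = any(hydrogens.values())
    if not have_h:
        warnings.warn("no hydrogens found; falling back to the distance-only "
                      "hydrogen-bond criterion", stacklevel=2)
    count = 0
    acc_xyz = coords[acceptors.indices]
    tree = cKDTree(acc_xyz)
    for d in donors.indices:
        near = tree.query_ball_point(coords[d], d_cut)
        for j in near:
            a = acceptors.indices[j]
            if a == d:
                continue
            if not have_h:
                count += 1
                continue
            ok = False
            for h in hydrogens[int(d)]:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang >= angle_cut:
                    ok = True
                    break
            count += ok
    return count


def hbond_series(ens: Ensemble, donors: SelectionMask, acceptors: SelectionMask,
                 d_cut: float = D_CUT_DEFAULT,
                 angle_cut: float = ANGLE_CUT_DEFAULT) -> ProfileSeries:
    """Hydrogen-bond count per frame."""
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        vals = [hbond_count(ens.frame(i), donors, acceptors, d_cut, angle_cut)
                for i in range(ens.n_frames)]
    return ProfileSeries(kind="hbond_count", values=np.asarray(vals, dtype=float),
                         times=ens.times, unit="count")
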