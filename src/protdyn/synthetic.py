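"""Synthetic conformational ensembles with known ground truth.

Every downstream stage of the package (trajectory statistics, correlation
matrices, dimensionality reduction, free-energy landscapes, ligand
fingerprints, cross-ensemble comparison) is testable against these
generators without downloading anything:

* :func:`make_toy_chain` — ideal helical / helix-loop-helix backbone bead
  models (the toy stand-in for a nuclear-receptor fold);
* :func:`sample_enm_gaussian` — frames from the exact Gaussian implied by an
  anisotropic-network Hessian, with the covariance as ground truth;
* :func:`sample_two_state` — a two-basin trajectory with prescribed state
  populations (ground truth for free-energy-landscape basin depths);
* :func:`sample_ligand_walk` — a rigid three-bead ligand (two rings + bridge
  at toy scale) placed frame-by-frame to realize a scripted contact
  timeline;
* :func:`make_homolog_family` — a structure family with smooth group-level
  deformations plus within-group noise, with group labels as ground truth;
* :func:`sample_dihedral_series` — a backbone whose one slow torsion
  oscillates across the ±180° seam, ground truth for dihedral PCA / tICA.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ATOMIC_MASSES, Ensemble, SelectionMask, StructureModel
from .enm import ANM_CUTOFF_DEFAULT, build_hessian, _check_connected
from .geometry import EXTENDED_PHI_PSI, HELIX_PHI_PSI, build_backbone

__all__ = [
    "GroundTruth",
    "make_toy_chain",
    "sample_enm_gaussian",
    "sample_two_state",
    "sample_ligand_walk",
    "surface_contact_script",
    "make_homolog_family",
    "sample_dihedral_series",
    "concat_models",
]

_FRAME_DT_NS = 0.1  # nominal saving interval of synthetic trajectories


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    covariance: np.ndarray | None = None          # 3N x 3N (Å²)
    state_labels: np.ndarray | None = None        # per frame, {0, 1}
    populations: tuple[float, float] | None = None
    contact_script: list[frozenset] | None = None  # per-frame residue ids
    family_labels: np.ndarray | None = None       # per structure group id
    slow_mode: np.ndarray | None = None           # per-frame slow coordinate
    displacement: np.ndarray | None = None        # basin offset (N, 3)

    def __post_init__(self) -> None:
        if self.populations is not None:
            if abs(sum(self.populations) - 1.0) > 1e-9:
                raise ValueError("populations must sum to 1")
        if self.covariance is not None:
            c = np.asarray(self.covariance)
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")


def _times(m: int) -> np.ndarray:
    return np.arange(m, dtype=float) * _FRAME_DT_NS


def make_toy_chain(n_residues: int, geometry: str = "helix") -> StructureModel:
    """Deterministic backbone model with ideal helical geometry.

    ``helix-loop-helix`` inserts an extended linker of ~n/5 residues between
    two helices.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if geometry == "helix":
        phi = np.full(n_residues, HELIX_PHI_PSI[0])
        psi = np.full(n_residues, HELIX_PHI_PSI[1])
    elif geometry == "helix-loop-helix":
        n_loop = max(3, n_residues // 5)
        n_h1 = (n_residues - n_loop) // 2
        n_h2 = n_residues - n_loop - n_h1
        phi = np.concatenate([
            np.full(n_h1, HELIX_PHI_PSI[0]),
            np.full(n_loop, EXTENDED_PHI_PSI[0]),
            np.full(n_h2, HELIX_PHI_PSI[0]),
        ])
        psi = np.concatenate([
            np.full(n_h1, HELIX_PHI_PSI[1]),
            np.full(n_loop, EXTENDED_PHI_PSI[1]),
            np.full(n_h2, HELIX_PHI_PSI[1]),
        ])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return build_backbone(phi, psi)


def sample_enm_gaussian(model: StructureModel, cutoff: float = ANM_CUTOFF_DEFAULT,
                        n_frames: int = 1000, temperature_scale: float = 1.0,
                        seed: int = 0,
                        mode_scales: dict[int, float] | None = None
                        ) -> tuple[Ensemble, GroundTruth]:
    """Frames from N(reference, temperature_scale · H⁺) for the ANM Hessian H.

    The six rigid-body modes are projected out before sampling, so the sampled
    ensemble recovers the ground-truth covariance without re-superposition.

    ``mode_scales`` multiplies the *variance* of selected internal modes
    (key 0 = softest); damping a mode (factor < 1) emulates a ligand
    suppressing one collective motion, and the returned ground-truth
    covariance reflects the scaling.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    coords = model.coords
    _check_connected(coords, cutoff)
    h = build_hessian(coords, cutoff)
    evals, evecs = np.linalg.eigh(h)
    zero = evals < 1e-8 * max(evals.max(), 1.0)
    if zero.sum() != 6:
        raise ValueError(f"expected 6 zero modes, found {int(zero.sum())}")
    lam = evals[~zero]
    vecs = evecs[:, ~zero]
    variances = temperature_scale / lam
    if mode_scales:
        for k, factor in mode_scales.items():
            if not 0 <= k < len(variances):
                raise ValueError(f"mode index {k} out of range")
            if factor < 0:
                raise ValueError("mode variance scale must be non-negative")
            variances[k] *= factor
    cov = (vecs * variances) @ vecs.T
    rng = np.random.default_rng(seed)
    if temperature_scale == 0:
        disp = np.zeros((n_frames, coords.size))
    else:
        z = rng.standard_normal((n_frames, len(lam)))
        disp = z * np.sqrt(variances) @ vecs.T
    frames = coords[None] + disp.reshape(n_frames, -1, 3)
    ens = Ensemble(topology=model, frames=frames, times=_times(n_frames))
    return ens, GroundTruth(covariance=cov)


def sample_two_state(model: StructureModel, displacement: np.ndarray,
                     populations: tuple[float, float] = (0.8, 0.2),
                     n_frames: int = 1000, noise_sd: float = 0.3,
                     seed: int = 0) -> tuple[Ensemble, GroundTruth]:
    """A two-basin ensemble: frames in basin 2 are offset by ``displacement``.

    Frame basins are i.i.d. Bernoulli draws (populations are equilibrium
    probabilities, not kinetics). Isotropic Gaussian noise of ``noise_sd`` Å
    per coordinate is added everywhere.
    """
    p1, p2 = populations
    if not (0 < p1 < 1) or abs(p1 + p2 - 1.0) > 1e-9:
        raise ValueError("populations must be (p1, p2) with 0 < p1 < 1, p1+p2 = 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    disp = np.asarray(displacement, dtype=float).reshape(-1, 3)
    if disp.shape != model.coords.shape:
        raise ValueError("displacement must be a 3N vector / (N, 3) array")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_frames) < p2).astype(int)
    frames = (model.coords[None] + labels[:, None, None] * disp[None]
              + rng.normal(scale=noise_sd, size=(n_frames,) + model.coords.shape))
    ens = Ensemble(topology=model, frames=frames, times=_times(n_frames))
    return ens, GroundTruth(state_labels=labels, populations=(p1, p2),
                            displacement=disp)


def concat_models(a: StructureModel, b: StructureModel) -> StructureModel:
    """Concatenate two models (atom order preserved; b after a)."""
    cat = np.concatenate
    return StructureModel(
        atom_names=cat([a.atom_names, b.atom_names]),
        elements=cat([a.elements, b.elements]),
        resids=cat([a.resids, b.resids]),
        resnames=cat([a.resnames, b.resnames]),
        chain_ids=cat([a.chain_ids, b.chain_ids]),
        masses=cat([a.masses, b.masses]),
        coords=np.vstack([a.coords, b.coords]),
        author_resids=cat([a.author_resids, b.author_resids]),
        is_hetatm=cat([a.is_hetatm, b.is_hetatm]),
    )


def _ligand_beads(center: np.ndarray, side: float = 1.5) -> np.ndarray:
    """An equilateral triangle of beads centered at ``center`` (rigid ligand)."""
    h = side / np.sqrt(3.0)
    local = np.array([[h, 0.0, 0.0],
                      [-h / 2, side / 2, 0.0],
                      [-h / 2, -side / 2, 0.0]])
    return center[None] + local


class PlacementError(RuntimeError):
    """Scripted contacts are geometrically unsatisfiable."""


def surface_contact_script(model: StructureModel, anchors: list[int],
                           frames_per_anchor: int, cutoff: float = 4.5,
                           margin: float = 0.3) -> list[frozenset]:
    """A geometrically realizable contact script visiting surface anchors.

    For each anchor residue, a ligand-sized probe is pushed radially outward
    from the chain centroid through the anchor until every residue is either
    clearly inside (≤ cutoff − margin) or clearly outside (≥ cutoff + margin)
    the contact shell; the residues inside become that epoch's scripted
    contact set. Scripts built this way are feasible by construction, unlike
    hand-written residue lists which can be impossible to realize on a dense
    helix face.
    """
    resids = model.resids
    known = np.unique(resids)
    centroid = model.coords.mean(axis=0)
    script: list[frozenset] = []
    for anchor in anchors:
        if anchor not in known:
            raise ValueError(f"anchor residue {anchor} not in model")
        ca = model.coords[(resids == anchor) & (model.atom_names == "CA")]
        ref = ca[0] if len(ca) else model.coords[resids == anchor].mean(axis=0)
        direction = ref - centroid
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([0.0, 0, 1.0])
        chosen = None
        for dist in np.arange(2.0, 10.0, 0.05):
            beads = _ligand_beads(ref + direction * dist)
            inside, clean = set(), True
            for r in known:
                res_xyz = model.coords[resids == r]
                dmin = np.linalg.norm(res_xyz[:, None] - beads[None],
                                      axis=-1).min()
                if dmin <= cutoff - margin:
                    inside.add(int(r))
                elif dmin < cutoff + margin:
                    clean = False
                    break
            if clean and inside:
                chosen = frozenset(inside)
                break
        if chosen is None:
            raise PlacementError(
                f"no clean contact shell found around residue {anchor}")
        script.extend([chosen] * frames_per_anchor)
    return script


def sample_ligand_walk(pocket_model: StructureModel,
                       contact_script: list,
                       jitter_sd: float = 0.05, seed: int = 0,
                       cutoff: float = 4.5) -> tuple[Ensemble, GroundTruth]:
    """Place a rigid 3-bead ligand per frame to realize a contact script.

    ``contact_script`` is one collection of residue indices (the package's
    sequential numbering) per frame; scripted residues end up within
    ``cutoff`` Å (heavy-atom minimum distance) of the ligand, all other
    residues outside it. The ligand is appended to the topology as chain L,
    resname LIG, flagged HETATM.
    """
    rng = np.random.default_rng(seed)
    resids = pocket_model.resids
    known = set(int(r) for r in np.unique(resids))
    script = [frozenset(int(r) for r in frame) for frame in contact_script]
    for k, frame in enumerate(script):
        missing = frame - known
        if missing:
            raise ValueError(f"frame {k}: scripted residues {sorted(missing)} "
                             "not in pocket model")
    prot_xyz = pocket_model.coords
    centroid = prot_xyz.mean(axis=0)
    margin = 0.25

    def _ok(beads: np.ndarray, wanted: frozenset) -> bool:
        for r in known:
            res_xyz = prot_xyz[resids == r]
            dmin = np.linalg.norm(res_xyz[:, None] - beads[None], axis=-1).min()
            if r in wanted and dmin > cutoff - margin + 1e-3:
                return False
            if r not in wanted and dmin < cutoff + margin - 1e-3:
                return False
        return True

    def _violation(center: np.ndarray, wanted: frozenset) -> float:
        beads = _ligand_beads(center)
        total = 0.0
        for r in known:
            res_xyz = prot_xyz[resids == r]
            dmin = np.linalg.norm(res_xyz[:, None] - beads[None], axis=-1).min()
            if r in wanted:
                total += max(0.0, dmin - (cutoff - margin)) ** 2
            else:
                total += max(0.0, (cutoff + margin) - dmin) ** 2
        return total

    def _place(wanted: frozenset) -> np.ndarray:
        from scipy.optimize import minimize
        anchor = np.vstack([prot_xyz[resids == r]
                            for r in sorted(wanted)]).mean(axis=0)
        out = anchor - centroid
        norm = np.linalg.norm(out)
        base_dir = out / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        # coarse direction/distance scan, polished by Nelder–Mead
        best, best_v = None, np.inf
        for trial in range(60):
            if trial == 0:
                direction = base_dir
            else:
                direction = base_dir + rng.normal(scale=0.7, size=3)
                direction /= np.linalg.norm(direction)
            for dist in np.arange(1.0, cutoff + 2.0, 0.5):
                c = anchor + direction * dist
                v = _violation(c, wanted)
                if v < best_v:
                    best, best_v = c, v
            if best_v == 0.0:
                return best
        starts = [best] + [best + rng.normal(scale=1.0, size=3)
                           for _ in range(5)]
        best_opt = None
        for x0 in starts:
            opt = minimize(lambda c: _violation(c, wanted), x0,
                           method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-10,
                                    "maxiter": 2000})
            if best_opt is None or opt.fun < best_opt.fun:
                best_opt = opt
            if best_opt.fun <= 1e-9:
                break
        if best_opt.fun > 1e-9:
            raise PlacementError(
                f"cannot place ligand for contacts {sorted(wanted)} "
                f"(residual violation {best_opt.fun:.3g})")
        return best_opt.x

    lig_model = StructureModel(
        atom_names=["L1", "L2", "L3"], elements=["C", "C", "C"],
        resids=[int(resids.max()) + 1] * 3, resnames=["LIG"] * 3,
        chain_ids=["L"] * 3, masses=[ATOMIC_MASSES["C"]] * 3,
        coords=_ligand_beads(centroid),
        is_hetatm=[True] * 3)
    topo = concat_models(pocket_model, lig_model)

    placements: dict[frozenset, np.ndarray] = {}
    frames = np.empty((len(script), topo.n_atoms, 3))
    for k, wanted in enumerate(script):
        if not wanted:
            beads = _ligand_beads(centroid + np.array([100.0, 0.0, 0.0]))
        else:
            if wanted not in placements:
                try:
                    placements[wanted] = _place(wanted)
                except PlacementError as exc:
                    raise PlacementError(f"frame {k}: {exc}") from None
            beads = _ligand_beads(placements[wanted])
            if not _ok(beads, wanted):
                raise PlacementError(
                    f"frame {k}: placement check failed for {sorted(wanted)}")
        if jitter_sd > 0:
            jitter = rng.normal(scale=jitter_sd, size=3)
            jitter = np.clip(jitter, -2 * jitter_sd, 2 * jitter_sd)
            beads = beads + jitter[None]
        frames[k, :pocket_model.n_atoms] = prot_xyz
        frames[k, pocket_model.n_atoms:] = beads
    ens = Ensemble(topology=topo, frames=frames, times=_times(len(script)))
    return ens, GroundTruth(contact_script=script)


def _smooth_deformation(n_atoms: int, rng: np.random.Generator,
                        n_waves: int = 3) -> np.ndarray:
    """A smooth low-frequency displacement field along the chain, unit RMS."""
    t = np.linspace(0, np.pi, n_atoms)
    field = np.zeros((n_atoms, 3))
    for k in range(1, n_waves + 1):
        amp = rng.normal(size=3) / k
        phase = rng.uniform(0, 2 * np.pi)
        field += np.sin(k * t + phase)[:, None] * amp[None]
    rms = np.sqrt((field ** 2).sum(axis=1).mean())
    return field / max(rms, 1e-12)


def make_homolog_family(base: StructureModel, n_groups: int = 4,
                        per_group: int = 6, within_sd: float = 0.5,
                        between_sd: float = 2.5,
                        seed: int = 0) -> tuple[list[StructureModel], GroundTruth]:
    """A family of structures with group-structured smooth deformations.

    Each group's mean is the base plus a smooth low-frequency deformation
    field of ``between_sd`` Å RMS; the group fields are mutually
    orthogonalized so every group is a geometrically distinct shape, not a
    chance overlap. Members deviate from their group mean by independent
    smooth fields of ``within_sd`` Å RMS — homologous structures differ by
    smooth collective deformations, not by per-atom jitter. Stands in for a
    set of homologous structures from different species, with the group
    labels as ground truth.
    """
    if not (between_sd > within_sd > 0):
        raise ValueError("require between_sd > within_sd > 0")
    rng = np.random.default_rng(seed)
    n = base.n_atoms
    fields: list[np.ndarray] = []
    for _ in range(n_groups):
        f = _smooth_deformation(n, rng).ravel()
        for prev in fields:
            f = f - (f @ prev) / (prev @ prev) * prev
        rms = np.sqrt((f ** 2).reshape(-1, 3).sum(axis=1).mean())
        fields.append(f / max(rms, 1e-12))
    structures: list[StructureModel] = []
    labels = []
    for g in range(n_groups):
        mean_coords = base.coords + fields[g].reshape(-1, 3) * between_sd
        for _ in range(per_group):
            noise = _smooth_deformation(n, rng) * within_sd
            structures.append(base.with_coords(mean_coords + noise))
            labels.append(g)
    return structures, GroundTruth(family_labels=np.asarray(labels))


def sample_dihedral_series(n_residues: int = 5, n_frames: int = 500,
                           center_deg: float = 178.0, amplitude_deg: float = 12.0,
                           n_cycles: float = 3.0, noise_deg: float = 1.0,
                           seed: int = 0) -> tuple[Ensemble, GroundTruth]:
    """A backbone whose central ψ torsion oscillates across the ±180° seam.

    The slow coordinate is ψ(t) = center + amplitude·sin(2π·cycles·t/M); with
    the default center of 178° it repeatedly wraps around ±180°, so a naive
    PCA on raw angles splits the motion while the sin/cos dihedral embedding
    keeps it in one piece. GroundTruth.slow_mode is the unwrapped signal in
    degrees.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    signal = center_deg + amplitude_deg * np.sin(2 * np.pi * n_cycles * t / n_frames)
    noisy = signal + rng.normal(scale=noise_deg, size=n_frames)
    mid = n_residues // 2
    phi = np.full(n_residues, EXTENDED_PHI_PSI[0])
    psi0 = np.full(n_residues, EXTENDED_PHI_PSI[1])
    topo = build_backbone(phi, psi0)
    frames = np.empty((n_frames, topo.n_atoms, 3))
    for k in range(n_frames):
        psi = psi0.copy()
        psi[mid] = ((noisy[k] + 180.0) % 360.0) - 180.0
        frames[k] = build_backbone(phi, psi).coords
    ens = Ensemble(topology=topo, frames=frames, times=_times(n_frames))
    return ens, GroundTruth(slow_mode=signal)
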