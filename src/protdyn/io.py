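"""Read and write structures and ensembles in standard formats.

MDAnalysis does the heavy lifting for PDB/DCD/XTC parsing and writing; this
module converts to and from the package's own containers and enforces its
conventions (Å, ns, 1-based sequential residue numbering with author numbers
kept as metadata, altloc A only).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .core import ATOMIC_MASSES, Ensemble, StructureModel, guess_element

__all__ = ["read_structure", "read_ensemble", "write_pdb", "write_dcd"]


class PDBParseError(ValueError):
    """A malformed ATOM/HETATM record; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _validate_pdb_records(path: Path) -> int:
    """Pre-scan a PDB file; return the atom-record count of the first model.

    MDAnalysis is forgiving about malformed records, so coordinate fields are
    checked here to report an exact line number.
    """
    n_atoms = 0
    in_first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                in_first_model = False
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(lineno, "record too short for coordinates")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PDBParseError(lineno, "unparseable coordinate field") from None
            try:
                int(line[22:26])
            except ValueError:
                raise PDBParseError(lineno, "unparseable residue number") from None
            if in_first_model:
                n_atoms += 1
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records (empty input)")
    return n_atoms


def _mass_for(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no mass tabulated for element {element!r}") from None


def _model_from_universe(u) -> StructureModel:
    ag = u.atoms
    # altloc: keep blank or 'A' only
    try:
        altlocs = ag.altLocs
        keep = np.isin(altlocs, ["", " ", "A"])
        if not keep.all():
            ag = ag[keep]
    except AttributeError:
        pass
    names = ag.names
    elements = []
    for i, name in enumerate(names):
        try:
            el = ag.elements[i].strip()
        except (AttributeError, IndexError):
            el = ""
        elements.append(el.upper() if el else guess_element(name))
    try:
        chains = np.asarray(ag.chainIDs, dtype="U6")
    except AttributeError:
        chains = np.asarray([s or "A" for s in ag.segids], dtype="U6")
    chains = np.where(np.char.strip(chains) == "", "A", chains)
    try:
        record_types = np.asarray(ag.record_types)
        is_het = record_types == "HETATM"
    except AttributeError:
        is_het = np.zeros(len(ag), dtype=bool)

    author_resids = ag.resids.astype(int)
    # renumber 1-based sequential per chain, preserving atom order
    resids = np.zeros(len(ag), dtype=int)
    counters: dict[str, int] = {}
    last_key: tuple[str, int, str] | None = None
    icodes = getattr(ag, "icodes", np.full(len(ag), "", dtype="U1"))
    for i in range(len(ag)):
        key = (str(chains[i]), int(author_resids[i]), str(icodes[i]))
        if key != last_key:
            counters[key[0]] = counters.get(key[0], 0) + 1
            last_key = key
        resids[i] = counters[key[0]]

    masses = np.array([_mass_for(e) for e in elements])
    return StructureModel(
        atom_names=names,
        elements=elements,
        resids=resids,
        resnames=ag.resnames,
        chain_ids=chains,
        masses=masses,
        coords=ag.positions.astype(float),
        author_resids=author_resids,
        is_hetatm=is_het,
    )


def read_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Read one StructureModel from a PDB file (first MODEL if several).

    Coordinates in Å; residues renumbered 1-based sequentially per chain with
    author numbering kept in ``author_resids``.
    """
    import MDAnalysis as mda

    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_records(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return _model_from_universe(u)


def read_ensemble(topology_path: str | Path,
                  traj_path: str | Path | None = None,
                  format: str | None = None) -> Ensemble:
    """Read an Ensemble from a multi-model PDB or a (topology, DCD/XTC) pair.

    Frame times are taken from the file when present (converted to ns), else
    0, 1, 2, ... in frame units.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if traj_path is None:
        traj_path = topology_path
    traj_path = Path(traj_path)
    if topology_path.suffix.lower() == ".pdb":
        _validate_pdb_records(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path), str(traj_path))
    model = _model_from_universe(u)
    frames = []
    times_ps = []
    try:
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
            times_ps.append(float(ts.time))
    except (EOFError, OSError) as exc:
        raise IOError(
            f"truncated trajectory {traj_path}: last good frame {len(frames) - 1}"
        ) from exc
    frames = np.asarray(frames)
    if frames.shape[1] != model.n_atoms:
        raise ValueError(
            f"topology has {model.n_atoms} atoms, trajectory {frames.shape[1]}")
    times = np.asarray(times_ps) / 1000.0  # ps -> ns
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(frames), dtype=float)
    return Ensemble(topology=model, frames=frames, times=times)


def _universe_from_model(model: StructureModel, n_frames: int = 1):
    import MDAnalysis as mda

    keys = model.residue_keys()
    resindex = np.zeros(model.n_atoms, dtype=int)
    pos = -1
    last = None
    for i, key in enumerate(zip(model.chain_ids, model.resids)):
        key = (str(key[0]), int(key[1]))
        if key != last:
            pos += 1
            last = key
        resindex[i] = pos
    segids_per_res = [k[0] for k in keys]
    uniq_segs = sorted(set(segids_per_res))
    seg_of_res = np.array([uniq_segs.index(s) for s in segids_per_res])
    u = mda.Universe.empty(
        n_atoms=model.n_atoms, n_residues=len(keys), n_segments=len(uniq_segs),
        atom_resindex=resindex, residue_segindex=seg_of_res, trajectory=True)
    u.add_TopologyAttr("names", model.atom_names)
    u.add_TopologyAttr("elements", model.elements)
    u.add_TopologyAttr("masses", model.masses)
    u.add_TopologyAttr("resids", [r for _, r in keys])
    u.add_TopologyAttr("resnames",
                       [model.resnames[np.flatnonzero(resindex == i)[0]]
                        for i in range(len(keys))])
    u.add_TopologyAttr("segids", uniq_segs)
    u.add_TopologyAttr("chainIDs", model.chain_ids)
    u.add_TopologyAttr(
        "record_types",
        np.where(model.is_hetatm, "HETATM", "ATOM"))
    u.atoms.positions = model.coords
    return u


def write_pdb(obj: StructureModel | Ensemble, path: str | Path) -> None:
    """Write a structure (single MODEL) or an ensemble (multi-model PDB)."""
    import MDAnalysis as mda

    path = Path(path)
    if isinstance(obj, StructureModel):
        model, frames = obj, obj.coords[None]
    else:
        model, frames = obj.topology, obj.frames
    u = _universe_from_model(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=model.n_atoms, multiframe=len(frames) > 1) as w:
            for xyz in frames:
                u.atoms.positions = xyz
                w.write(u.atoms)


def write_dcd(ens: Ensemble, path: str | Path) -> None:
    """Write ensemble frames as a DCD trajectory (Å)."""
    import MDAnalysis as mda

    u = _universe_from_model(ens.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ens.n_atoms) as w:
            for xyz in ens.frames:
                u.atoms.positions = xyz
                w.write(u.atoms)
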