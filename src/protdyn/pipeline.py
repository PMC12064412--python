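"""Config-driven orchestration of the full analysis battery.

Two entry profiles:

* ``trajectory`` — the apo/holo comparison battery: per-trajectory scalar
  and profile statistics, DCCM/RDCM/contact matrices, dimensionality
  reduction with free-energy landscapes, ligand fingerprints when a ligand
  is present, residue networks, and an apo-vs-holo DCCM difference report;
* ``family`` — the structure-set comparison battery: per-structure elastic
  network modes, RMSIP and covariance-overlap similarity matrices,
  fluctuation profiles with peak calling, consensus DCCM, hierarchical
  clustering with Newick trees, and label agreement (ARI).

Every table is written as TSV under the output directory, together with a
JSON manifest recording the package version, the full configuration and its
hash, and per-stage runtimes; the same configuration and seed reproduce
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .compare import (compare_partitions, consensus_dccm, fluctuation_peaks,
                      hierarchical_cluster, similarity_matrix)
from .core import Ensemble, SelectionMask, StructureModel
from .correlation import (dccm, dccm_from_covariance, distance_matrices, rdcm,
                          windowed_pearson)
from .dimred import (cartesian_features, dihedral_features, fel, pca,
                     project_external, tica)
from .enm import enm_modes
from .hbonds import hbond_series
from .io import read_ensemble, read_structure
from .ligand import (fingerprint_series, interaction_timeline,
                     pocket_center_distance, tanimoto_matrix)
from .network import build_network, network_summary
from .sasa import sasa_series
from .secstruct import ss_fractions
from .select import select
from .superpose import (ResidueProfile, radius_of_gyration, rmsd_series,
                        rmsf_profile)
from .synthetic import (make_homolog_family, make_toy_chain,
                        sample_enm_gaussian, sample_ligand_walk,
                        surface_contact_script)

__all__ = ["RunConfig", "TrajectoryProfile", "FamilyProfile", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnsembleInput(_Strict):
    topology: str | None = None
    trajectory: str | None = None


class TrajectoryProfile(_Strict):
    apo: EnsembleInput | None = None
    holo: EnsembleInput | None = None
    synthetic: bool = True            # generate an apo/holo pair when no paths
    n_residues: int = 40
    n_frames: int = 2000
    damp_mode: int = 0                # holo: softest internal mode index
    damp_factor: float = 0.1          # holo: variance multiplier for that mode
    rmsd_selection: str = "backbone"
    rmsf_selection: str = "calpha"
    ligand_selection: str = "hetatm"
    contact_cutoff: float = 8.0
    fel_bins: int = 32
    temperature: float = 300.0
    tica_lag: int = 10
    n_components: int = 2
    window: int | None = None
    sasa_stride: int = 0              # 0: choose so ~100 frames are evaluated
    occupancy_min: float = 0.75
    corr_floor: float = 0.01
    diff_quantile: float = 0.95       # DCCM difference flagging threshold


class FamilyProfile(_Strict):
    structures_dir: str | None = None
    labels_table: str | None = None   # TSV: id, group
    synthetic: bool = True
    n_residues: int = 40
    n_groups: int = 4
    per_group: int = 6
    within_sd: float = 0.5
    between_sd: float = 2.5
    geometry: str = "helix"
    enm_kind: str = "anm"             # subspace similarity mode sets
    subspace_d: int = 20
    k_clusters: int | None = None


class RunConfig(_Strict):
    profile: str                      # "trajectory" | "family"
    output_dir: str
    seed: int = 0
    trajectory: TrajectoryProfile | None = None
    family: FamilyProfile | None = None


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _matrix_df(values: np.ndarray, labels) -> pd.DataFrame:
    df = pd.DataFrame(values, columns=[str(l) for l in labels])
    df.insert(0, "residue", [str(l) for l in labels])
    return df


class _Runner:
    def __init__(self, out: Path):
        self.out = out
        self.runtimes: dict[str, float] = {}
        self.failed: list[str] = []
        self.skipped: list[str] = []

    def stage(self, name: str, fn, *, needs: tuple[str, ...] = ()):
        if any(n in self.failed or n in self.skipped for n in needs):
            self.skipped.append(name)
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            warnings.warn(f"stage {name} failed: {exc}", stacklevel=2)
            self.failed.append(name)
            return None
        finally:
            self.runtimes[name] = round(time.perf_counter() - t0, 4)
        return result


def _load_or_make_pair(cfg: TrajectoryProfile, seed: int
                       ) -> dict[str, Ensemble]:
    systems: dict[str, Ensemble] = {}
    if cfg.apo and cfg.apo.topology:
        systems["apo"] = read_ensemble(cfg.apo.topology, cfg.apo.trajectory)
        if cfg.holo and cfg.holo.topology:
            systems["holo"] = read_ensemble(cfg.holo.topology, cfg.holo.trajectory)
        return systems
    if not cfg.synthetic:
        raise ValueError("no input paths and synthetic generation disabled")
    chain = make_toy_chain(cfg.n_residues, "helix-loop-helix")
    apo, _ = sample_enm_gaussian(chain, n_frames=cfg.n_frames, seed=seed)
    holo_prot, _ = sample_enm_gaussian(
        chain, n_frames=cfg.n_frames, seed=seed + 1,
        mode_scales={cfg.damp_mode: cfg.damp_factor})
    # holo carries a scripted ligand visiting a few pocket residues
    rng = np.random.default_rng(seed + 2)
    anchors = sorted(rng.choice(
        np.arange(4, cfg.n_residues - 3), size=3, replace=False).tolist())
    third = max(cfg.n_frames // 3, 1)
    script = surface_contact_script(chain, anchors, third)
    while len(script) < cfg.n_frames:   # rounding remainder: extend last epoch
        script.append(script[-1])
    script = script[:cfg.n_frames]
    lig_ens, _ = sample_ligand_walk(chain, script, seed=seed + 3)
    n_prot = chain.n_atoms
    # the ligand rides its contact patch: per frame, translate the scripted
    # placement by the patch centroid's displacement from the reference
    lig_frames = lig_ens.frames[:, n_prot:].copy()
    for k, patch in enumerate(script):
        sel = np.isin(chain.resids, sorted(patch))
        shift = holo_prot.frames[k, sel].mean(axis=0) - chain.coords[sel].mean(axis=0)
        lig_frames[k] += shift
    frames = np.concatenate([holo_prot.frames, lig_frames], axis=1)
    holo = Ensemble(topology=lig_ens.topology, frames=frames,
                    times=holo_prot.times)
    systems["apo"] = apo
    systems["holo"] = holo
    return systems


def _trajectory_system_stages(name: str, ens: Ensemble, cfg: TrajectoryProfile,
                              runner: _Runner, out: Path,
                              only: tuple[str, ...] | None = None) -> dict:
    """Run the per-system stages; ``only`` restricts to a subset of stage
    names (dependencies like dccm+contacts for network are the caller's
    responsibility)."""
    def _want(stage: str) -> bool:
        return only is None or stage in only

    res: dict = {}
    topo = ens.topology
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel_rmsd = select(topo, cfg.rmsd_selection)
        sel_rmsf = select(topo, cfg.rmsf_selection)
        sel_prot = select(topo, "protein")
        sel_lig = select(topo, cfg.ligand_selection)
    d = out / name

    def add_series(stage, fn, fname, colname):
        series = runner.stage(stage, fn)
        if series is not None:
            vals = np.atleast_2d(series.values.T).T
            cols = series.labels or [colname]
            df = pd.DataFrame({"frame": np.arange(ens.n_frames),
                               "time_ns": series.times})
            for k, c in enumerate(cols):
                df[c] = vals[:, k]
            _write_tsv(d / fname, df)
        return series

    if _want("rmsd"):
        res["rmsd"] = add_series(f"{name}.rmsd",
                                 lambda: rmsd_series(ens, sel_rmsd),
                                 "rmsd.tsv", "rmsd_A")
    if _want("rg"):
        res["rg"] = add_series(f"{name}.rg",
                               lambda: radius_of_gyration(ens, sel_prot),
                               "rg.tsv", "rg_A")
    if _want("rg_axis"):
        res["rg_axis"] = add_series(
            f"{name}.rg_axis",
            lambda: radius_of_gyration(ens, sel_prot, per_axis=True),
            "rg_axis.tsv", "rg_A")

    stride = cfg.sasa_stride or max(1, ens.n_frames // 100)
    sub = Ensemble(topology=topo, frames=ens.frames[::stride],
                   times=ens.times[::stride])
    sasa = runner.stage(f"{name}.sasa", lambda: sasa_series(sub, n_points=240)) \
        if _want("sasa") else None
    if sasa is not None:
        _write_tsv(d / "sasa.tsv", pd.DataFrame(
            {"time_ns": sasa.times, "sasa_A2": sasa.values}))

    def _hbonds():
        donors = select(topo, "name N")
        acceptors = select(topo, "name O")
        return hbond_series(sub, donors, acceptors)
    hb = runner.stage(f"{name}.hbonds", _hbonds) if _want("hbonds") else None
    if hb is not None:
        _write_tsv(d / "hbonds.tsv", pd.DataFrame(
            {"time_ns": hb.times, "hbond_count": hb.values}))

    def _ss():
        fr = ss_fractions(sub)
        return pd.DataFrame({"time_ns": sub.times, **fr})
    ss = runner.stage(f"{name}.ss", _ss) if _want("ss") else None
    if ss is not None:
        _write_tsv(d / "ss_fractions.tsv", ss)

    rmsf = runner.stage(f"{name}.rmsf", lambda: rmsf_profile(ens, sel_rmsf)) \
        if _want("rmsf") else None
    res["rmsf"] = rmsf
    if rmsf is not None:
        _write_tsv(d / "rmsf.tsv", pd.DataFrame(
            {"residue": rmsf.residue_index, "rmsf_A": rmsf.value}))

    mat = runner.stage(f"{name}.dccm", lambda: dccm(ens, sel_rmsf)) \
        if _want("dccm") else None
    res["dccm"] = mat
    if mat is not None:
        _write_tsv(d / "dccm.tsv", _matrix_df(mat.values, mat.labels))

    contacts = runner.stage(
        f"{name}.contacts",
        lambda: distance_matrices(ens, sel_rmsf, cfg.contact_cutoff)) \
        if _want("contacts") else None
    res["contacts"] = contacts
    if contacts is not None:
        _write_tsv(d / "mean_distance.tsv",
                   _matrix_df(contacts.mean_distance, contacts.labels))
        _write_tsv(d / "occupancy.tsv",
                   _matrix_df(contacts.occupancy, contacts.labels))
        _write_tsv(d / "formation_time.tsv",
                   _matrix_df(contacts.formation_time, contacts.labels))

    rd = runner.stage(f"{name}.rdcm", lambda: rdcm(ens, sel_rmsf)) \
        if _want("rdcm") else None
    if rd is not None:
        _write_tsv(d / "rdcm.tsv", _matrix_df(rd.values, rd.labels))

    window = cfg.window or max(ens.n_frames // 4, 10)
    wins = runner.stage(
        f"{name}.windowed",
        lambda: windowed_pearson(ens, sel_rmsf, window=window)) \
        if _want("windowed") else None
    if wins:
        for k, w in enumerate(wins):
            _write_tsv(d / "windowed" / f"dccm_w{k:02d}.tsv",
                       _matrix_df(w.values, w.labels))

    def _dimred():
        feats = cartesian_features(ens, sel_rmsf)
        modes, proj = pca(feats, max(cfg.n_components, 2))
        dfeats, _ = dihedral_features(ens)
        _, dproj = pca(dfeats, min(max(cfg.n_components, 2), dfeats.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tres, tproj = tica(feats, cfg.tica_lag, max(cfg.n_components, 2))
        return modes, proj, dproj, tproj
    dim = runner.stage(f"{name}.dimred", _dimred) if _want("dimred") else None
    if dim is not None:
        modes, proj, dproj, tproj = dim
        res["pca_modes"], res["pca_proj"] = modes, proj
        df = pd.DataFrame({"time_ns": ens.times})
        for k in range(proj.shape[1]):
            df[f"PC{k + 1}"] = proj[:, k]
        for k in range(dproj.shape[1]):
            df[f"dPC{k + 1}"] = dproj[:, k]
        for k in range(tproj.shape[1]):
            df[f"tIC{k + 1}"] = tproj[:, k]
        _write_tsv(d / "projections.tsv", df)

        def _fel():
            return fel(proj[:, :2], n_bins=cfg.fel_bins,
                       temperature=cfg.temperature, times=ens.times)
        land = runner.stage(f"{name}.fel", _fel) \
            if (only is None or "fel" in only) else None
        if land is not None:
            rows = []
            for i in range(len(land.edges_x) - 1):
                for j in range(len(land.edges_y) - 1):
                    if np.isnan(land.g_kt[i, j]):
                        continue
                    rows.append({
                        "pc1_center": (land.edges_x[i] + land.edges_x[i + 1]) / 2,
                        "pc2_center": (land.edges_y[j] + land.edges_y[j + 1]) / 2,
                        "g_kt": land.g_kt[i, j],
                        "g_kj_per_mol": land.g_kj_per_mol[i, j]})
            _write_tsv(d / "fel.tsv", pd.DataFrame(rows))
            _write_tsv(d / "fel_minima.tsv", pd.DataFrame(land.minima))

    if len(sel_lig) and _want("ligand"):
        def _ligand():
            pdist = pocket_center_distance(ens, sel_lig, sel_prot)
            fp = fingerprint_series(ens, sel_lig, sel_prot)
            tm = tanimoto_matrix(fp, stride=max(1, ens.n_frames // 200))
            tl = interaction_timeline(fp)
            return pdist, fp, tm, tl
        lig = runner.stage(f"{name}.ligand", _ligand)
        if lig is not None:
            pdist, fp, tm, tl = lig
            _write_tsv(d / "pocket_distance.tsv", pd.DataFrame(
                {"time_ns": pdist.times, "distance_A": pdist.values}))
            cols = [f"{r}:{c}" for r, c in fp.bit_definitions]
            fdf = pd.DataFrame(fp.bits, columns=cols)
            fdf.insert(0, "frame", np.arange(len(fdf)))
            _write_tsv(d / "fingerprints.tsv", fdf)
            (d / "fingerprint_bits.json").write_text(
                json.dumps([list(b) for b in fp.bit_definitions]))
            _write_tsv(d / "tanimoto.tsv", pd.DataFrame(tm))
            rows = [{"residue": r, "class": c, **{
                "occupancy": e["occupancy"], "longest_run": e["longest_run"],
                "n_runs": len(e["runs"])}}
                for (r, c), e in tl.entries.items()]
            _write_tsv(d / "interaction_timeline.tsv", pd.DataFrame(rows))

    if (res.get("dccm") is not None and res.get("contacts") is not None
            and _want("network")):
        def _network():
            net = build_network(res["contacts"], res["dccm"],
                                cfg.occupancy_min, cfg.corr_floor)
            summary = network_summary(net)
            edges = pd.DataFrame(net.edges, columns=["i", "j", "weight"])
            _write_tsv(d / "network_edges.tsv", edges)
            (d / "network_summary.json").write_text(json.dumps(
                {k: v for k, v in summary.items() if k != "segment_edges"},
                default=str, indent=1))
            return net
        res["network"] = runner.stage(f"{name}.network", _network)
    return res


def _dccm_difference(apo: dict, holo: dict, cfg: TrajectoryProfile,
                     out: Path) -> pd.DataFrame:
    a, h = apo["dccm"], holo["dccm"]
    common = np.intersect1d(a.labels, h.labels)
    ia = np.searchsorted(a.labels, common)
    ih = np.searchsorted(h.labels, common)
    diff = a.values[np.ix_(ia, ia)] - h.values[np.ix_(ih, ih)]
    _write_tsv(out / "dccm_difference.tsv", _matrix_df(diff, common))
    absdiff = np.abs(diff)
    iu = np.triu_indices_from(absdiff, k=1)
    thresh = np.quantile(absdiff[iu], cfg.diff_quantile)
    rows = [{"residue_i": int(common[i]), "residue_j": int(common[j]),
             "delta_c": float(diff[i, j])}
            for i, j in zip(*iu) if absdiff[i, j] >= thresh]
    rows.sort(key=lambda r: -abs(r["delta_c"]))
    df = pd.DataFrame(rows)
    _write_tsv(out / "dccm_difference_flagged.tsv", df)
    return df


def _run_trajectory(cfg: TrajectoryProfile, seed: int, runner: _Runner,
                    out: Path) -> dict:
    systems = runner.stage("load", lambda: _load_or_make_pair(cfg, seed))
    if systems is None:
        return {}
    results = {}
    for name, ens in systems.items():
        results[name] = _trajectory_system_stages(name, ens, cfg, runner, out)
    if ("apo" in results and "holo" in results
            and results["apo"].get("dccm") is not None
            and results["holo"].get("dccm") is not None):
        results["dccm_difference"] = runner.stage(
            "dccm_difference",
            lambda: _dccm_difference(results["apo"], results["holo"], cfg, out))
    return results


def _load_or_make_family(cfg: FamilyProfile, seed: int
                         ) -> tuple[list[StructureModel], list[str], np.ndarray | None]:
    if cfg.structures_dir:
        paths = sorted(Path(cfg.structures_dir).glob("*.pdb"))
        if not paths:
            raise ValueError(f"no PDB files in {cfg.structures_dir}")
        structures = [read_structure(p) for p in paths]
        names = [p.stem for p in paths]
        labels = None
        if cfg.labels_table:
            table = pd.read_csv(cfg.labels_table, sep="\t")
            lookup = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1]))
            labels = np.array([lookup[n] for n in names])
        return structures, names, labels
    if not cfg.synthetic:
        raise ValueError("no structures_dir and synthetic generation disabled")
    base = make_toy_chain(cfg.n_residues, cfg.geometry)
    fam, gt = make_homolog_family(base, cfg.n_groups, cfg.per_group,
                                  cfg.within_sd, cfg.between_sd, seed)
    names = [f"s{i:03d}" for i in range(len(fam))]
    return fam, names, gt.family_labels


def _run_family(cfg: FamilyProfile, seed: int, runner: _Runner,
                out: Path) -> dict:
    loaded = runner.stage("load", lambda: _load_or_make_family(cfg, seed))
    if loaded is None:
        return {}
    structures, names, labels = loaded
    results: dict = {"names": names, "labels": labels}

    def _modes():
        subspace = [enm_modes(s, cfg.enm_kind).modes for s in structures]
        gnm = [enm_modes(s, "gnm") for s in structures]
        return subspace, gnm
    modes = runner.stage("enm_modes", _modes)
    if modes is None:
        return results
    subspace_modes, gnm_models = modes

    def _fluct():
        rows = []
        peaks_rows = []
        for name, g in zip(names, gnm_models):
            prof = ResidueProfile(
                residue_index=np.arange(1, g.n_residues + 1),
                value=g.fluctuations, kind="gnm_msf", unit="1/gamma")
            for r, v in zip(prof.residue_index, prof.value):
                rows.append({"structure": name, "residue": int(r), "msf": v})
            for r, h in fluctuation_peaks(prof):
                peaks_rows.append({"structure": name, "residue": r, "height": h})
        _write_tsv(out / "fluctuations.tsv", pd.DataFrame(rows))
        _write_tsv(out / "fluctuation_peaks.tsv",
                   pd.DataFrame(peaks_rows,
                                columns=["structure", "residue", "height"]))
    runner.stage("fluctuations", _fluct)

    def _consensus():
        mats = []
        for s in structures:
            anm = enm_modes(s, "anm")
            cov = (anm.modes.vectors * anm.modes.eigenvalues) @ anm.modes.vectors.T
            mats.append(dccm_from_covariance(cov))
        cons, agree = consensus_dccm(mats)
        _write_tsv(out / "consensus_dccm.tsv",
                   _matrix_df(cons.values, cons.labels))
        _write_tsv(out / "consensus_agreement.tsv",
                   _matrix_df(agree, cons.labels))
        return cons
    runner.stage("consensus_dccm", _consensus)

    k = cfg.k_clusters or (len(np.unique(labels)) if labels is not None else 2)
    for metric in ("rmsip", "covariance_overlap"):
        def _cluster(metric=metric):
            sim = similarity_matrix(subspace_modes, names, metric,
                                    cfg.subspace_d)
            _write_tsv(out / f"{metric}.tsv", _matrix_df(sim.values, names))
            tree = hierarchical_cluster(sim)
            (out / f"{metric}_dendrogram.nwk").write_text(tree.to_newick())
            flat = tree.flat_clusters(k=k)
            order = {n: i for i, n in enumerate(tree.labels)}
            clusters = np.array([flat[order[n]] for n in names])
            _write_tsv(out / f"{metric}_clusters.tsv", pd.DataFrame(
                {"structure": names, "cluster": clusters}))
            ari = (compare_partitions(clusters, labels)
                   if labels is not None else np.nan)
            return {"clusters": clusters, "ari": ari}
        results[metric] = runner.stage(f"cluster.{metric}", _cluster)

    def _pca_family():
        coords = np.stack([s.coords for s in structures])
        feats = coords.reshape(len(structures), -1)
        modes, proj = pca(feats, 2)
        df = pd.DataFrame({"structure": names,
                           "PC1": proj[:, 0], "PC2": proj[:, 1]})
        if labels is not None:
            df["group"] = labels
        _write_tsv(out / "family_pca.tsv", df)
        return modes, proj
    results["pca"] = runner.stage("family_pca", _pca_family)
    return results


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run a full analysis battery; returns results plus run metadata."""
    if isinstance(config, dict):
        config = RunConfig.model_validate(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = _Runner(out)
    if config.profile == "trajectory":
        cfg = config.trajectory or TrajectoryProfile()
        results = _run_trajectory(cfg, config.seed, runner, out)
    elif config.profile == "family":
        cfg = config.family or FamilyProfile()
        results = _run_family(cfg, config.seed, runner, out)
    else:
        raise ValueError(f"unknown profile {config.profile!r}")
    config_json = config.model_dump_json()
    manifest = {
        "package_version": __version__,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stage_runtimes_s": runner.runtimes,
        "failed_stages": runner.failed,
        "skipped_stages": runner.skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
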