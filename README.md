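# protdyn

Comparative protein-dynamics analysis in Python: the battery of trajectory
and structure-set analyses used to ask how ligand binding (for example,
bisphenol A in the PPARγ ligand-binding domain) changes a protein's
conformational behaviour, and whether dynamics-based classification of a
homolog family follows species taxonomy.

It is written for structural bioinformaticians who have (or simulate)
conformational ensembles — MD trajectories, multi-model PDB sets, homolog
structure collections — and want the standard comparative statistics as a
tested, scriptable library rather than a pile of one-off notebooks.

## What it computes

**Per-trajectory statistics** — Kabsch-minimized RMSD, per-residue RMSF,
mass-weighted radius of gyration (total and per axis, gmx-gyrate
convention), Shrake–Rupley solvent-accessible surface area, geometric
hydrogen-bond counts, and coarse secondary-structure content (H/E/C) from
the Kabsch–Sander electrostatic energy
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol.

**Correlated motions and contacts** — the dynamic cross-correlation matrix

    C_ij = ⟨Δr_i · Δr_j⟩ / √(⟨Δr_i²⟩ ⟨Δr_j²⟩),

the residue distance correlation matrix (Pearson correlation of per-residue
mean-distance time series), windowed correlations, and mean-distance /
occupancy / formation-time contact matrices.

**Dimensionality reduction and landscapes** — PCA, dihedral PCA on
(cos φ, sin φ, cos ψ, sin ψ) features (periodicity-safe), tICA via the
symmetrized time-lagged covariance generalized eigenproblem
C(τ)v = λC(0)v, and free-energy landscapes G = −kT ln(P/P_max) with basin
minima and representative frame times.

**Ligand interactions** — pocket-center distance, per-frame interaction
fingerprints (residue × {any-contact, hydrophobic, H-bond donor/acceptor}
bits), Tanimoto similarity matrices T = |a∧b|/|a∨b|, and persistence
timelines with residues ranked by contact occupancy.

**Cross-ensemble comparison** — GNM/ANM elastic-network modes, subspace
similarity by RMSIP

    RMSIP(d) = √( (1/d) Σᵢ Σⱼ (vᵢ·wⱼ)² )

and by covariance overlap

    Ω = 1 − √( (Σλᵢ + Σμᵢ − 2ΣᵢΣⱼ √(λᵢμⱼ)(vᵢ·wⱼ)²) / (Σλᵢ + Σμᵢ) ),

average-linkage clustering of the resulting distances with Newick export,
adjusted-Rand comparison against external labels, greedy RMSD
deduplication, and residue interaction networks (edges where contact
occupancy ≥ 0.75 and |C_ij| above a floor, weight −log|C_ij|) with Yen
k-shortest-path analysis.

**Synthetic ensembles with ground truth** — every analysis is testable
end-to-end without downloads: Gaussian ensembles drawn from an
elastic-network covariance, two-basin trajectories with prescribed
populations, ligand-in-pocket trajectories realizing scripted contact
timelines, homolog families with group-structured smooth deformations, and
torsion series crossing the ±180° seam.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
systems with known ground truth (a helix-loop-helix chain; the "holo" copy
carries a 3-bead ligand and has its softest collective mode damped 10-fold,
emulating a ligand rigidifying one motion):

```bash
python analysis/01_simulate_systems.py --seed 1
python analysis/02_trajectory_statistics.py --seed 1
python analysis/03_correlations_and_networks.py --seed 1
python analysis/05_ligand_fingerprints.py --seed 1
```

prints, among other things:

```
apo:  mean RMSD 3.46 Å (plateau 3.50 Å); max RMSF 5.88 Å at residue 30; mean helix content 57%
holo: mean RMSD 1.86 Å (plateau 1.88 Å); max RMSF 2.38 Å at residue 30; mean helix content 59%
apo:  mean |C_ij| 0.696; 97 network edges
holo: mean |C_ij| 0.450; 97 network edges
top contact residue: 5 (occupancy 0.65, longest run 358 frames)
```

Read: the liganded system is less mobile (smaller RMSD/RMSF — its softest
mode was damped), its inter-residue correlations are weaker (mean |C_ij|
0.45 vs 0.70), secondary-structure content is unchanged, and the
fingerprint timeline identifies residue 5 as the dominant, persistent
contact — exactly what was scripted. `06_family_comparison.py` runs the
structure-family battery (RMSIP/covariance-overlap clustering recovers the
4 planted groups with ARI 1.00). All tables land under `results/` as TSV.

The same battery runs on real data through the CLI or a config file:

```bash
protdyn trajstats --topology top.pdb --trajectory run.xtc --out out/
protdyn ensemble --structures-dir structures/ --labels-table species.tsv --out out/
protdyn run --config analysis.yaml
```

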