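# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `protdyn`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from elsewhere.

## Conventions

Coordinates and distances are in ångström, times in nanoseconds, masses in
dalton. Residues are renumbered 1-based and sequential per chain on input;
the source file's author numbering (including insertion codes) is kept as
per-atom metadata for reporting. Alternate locations keep altloc A only and
occupancies are ignored: the object of study is a conformational ensemble,
not crystallographic detail. HETATM ligand atoms live in the same
`StructureModel`, flagged, so ligand analyses reuse the protein machinery.
File parsing and writing (PDB, DCD, XTC) is delegated to MDAnalysis behind
the package's own containers; a pre-scan of PDB records supplies exact line
numbers for malformed input.

## Superposition and trajectory statistics

Rigid-body fits use the Kabsch SVD construction with reflection correction
(determinant forced to +1) and optional mass weights. RMSD series use the
first frame as reference (a common simulation-package convention; the
reference is overridable) on backbone atoms by default; RMSF uses Cα atoms
after three rounds of iterated mean-structure superposition. These defaults
reflect the usual practice when comparing liganded and unliganded runs of
one protein; both selections are parameters.

Per-axis radius of gyration follows the gmx-gyrate convention: Rg_x
collects the mass-weighted spread in the *other two* coordinates, so a
flat ring in the xy-plane has Rg_z equal to the ring radius.

SASA is Shrake–Rupley with Bondi radii, probe 1.4 Å and 960 golden-spiral
points per atom by default; the single-sphere case is exact to well under
1% at that density (the acceptance script recomputes this). Hydrogen bonds
use a two-threshold geometric predicate (donor–acceptor ≤ 3.5 Å,
donor-H···acceptor ≥ 120°); hydrogens are located by covalent distance
(< 1.2 Å), and hydrogen-free models fall back to the distance-only
criterion with a logged warning. Secondary structure implements the
Kabsch–Sander electrostatic H-bond energy with reconstructed amide
hydrogens and assigns only the coarse classes H (two consecutive i→i+4
turns), E (parallel/antiparallel bridge patterns) and C; the 8-state
alphabet (3₁₀/π helices, bends) is deliberately out of scope because only
coarse content over time is compared.

## Correlation analyses

The DCCM is computed on per-residue points (mean of the selected atoms of
each residue) after superposition onto the iterated mean. Zero-variance
residues get zero off-diagonal correlations with a warning. The residue
distance correlation matrix (RDCM) is defined here as the Pearson
correlation over time of the per-residue mean-distance series
s_i(t) = mean_j d_ij(t). Among the possible readings of a "distance
correlation matrix" this one is preferred because it yields an N×N matrix
with residue axes and needs no superposition; the per-pair-series
alternative yields an N²-sized object and is noted as such.

Contact matrices use an 8 Å Cα–Cα cutoff by default (the common
coarse-grained convention). A formation event is a no-contact→contact
transition, with a contact already present in frame 1 counting as an event
at frame 1; the formation time is the mean event frame index normalized by
the trajectory length, so values live in (0, 1] regardless of length, and
pairs never in contact are missing (NaN). This event-mean convention is a
documented choice — "time of encounter formation" admits several readings.

## Dimensionality reduction and landscapes

PCA is computed by SVD of the centered feature matrix; the sign convention
makes each component's largest-magnitude loading positive. Dihedral PCA
embeds each backbone torsion as (cos, sin), which is smooth across the
±180° seam where raw angles jump by 360°. tICA solves
C(τ)v = λC(0)v with the symmetrized estimator ½(C(τ)+C(τ)ᵀ) (appropriate
for trajectories too short to test reversibility); a singular C(0) is
ridge-regularized with a logged ε, components are ordered by |λ|, and
implied timescales −τ/ln λ are reported for λ ∈ (0, 1).

Free-energy landscapes are G = −kT ln(P/P_max) over a 2D histogram;
unoccupied bins are missing, the global minimum is exactly 0, and minima
are local minima under the 8-neighbour rule with a deterministic plateau
tie-break (first bin in scan order of a flat neighbourhood — without this,
two adjacent equal-count bins would suppress each other and a basin could
go unreported). Each minimum reports its most central member frame and
that frame's time. Energies are in kT internally; conversion to kJ/mol
uses a default temperature of 300 K, a conventional simulation temperature
supplied explicitly wherever it matters.

The basin-depth identity ΔG = −ln(p₂/p₁) kT for a two-state ensemble is
verified on ensembles of 20 000 frames with basins a few bin-widths wide;
the single-bin depth estimator carries Poisson noise of a few hundredths
of kT at these sizes, so the validation averages five replicate ensembles.

UMAP and t-SNE are intentionally not reimplemented or wrapped into the
validated surface: they are stochastic and version-sensitive, and the
package's claims are limited to deterministic, testable statistics.

## Ligand fingerprints

Fingerprint bits are (residue, interaction class) pairs — any-contact
(heavy-atom minimum distance ≤ 4.5 Å), hydrophobic (carbon–carbon
≤ 4.0 Å), and H-bond donor/acceptor via the geometric predicate — rather
than chemical substructure keys, because the downstream consumers
(persistence timelines, per-residue interaction diagrams) are residue-
annotated. Two all-zero fingerprints are defined as identical (T = 1,
logged when triggered): frames agreeing in having no contacts are alike.

## Elastic networks and ensemble comparison

GNM uses the Kirchhoff matrix at 7.3 Å, ANM the 3N×3N Hessian at 13 Å,
both with uniform springs. A connected contact graph has exactly 1 (GNM)
or 6 (ANM) zero modes; extra near-zero modes on a connected graph are
mechanisms of sparse/collinear toy geometries and are excluded with a
warning rather than treated as errors. Mean-square fluctuations come from
the pseudo-inverse diagonal (GNM) or 3×3 block traces (ANM); retained
modes are exposed with variances 1/λ so elastic mode sets plug directly
into RMSIP and covariance overlap alongside PCA mode sets.

For homolog-family classification the package compares per-structure ANM
mode sets: RMSIP and covariance overlap need directional (3N) modes to be
commensurable with Cartesian PCA modes, whereas GNM modes are scalar
per-residue weights, which are kept for fluctuation profiles. The family
pipeline uses the top d = 20 modes; truncated subspaces at small d are
noticeably seed-sensitive because near-degenerate eigenvectors rotate
chaotically under small geometric perturbations, and d = 20 averages over
enough of the soft spectrum to classify reliably (the standalone
`rmsip`/`covariance_overlap` operations default to the conventional
d = 10).

Greedy RMSD deduplication keeps a structure iff its minimum RMSD to all
previously kept structures exceeds the cutoff. The default cutoff of 0.19
is interpreted in nanometres (1.9 Å), the unit convention of the major MD
engines; the unit is a flag.

Hierarchical clustering is average-linkage on 1 − similarity (scipy
linkage under the hood), with leaves sorted lexicographically before
linkage so ties break deterministically; trees export as Newick with
branch lengths. Partition agreement uses the standard adjusted Rand index
(permutation-model expectation), with the degenerate single-class cases
defined as 1 (both single-class) or 0 (one single-class, warned).

## Residue networks

Edges connect residue pairs with contact occupancy ≥ 0.75 and |C_ij| at
least a small floor; the weight is −log|C_ij|, the standard
dynamical-network convention, so strongly correlated contacts are short.
Whether such networks should derive from correlations, contacts or both is
not settled usage; the combined rule is the documented choice and both
thresholds are configuration keys. k-shortest loopless paths use Yen's
algorithm (networkx) with oversampling and a lexicographic tie-break;
disconnected pairs yield an empty result, not an exception. Summaries
(weighted mean path length, betweenness ranking) are computed on the
largest connected component.

## Synthetic generators: what they emulate and what they do not

The generators define the study conditions for every test:

* **ENM Gaussian ensembles** sample exactly from N(x₀, τ·H⁺) with the six
  rigid-body modes projected out, so the sample covariance converges to
  the known matrix without re-superposition; a per-mode variance scale can
  damp chosen modes (the "holo" condition damps the softest internal mode
  10-fold, emulating a ligand suppressing one collective motion).
* **Two-state ensembles** draw i.i.d. Bernoulli basin labels (populations
  0.8/0.2 by default) — equilibrium statistics only, no kinetics.
* **Ligand walks** place a rigid 3-bead triangle (a two-ring-plus-bridge
  ligand at toy scale) so that scripted residues are inside the contact
  cutoff and all others outside it; feasibility is the caller's problem in
  general, so `surface_contact_script` derives scripts from actual probe
  placements, which are feasible by construction. In the apo/holo
  pipeline the ligand rides its contact patch (translated by the patch
  centroid's per-frame displacement), so scripted contacts persist while
  the protein fluctuates — occupancies are then high but not exactly 1.
* **Homolog families** deform a base fold by smooth low-frequency fields:
  group means use mutually orthogonalized fields of 2.5 Å RMS, members
  add independent smooth fields of 0.5 Å RMS (a 5:1 ratio). Both levels
  are smooth because homologous structures differ by collective
  deformations, not per-atom jitter — and because elastic-network mode
  subspaces respond chaotically to jagged noise, which would test the
  ENM's sensitivity rather than the clustering machinery. The default
  base is a straight helix, whose non-degenerate soft modes make the
  family classification well-posed.
* **Dihedral series** rebuild a short backbone per frame with one ψ
  oscillating across ±180°, the adversarial case for naive angle PCA.

None of these emulate solvent, force-field realism, anharmonicity beyond
two states, or kinetics; a passing suite shows the *statistics* are
computed correctly and recover planted structure, not that any biological
conclusion transfers to real trajectories.

## Problem sizes

The default validation sizes — 10–50 residue chains, 20 000-frame
ensembles for convergence checks, 24-structure families, 1000-frame
apo/holo batteries — were chosen so each check isolates one property with
comfortable statistical margins while the whole suite stays interactive
on a single CPU.

## Known limitations

* Secondary structure is 3-state; π/3₁₀ helices and isolated bridges
  are folded into H/E/C coarsely.
* The hydrogen-bond fallback (no hydrogens) is distance-only and
  therefore more permissive; it is always logged.
* Cross-structure comparison assumes equal atom counts or an external
  residue correspondence; structural alignment itself is out of scope.
* `windowed_pearson` inherits the DCCM superposition per window; very
  short windows (< 10 frames) are allowed but warned against.
* The DCCM of a tiny system differs slightly from its analytic
  counterpart after superposition onto a small selection, because the fit
  removes six degrees of freedom; validation superposes on all atoms
  (near-identity for generator ensembles with rigid modes projected out).
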