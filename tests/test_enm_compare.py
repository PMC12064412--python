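"""Elastic networks, subspace similarity, clustering, partitions, dedup."""

import numpy as np
import pytest

from protdyn.compare import (SimilarityMatrix, compare_partitions,
                             consensus_dccm, covariance_overlap,
                             deduplicate_by_rmsd, fluctuation_peaks,
                             hierarchical_cluster, rmsip, similarity_matrix)
from protdyn.core import SelectionMask, StructureModel
from protdyn.correlation import CorrelationMatrix
from protdyn.enm import ConnectivityError, build_kirchhoff, enm_modes
from protdyn.modes import ModeSet
from protdyn.superpose import ResidueProfile
from protdyn.synthetic import make_toy_chain


def _beads(coords):
    n = len(coords)
    return StructureModel(
        atom_names=["CA"] * n, elements=["C"] * n, resids=list(range(1, n + 1)),
        resnames=["ALA"] * n, chain_ids=["A"] * n, masses=[12.0] * n,
        coords=coords)


class TestEnm:
    def test_3bead_gnm_hand_computed(self):
        """Fluctuations of a 3-bead chain match the hand pseudo-inverse."""
        m = _beads(np.array([[0.0, 0, 0], [4, 0, 0], [8, 0, 0]]))
        model = enm_modes(m, "gnm", cutoff=5.0)
        # Kirchhoff = [[1,-1,0],[-1,2,-1],[0,-1,1]]; pinv diagonal known
        k = np.array([[1.0, -1, 0], [-1, 2, -1], [0, -1, 1]])
        diag = np.diag(np.linalg.pinv(k))
        assert np.allclose(model.fluctuations, diag, atol=1e-10)

    def test_gnm_matches_dense_pinv(self):
        m = make_toy_chain(30, "helix-loop-helix")
        model = enm_modes(m, "gnm")
        ca = m.coords[m.atom_names == "CA"]
        k = build_kirchhoff(ca, model.cutoff)
        pinv = np.linalg.pinv(k, hermitian=True, rcond=1e-8)
        assert np.allclose(model.fluctuations, np.diag(pinv), atol=1e-8)

    def test_chain_ends_fluctuate_more(self):
        m = make_toy_chain(20, "helix")
        g = enm_modes(m, "gnm")
        f = g.fluctuations
        assert f[0] > f[len(f) // 2] and f[-1] > f[len(f) // 2]

    def test_anm_has_six_zero_modes(self):
        m = make_toy_chain(12, "helix")
        model = enm_modes(m, "anm")
        assert model.n_zero_modes == 6
        assert np.all(model.stiffness > 0)

    def test_disconnected_graph_rejected(self):
        coords = np.array([[0.0, 0, 0], [4, 0, 0], [100, 0, 0], [104, 0, 0]])
        with pytest.raises(ConnectivityError):
            enm_modes(_beads(coords), "gnm", cutoff=5.0)


class TestRmsip:
    def test_identical_modes_one(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(30, 10)))
        m = ModeSet(np.zeros(30), q, np.ones(10))
        assert rmsip(m, m, 10) == pytest.approx(1.0)

    def test_orthogonal_subspaces_zero(self):
        v = np.eye(20)[:, :5]
        w = np.eye(20)[:, 5:10]
        a = ModeSet(np.zeros(20), v, np.ones(5))
        b = ModeSet(np.zeros(20), w, np.ones(5))
        assert rmsip(a, b, 5) == pytest.approx(0.0)

    def test_random_subspace_null_mean(self):
        """E[RMSIP] for random d=10 subspaces in dim 300 is sqrt(d/300)."""
        vals = []
        for s in range(200):
            r = np.random.default_rng(s)
            qa, _ = np.linalg.qr(r.normal(size=(300, 10)))
            qb, _ = np.linalg.qr(r.normal(size=(300, 10)))
            vals.append(rmsip(ModeSet(np.zeros(300), qa, np.ones(10)),
                              ModeSet(np.zeros(300), qb, np.ones(10)), 10))
        assert abs(np.mean(vals) - np.sqrt(10 / 300)) < 0.02

    def test_sign_flip_invariance(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(12, 4)))
        flipped = q * np.array([1, -1, 1, -1])
        a = ModeSet(np.zeros(12), q, np.ones(4))
        b = ModeSet(np.zeros(12), flipped, np.ones(4))
        assert rmsip(a, b, 4) == pytest.approx(1.0)
        assert covariance_overlap(a, b, 4) == pytest.approx(1.0)


class TestCovarianceOverlap:
    def test_identical_one(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(15, 5)))
        lam = np.array([5.0, 4, 3, 2, 1])
        m = ModeSet(np.zeros(15), q, lam)
        assert covariance_overlap(m, m, 5) == pytest.approx(1.0)

    def test_scaled_spectrum_closed_form(self, rng):
        """Same vectors, eigenvalues scaled by c: Ω = 1 − √((1+c−2√c)/(1+c))."""
        q, _ = np.linalg.qr(rng.normal(size=(15, 5)))
        lam = np.array([5.0, 4, 3, 2, 1])
        for c in (4.0, 9.0):
            a = ModeSet(np.zeros(15), q, lam)
            b = ModeSet(np.zeros(15), q, c * lam)
            expected = 1 - np.sqrt((1 + c - 2 * np.sqrt(c)) / (1 + c))
            assert covariance_overlap(a, b, 5) == pytest.approx(
                expected, abs=1e-10)

    def test_orthogonal_subspaces_closed_form(self):
        """Disjoint subspaces with equal spectra: cross term vanishes."""
        v = np.eye(20)[:, :4]
        w = np.eye(20)[:, 4:8]
        lam = np.array([4.0, 3, 2, 1])
        a = ModeSet(np.zeros(20), v, lam)
        b = ModeSet(np.zeros(20), w, lam)
        assert covariance_overlap(a, b, 4) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        qa, _ = np.linalg.qr(rng.normal(size=(12, 4)))
        qb, _ = np.linalg.qr(rng.normal(size=(12, 4)))
        a = ModeSet(np.zeros(12), qa, np.array([3.0, 2, 1.5, 1]))
        b = ModeSet(np.zeros(12), qb, np.array([2.5, 2, 1, 0.5]))
        assert covariance_overlap(a, b, 4) == pytest.approx(
            covariance_overlap(b, a, 4))


class TestConsensusDccm:
    def _cm(self, vals):
        return CorrelationMatrix(labels=np.arange(1, len(vals) + 1),
                                 values=np.asarray(vals))

    def test_identical_inputs(self):
        m = self._cm([[1, 0.5, 0.1], [0.5, 1, -0.2], [0.1, -0.2, 1]])
        cons, agree = consensus_dccm([m, m, m])
        assert np.allclose(cons.values, m.values)
        off = ~np.eye(3, dtype=bool)
        assert np.all(agree[off] == 1.0)

    def test_opposite_inputs_cancel(self):
        a = self._cm([[1, 0.6], [0.6, 1]])
        b = self._cm([[1, -0.6], [-0.6, 1]])
        cons, agree = consensus_dccm([a, b])
        assert cons.values[0, 1] == 0.0
        assert agree[0, 1] == 0.5

    def test_mean_matches_hand_arithmetic(self):
        ms = [self._cm([[1, x], [x, 1]]) for x in (0.3, 0.6, -0.3)]
        cons, _ = consensus_dccm(ms)
        assert cons.values[0, 1] == pytest.approx((0.3 + 0.6 - 0.3) / 3)


class TestFluctuationPeaks:
    def test_two_bumps_found(self):
        x = np.arange(100)
        prof = ResidueProfile(
            residue_index=x + 1,
            value=(np.exp(-((x - 30) ** 2) / 20) +
                   0.8 * np.exp(-((x - 70) ** 2) / 20) + 0.05))
        peaks = fluctuation_peaks(prof)
        assert len(peaks) == 2
        assert abs(peaks[0][0] - 31) <= 1 and abs(peaks[1][0] - 71) <= 1

    def test_monotone_profile_no_peaks(self):
        prof = ResidueProfile(residue_index=np.arange(1, 51),
                              value=np.linspace(0, 1, 50))
        assert fluctuation_peaks(prof) == []

    def test_count_non_increasing_in_threshold(self, rng):
        prof = ResidueProfile(residue_index=np.arange(1, 81),
                              value=np.abs(rng.normal(size=80)))
        counts = [len(fluctuation_peaks(prof, min_prominence=p))
                  for p in (0.05, 0.2, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestHierarchicalCluster:
    def test_two_groups_recovered(self):
        vals = np.full((6, 6), 0.2)
        vals[:3, :3] = 0.9
        vals[3:, 3:] = 0.9
        np.fill_diagonal(vals, 1.0)
        sim = SimilarityMatrix(labels=[f"s{i}" for i in range(6)], values=vals)
        tree = hierarchical_cluster(sim)
        flat = tree.flat_clusters(k=2)
        order = {n: i for i, n in enumerate(tree.labels)}
        got = [flat[order[f"s{i}"]] for i in range(6)]
        assert len(set(got[:3])) == 1 and len(set(got[3:])) == 1
        assert got[0] != got[3]

    def test_identical_structures_zero_heights(self):
        vals = np.ones((4, 4))
        sim = SimilarityMatrix(labels=list("abcd"), values=vals)
        tree = hierarchical_cluster(sim)
        assert np.allclose(tree.linkage_matrix[:, 2], 0.0)

    def test_matches_reference_average_linkage(self, rng):
        """Tree heights match a hand-rolled average-linkage implementation."""
        d = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        sim = SimilarityMatrix(labels=[f"x{i}" for i in range(6)], values=1 - d)
        tree = hierarchical_cluster(sim)

        # brute-force average linkage on the same distances
        clusters = {i: [i] for i in range(6)}
        heights = []
        dist = d.copy()
        active = list(range(6))
        while len(active) > 1:
            best = None
            for ai in range(len(active)):
                for bi in range(ai + 1, len(active)):
                    a, b = active[ai], active[bi]
                    h = np.mean([dist[i, j] for i in clusters[a]
                                 for j in clusters[b]])
                    if best is None or h < best[0]:
                        best = (h, a, b)
            h, a, b = best
            heights.append(h)
            new_id = max(clusters) + 1
            clusters[new_id] = clusters.pop(a) + clusters.pop(b)
            active = [k for k in active if k not in (a, b)] + [new_id]
        assert np.allclose(sorted(tree.linkage_matrix[:, 2]), sorted(heights),
                           atol=1e-10)

    def test_newick_well_formed(self):
        vals = np.eye(3) * 0.5 + 0.5
        sim = SimilarityMatrix(labels=list("abc"), values=vals)
        nwk = hierarchical_cluster(sim).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2


class TestComparePartitions:
    def test_identical_partitions(self):
        assert compare_partitions([0, 0, 1, 1], [5, 5, 9, 9]) == 1.0

    def test_permutation_null_near_zero(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 50)
        vals = [compare_partitions(rng.permutation(labels), labels)
                for _ in range(200)]
        assert abs(np.mean(vals)) < 0.02

    def test_hand_computed_contingency(self):
        # two groups of 4 with one element swapped; ARI by hand = 0.5102...
        a = [0, 0, 0, 0, 1, 1, 1, 1]
        b = [0, 0, 0, 1, 0, 1, 1, 1]
        from itertools import combinations
        # independent ARI from the pair-counting definition
        n11 = sum(1 for i, j in combinations(range(8), 2)
                  if (a[i] == a[j]) and (b[i] == b[j]))
        n00 = sum(1 for i, j in combinations(range(8), 2)
                  if (a[i] != a[j]) and (b[i] != b[j]))
        n10 = sum(1 for i, j in combinations(range(8), 2)
                  if (a[i] == a[j]) and (b[i] != b[j]))
        n01 = sum(1 for i, j in combinations(range(8), 2)
                  if (a[i] != a[j]) and (b[i] == b[j]))
        assert n11 + n00 + n10 + n01 == 28
        n = 28
        sum_a = n11 + n10
        sum_b = n11 + n01
        exp = sum_a * sum_b / n
        mx = (sum_a + sum_b) / 2
        ari_hand = (n11 - exp) / (mx - exp)
        assert compare_partitions(a, b) == pytest.approx(ari_hand)

    def test_degenerate_single_class(self):
        assert compare_partitions([0, 0, 0], [1, 1, 1]) == 1.0
        with pytest.warns(UserWarning):
            assert compare_partitions([0, 0, 0], [0, 1, 2]) == 0.0


class TestDeduplicate:
    def _shifted(self, base, rms):
        # uniform displacement of one atom gives rmsd = rms after fit? use
        # random smooth-ish perturbation with exact RMS instead
        rng = np.random.default_rng(99)
        d = rng.normal(size=base.coords.shape)
        # remove net translation so Kabsch cannot undo it exactly
        d -= d.mean(axis=0)
        d *= rms / np.sqrt((d ** 2).sum(axis=1).mean())
        return base.with_coords(base.coords + d)

    def test_exact_duplicate_removed(self, helix10):
        kept = deduplicate_by_rmsd([helix10, helix10], cutoff=0.19, unit="nm")
        assert kept == [0]

    def test_all_distant_kept(self, helix10):
        others = [self._shifted(helix10, 5.0)]
        rng = np.random.default_rng(1)
        d2 = rng.normal(size=helix10.coords.shape) * 4
        others.append(helix10.with_coords(helix10.coords + d2))
        kept = deduplicate_by_rmsd([helix10] + others, cutoff=0.19, unit="nm")
        assert kept == [0, 1, 2]

    def test_greedy_rule_matches_simulation(self, helix40):
        """A chain of structures at ~1.5 Å spacing with a 1.9 Å cutoff keeps
        the same subset as a direct simulation of the greedy rule."""
        rng = np.random.default_rng(5)
        structures = [helix40]
        coords = helix40.coords.copy()
        for _ in range(7):
            step = rng.normal(size=coords.shape)
            step -= step.mean(axis=0)
            step *= 1.5 / np.sqrt((step ** 2).sum(axis=1).mean())
            coords = coords + step
            structures.append(helix40.with_coords(coords.copy()))
        kept = deduplicate_by_rmsd(structures, cutoff=0.19, unit="nm")

        from protdyn.superpose import kabsch_superpose
        sim_kept = []
        for i, s in enumerate(structures):
            if all(kabsch_superpose(s.coords, structures[j].coords)[2] > 1.9
                   for j in sim_kept):
                sim_kept.append(i)
        assert kept == sim_kept
        assert 1 < len(kept) < len(structures)


def test_similarity_matrix_contract():
    with pytest.raises(ValueError):
        SimilarityMatrix(labels=["a", "b"],
                         values=np.array([[1.0, 0.5], [0.4, 1.0]]))
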