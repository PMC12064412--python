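"""DCCM, contact matrices, RDCM, windowed correlations, segment trends."""

import numpy as np
import pytest

from protdyn.core import Ensemble, SelectionMask, StructureModel
from protdyn.correlation import (dccm, dccm_from_covariance,
                                 distance_matrices, helix_distance_report,
                                 rdcm, windowed_pearson)
from protdyn.select import select
from protdyn.synthetic import make_toy_chain, sample_enm_gaussian


def _bead_ensemble(frames, resids=None):
    m, n, _ = frames.shape
    resids = resids or list(range(1, n + 1))
    model = StructureModel(
        atom_names=["CA"] * n, elements=["C"] * n, resids=resids,
        resnames=["ALA"] * n, chain_ids=["A"] * n, masses=[12.0] * n,
        coords=frames[0])
    return Ensemble(topology=model, frames=frames)


def _full_mask(ens):
    return SelectionMask(np.arange(ens.n_atoms), ens.n_atoms)


class TestDccm:
    def test_duplicated_residue_perfectly_correlated(self, rng):
        base = rng.normal(size=(50, 1, 3))
        frames = np.concatenate([base, base + 5.0, rng.normal(size=(50, 1, 3))],
                                axis=1)
        frames = frames + np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]])[None]
        ens = _bead_ensemble(frames)
        c = dccm(ens, _full_mask(ens), presuperposed=True)
        assert c.values[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_displacements_near_zero(self, rng):
        frames = rng.normal(size=(5000, 6, 3)) + np.arange(6)[None, :, None] * 20
        ens = _bead_ensemble(frames)
        c = dccm(ens, _full_mask(ens), presuperposed=True)
        off = c.values[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_matches_analytic_covariance_dccm(self, enm_ensemble, ca_mask10):
        """Sampled DCCM vs the closed form from the ground-truth covariance."""
        from protdyn.superpose import superpose_ensemble
        ens, gt = enm_ensemble
        work = superpose_ensemble(ens)
        c = dccm(work, ca_mask10, presuperposed=True)
        idx3 = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2]
                               for i in ca_mask10.indices])
        sub = gt.covariance[np.ix_(idx3, idx3)]
        analytic = dccm_from_covariance(sub)
        assert np.abs(c.values - analytic.values).max() < 0.1  # M=5000

    def test_shuffle_invariance(self, helix10, ca_mask10, rng):
        ens, _ = sample_enm_gaussian(helix10, n_frames=300, seed=2)
        perm = rng.permutation(300)
        shuffled = Ensemble(topology=helix10, frames=ens.frames[perm])
        a = dccm(ens, ca_mask10).values
        b = dccm(shuffled, ca_mask10).values
        assert np.allclose(a, b, atol=1e-10)

    def test_zero_variance_row_zeroed(self):
        frames = np.zeros((20, 3, 3))
        frames[:, 1, 0] = np.sin(np.arange(20))
        frames[:, 2, :] = [8, 0, 0]
        frames[:, 2, 1] = np.cos(np.arange(20))
        frames[:, 0, :] = [0, 5, 0]  # static bead
        with pytest.warns(UserWarning, match="zero-variance"):
            c = dccm(_bead_ensemble(frames), SelectionMask(np.arange(3), 3),
                     presuperposed=True)
        assert c.values[0, 1] == 0.0 and c.values[0, 0] == 1.0


class TestContactMatrices:
    def test_occupancy_by_construction(self):
        frames = np.zeros((100, 2, 3))
        frames[:, 1, 0] = 20.0
        frames[:30, 1, 0] = 5.0       # in contact (8 Å default) frames 0-29
        summ = distance_matrices(_bead_ensemble(frames),
                                 SelectionMask(np.arange(2), 2))
        assert summ.occupancy[0, 1] == pytest.approx(0.30)

    def test_always_in_contact_edge_convention(self):
        frames = np.zeros((50, 2, 3))
        frames[:, 1, 0] = 5.0
        summ = distance_matrices(_bead_ensemble(frames),
                                 SelectionMask(np.arange(2), 2))
        assert summ.occupancy[0, 1] == 1.0
        assert summ.formation_time[0, 1] == pytest.approx(1 / 50)

    def test_alternating_contact_hand_enumeration(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = np.where(np.arange(10) % 2 == 0, 5.0, 20.0)
        summ = distance_matrices(_bead_ensemble(frames),
                                 SelectionMask(np.arange(2), 2))
        # formation events at frames 0,2,4,6,8 -> mean index (1+3+5+7+9)/5=5
        assert summ.formation_time[0, 1] == pytest.approx(5 / 10)
        assert summ.occupancy[0, 1] == pytest.approx(0.5)

    def test_never_in_contact_missing(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = 50.0
        summ = distance_matrices(_bead_ensemble(frames),
                                 SelectionMask(np.arange(2), 2))
        assert np.isnan(summ.formation_time[0, 1])

    def test_occupancy_monotone_in_cutoff(self, helix10, ca_mask10):
        ens, _ = sample_enm_gaussian(helix10, n_frames=100, seed=5)
        occ = [distance_matrices(ens, ca_mask10, c).occupancy
               for c in (4.0, 8.0, 12.0)]
        assert np.all(occ[0] <= occ[1] + 1e-12)
        assert np.all(occ[1] <= occ[2] + 1e-12)


class TestRdcm:
    def test_uniform_breathing_all_one(self):
        base = np.array([[0.0, 0, 0], [4, 0, 0], [0, 5, 0], [3, 3, 3]])
        scales = 1.0 + 0.2 * np.sin(np.arange(40))
        frames = scales[:, None, None] * base[None]
        c = rdcm(_bead_ensemble(frames), SelectionMask(np.arange(4), 4))
        assert np.allclose(c.values, 1.0, atol=1e-8)

    def test_two_independent_halves_block_structure(self, rng):
        # two rigid 3-bead halves, each translating independently
        half1 = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0]])
        half2 = half1 + [50.0, 0, 0]
        m = 400
        s1 = rng.normal(size=(m, 1, 1)) * 3
        s2 = rng.normal(size=(m, 1, 1)) * 3
        frames = np.concatenate([
            half1[None] + s1 * np.array([1.0, 0, 0]),
            half2[None] + s2 * np.array([1.0, 0, 0])], axis=1)
        c = rdcm(_bead_ensemble(frames), SelectionMask(np.arange(6), 6))
        within = np.abs(c.values[:3, :3][~np.eye(3, dtype=bool)]).mean()
        across = np.abs(c.values[:3, 3:]).mean()
        assert across < within

    def test_symmetric_unit_diagonal(self, helix10, ca_mask10):
        ens, _ = sample_enm_gaussian(helix10, n_frames=60, seed=9)
        c = rdcm(ens, ca_mask10)
        assert np.allclose(c.values, c.values.T)
        assert np.allclose(np.diag(c.values), 1.0)

    def test_rigid_body_invariance(self, helix10, ca_mask10, rng):
        from protdyn.geometry import random_rotation
        ens, _ = sample_enm_gaussian(helix10, n_frames=50, seed=4)
        moved = np.array([f @ random_rotation(rng).T + rng.normal(size=3)
                          for f in ens.frames])
        a = rdcm(ens, ca_mask10).values
        b = rdcm(Ensemble(topology=helix10, frames=moved), ca_mask10).values
        assert np.allclose(a, b, atol=1e-8)


class TestWindowedPearson:
    def test_nonoverlapping_partition(self, helix10, ca_mask10):
        ens, _ = sample_enm_gaussian(helix10, n_frames=120, seed=6)
        wins = windowed_pearson(ens, ca_mask10, window=40)
        assert len(wins) == 3

    def test_order_sensitivity(self, helix10, ca_mask10, rng):
        """Windowed matrices depend on frame order, unlike the global DCCM."""
        ens, _ = sample_enm_gaussian(helix10, n_frames=200, seed=8)
        drift = np.linspace(0, 3, 200)[:, None, None] * np.array([1.0, 0, 0])
        frames = ens.frames + drift[..., :]
        ens_d = Ensemble(topology=helix10, frames=frames)
        perm = rng.permutation(200)
        ens_p = Ensemble(topology=helix10, frames=frames[perm])
        w1 = windowed_pearson(ens_d, ca_mask10, window=50)
        w2 = windowed_pearson(ens_p, ca_mask10, window=50)
        diff = max(np.abs(a.values - b.values).max()
                   for a, b in zip(w1, w2))
        assert diff > 1e-3

    def test_window_too_long_rejected(self, helix10, ca_mask10):
        ens, _ = sample_enm_gaussian(helix10, n_frames=20, seed=0)
        with pytest.raises(ValueError):
            windowed_pearson(ens, ca_mask10, window=30)


class TestHelixDistanceReport:
    def test_linear_approach_negative_slope(self):
        n = 6
        base = np.zeros((n, 3))
        base[:3, 0] = [0, 4, 8]
        base[3:, 0] = [40, 44, 48]
        frames = np.repeat(base[None], 80, axis=0)
        frames[:, 3:, 0] -= np.linspace(0, 10, 80)[:, None]  # halves approach
        ens = _bead_ensemble(frames)
        rep = helix_distance_report(ens, {"A": (1, 3), "B": (4, 6)},
                                    SelectionMask(np.arange(n), n))
        assert rep[("A", "B")]["trend"] == -1

    def test_static_zero_trend(self):
        base = np.zeros((4, 3))
        base[:, 0] = [0, 4, 30, 34]
        frames = np.repeat(base[None], 50, axis=0)
        ens = _bead_ensemble(frames)
        rep = helix_distance_report(ens, {"A": (1, 2), "B": (3, 4)},
                                    SelectionMask(np.arange(4), 4))
        assert rep[("A", "B")]["trend"] == 0

    def test_slope_sign_matches_quartile_oracle(self, rng):
        n = 4
        base = np.zeros((n, 3))
        base[:, 0] = [0, 4, 30, 34]
        for sign in (+1, -1):
            frames = np.repeat(base[None], 100, axis=0)
            frames[:, 2:, 0] += sign * np.linspace(0, 8, 100)[:, None]
            frames += rng.normal(scale=0.05, size=frames.shape)
            ens = _bead_ensemble(frames)
            rep = helix_distance_report(ens, {"A": (1, 2), "B": (3, 4)},
                                        SelectionMask(np.arange(n), n))
            series = rep[("A", "B")]["series"]
            q = len(series) // 4
            oracle = np.sign(series[-q:].mean() - series[:q].mean())
            assert rep[("A", "B")]["trend"] == oracle

    def test_overlapping_segments_rejected(self, helix10):
        ens, _ = sample_enm_gaussian(helix10, n_frames=20, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            helix_distance_report(ens, {"A": (1, 5), "B": (5, 8)})
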