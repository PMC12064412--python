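"""Ligand fingerprints, Tanimoto similarity, interaction timelines."""

import numpy as np
import pytest

from protdyn.core import Ensemble, SelectionMask, StructureModel
from protdyn.ligand import (FingerprintSeries, fingerprint_series,
                            frame_fingerprint, interaction_timeline,
                            pocket_center_distance, tanimoto_matrix)
from protdyn.select import select
from protdyn.synthetic import make_toy_chain, sample_ligand_walk


def _system(lig_offset):
    """A 2-residue mini-protein plus a 2-atom ligand at a given offset."""
    prot = make_toy_chain(3)
    lig = StructureModel(
        atom_names=["L1", "L2"], elements=["C", "O"],
        resids=[4, 4], resnames=["LIG"] * 2, chain_ids=["L"] * 2,
        masses=[12.0, 16.0],
        coords=prot.coords[prot.atom_names == "CA"][1] + np.array(
            [lig_offset, [lig_offset[0] + 1.2, lig_offset[1], lig_offset[2]]]),
        is_hetatm=[True, True])
    from protdyn.synthetic import concat_models
    return concat_models(prot, lig)


class TestPocketDistance:
    def test_centroid_coincidence_zero(self):
        m = make_toy_chain(6)
        ca = m.coords[m.atom_names == "CA"]
        lig = StructureModel(
            atom_names=["L1"], elements=["C"], resids=[7], resnames=["LIG"],
            chain_ids=["L"], masses=[12.0], coords=ca.mean(0)[None],
            is_hetatm=[True])
        from protdyn.synthetic import concat_models
        topo = concat_models(m, lig)
        ens = Ensemble(topology=topo, frames=topo.coords[None])
        d = pocket_center_distance(ens, select(topo, "hetatm"),
                                   select(topo, "protein"))
        assert d.values[0] == pytest.approx(0.0, abs=1e-10)

    def test_known_displacement(self):
        m = make_toy_chain(6)
        ca = m.coords[m.atom_names == "CA"]
        lig = StructureModel(
            atom_names=["L1"], elements=["C"], resids=[7], resnames=["LIG"],
            chain_ids=["L"], masses=[12.0],
            coords=(ca.mean(0) + [5.0, 0, 0])[None], is_hetatm=[True])
        from protdyn.synthetic import concat_models
        topo = concat_models(m, lig)
        ens = Ensemble(topology=topo, frames=topo.coords[None])
        d = pocket_center_distance(ens, select(topo, "hetatm"),
                                   select(topo, "protein"))
        assert d.values[0] == pytest.approx(5.0)

    def test_scripted_drift_tracked(self):
        pocket = make_toy_chain(10)
        script = [{3}] * 10 + [{8}] * 10
        ens, _ = sample_ligand_walk(pocket, script, jitter_sd=0.0, seed=1)
        d = pocket_center_distance(ens, select(ens.topology, "hetatm"),
                                   select(ens.topology, "protein"))
        assert np.ptp(d.values[:10]) < 1e-6   # constant placement per epoch
        assert abs(d.values[0] - d.values[-1]) > 0.1


class TestFrameFingerprint:
    def test_distant_ligand_all_zero(self):
        m = _system(np.array([100.0, 0.0, 0.0]))
        bits, defs = frame_fingerprint(m, select(m, "hetatm"),
                                       select(m, "protein"))
        assert bits.sum() == 0

    def test_contact_bits_match_predicates(self):
        m = _system(np.array([3.0, 0.0, 0.0]))
        lig = select(m, "hetatm")
        prot = select(m, "protein")
        bits, defs = frame_fingerprint(m, lig, prot)
        lig_xyz = m.coords[lig.indices]
        for b, (res, cls) in enumerate(defs):
            res_idx = prot.indices[m.resids[prot.indices] == res]
            res_xyz = m.coords[res_idx]
            dmin = np.linalg.norm(res_xyz[:, None] - lig_xyz[None],
                                  axis=-1).min()
            if cls == "any_contact":
                assert bits[b] == int(dmin <= 4.5)
            elif cls == "hydrophobic":
                res_c = res_xyz[np.char.upper(m.elements[res_idx]) == "C"]
                lig_c = lig_xyz[np.char.upper(m.elements[lig.indices]) == "C"]
                dcc = np.linalg.norm(res_c[:, None] - lig_c[None],
                                     axis=-1).min()
                assert bits[b] == int(dcc <= 4.0)

    @pytest.mark.parametrize("offset,expect_any", [
        ([3.0, 0, 0], True), ([4.6, 2.0, 0], False), ([2.0, 2.0, 2.0], True),
        ([5.0, 5.0, 0], False), ([0.0, 4.0, 1.0], True),
    ])
    def test_any_contact_over_geometries(self, offset, expect_any):
        m = _system(np.array(offset, dtype=float))
        lig = select(m, "hetatm")
        prot = select(m, "protein")
        bits, defs = frame_fingerprint(m, lig, prot)
        lig_xyz = m.coords[lig.indices]
        prot_xyz = m.coords[prot.indices]
        dmin = np.linalg.norm(prot_xyz[:, None] - lig_xyz[None], axis=-1).min()
        got_any = any(bits[b] for b, (r, c) in enumerate(defs)
                      if c == "any_contact")
        assert got_any == (dmin <= 4.5)


class TestTanimoto:
    def _fp(self, rows):
        bits = np.asarray(rows, dtype=np.uint8)
        defs = [(i + 1, "any_contact") for i in range(bits.shape[1])]
        return FingerprintSeries(bit_definitions=defs, bits=bits)

    def test_identical_frames_one(self):
        fp = self._fp([[1, 0, 1], [1, 0, 1]])
        t = tanimoto_matrix(fp)
        assert t[0, 1] == 1.0

    def test_disjoint_zero(self):
        fp = self._fp([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert tanimoto_matrix(fp)[0, 1] == 0.0

    def test_one_shared_of_three(self):
        fp = self._fp([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert tanimoto_matrix(fp)[0, 1] == pytest.approx(1 / 3)

    def test_empty_pair_convention(self):
        fp = self._fp([[0, 0], [0, 0], [1, 0]])
        with pytest.warns(UserWarning):
            t = tanimoto_matrix(fp)
        assert t[0, 1] == 1.0

    def test_matrix_identities(self, rng):
        bits = (rng.random((20, 8)) < 0.4).astype(np.uint8)
        bits[0] = 1  # guarantee nonzero
        fp = self._fp(bits)
        t = tanimoto_matrix(fp)
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 1.0)
        assert t.min() >= 0 and t.max() <= 1

    def test_one_minus_t_triangle_inequality(self, rng):
        """1 − T is a metric on bit sets (spot-check on random triples)."""
        bits = (rng.random((30, 10)) < 0.5).astype(np.uint8)
        bits[:, 0] = 1
        fp = self._fp(bits)
        t = tanimoto_matrix(fp)
        d = 1 - t
        for _ in range(100):
            i, j, k = rng.integers(0, 30, size=3)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestTimeline:
    def _fp(self, col):
        bits = np.zeros((len(col), 1), dtype=np.uint8)
        bits[:, 0] = col
        return FingerprintSeries(bit_definitions=[(5, "any_contact")],
                                 bits=bits)

    def test_single_run(self):
        col = [1] * 30 + [0] * 70
        tl = interaction_timeline(self._fp(col))
        e = tl.entries[(5, "any_contact")]
        assert e["occupancy"] == pytest.approx(0.30)
        assert e["runs"] == [(0, 30)]
        assert e["longest_run"] == 30

    def test_alternating_runs(self):
        col = [1, 0] * 10
        tl = interaction_timeline(self._fp(col))
        e = tl.entries[(5, "any_contact")]
        assert len(e["runs"]) == 10
        assert all(l == 1 for _, l in e["runs"])

    def test_occupancy_equals_bit_means(self, rng):
        """Consistency: timeline occupancies equal column means of bits."""
        bits = (rng.random((50, 6)) < 0.3).astype(np.uint8)
        defs = [(r, c) for r in (1, 2) for c in ("any_contact", "hydrophobic",
                                                 "hbond_donor")]
        fp = FingerprintSeries(bit_definitions=defs, bits=bits)
        tl = interaction_timeline(fp)
        for b, key in enumerate(defs):
            assert tl.entries[key]["occupancy"] == pytest.approx(
                bits[:, b].mean())

    def test_ranking_matches_recomputed_occupancy(self):
        pocket = make_toy_chain(12)
        script = ([{3}] * 50 + [{7}] * 30 + [set()] * 20)
        ens, _ = sample_ligand_walk(pocket, script, seed=2)
        fp = fingerprint_series(ens, select(ens.topology, "hetatm"),
                                select(ens.topology, "protein"))
        tl = interaction_timeline(fp)
        occ = {r: np.mean([fp.bits[t, b]
                           for b, (rr, c) in enumerate(fp.bit_definitions)
                           if rr == r and c == "any_contact"
                           for t in range(fp.bits.shape[0])])
               for r in (3, 7)}
        assert tl.ranking[0] == max(occ, key=occ.get)
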