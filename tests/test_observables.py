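"""Order parameters: Q fractions, COM distance, RMSD/RMSF, helix proxy."""

import numpy as np
import pytest

from bindfold import (
    com_distance,
    helix_proxy,
    per_residue_interface_q,
    q_fraction,
    rmsd_kabsch,
    rmsf,
)
from bindfold.contacts import SPAN_B, SPAN_INTER
from bindfold.observables import compute_series, native_pair_arrays
from bindfold.synthetic import ideal_helix


class TestQFraction:
    def test_native_frame_is_one(self, toy_topology, toy_native_map_fixture):
        pairs, sigma = native_pair_arrays(toy_native_map_fixture, SPAN_B)
        assert q_fraction(toy_topology.native_coords, pairs, sigma) == 1.0

    def test_uniformly_expanded_frame_is_zero(self, toy_topology,
                                              toy_native_map_fixture):
        pairs, sigma = native_pair_arrays(toy_native_map_fixture, SPAN_B)
        assert q_fraction(1.3 * toy_topology.native_coords, pairs, sigma) == 0.0

    def test_strict_threshold_count(self):
        # pairs at 1.0, 1.1, 1.25, 2.0 times sigma with factor 1.2 -> 2/4
        sigma = np.full(4, 0.5)
        ratios = np.array([1.0, 1.1, 1.25, 2.0])
        coords = np.zeros((8, 3))
        pairs = np.array([[0, 1], [2, 3], [4, 5], [6, 7]])
        for k, r in enumerate(ratios):
            coords[2 * k + 1, 0] = coords[2 * k, 0] + r * sigma[k]
            coords[2 * k, 1] = coords[2 * k + 1, 1] = 10.0 * k
        assert q_fraction(coords, pairs, sigma) == 0.5

    def test_empty_pairs_error(self, toy_topology):
        with pytest.raises(ValueError, match="undefined|empty"):
            q_fraction(toy_topology.native_coords, np.zeros((0, 2), int),
                       np.zeros(0))

    def test_monotone_under_uniform_expansion(self, toy_topology,
                                              toy_native_map_fixture):
        pairs, sigma = native_pair_arrays(toy_native_map_fixture, SPAN_INTER)
        scales = [1.0, 1.1, 1.2, 1.4, 2.0]
        qs = [q_fraction(s * toy_topology.native_coords, pairs, sigma)
              for s in scales]
        assert all(a >= b for a, b in zip(qs, qs[1:]))

    def test_rigid_motion_invariance(self, toy_topology,
                                     toy_native_map_fixture, rng):
        pairs, sigma = native_pair_arrays(toy_native_map_fixture, SPAN_INTER)
        coords = toy_topology.native_coords + 0.2 * rng.standard_normal(
            toy_topology.native_coords.shape
        )
        q1 = q_fraction(coords, pairs, sigma)
        q2 = q_fraction(coords + np.array([3.0, -1.0, 2.0]), pairs, sigma)
        assert q1 == q2


class TestPerResidueInterfaceQ:
    def test_native_frame_all_one(self, toy_topology, toy_native_map_fixture):
        pairs, sigma = native_pair_arrays(toy_native_map_fixture, SPAN_INTER)
        _, pep = toy_topology.partition()
        prof = per_residue_interface_q(
            toy_topology.native_coords, pairs, sigma, pep
        )
        assert np.all(prof.values[prof.defined] == 1.0)

    def test_separated_chains_all_zero(self, toy_topology,
                                       toy_native_map_fixture):
        pairs, sigma = native_pair_arrays(toy_native_map_fixture, SPAN_INTER)
        coords = toy_topology.native_coords.copy()
        _, pep = toy_topology.partition()
        coords[pep] += np.array([0.0, 0.0, 50.0])
        prof = per_residue_interface_q(coords, pairs, sigma, pep)
        assert np.all(prof.values[prof.defined] == 0.0)

    def test_half_formed_residue(self):
        # residue bead 4 has native interfacial pairs to beads 0-3 at sigma 0.5;
        # two are stretched far beyond formation
        pairs = np.array([[0, 4], [1, 4], [2, 4], [3, 4]])
        sigma = np.full(4, 0.5)
        coords = np.zeros((5, 3))
        coords[0] = [0.5, 0, 0]
        coords[1] = [0, 0.5, 0]
        coords[2] = [0, 0, 2.0]
        coords[3] = [0, 2.0, 0]
        prof = per_residue_interface_q(coords, pairs, sigma, np.array([4]))
        assert prof.values[0] == pytest.approx(0.5)


class TestComDistance:
    def test_two_single_beads(self):
        from bindfold.contacts import SPAN_A
        from bindfold.model import CGTopology

        top = CGTopology(
            n_beads=2, chain_of_bead=np.array(["A", "B"], dtype=object),
            chain_slices={"A": slice(0, 1), "B": slice(1, 2)},
            bonds=np.zeros((0, 2), int), bond_r0=np.zeros(0),
            angles=np.zeros((0, 3), int), angle_theta0=np.zeros(0),
            torsions=np.zeros((0, 4), int), torsion_phi0=np.zeros(0),
            native_pairs=np.zeros((0, 2), int), native_sigma=np.zeros(0),
            native_span=[],
        )
        coords = np.array([[0.0, 0, 0], [0, 0, 2.0]])
        assert com_distance(coords, top) == pytest.approx(2.0)
        assert com_distance(np.zeros((2, 3)), top) == 0.0


class TestRmsd:
    def test_identity_zero(self, rng):
        a = rng.standard_normal((10, 3))
        assert rmsd_kabsch(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        a = rng.standard_normal((10, 3))
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        b = a @ rot.T + np.array([1.0, 2.0, 3.0])
        assert rmsd_kabsch(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_against_quaternion_oracle(self, rng):
        # independent superposition via the Horn quaternion method
        a = rng.standard_normal((4, 3))
        b = a + 0.1 * rng.standard_normal((4, 3))

        def horn_rmsd(p, q):
            p0 = p - p.mean(axis=0)
            q0 = q - q.mean(axis=0)
            m = q0.T @ p0
            sxx, sxy, sxz = m[0]
            syx, syy, syz = m[1]
            szx, szy, szz = m[2]
            k = np.array([
                [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
                [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
                [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
                [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
            ])
            lam = np.linalg.eigvalsh(k)[-1]
            e = float((p0**2).sum() + (q0**2).sum() - 2 * lam)
            return np.sqrt(max(e, 0.0) / len(p))

        assert rmsd_kabsch(a, b) == pytest.approx(horn_rmsd(a, b), abs=1e-9)

    def test_count_mismatch(self, rng):
        with pytest.raises(ValueError):
            rmsd_kabsch(rng.standard_normal((4, 3)), rng.standard_normal((5, 3)))


class TestRmsf:
    def test_rigid_trajectory_zero(self, toy_topology):
        frames = np.repeat(toy_topology.native_coords[None], 5, axis=0)
        prof = rmsf(frames)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_isotropic_jitter_closed_form(self, rng):
        # enough anchor atoms that the superposition fit absorbs a
        # negligible share of the single noisy atom's displacement
        base = rng.standard_normal((80, 3)) * 2.0
        sigma = 0.05
        n = 10_000
        frames = np.repeat(base[None], n, axis=0)
        frames[:, 3, :] += sigma * rng.standard_normal((n, 3))
        prof = rmsf(frames)
        assert prof.values[3] == pytest.approx(sigma * np.sqrt(3), rel=0.05)
        assert prof.values[3] > 5 * np.median(np.delete(prof.values, 3))

    def test_noisy_loop_exceeds_core(self, toy_topology, rng):
        base = toy_topology.native_coords
        n = 400
        frames = np.repeat(base[None], n, axis=0)
        frames += 0.01 * rng.standard_normal(frames.shape)
        loop = np.arange(8, 16)
        frames[:, loop, :] += 0.08 * rng.standard_normal((n, len(loop), 3))
        a, _ = toy_topology.partition()
        prof = rmsf(frames, selection=a)
        core = np.setdiff1d(a, loop)
        assert prof.values[np.isin(prof.residue_indices, loop)].min() \
            > np.median(prof.values[np.isin(prof.residue_indices, core)])

    def test_single_frame_rejected(self, toy_topology):
        with pytest.raises(ValueError):
            rmsf(toy_topology.native_coords[None])


class TestHelixProxy:
    def test_ideal_helix_flagged(self):
        pos = ideal_helix(12)
        flags = helix_proxy(pos)
        assert flags[1:-1].all()

    def test_extended_chain_not_flagged(self):
        pos = np.column_stack([0.38 * np.arange(12), np.zeros(12), np.zeros(12)])
        assert not helix_proxy(pos).any()

    def test_half_helix_half_coil(self):
        helix = ideal_helix(8)
        coil = np.column_stack([
            0.38 * np.arange(1, 9), np.zeros(8), np.zeros(8)
        ]) + helix[-1]
        pos = np.vstack([helix, coil])
        flags = helix_proxy(pos)
        assert flags[:6].all()          # helical half (interior)
        assert not flags[10:].any()     # coil half, boundary +/- 1 residue


class TestComputeSeries:
    def test_reread_trajectory_identical(self, toy_system, toy_topology,
                                         toy_native_map_fixture, tmp_path):
        from bindfold import SamplerConfig, Trajectory, run_langevin

        cfg = SamplerConfig(temperature=100.0, n_steps=2000, save_every=200,
                            seed=9)
        traj = run_langevin(toy_system, toy_topology.native_coords.copy(), cfg)
        s1 = compute_series(traj.coords.astype(float), toy_topology,
                            toy_native_map_fixture)
        traj.save(tmp_path / "t.h5")
        back = Trajectory.load(tmp_path / "t.h5")
        s2 = compute_series(back.coords.astype(float), toy_topology,
                            toy_native_map_fixture)
        assert np.array_equal(s1.q_f, s2.q_f)
        assert np.array_equal(s1.d_com, s2.d_com)
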