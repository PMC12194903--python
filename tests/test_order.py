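"""Nematic order, directors, tilt distributions and deuterium order."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import bilayerkit as bk


def _random_unit(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestNematic:
    def test_identical_vectors_give_exactly_one(self):
        u = np.tile([0.3, 0.4, np.sqrt(1 - 0.25)], (50, 1))
        s, d = bk.nematic_order(u)
        assert s == 1.0
        np.testing.assert_allclose(np.abs(d @ u[0]), 1.0, atol=1e-12)

    def test_isotropic_vectors_near_zero(self, rng):
        s, _ = bk.nematic_order(_random_unit(rng, 10_000))
        assert s < 0.05

    def test_nematic_symmetry_u_minus_u(self):
        u = np.tile([0.0, 0.0, 1.0], (40, 1))
        u[::2] *= -1
        s, _ = bk.nematic_order(u)
        assert s == 1.0

    def test_global_rotation_invariance(self, rng):
        u = _random_unit(rng, 500)
        # make it anisotropic
        u[:, 2] += 1.5
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        s0, _ = bk.nematic_order(u)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        s1, _ = bk.nematic_order(u @ rot.T)
        assert abs(s1 - s0) < 1e-9

    def test_q_tensor_s_equals_p2_against_director(self, rng):
        # axially distributed about +Z
        n = 50_000
        theta = np.abs(rng.normal(0, 0.3, n))
        phi = rng.uniform(0, 2 * np.pi, n)
        u = np.column_stack([np.sin(theta) * np.cos(phi),
                             np.sin(theta) * np.sin(phi), np.cos(theta)])
        s, d = bk.nematic_order(u)
        cos_a = u @ d
        p2 = np.mean(1.5 * cos_a ** 2 - 0.5)
        assert s == pytest.approx(p2, rel=0.01)

    def test_s_monotone_in_imposed_order(self):
        vals = []
        for kappa in (2.0, 8.0, 32.0, 128.0):
            spec = bk.SyntheticSpec(n_lipids_per_leaflet=200,
                                    waters_per_lipid=0, chain_length=4,
                                    orientational_noise=kappa, seed=11)
            frame, topo = bk.build_bilayer(spec)
            asg = bk.assign_leaflets(frame, topo)
            v = bk.head_to_terminal_vectors(frame, topo, asg)
            s, _ = bk.nematic_order(v, "top")
            vals.append(s)
        assert np.all(np.diff(vals) > 0)

    def test_director_sign_convention(self, small_planar):
        _, frame, topo = small_planar
        asg = bk.assign_leaflets(frame, topo)
        v = bk.head_to_terminal_vectors(frame, topo, asg)
        _, d_top = bk.nematic_order(v, "top")
        _, d_bot = bk.nematic_order(v, "bottom")
        assert d_top[2] < 0 < d_bot[2]


class TestDirectorSeparation:
    def test_mirrored_ten_degrees_gives_twenty(self):
        t = np.radians(10)
        d1 = np.array([np.sin(t), 0, np.cos(t)])
        d2 = np.array([-np.sin(t), 0, np.cos(t)])
        assert bk.director_separation(d1, d2) == pytest.approx(20.0, abs=0.01)

    def test_parallel_and_antiparallel_fold_to_zero(self):
        d = np.array([0.2, 0.1, 0.97])
        d /= np.linalg.norm(d)
        assert bk.director_separation(d, d) == pytest.approx(0.0, abs=1e-6)
        assert bk.director_separation(d, -d) == pytest.approx(0.0, abs=1e-6)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            bk.director_separation(np.zeros(3), np.array([0, 0, 1.0]))

    def test_tilt_phase_small_cross_tilt_large(self):
        def separation(cross):
            spec = bk.SyntheticSpec(n_lipids_per_leaflet=128,
                                    waters_per_lipid=0, chain_length=4,
                                    chain_tilt=10.0, cross_tilt=cross,
                                    orientational_noise=200.0, seed=21)
            frame, topo = bk.build_bilayer(spec)
            asg = bk.assign_leaflets(frame, topo)
            v = bk.head_to_terminal_vectors(frame, topo, asg)
            _, d1 = bk.nematic_order(v, "top")
            _, d2 = bk.nematic_order(v, "bottom")
            return bk.director_separation(d1, d2)

        assert separation(False) < 5.0
        assert separation(True) == pytest.approx(20.0, abs=1.0)


class TestTilt:
    def test_delta_peaks(self):
        for tilt in (0.0, 45.0):
            spec = bk.SyntheticSpec(n_lipids_per_leaflet=16,
                                    waters_per_lipid=0, chain_length=4,
                                    chain_tilt=tilt)
            frame, topo = bk.build_bilayer(spec)
            asg = bk.assign_leaflets(frame, topo)
            v = bk.head_to_terminal_vectors(frame, topo, asg)
            ang = bk.tilt_angles(v)
            np.testing.assert_allclose(ang, tilt, atol=1e-9)

    def test_histogram_normalised(self, rng):
        hist = bk.tilt_distribution(_random_unit(rng, 5000), bins=45)
        assert hist.frequency.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_density_follows_sine(self, rng):
        hist = bk.tilt_distribution(_random_unit(rng, 100_000), bins=18)
        centers = np.radians(hist.bin_centers)
        expected = np.sin(centers)
        expected /= expected.sum()
        np.testing.assert_allclose(hist.frequency, expected, atol=0.004)


class TestDeuteriumOrder:
    def test_all_trans_along_z_is_minus_half(self, small_planar):
        _, frame, topo = small_planar
        prof = bk.deuterium_order(frame, topo)
        np.testing.assert_allclose(prof.scd, -0.5, atol=1e-12)
        assert len(prof.carbon_index) == 14

    def test_chain_along_x_is_plus_quarter(self):
        spec = bk.SyntheticSpec(n_lipids_per_leaflet=16, waters_per_lipid=0,
                                chain_length=6, chain_tilt=90.0)
        frame, topo = bk.build_bilayer(spec)
        prof = bk.deuterium_order(frame, topo)
        np.testing.assert_allclose(prof.scd, 0.25, atol=1e-12)

    def test_zigzag_tetrahedral_reconstruction(self):
        # explicit zigzag chain along Z: H's reconstructed tetrahedrally
        dz, off = 0.127, 0.05
        n_c = 8
        pos = [[0.0, 0.0, 2.0], [0.0, 0.0, 2.1]]  # N, P
        for i in range(1, n_c + 1):
            pos.append([off * (-1) ** i, 0.0, 2.0 - i * dz])
        for i in range(1, n_c + 1):
            pos.append([0.5 + off * (-1) ** i, 0.0, 2.0 - i * dz])
        pos = np.array(pos)
        names = np.array(["N", "P"] + [f"C{i}A" for i in range(1, n_c + 1)]
                         + [f"C{i}B" for i in range(1, n_c + 1)], dtype=object)
        f = bk.BoxedFrame(box=np.array([5.0, 5.0, 5.0]), positions=pos,
                          names=names,
                          resnames=np.array(["DPPC"] * len(pos), dtype=object),
                          resids=np.ones(len(pos), dtype=int),
                          masses=np.full(len(pos), 14.0))
        topo = bk.extract_lipid_topology(f)
        prof = bk.deuterium_order(f, topo)
        np.testing.assert_allclose(prof.scd, -0.5, atol=1e-9)

    def test_isotropic_chains_average_to_zero(self):
        spec = bk.SyntheticSpec(n_lipids_per_leaflet=20_000,
                                waters_per_lipid=0, chain_length=3,
                                orientational_noise=0.0, seed=31)
        frame, topo = bk.build_bilayer(spec)
        prof = bk.deuterium_order(frame, topo)
        assert np.abs(prof.scd).max() < 0.01

    def test_bounds(self, rng):
        spec = bk.SyntheticSpec(n_lipids_per_leaflet=500, waters_per_lipid=0,
                                chain_length=8, orientational_noise=3.0,
                                seed=5)
        frame, topo = bk.build_bilayer(spec)
        prof = bk.deuterium_order(frame, topo)
        assert np.all(prof.scd >= -0.5 - 1e-12)
        assert np.all(prof.scd <= 1.0 + 1e-12)
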