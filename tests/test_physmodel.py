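import numpy as np
import pytest

from ccrama import physmodel as pm
from ccrama.physmodel import (BackboneGeometry, PhysicalConstants,
                              RATE_REGISTRY, REMOTE_RATE_IDS, KNOWN_RATE_IDS,
                              build_fragment, csa_frame, dihedral_angle,
                              bond_angle, p2, prefactor, structural_amplitude)


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


class TestRegistry:
    def test_eight_remote_two_known(self):
        assert len(REMOTE_RATE_IDS) == 8
        assert len(KNOWN_RATE_IDS) == 2
        assert set(KNOWN_RATE_IDS) == {"N_NHN", "C_CCA"}

    def test_instantaneous_distance_only_for_sequential_ha_hn(self):
        for rid, kind in RATE_REGISTRY.items():
            for inter in kind.interactions:
                if isinstance(inter, pm.Dipole) and \
                        inter.distance_mode == "instantaneous":
                    assert rid == "HAHN1_C"
                    assert {inter.a, inter.b} == {("HA", 0), ("H", 1)}


class TestFragment:
    @pytest.mark.parametrize("phi,psi", [(-63.0, -43.0), (-135.0, 135.0),
                                         (60.0, 45.0), (179.0, -179.0)])
    def test_round_trip_and_internal_coordinates(self, phi, psi):
        g = BackboneGeometry()
        f = build_fragment(phi, psi, g)
        assert np.isclose(dihedral_angle(f[("C", -1)], f[("N", 0)],
                                         f[("CA", 0)], f[("C", 0)]), phi)
        assert np.isclose(dihedral_angle(f[("N", 0)], f[("CA", 0)],
                                         f[("C", 0)], f[("N", 1)]), psi)
        assert np.isclose(np.linalg.norm(f[("H", 0)] - f[("N", 0)]), g.r_NH)
        assert np.isclose(np.linalg.norm(f[("HA", 0)] - f[("CA", 0)]),
                          g.r_CaHa)
        assert np.isclose(bond_angle(f[("N", 0)], f[("CA", 0)],
                                     f[("C", 0)]), g.ang_n_ca_c)

    def test_rotation_leaves_projection_angles_unchanged(self, rng):
        f = build_fragment(-70.0, 140.0)
        R = random_rotation(rng)
        nh = f[("H", 0)] - f[("N", 0)]
        caha = f[("HA", 0)] - f[("CA", 0)]
        before = np.dot(nh, caha)
        after = np.dot(R @ nh, R @ caha)
        assert np.isclose(before, after, atol=1e-12)

    def test_ca_ca_distance_matches_independent_builder(self):
        # independent oracle: successive NeRF-free construction of the
        # extended (180, 180) conformer from explicit rotations in a plane
        g = BackboneGeometry()
        f = build_fragment(180.0, 180.0, g)
        d = np.linalg.norm(f[("CA", 1)] - f[("CA", 0)])
        # all-trans conformer is planar: walk CA(i) -> C' -> N -> CA(i+1)
        # in 2-D with alternating turn sense (zig-zag)
        pts = [np.zeros(2)]
        heading = 0.0
        turns = ((g.r_ca_c, g.ang_ca_c_n, +1.0), (g.r_c_n, g.ang_c_n_ca, -1.0),
                 (g.r_n_ca, None, 0.0))
        for bond, interior, sense in turns:
            pts.append(pts[-1] + bond * np.array([np.cos(heading),
                                                  np.sin(heading)]))
            if interior is not None:
                heading += sense * (np.pi - np.radians(interior))
        oracle = np.linalg.norm(pts[-1] - pts[0])
        assert np.isclose(d, oracle, atol=1e-8)

    def test_unknown_atom_raises(self):
        f = build_fragment(0.0, 0.0)
        with pytest.raises(pm.UnknownAtomError, match="CB"):
            pm.fragment_atom(f, ("CB", 0))


class TestCsaFrame:
    def test_zz_perpendicular_to_plane(self):
        f = build_fragment(-60.0, -45.0)
        xx, yy, zz = csa_frame(f, ("C", 0), pm.C_PRIME_CSA)
        cn = f[("N", 1)] - f[("C", 0)]
        co = f[("O", 0)] - f[("C", 0)]
        assert abs(np.dot(zz, cn / np.linalg.norm(cn))) < 1e-12
        assert abs(np.dot(zz, co / np.linalg.norm(co))) < 1e-12
        assert np.allclose(np.cross(xx, yy), zz)

    def test_frame_angles_match_tensor_geometry(self):
        f = build_fragment(100.0, -100.0)
        xx, _, _ = csa_frame(f, ("N", 0), pm.N_CSA)
        nh = f[("H", 0)] - f[("N", 0)]
        nh /= np.linalg.norm(nh)
        assert np.isclose(np.degrees(np.arccos(np.dot(xx, nh))), 20.0)
        xx, _, _ = csa_frame(f, ("C", 0), pm.C_PRIME_CSA)
        cn = f[("N", 1)] - f[("C", 0)]
        cn /= np.linalg.norm(cn)
        assert np.isclose(np.degrees(np.arccos(np.dot(xx, cn))), 37.0)

    def test_colinear_bonds_degenerate(self):
        coords = {("N", 0): np.zeros(3), ("H", 0): np.array([1.0, 0, 0]),
                  ("C", -1): np.array([-2.0, 0, 0])}
        with pytest.raises(pm.DegenerateFrameError):
            csa_frame(coords, ("N", 0), pm.N_CSA)


class TestPrefactor:
    def test_zero_gamma_kills_dd(self):
        c = PhysicalConstants()
        c = pm.replace(c, gamma_C=1e-30)  # effectively zero, keeps ordering
        k = RATE_REGISTRY["NHN_CAHA"]
        assert abs(prefactor(k, c)[0]) < 1e-30 * abs(
            prefactor(k, PhysicalConstants())[0])

    def test_dd_prefactor_matches_direct_expression(self):
        # independent evaluation of (2/5)(mu0 hbar / 4 pi)^2 gH^2 gN gC / r^6
        c = PhysicalConstants()
        k = RATE_REGISTRY["NHN_CAHA"]
        got = prefactor(k, c, distances={0: 2.5, 1: 2.5})[0]
        expect = (0.4 * (1e-7 * 1.054571817e-34) ** 2
                  * c.gamma_N * c.gamma_H * c.gamma_C * c.gamma_H
                  / (2.5e-10 ** 3) ** 2)
        assert np.isclose(got, expect, rtol=1e-12)

    def test_csa_csa_weights_proportional_to_delta_products(self):
        c = PhysicalConstants()
        k = RATE_REGISTRY["Cm1_C"]
        quad = prefactor(k, c)
        dx, dy = pm.C_PRIME_CSA.delta_x, pm.C_PRIME_CSA.delta_y
        ratios = quad / quad[0]
        assert np.allclose(ratios, [1.0, dy / dx, dy / dx, (dy / dx) ** 2])

    def test_missing_csa_tensor(self):
        with pytest.raises(ValueError, match="CSA"):
            prefactor(RATE_REGISTRY["NHN_C"], csa_map={})


class TestStructuralAmplitude:
    def test_parallel_dipoles_give_full_prefactor(self):
        # synthetic coordinates with both dipole vectors parallel
        coords = {("N", 0): np.zeros(3), ("H", 0): np.array([0, 0, 1.01]),
                  ("CA", 0): np.array([3.0, 0, 0]),
                  ("HA", 0): np.array([3.0, 0, 1.09])}
        k = RATE_REGISTRY["NHN_CAHA"]
        a = structural_amplitude(k, 0, 0, coords=coords)
        assert np.isclose(a, prefactor(k)[0], rtol=1e-12)

    def test_magic_angle_projection_nulls_p2(self):
        assert abs(p2(np.cos(np.radians(pm.MAGIC_ANGLE_DEG)))) < 1e-12

    def test_known_amplitude_p2_factor(self):
        # P2(cos 20 deg) enters the amide-plane amplitude
        assert np.isclose(p2(np.cos(np.radians(20.0))), 0.8245,
                          atol=5e-5)
        k = RATE_REGISTRY["N_NHN"]
        a = structural_amplitude(k, -63.0, -43.0)
        assert np.isclose(a / prefactor(k)[0], p2(np.cos(np.radians(20.0))),
                          rtol=1e-10)

    def test_known_amplitudes_independent_of_conformation(self):
        for rid in KNOWN_RATE_IDS:
            k = RATE_REGISTRY[rid]
            a1 = structural_amplitude(k, -60.0, -45.0)
            a2 = structural_amplitude(k, 120.0, 10.0)
            assert np.isclose(float(a1), float(a2), rtol=1e-9)

    def test_exchanging_interaction_vectors_is_symmetric(self):
        k = RATE_REGISTRY["NHN_NHN1"]
        swapped = pm.RateKind("swapped", k.mechanism_class,
                              (k.interactions[1], k.interactions[0]))
        a = structural_amplitude(k, -70.0, 150.0)
        b = structural_amplitude(swapped, -70.0, 150.0)
        assert np.isclose(float(a), float(b), rtol=1e-12)

    def test_dd_amplitude_bounded_by_p2_range(self, surfaces_10deg):
        for rid in ("NHN_CAHA", "CAHA_NHN1", "NHN_NHN1"):
            k = RATE_REGISTRY[rid]
            pref = prefactor(k)[0]  # signed (gamma_N < 0)
            lo, hi = sorted((pref, -0.5 * pref))
            tol = 1e-6 * abs(pref)
            v = surfaces_10deg[rid].values
            assert v.min() >= lo - tol
            assert v.max() <= hi + tol


class TestSurfaces:
    def test_surface_equals_pointwise_amplitude(self, surfaces_10deg):
        k = RATE_REGISTRY["CAHA_C"]
        s = surfaces_10deg["CAHA_C"]
        phi, psi = s.centers[3], s.centers[30]
        assert np.isclose(s.values[3, 30],
                          float(structural_amplitude(k, phi, psi)),
                          rtol=1e-12)

    def test_periodicity(self):
        k = RATE_REGISTRY["NHN_CAHA"]
        a = structural_amplitude(k, -180.0, 50.0)
        b = structural_amplitude(k, 180.0 - 1e-9, 50.0)
        assert np.isclose(float(a), float(b), rtol=1e-6)

    def test_uniform_average_matches_brute_force(self, surfaces_10deg):
        for rid in REMOTE_RATE_IDS:
            s = surfaces_10deg[rid]
            brute = 0.0
            for i in range(0, 36, 1):
                for j in range(0, 36, 1):
                    brute += s.values[i, j]
            brute /= 36 * 36
            assert np.isclose(s.values.mean(), brute, rtol=1e-12)

    def test_grid_centers_convention(self):
        c = pm.grid_centers(10.0)
        assert c[0] == -175.0 and c[-1] == 175.0 and len(c) == 36
        with pytest.raises(ValueError):
            pm.grid_centers(7.0)

    def test_save_load_round_trip(self, surfaces_10deg, tmp_path):
        path = tmp_path / "surf.h5"
        pm.save_surfaces(path, surfaces_10deg)
        back = pm.load_surfaces(path)
        assert set(back) == set(surfaces_10deg)
        for rid in back:
            assert np.array_equal(back[rid].values,
                                  surfaces_10deg[rid].values)
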