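"""Directional moduli and anisotropy maps, checked against independent
oracles: brute-force tensor rotation for E(u)/G(u,v), a dense chi grid and
the closed-form 2x2 eigenproblem for the per-direction shear extrema."""

import math

import numpy as np
import pytest

import elastimap as em
from elastimap.maps import (icosphere_directions, shear_extrema_batch,
                            shear_plane_basis, young_modulus_batch)

from conftest import random_rotation, random_unit


def rotation_taking_x_to(u: np.ndarray) -> np.ndarray:
    """A proper rotation mapping the x-axis onto u (for the rotate-and-read
    oracle)."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, u)
    s = np.linalg.norm(v)
    c = float(np.dot(x, u))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


class TestYoungModulus:
    def test_isotropic_constant_everywhere(self, iso10):
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert em.young_modulus(iso10, random_unit(rng)) == \
                pytest.approx(10.0, abs=1e-9)

    def test_cubic_closed_forms(self, cubic_example):
        assert em.young_modulus(cubic_example, [1, 0, 0]) == \
            pytest.approx(10.0, abs=1e-9)
        u111 = np.ones(3) / math.sqrt(3)
        # 1/E<111> = S11 - 2 (S11 - S12 - S44/2) / 3
        assert em.young_modulus(cubic_example, u111) == \
            pytest.approx(1.0 / (0.1 - 2 * (0.1 + 0.025 - 1 / 6) / 3), abs=1e-9)

    def test_contraction_matches_rotation_oracle(self, random_stable_set):
        # E(u) must equal 1/S'_1111 after rotating the frame so x || u
        rng = np.random.default_rng(42)
        for t in random_stable_set[:10]:
            S_full = t.compliance().full
            for _ in range(5):
                u = random_unit(rng)
                R = rotation_taking_x_to(u)
                S_rot = em.rotate_full(S_full, R.T)
                assert em.young_modulus(t, u) == \
                    pytest.approx(1.0 / S_rot[0, 0, 0, 0], abs=1e-9)

    def test_non_unit_direction_rejected(self, iso10):
        with pytest.raises(em.ElasticityError, match="unit"):
            em.young_modulus(iso10, [1.0, 1.0, 0.0])

    def test_batch_agrees_with_scalar(self, cubic_example):
        U = icosphere_directions(42)
        vals = young_modulus_batch(cubic_example, U)
        for u, v in zip(U[:10], vals[:10]):
            assert em.young_modulus(cubic_example, u) == pytest.approx(v)


class TestShearModulus:
    def test_isotropic_equals_mu_for_any_pair(self, iso10):
        rng = np.random.default_rng(1)
        for _ in range(10):
            u = random_unit(rng)
            w1, _ = shear_plane_basis(u)
            assert em.shear_modulus(iso10, u, w1) == pytest.approx(4.0, abs=1e-9)

    def test_cubic_closed_forms(self, cubic_example):
        # 1/G = S44 on (001) along <100>; 1/G = 2 (S11 - S12) along <110>
        assert em.shear_modulus(cubic_example, [0, 0, 1], [1, 0, 0]) == \
            pytest.approx(3.0, abs=1e-9)
        r2 = math.sqrt(2)
        assert em.shear_modulus(cubic_example, [1 / r2, 1 / r2, 0],
                                [-1 / r2, 1 / r2, 0]) == \
            pytest.approx(4.0, abs=1e-9)

    def test_symmetric_under_swap(self, random_stable_set):
        rng = np.random.default_rng(2)
        for t in random_stable_set[:10]:
            u = random_unit(rng)
            w1, w2 = shear_plane_basis(u)
            chi = rng.uniform(0, math.pi)
            v = math.cos(chi) * w1 + math.sin(chi) * w2
            assert em.shear_modulus(t, u, v) == \
                pytest.approx(em.shear_modulus(t, v, u), rel=1e-12)

    def test_matches_rotation_oracle(self, random_stable_set):
        # G(u, v) = 1 / (4 S'_1212) in a frame with x || u, y || v
        rng = np.random.default_rng(3)
        for t in random_stable_set[:8]:
            u = random_unit(rng)
            w1, w2 = shear_plane_basis(u)
            R = np.array([u, w1, w2])  # rows: new axes
            S_rot = em.rotate_full(t.compliance().full, R)
            assert em.shear_modulus(t, u, w1) == \
                pytest.approx(1.0 / (4.0 * S_rot[0, 1, 0, 1]), abs=1e-9)

    def test_non_orthogonal_pair_rejected(self, iso10):
        with pytest.raises(em.ElasticityError, match="orthogonal"):
            em.shear_modulus(iso10, [0, 0, 1], [0, 1 / math.sqrt(2), 1 / math.sqrt(2)])


class TestShearExtremaOverV:
    def test_isotropic_flat_in_chi(self, iso10):
        ext = em.shear_extrema_over_v(iso10, [0, 0, 1])
        assert ext.G_min == pytest.approx(4.0, abs=1e-9)
        assert ext.G_max == pytest.approx(4.0, abs=1e-9)
        assert ext.G_avg == pytest.approx(4.0, abs=1e-9)

    def test_cubic_flat_along_cube_axis(self, cubic_example):
        # for u || <100> the restricted shear form is S44 * identity
        ext = em.shear_extrema_over_v(cubic_example, [0, 0, 1])
        assert ext.G_min == pytest.approx(3.0, abs=1e-9)
        assert ext.G_max == pytest.approx(3.0, abs=1e-9)

    def test_cubic_extrema_along_face_diagonal(self, cubic_example):
        # u || <110>: G = 1/S44 = 3 for v || z, G = 1/(2(S11-S12)) = 4
        # for v || <-110>
        r2 = math.sqrt(2)
        u = np.array([1 / r2, 1 / r2, 0.0])
        ext = em.shear_extrema_over_v(cubic_example, u)
        assert ext.G_min == pytest.approx(3.0, abs=1e-9)
        assert ext.G_max == pytest.approx(4.0, abs=1e-9)
        # minimizing v lies along the crystal z axis
        w1, w2 = shear_plane_basis(u)
        v = math.cos(ext.chi_min) * w1 + math.sin(ext.chi_min) * w2
        assert abs(abs(v[2]) - 1.0) < 1e-5

    def test_ordering_min_avg_max(self, random_stable_set):
        rng = np.random.default_rng(4)
        for t in random_stable_set[:10]:
            ext = em.shear_extrema_over_v(t, random_unit(rng))
            assert ext.G_min <= ext.G_avg <= ext.G_max

    def test_refinement_matches_dense_scan_and_closed_form(self, random_stable_set):
        rng = np.random.default_rng(5)
        for t in random_stable_set[:6]:
            u = random_unit(rng)
            ext = em.shear_extrema_over_v(t, u)
            # oracle 1: dense 1e5-point chi scan
            w1, w2 = shear_plane_basis(u)
            chis = np.linspace(0, math.pi, 100000, endpoint=False)
            V = np.outer(np.cos(chis), w1) + np.outer(np.sin(chis), w2)
            inv = 4.0 * np.einsum("ijkl,ni,nj,nk,nl->n",
                                  t.compliance().full,
                                  np.broadcast_to(u, V.shape), V,
                                  np.broadcast_to(u, V.shape), V)
            assert ext.G_min == pytest.approx(1.0 / inv.max(), abs=1e-6)
            assert ext.G_max == pytest.approx(1.0 / inv.min(), abs=1e-6)
            # oracle 2: closed-form eigenvalues of the 2x2 restriction
            g_min, g_max = shear_extrema_batch(t, u[None, :])
            assert ext.G_min == pytest.approx(g_min[0], abs=1e-9)
            assert ext.G_max == pytest.approx(g_max[0], abs=1e-9)

    def test_small_n_chi_rejected(self, iso10):
        with pytest.raises(em.ElasticityError):
            em.shear_extrema_over_v(iso10, [0, 0, 1], n_chi=4)


class TestGlobalExtrema:
    def test_isotropic_young_min_equals_max(self, iso10):
        ext = em.global_extrema(iso10, "young")
        assert ext.min_value == pytest.approx(10.0, abs=1e-9)
        assert ext.max_value == pytest.approx(10.0, abs=1e-9)

    def test_cubic_young_extrema_along_100_and_111(self, cubic_example):
        ext = em.global_extrema(cubic_example, "young")
        assert ext.max_value == pytest.approx(10.0, abs=1e-8)
        assert ext.min_value == pytest.approx(7.826087, abs=1e-5)
        # max along a <100> axis, min along a <111> diagonal
        assert np.max(np.abs(ext.max_direction.vector)) > 1 - 1e-5
        assert np.allclose(np.abs(ext.min_direction.vector),
                           1 / math.sqrt(3), atol=1e-4)

    def test_reported_directions_reproduce_reported_values(self, random_stable_set):
        for t in random_stable_set[:3]:
            ext = em.global_extrema(t, "young")
            assert em.young_modulus(t, ext.min_direction.vector) == \
                pytest.approx(ext.min_value, abs=1e-6)
            assert em.young_modulus(t, ext.max_direction.vector) == \
                pytest.approx(ext.max_value, abs=1e-6)
            exs = em.global_extrema(t, "shear")
            assert em.shear_modulus(t, exs.min_direction.vector,
                                    exs.min_secondary.vector) == \
                pytest.approx(exs.min_value, abs=1e-6)

    def test_values_invariant_under_frame_rotation(self, random_stable_set):
        for seed, t in enumerate(random_stable_set[:3]):
            tr = t.rotated(random_rotation(300 + seed))
            for prop in ("young", "shear"):
                a = em.global_extrema(t, prop)
                b = em.global_extrema(tr, prop)
                assert a.min_value == pytest.approx(b.min_value, abs=1e-6)
                assert a.max_value == pytest.approx(b.max_value, abs=1e-6)

    def test_unknown_property_rejected(self, iso10):
        with pytest.raises(em.ElasticityError):
            em.global_extrema(iso10, "bulk")


class TestAnisotropyIndex:
    def test_isotropic_indices_are_one(self, iso10):
        s = em.anisotropy_summary(iso10)
        assert s.A_E == pytest.approx(1.0, abs=1e-9)
        assert s.A_G == pytest.approx(1.0, abs=1e-9)

    def test_cubic_young_index(self, cubic_example):
        ext = em.global_extrema(cubic_example, "young")
        assert em.anisotropy_index(ext) == pytest.approx(10.0 / 7.826087,
                                                         abs=1e-4)

    def test_indices_at_least_one(self, random_stable_set):
        for t in random_stable_set[:3]:
            s = em.anisotropy_summary(t)
            assert s.A_E >= 1.0 and s.A_G >= 1.0

    def test_non_positive_minimum_rejected(self):
        bad = em.ExtremumResult(
            property="young", min_value=-1.0, max_value=2.0,
            min_direction=em.Direction.from_vector([0, 0, 1.0]),
            max_direction=em.Direction.from_vector([0, 0, 1.0]))
        with pytest.raises(em.ElasticityError):
            em.anisotropy_index(bad)


class TestSymmetryOfSurfaces:
    def test_tetragonal_young_has_fourfold_azimuthal_symmetry(self):
        t = em.random_stable_stiffness("tetragonal", seed=7)
        rng = np.random.default_rng(8)
        for _ in range(20):
            theta, phi = rng.uniform(0.1, math.pi - 0.1), rng.uniform(0, 2 * math.pi)
            u1 = em.Direction.from_angles(theta, phi).vector
            u2 = em.Direction.from_angles(theta, phi + math.pi / 2).vector
            assert em.young_modulus(t, u1) == \
                pytest.approx(em.young_modulus(t, u2), abs=1e-9)

    def test_hexagonal_young_is_azimuthally_invariant(self):
        # transversely isotropic: E depends on the polar angle only
        t = em.random_stable_stiffness("hexagonal", seed=9)
        rng = np.random.default_rng(10)
        for _ in range(20):
            theta = rng.uniform(0.05, math.pi - 0.05)
            vals = [em.young_modulus(
                t, em.Direction.from_angles(theta, phi).vector)
                for phi in rng.uniform(0, 2 * math.pi, size=4)]
            assert np.ptp(vals) < 1e-9 * max(vals)

    def test_sphere_map_isotropic_constant(self, iso10):
        surf = em.sphere_map(iso10, "young", resolution=16)
        assert np.allclose(surf.values, 10.0, atol=1e-9)

    def test_sphere_map_antipodal_symmetry(self, random_stable_set):
        t = random_stable_set[0]
        surf = em.sphere_map(t, "young", resolution=32)
        # u(theta, phi) and u(pi - theta, phi + pi) are antipodes
        n_phi = len(surf.phi)
        flipped = surf.values[::-1, :]
        rolled = np.roll(flipped, n_phi // 2, axis=1)
        assert np.allclose(surf.values, rolled, atol=1e-9)

    def test_grid_maximum_bounded_by_global_and_converges(self, random_stable_set):
        t = random_stable_set[1]
        ext = em.global_extrema(t, "young")
        gaps = []
        for res in (16, 64):
            surf = em.sphere_map(t, "young", resolution=res)
            assert surf.values.max() <= ext.max_value + 1e-9
            gaps.append(ext.max_value - surf.values.max())
        assert gaps[1] <= gaps[0] + 1e-12

    def test_shear_min_surface_positive_for_stable(self, random_stable_set):
        surf = em.sphere_map(random_stable_set[2], "shear_min", resolution=16)
        assert np.all(surf.values > 0)
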