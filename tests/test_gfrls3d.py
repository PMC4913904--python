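import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from toothseg import gfrls3d
from toothseg.gfrls3d import (GFRLSParams, RegionMeans, evolve_step,
                              gaussian_regularize, grad_mag3d, has_converged,
                              heaviside, initialize_levelset, region_means,
                              segment, selective_binary, spf_field)


class TestInitializeLevelset:
    def test_box_counts(self):
        phi = initialize_levelset((4, 4, 4), ((1, 1, 1), (3, 3, 3)))
        assert (phi == 1).sum() == 8
        assert (phi == -1).sum() == 56

    def test_margin_box(self):
        phi = initialize_levelset((5, 5, 5), ((1, 1, 1), (4, 4, 4)))
        assert phi[2, 2, 2] == 1 and phi[0, 0, 0] == -1

    @pytest.mark.parametrize("box", [
        ((0, 0, 0), (0, 1, 1)),          # zero volume
        ((0, 0, 0), (5, 4, 4)),          # outside the grid
        ((2, 2, 2), (1, 3, 3)),          # inverted
    ])
    def test_degenerate_boxes_rejected(self, box):
        with pytest.raises(ValueError):
            initialize_levelset((4, 4, 4), box)


class TestHeaviside:
    def test_zero_maps_to_half(self):
        for eps in (0.1, 1.0, 10.0):
            assert heaviside(0.0, eps) == 0.5

    def test_arctan_value_at_one(self):
        assert heaviside(1.0, 1.0) == pytest.approx(0.75)

    @given(z=st.floats(-100, 100), eps=st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry(self, z, eps):
        assert heaviside(z, eps) + heaviside(-z, eps) == pytest.approx(1.0)

    def test_strictly_increasing(self):
        z = np.linspace(-5, 5, 101)
        h = heaviside(z, 1.5)
        assert np.all(np.diff(h) > 0)
        assert np.all((h > 0) & (h < 1))


class TestRegionMeans:
    def test_sharp_heaviside_limit(self):
        # balanced two-level partition; as epsilon -> 0 the weights approach
        # indicators, so the means approach the plain region averages
        I = np.zeros((4, 4, 4))
        phi = -np.ones((4, 4, 4))
        I[:2] = 1.0
        phi[:2] = 1.0
        means = region_means(I, phi, epsilon=0.01)
        assert means.c1 == pytest.approx(1.0, abs=1e-2)
        assert means.c2 == pytest.approx(0.0, abs=1e-2)

    def test_constant_image(self):
        I = np.full((3, 3, 3), 5.0)
        phi = initialize_levelset((3, 3, 3), ((1, 1, 1), (2, 2, 2)))
        means = region_means(I, phi, epsilon=1.0)
        assert means.c1 == pytest.approx(5.0)
        assert means.c2 == pytest.approx(5.0)

    def test_two_voxel_hand_evaluation(self):
        # I=(10,2), phi=(+1,-1), eps=1: H(+1)=0.75, H(-1)=0.25, so
        # c1 = (10*0.75 + 2*0.25) / (0.75+0.25) = 8
        # c2 = (10*0.25 + 2*0.75) / (0.25+0.75) = 4
        I = np.array([10.0, 2.0]).reshape(2, 1, 1)
        phi = np.array([1.0, -1.0]).reshape(2, 1, 1)
        means = region_means(I, phi, epsilon=1.0)
        assert means.c1 == pytest.approx(8.0)
        assert means.c2 == pytest.approx(4.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            region_means(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)), 1.0)


class TestSPF:
    def test_two_level_image_saturates(self):
        I = np.array([0.0, 1.0, 1.0, 0.0]).reshape(4, 1, 1)
        spf = spf_field(I, RegionMeans(c1=1.0, c2=0.0))
        np.testing.assert_allclose(spf.ravel(), [-1, 1, 1, -1])

    def test_constant_image_gives_zero(self):
        I = np.full((3, 3, 3), 0.4)
        spf = spf_field(I, RegionMeans(c1=0.4, c2=0.4))
        assert np.all(spf == 0)

    def test_three_level_arithmetic(self):
        I = np.array([0.0, 0.5, 1.0]).reshape(3, 1, 1)
        spf = spf_field(I, RegionMeans(c1=1.0, c2=0.0))
        np.testing.assert_allclose(spf.ravel(), [-1.0, 0.0, 1.0])

    @given(arrays(np.float64, (3, 3, 3), elements=st.floats(0, 1)),
           st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_range_invariant(self, I, c1, c2):
        spf = spf_field(I, RegionMeans(c1=c1, c2=c2))
        assert np.all(np.abs(spf) <= 1.0 + 1e-12)


class TestGradMag:
    def test_linear_ramp_x(self):
        zz, yy, xx = np.mgrid[:5, :5, :5]
        np.testing.assert_allclose(grad_mag3d(xx.astype(float)), 1.0)

    def test_diagonal_ramp(self):
        zz, yy, xx = np.mgrid[:5, :5, :5]
        phi = (zz + yy + xx).astype(float)
        np.testing.assert_allclose(grad_mag3d(phi), np.sqrt(3.0))

    def test_constant_field(self):
        assert np.all(grad_mag3d(np.ones((3, 3, 3))) == 0)


class TestSelectiveBinary:
    def test_tie_at_zero_counts_as_inside(self):
        phi = np.array([-0.2, 0.0, 0.7]).reshape(3, 1, 1)
        np.testing.assert_array_equal(selective_binary(phi).ravel(), [-1, 1, 1])

    def test_idempotent_on_binary(self):
        phi = np.where(np.random.default_rng(0).random((3, 3, 3)) > 0.5, 1.0, -1.0)
        np.testing.assert_array_equal(selective_binary(phi), phi)

    def test_all_negative(self):
        assert np.all(selective_binary(-np.ones((2, 2, 2))) == -1)


class TestGaussianRegularize:
    def test_constant_preserved(self):
        phi = np.full((5, 5, 5), 0.3)
        np.testing.assert_allclose(gaussian_regularize(phi, 1.0), 0.3)

    def test_step_field_pulled_inside_unit_interval(self):
        phi = selective_binary(initialize_levelset((8, 8, 8), ((2, 2, 2), (6, 6, 6))))
        out = gaussian_regularize(phi, 1.0)
        assert out.min() >= -1.0 and out.max() <= 1.0
        near = out[1:3, 4, 4]  # straddles the interface
        assert np.all((near > -1.0) & (near < 1.0))

    def test_kernel_normalized(self):
        impulse = np.zeros((9, 9, 9))
        impulse[4, 4, 4] = 1.0
        assert gaussian_regularize(impulse, 1.0).sum() == pytest.approx(1.0)


class TestEvolveStep:
    def test_constant_image_is_fixed_point(self):
        phi = initialize_levelset((4, 4, 4), ((1, 1, 1), (3, 3, 3)))
        I = np.full((4, 4, 4), 0.5)
        np.testing.assert_array_equal(evolve_step(phi, I, GFRLSParams()), phi)

    def test_constant_phi_is_fixed_point(self):
        phi = np.ones((4, 4, 4))
        I = np.random.default_rng(0).random((4, 4, 4))
        np.testing.assert_array_equal(evolve_step(phi, I, GFRLSParams()), phi)

    def test_single_euler_step_hand_computed(self):
        # phi = +1 on the x=0 plane, -1 elsewhere; one bright voxel at the
        # center, adjacent to the interface.  By hand with eps=1:
        # H(+1)=0.75, H(-1)=0.25 so c1=0.25/11.25, c2=0.75/15.75; the bright
        # voxel carries the max |I - midpoint|, so spf there is exactly +1,
        # and central differences give |grad phi| = 1 there, so
        # phi_new = -1 + dt*alpha*1*1 = -1 + 20.
        phi = -np.ones((3, 3, 3))
        phi[:, :, 0] = 1.0
        I = np.zeros((3, 3, 3))
        I[1, 1, 1] = 1.0
        params = GFRLSParams(alpha=20.0, epsilon=1.0, dt=1.0)
        out = evolve_step(phi, I, params)
        assert out[1, 1, 1] == pytest.approx(-1.0 + 20.0)
        assert out[1, 1, 1] > phi[1, 1, 1]


class TestHasConverged:
    def test_identical_fields(self):
        phi = np.ones((10, 10, 10))
        assert has_converged(phi, phi, 0.0)

    def test_all_flipped(self):
        phi = np.ones((10, 10, 10))
        assert not has_converged(phi, -phi, 0.01)

    def test_fractional_tolerance(self):
        prev = np.ones(1000).reshape(10, 10, 10)
        curr = prev.copy()
        curr[0, 0, 0] = -1
        assert has_converged(prev, curr, 0.01)  # 0.001 <= 0.01
        assert not has_converged(prev, curr, 0.0005)


class TestSegment:
    @pytest.fixture
    def bright_sphere(self):
        zz, yy, xx = np.mgrid[:48, :48, :48]
        obj = ((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2) < 16 ** 2
        I = np.where(obj, 0.9, 0.1)
        return I, obj

    @staticmethod
    def dice(a, b):
        return 2 * (a & b).sum() / (a.sum() + b.sum())

    def test_noiseless_two_level_matches_truth(self, bright_sphere):
        I, obj = bright_sphere
        res = segment(I)
        assert res.converged
        assert self.dice(res.mask.astype(bool), obj) >= 0.99

    def test_expansion_from_interior_seed_is_monotone(self, bright_sphere):
        I, obj = bright_sphere
        params = GFRLSParams()
        phi = initialize_levelset(I.shape, ((20, 20, 20), (28, 28, 28)))
        volumes = [(phi >= 0).sum()]
        for _ in range(30):
            phi = evolve_step(phi, I, params)
            phi = selective_binary(phi)
            phi = gaussian_regularize(phi, params.sigma)
            volumes.append((phi >= 0).sum())
        grew = np.diff(volumes)
        assert np.all(grew[:10] >= 0) and volumes[-1] > volumes[0]
        seed = initialize_levelset(I.shape, ((20, 20, 20), (28, 28, 28))) > 0
        assert np.all((phi >= 0)[seed])  # seed region never lost
        assert self.dice(phi >= 0, obj) >= 0.99

    def test_shrink_onto_object_from_enclosing_box(self, bright_sphere):
        I, obj = bright_sphere
        res = segment(I, init_box=((2, 2, 2), (46, 46, 46)))
        assert self.dice(res.mask.astype(bool), obj) >= 0.99

    def test_constant_image_converges_immediately_to_init_box(self):
        # spf == 0: no force drives the surface, so evolution stops at once
        # and the mask is exactly the initial cuboid
        I = np.full((16, 16, 16), 0.5)
        res = segment(I, init_box=((4, 4, 4), (12, 12, 12)))
        assert res.converged and res.iterations == 1
        expected = np.zeros((16, 16, 16), dtype=bool)
        expected[4:12, 4:12, 4:12] = True
        np.testing.assert_array_equal(res.mask.astype(bool), expected)

    def test_affine_intensity_invariance(self, bright_sphere):
        I, _ = bright_sphere
        res1 = segment(I)
        res2 = segment(I * 1000.0 - 37.0)
        np.testing.assert_array_equal(res1.mask, res2.mask)

    def test_determinism(self, bright_sphere):
        I, _ = bright_sphere
        np.testing.assert_array_equal(segment(I).mask, segment(I).mask)

    def test_non_convergence_warns_not_raises(self, bright_sphere):
        I, _ = bright_sphere
        params = GFRLSParams(max_iter=2, conv_tol=0.0)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = segment(I, params)
        assert not res.converged

    def test_phi_bounded_after_full_iteration(self, bright_sphere):
        I, _ = bright_sphere
        res = segment(I)
        assert res.phi.min() >= -1.0 and res.phi.max() <= 1.0
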