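"""Rigid/deformable registration, stack reconstruction, landmark error."""

import math

import numpy as np
import pytest
import scipy.ndimage as ndi

from msilazy import (
    LandmarkSet,
    PhantomSpec,
    RegistrationError,
    RegistrationParams,
    RigidTransform,
    TransformChain,
    apply_chain,
    landmark_error,
    make_slice_stack,
    mattes_mi,
    pre_rotate,
    reconstruct_stack,
    register_deformable,
    register_rigid,
)
from msilazy.synthetic import render_structure_image

PX = 20.0  # µm, lateral resolution of the phantoms
SPACING = (PX, PX)


@pytest.fixture(scope="module")
def base_image():
    return render_structure_image(PhantomSpec(width=96, height=96, seed=31))


@pytest.fixture(scope="module")
def center(base_image):
    h, w = base_image.shape
    return ((w - 1) * PX / 2, (h - 1) * PX / 2)


class TestPreRotate:
    def test_zero_is_identity(self, base_image):
        rotated, t = pre_rotate(base_image, 0.0, SPACING)
        np.testing.assert_allclose(rotated, base_image, atol=1e-12)
        assert t.theta == 0

    def test_ninety_degrees_is_transpose_flip(self, base_image):
        rotated, _ = pre_rotate(base_image, 90.0, SPACING)
        expected = np.flipud(base_image.T)
        interior = (slice(2, -2),) * 2
        assert np.abs(rotated[interior] - expected[interior]).max() < 0.02 * np.ptp(base_image)

    def test_round_trip(self, base_image):
        # smooth image: the double linear interpolation loss stays below 2%
        # of the dynamic range only away from step edges
        smooth = ndi.gaussian_filter(base_image, 3.0)
        once, _ = pre_rotate(smooth, 12.0, SPACING)
        back, _ = pre_rotate(once, -12.0, SPACING)
        interior = (slice(8, -8),) * 2
        err = np.abs(back[interior] - smooth[interior]).max()
        assert err < 0.02 * np.ptp(smooth)

    def test_angle_bound(self, base_image):
        with pytest.raises(ValueError):
            pre_rotate(base_image, 190.0, SPACING)


class TestRegisterRigid:
    def test_identical_images(self, base_image):
        t = register_rigid(base_image, base_image, spacing=SPACING)
        assert abs(t.theta) < math.radians(0.1)
        assert max(abs(t.tx), abs(t.ty)) < 0.25 * PX

    def test_translation_recovered(self, base_image, center):
        true = RigidTransform(0.0, 3 * PX, -2 * PX, center)
        moving = apply_chain(base_image, TransformChain([true.inverse()]), spacing=SPACING)
        est = register_rigid(base_image, moving, spacing=SPACING)
        assert abs(est.tx - true.tx) < 0.5 * PX
        assert abs(est.ty - true.ty) < 0.5 * PX

    def test_rotation_recovered(self, base_image, center):
        true = RigidTransform(math.radians(10.0), 0.0, 0.0, center)
        moving = apply_chain(base_image, TransformChain([true.inverse()]), spacing=SPACING)
        est = register_rigid(base_image, moving, spacing=SPACING)
        assert abs(math.degrees(est.theta) - 10.0) < 0.5

    def test_constant_image_rejected(self):
        with pytest.raises(RegistrationError):
            register_rigid(np.zeros((32, 32)), np.ones((32, 32)))

    def test_deterministic(self, base_image, center):
        true = RigidTransform(math.radians(5.0), PX, PX, center)
        moving = apply_chain(base_image, TransformChain([true.inverse()]), spacing=SPACING)
        a = register_rigid(base_image, moving, spacing=SPACING)
        b = register_rigid(base_image, moving, spacing=SPACING)
        assert (a.theta, a.tx, a.ty) == (b.theta, b.tx, b.ty)

    def test_mi_improves_for_accepted_registration(self, base_image, center):
        true = RigidTransform(math.radians(8.0), 4 * PX, -3 * PX, center)
        moving = apply_chain(base_image, TransformChain([true.inverse()]), spacing=SPACING)
        est = register_rigid(base_image, moving, spacing=SPACING)
        aligned = apply_chain(moving, TransformChain([est]), spacing=SPACING)
        assert mattes_mi(base_image, aligned) >= mattes_mi(base_image, moving)


class TestParameterRecoveryRate:
    def test_random_transform_recovery(self, base_image, center):
        """>= 95% of 40 random |theta|<=15 deg, |t|<=10 px trials within 0.5/0.5."""
        rng = np.random.default_rng(11)
        recovered = 0
        for _ in range(40):
            theta = math.radians(rng.uniform(-15, 15))
            tx, ty = rng.uniform(-10, 10, 2) * PX
            true = RigidTransform(theta, tx, ty, center)
            moving = apply_chain(
                base_image, TransformChain([true.inverse()]), spacing=SPACING
            )
            est = register_rigid(base_image, moving, spacing=SPACING)
            ok = (
                abs(math.degrees(est.theta - true.theta)) <= 0.5
                and abs(est.tx - true.tx) <= 0.5 * PX
                and abs(est.ty - true.ty) <= 0.5 * PX
            )
            recovered += ok
        assert recovered >= 38  # 95% of 40


class TestRegisterDeformable:
    def test_zero_deformation_pair(self, base_image, center):
        params = RegistrationParams(metric="mean_squares",
                                    deformable_iterations=100, grid_spacing_mm=0.4)
        chain = register_deformable(
            base_image, base_image, RigidTransform.identity(center), params, SPACING
        )
        displacements = np.abs(np.array(chain.steps[1].GetParameters())) / PX
        assert displacements.max() < 0.1

    def test_sinusoidal_warp_reduces_landmark_error(self, base_image, center):
        yy, xx = np.mgrid[0 : base_image.shape[0], 0 : base_image.shape[1]]
        moving = ndi.map_coordinates(
            base_image, [yy + 2.0 * np.sin(2 * np.pi * xx / 32), xx], order=1
        )
        rigid = register_rigid(base_image, moving, spacing=SPACING)
        params = RegistrationParams(metric="mean_squares",
                                    deformable_iterations=300, grid_spacing_mm=0.2)
        chain = register_deformable(base_image, moving, rigid, params, SPACING)
        # landmarks: fixed grid points; their true moving positions under the warp
        fixed_pts = np.array([(x, y) for x in (400, 900, 1400) for y in (400, 900, 1400)])
        # moving(y, x) = base(y + A sin(2 pi x / 32), x): a feature at base
        # row y therefore appears at row y - A sin in the moving image
        moving_pts = np.array(
            [(x, y - PX * 2.0 * np.sin(2 * np.pi * (x / PX) / 32)) for x, y in fixed_pts]
        )
        before, _, _ = landmark_error(
            LandmarkSet(0, fixed_pts), LandmarkSet(1, moving_pts),
            TransformChain([RigidTransform.identity(center)]),
        )
        after, _, _ = landmark_error(
            LandmarkSet(0, fixed_pts), LandmarkSet(1, moving_pts), chain
        )
        assert after <= before

    def test_warp_improves_mi_over_rigid(self, base_image):
        yy, xx = np.mgrid[0 : base_image.shape[0], 0 : base_image.shape[1]]
        moving = ndi.map_coordinates(
            base_image, [yy + 2.0 * np.sin(2 * np.pi * xx / 32), xx], order=1
        )
        rigid = register_rigid(base_image, moving, spacing=SPACING)
        params = RegistrationParams(metric="mean_squares",
                                    deformable_iterations=300, grid_spacing_mm=0.2)
        chain = register_deformable(base_image, moving, rigid, params, SPACING)
        mi_rigid = mattes_mi(
            base_image, apply_chain(moving, TransformChain([rigid]), spacing=SPACING)
        )
        mi_def = mattes_mi(base_image, apply_chain(moving, chain, spacing=SPACING))
        assert mi_def > mi_rigid

    def test_custom_backend_hook(self, base_image, center):
        sentinel = TransformChain([RigidTransform.identity(center)])
        out = register_deformable(
            base_image, base_image, RigidTransform.identity(center),
            backend=lambda f, m, i, p, s: sentinel,
        )
        assert out is sentinel


class TestReconstructStack:
    def test_identical_slices_give_identity_chains(self, base_image):
        chains = reconstruct_stack([base_image] * 3, 1, spacing=SPACING)
        for chain in chains:
            step = chain.steps[0]
            assert abs(math.degrees(step.theta)) < 0.1
            assert max(abs(step.tx), abs(step.ty)) < 0.25 * PX

    def test_cumulative_shifts_recovered(self, center):
        spec = PhantomSpec(width=96, height=96, seed=31)
        transforms = [
            RigidTransform(0.0, s * PX, s * PX, center) for s in (0, 1, 2, 3, 4)
        ]
        stack = make_slice_stack(spec, n_slices=5, transforms=transforms,
                                 morphology_drift=0.0)
        chains = reconstruct_stack(stack.slices, 0, spacing=SPACING)
        for i, chain in enumerate(chains):
            step = chain.steps[0]
            assert abs(step.tx - i * PX) <= 0.5 * PX
            assert abs(step.ty - i * PX) <= 0.5 * PX

    def test_middle_reference(self, center):
        spec = PhantomSpec(width=96, height=96, seed=31)
        transforms = [
            RigidTransform(0.0, s * PX, 0.0, center) for s in (-2, -1, 0, 1, 2)
        ]
        stack = make_slice_stack(spec, n_slices=5, transforms=transforms,
                                 morphology_drift=0.0)
        chains = reconstruct_stack(stack.slices, 2, spacing=SPACING)
        assert chains[2].is_identity() or abs(chains[2].steps[0].tx) < 1e-9
        for i, chain in enumerate(chains):
            assert abs(chain.steps[0].tx - (i - 2) * PX) <= 0.5 * PX

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_stack([], 0)


class TestApplyChain:
    def test_identity(self, base_image, center):
        out = apply_chain(
            base_image, TransformChain([RigidTransform.identity(center)]), spacing=SPACING
        )
        np.testing.assert_allclose(out, base_image, atol=1e-12)

    def test_shift_round_trip(self, base_image, center):
        fwd = TransformChain([RigidTransform(0.0, 3 * PX, 0.0, center)])
        back = TransformChain([RigidTransform(0.0, -3 * PX, 0.0, center)])
        shifted = apply_chain(base_image, fwd, spacing=SPACING)
        restored = apply_chain(shifted, back, spacing=SPACING)
        interior = (slice(5, -5),) * 2
        assert np.abs(restored[interior] - base_image[interior]).max() < 1e-6

    def test_nearest_keeps_mask_binary(self, base_image, center):
        mask = (base_image > base_image.mean()).astype(np.int16)
        chain = TransformChain([RigidTransform(math.radians(7.0), PX, -PX, center)])
        out = apply_chain(mask, chain, interpolation="nearest", spacing=SPACING)
        assert set(np.unique(out)) <= {0, 1}


class TestLandmarkError:
    def test_ground_truth_chain_zero_error(self, center):
        rng = np.random.default_rng(0)
        fixed = rng.uniform(100, 1500, (7, 2))
        true = RigidTransform(math.radians(9.0), 55.0, -20.0, center)
        moving = np.array([true.point(p) for p in fixed])
        mean, _, _ = landmark_error(
            LandmarkSet(0, fixed), LandmarkSet(1, moving), TransformChain([true])
        )
        assert mean < 1e-6

    def test_uniform_offset(self):
        fixed = np.array([[0.0, 0.0], [100.0, 0.0]])
        moving = fixed + [0.0, 10.0]
        mean, sd, _ = landmark_error(
            LandmarkSet(0, fixed), LandmarkSet(1, moving),
            TransformChain([RigidTransform.identity()]),
        )
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(0.0)

    def test_population_sd_hand_case(self):
        fixed = LandmarkSet(0, [[0.0, 0.0], [10.0, 0.0]])
        moving = LandmarkSet(1, [[0.0, 3.0], [10.0, 5.0]])
        mean, sd, per_point = landmark_error(
            fixed, moving, TransformChain([RigidTransform.identity()])
        )
        assert mean == pytest.approx(4.0)
        assert sd == pytest.approx(1.0)
        np.testing.assert_allclose(per_point, [3.0, 5.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            landmark_error(
                LandmarkSet(0, [[0, 0]]), LandmarkSet(1, [[0, 0], [1, 1]]),
                TransformChain([RigidTransform.identity()]),
            )
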