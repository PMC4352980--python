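"""Multimodal alignment, sphere landmarks, time-lapse registration,
segmentation."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, strategies as st

from spiraltomo import (
    PhantomSpec,
    Primitive,
    RigidTransform,
    Volume,
    align_spim_z,
    detect_spheres,
    eye_landmark_transform,
    fuse_multimodal,
    make_phantom,
    register_timelapse,
    segment_region,
    simulate_spim_stack,
)
from spiraltomo.register import SpimStack, _resample_rigid, intensity_dorsal_hint
from scipy.spatial.transform import Rotation

VOX = 2.0


def _rot(seed=None, angles=None):
    if angles is None:
        angles = np.random.default_rng(seed).uniform(-15, 15, 3)
    return Rotation.from_euler("xyz", angles, degrees=True).as_matrix()


@pytest.fixture(scope="module")
def fluor(two_sphere_volumes):
    return two_sphere_volumes[1]


@pytest.fixture(scope="module")
def head_volume(head_spec):
    att, _ = make_phantom(head_spec, VOX)
    return Volume(ndi.gaussian_filter(att.voxels, 1.0), VOX)


@pytest.fixture(scope="module")
def sphere_volume():
    v = np.zeros((64, 64, 64), np.float32)
    yy, xx, zz = np.mgrid[:64, :64, :64]
    v[(yy - 32) ** 2 + (xx - 32) ** 2 + (zz - 32) ** 2 <= 16**2] = 10.0
    return Volume(v, 1.0)


class TestAlignSpimZ:
    def test_centered_stack_has_near_zero_offset(self, fluor):
        s0 = simulate_spim_stack(fluor, 0.0, 2.0, 0.0)
        s90 = simulate_spim_stack(fluor, 90.0, 2.0, 0.0)
        assert abs(align_spim_z(s0, s90)) < VOX

    def test_thirty_micron_offset_recovered(self, fluor):
        s0 = simulate_spim_stack(fluor, 0.0, 2.0, 30.0)
        s90 = simulate_spim_stack(fluor, 90.0, 2.0, 30.0)
        assert abs(align_spim_z(s0, s90) - 30.0) <= 2.0

    def test_swapping_views_negates_the_offset(self, fluor):
        s0 = simulate_spim_stack(fluor, 0.0, 2.0, -18.0)
        s90 = simulate_spim_stack(fluor, 90.0, 2.0, -18.0)
        fwd = align_spim_z(s0, s90)
        rev = align_spim_z(s90, s0)
        assert abs(fwd + rev) <= 2.0

    def test_structureless_stacks_rejected(self):
        empty = SpimStack(np.zeros((16, 16, 16), np.float32), 2.0, 0.0, 2.0)
        empty90 = SpimStack(np.zeros((16, 16, 16), np.float32), 2.0, 90.0, 2.0)
        with pytest.raises(ValueError, match="insufficient mutual structure"):
            align_spim_z(empty, empty90)


class TestFuseMultimodal:
    def test_cocentered_sphere_channels_coincide(self):
        spec = PhantomSpec(
            [Primitive.sphere((70, 80, 96), 20, attenuation=0.01, fluorescence=1.0)],
            (192, 192, 192),
        )
        att, flu = make_phantom(spec, VOX)
        offset = 24.0
        stack = simulate_spim_stack(flu, 0.0, 2.0, offset)
        fused = fuse_multimodal(att, stack, offset)
        c_t = np.array(ndi.center_of_mass(fused.channels["tomography"]))
        c_f = np.array(ndi.center_of_mass(fused.channels["fluorescence"]))
        assert np.linalg.norm(c_t - c_f) < 1.0

    def test_zero_fluorescence_leaves_tomography_untouched(self, two_sphere_volumes):
        att, _ = two_sphere_volumes
        stack = SpimStack(np.zeros((96, 96, 60), np.float32), 2.0, 0.0, VOX)
        fused = fuse_multimodal(att, stack, 0.0)
        np.testing.assert_array_equal(fused.channels["tomography"], att.voxels)
        assert not fused.channels["fluorescence"].any()

    def test_fusing_twice_composes_offsets(self, two_sphere_volumes):
        att, flu = two_sphere_volumes
        stack = simulate_spim_stack(flu, 0.0, VOX, 0.0)
        a, b = 8.0, -6.0
        once = fuse_multimodal(att, stack, a + b).channels["fluorescence"]
        mid = fuse_multimodal(att, stack, a).channels["fluorescence"]
        mid_stack = SpimStack(mid, VOX, 0.0, VOX)
        twice = fuse_multimodal(att, mid_stack, b).channels["fluorescence"]
        inner = np.s_[8:-8, 8:-8, 8:-8]
        assert np.corrcoef(once[inner].ravel(), twice[inner].ravel())[0, 1] > 0.99

    def test_disjoint_stack_rejected(self, two_sphere_volumes):
        att, _ = two_sphere_volumes
        stack = SpimStack(np.ones((96, 96, 10), np.float32), 2.0, 0.0, VOX)
        with pytest.raises(ValueError, match="overlap"):
            fuse_multimodal(att, stack, 10_000.0)


class TestDetectSpheres:
    def test_single_sphere_center_and_radius_within_one_voxel(self):
        spec = PhantomSpec(
            [Primitive.sphere((64, 64, 64), 20, attenuation=1.0)], (128, 128, 128)
        )
        att, _ = make_phantom(spec, VOX)
        vol = Volume(ndi.gaussian_filter(att.voxels, 1.0), VOX)
        dets = detect_spheres(vol, r_min=6, r_max=14, n_best=1)
        assert len(dets) == 1
        assert np.linalg.norm(dets[0].center - np.array([32, 32, 32])) <= 1.0
        assert abs(dets[0].radius - 10.0) <= 1.0

    def test_two_lenses_are_the_top_two_detections(self, head_spec):
        att, _ = make_phantom(head_spec, VOX)
        vol = Volume(ndi.gaussian_filter(att.voxels, 1.0), VOX)
        dets = detect_spheres(vol, r_min=5, r_max=10, n_best=2)
        got = sorted([d.center for d in dets], key=lambda c: c[0])
        assert np.linalg.norm(got[0] - np.array([33, 48, 48])) <= 1.0
        assert np.linalg.norm(got[1] - np.array([63, 48, 48])) <= 1.0

    def test_featureless_volume_yields_nothing(self):
        assert detect_spheres(np.full((24, 24, 24), 5.0), 3, 8) == []


class TestEyeLandmarkTransform:
    EYES = np.array([[10.0, 20.0, 30.0], [40.0, 25.0, 28.0]])
    DORSAL = np.array([0.0, 0.0, 1.0])

    def test_identical_landmarks_give_identity(self):
        t = eye_landmark_transform(self.EYES, self.EYES, self.DORSAL, self.DORSAL)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_known_rigid_motion_recovered_exactly(self):
        R = _rot(angles=(20.0, 5.0, -10.0))
        tr = np.array([3.0, -2.0, 5.0])
        moved = self.EYES @ R.T + tr
        t = eye_landmark_transform(self.EYES, moved, self.DORSAL, R @ self.DORSAL)
        np.testing.assert_allclose(t.rotation, R, atol=1e-9)
        np.testing.assert_allclose(t.translation, tr, atol=1e-9)
        assert t.residual < 1e-9

    def test_growth_keeps_transform_rigid_with_half_mismatch_residual(self):
        d = self.EYES[1] - self.EYES[0]
        grown = np.array([self.EYES[0] - 0.05 * d, self.EYES[1] + 0.05 * d])
        t = eye_landmark_transform(self.EYES, grown, self.DORSAL, self.DORSAL)
        np.testing.assert_allclose(t.rotation @ t.rotation.T, np.eye(3), atol=1e-12)
        mismatch = np.linalg.norm(grown[1] - grown[0]) - np.linalg.norm(d)
        assert t.residual == pytest.approx(mismatch / 2.0, rel=1e-9)

    def test_degenerate_landmarks_rejected(self):
        same = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="eye axis"):
            eye_landmark_transform(same, self.EYES, self.DORSAL, self.DORSAL)
        along = self.EYES[1] - self.EYES[0]
        with pytest.raises(ValueError, match="dorsal"):
            eye_landmark_transform(self.EYES, self.EYES, along, self.DORSAL)

    @given(st.integers(0, 2**31 - 1))
    def test_rigid_transforms_stay_orthonormal_under_compose_and_invert(self, seed):
        rng = np.random.default_rng(seed)
        a = RigidTransform(_rot(seed), rng.uniform(-10, 10, 3))
        b = RigidTransform(_rot(seed + 1), rng.uniform(-10, 10, 3))
        c = a.compose(b).compose(a.inverse())
        np.testing.assert_allclose(c.rotation @ c.rotation.T, np.eye(3), atol=1e-9)
        roundtrip = c.compose(c.inverse())
        np.testing.assert_allclose(roundtrip.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(roundtrip.translation, 0.0, atol=1e-9)


class TestRegisterTimelapse:
    def test_static_phantom_with_rigid_jitter_realigns(self, head_volume):
        rng = np.random.default_rng(11)
        vols = [head_volume]
        for _ in range(2):
            t = RigidTransform(
                _rot(angles=rng.uniform(-12, 12, 3)), rng.uniform(-5, 5, 3)
            )
            vols.append(_resample_rigid(head_volume, t.inverse()))
        reg = register_timelapse(vols, r_min=5, r_max=10)
        assert not any(reg.failed)
        for t in (1, 2):
            r = np.corrcoef(
                reg.volumes[0].voxels.ravel(), reg.volumes[t].voxels.ravel()
            )[0, 1]
            assert r > 0.95

    def test_single_time_point_is_identity(self, head_volume):
        reg = register_timelapse([head_volume], r_min=5, r_max=10)
        np.testing.assert_allclose(reg.transforms[0].rotation, np.eye(3))
        assert reg.volumes[0] is head_volume

    def test_growth_preserves_eye_midpoint(self, head_volume):
        grown_spec = PhantomSpec(
            [
                Primitive.sphere((63, 96, 96), 14, attenuation=0.02),
                Primitive.sphere((129, 96, 96), 14, attenuation=0.02),
                Primitive("ellipsoid", (96, 120, 120), (40, 30, 24), attenuation=0.006),
            ],
            (192, 192, 192),
        )
        att, _ = make_phantom(grown_spec, VOX)
        grown = Volume(ndi.gaussian_filter(att.voxels, 1.0), VOX)
        reg = register_timelapse([head_volume, grown], r_min=5, r_max=10)
        t = reg.transforms[1]
        mid = np.array([48.0, 48.0, 48.0])  # eye midpoint, (x, y, z) voxels
        assert np.linalg.norm(t.apply(mid) - mid) < 1.0

    def test_detection_failure_flags_and_passes_through(self, head_volume):
        flat = Volume(np.zeros_like(head_volume.voxels), VOX)
        reg = register_timelapse([head_volume, flat], r_min=5, r_max=10)
        assert reg.failed == [False, True]
        assert reg.transforms[1] is None
        assert reg.volumes[1] is flat


class TestSegmentRegion:
    def test_uniform_sphere_volume_within_ten_percent(self, sphere_volume):
        res = segment_region(sphere_volume, (32, 32, 32), 0.5)
        analytic = 4.0 / 3.0 * np.pi * 16**3
        assert abs(res.volume_um3 - analytic) / analytic < 0.10

    def test_zero_threshold_returns_seed_voxel_only(self, sphere_volume):
        res = segment_region(sphere_volume, (32, 32, 32), 0.0)
        assert res.n_voxels == 1
        assert res.mask[32, 32, 32]

    def test_mask_independent_of_interior_seed_choice(self, sphere_volume):
        a = segment_region(sphere_volume, (32, 32, 32), 0.5)
        b = segment_region(sphere_volume, (36, 29, 34), 0.5)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_seed_on_edge_suggests_reseeding(self, sphere_volume):
        with pytest.raises(ValueError, match="high-gradient"):
            segment_region(sphere_volume, (32 + 16, 32, 32), 0.5)


class TestDorsalHint:
    def test_hint_points_from_eye_midpoint_to_body(self, head_spec):
        att, _ = make_phantom(head_spec, VOX)
        eyes = np.array([[33.0, 48, 48], [63.0, 48, 48]])
        hint = intensity_dorsal_hint(att, eyes)
        # the body ellipsoid sits at larger y and z than the eye midpoint
        assert hint[1] > 0 and hint[2] > 0
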