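"""Flat-field correction, sinograms, filtered back-projection, axis finding."""

import numpy as np
import pytest

from spiraltomo import (
    CorrectionFrames,
    OpticsParams,
    PhantomSpec,
    Primitive,
    Sinogram,
    Volume,
    build_sinograms,
    correct_projection,
    estimate_axis,
    fbp_slice,
    make_phantom,
    project_attenuation,
    reconstruct_volume,
    simulate_spiral,
    to_optical_depth,
)
from spiraltomo.edof import ProjectionSet
from spiraltomo.simulate import SpiralParams, correction_frames, rotate_volume

VOX = 2.0


def _disk_sinogram(width=128, radius=40.0, mu=0.01, n_angles=360, offset=0.0,
                   pixel_size=1.0):
    """Closed-form chord-length sinogram of a centred uniform disk."""
    angles = np.arange(n_angles) * (360.0 / n_angles)
    s = np.arange(width) - (width - 1) / 2.0 - offset
    chord = np.where(
        np.abs(s) * pixel_size < radius,
        2 * mu * np.sqrt(np.clip(radius**2 - (s * pixel_size) ** 2, 0, None)),
        0.0,
    )
    return Sinogram(np.tile(chord, (n_angles, 1)), angles, 0, pixel_size_um=pixel_size)


class TestCorrection:
    def test_raw_equal_to_background_gives_unit_transmittance(self):
        corr = CorrectionFrames(np.full((4, 4), 900.0), np.full((4, 4), 100.0))
        np.testing.assert_allclose(correct_projection(corr.background, corr), 1.0)

    def test_raw_equal_to_dark_clips_to_tiny_positive(self):
        corr = CorrectionFrames(np.full((4, 4), 900.0), np.full((4, 4), 100.0))
        t = correct_projection(corr.dark, corr)
        assert np.all(t > 0) and np.all(t <= 1e-6)

    def test_vignetted_simulation_corrects_to_flat_field(self):
        optics = OpticsParams(
            depth_of_field_um=np.inf, pixel_size_um=VOX, noise_sd=0.0,
            vignetting_strength=0.3,
        )
        vol = Volume(np.zeros((24, 24, 24), np.float32), VOX)
        spiral = SpiralParams(1, 90.0, 4, z_start_um=0.0, z_end_um=48.0)
        frame = next(iter(simulate_spiral(vol, optics, spiral, seed=0,
                                          quantize=False)))
        assert frame.pixels.std() > 1.0  # vignetting is visible in the raw frame
        corr = correction_frames(optics, frame.pixels.shape)
        t = correct_projection(frame.pixels, corr)
        np.testing.assert_allclose(t, 1.0, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        corr = CorrectionFrames(np.full((4, 4), 900.0), np.full((4, 4), 100.0))
        with pytest.raises(ValueError, match="shape"):
            correct_projection(np.zeros((5, 5)), corr)


class TestOpticalDepth:
    def test_known_values_and_positivity_guard(self):
        assert to_optical_depth(np.array([1.0])) == pytest.approx(0.0)
        assert to_optical_depth(np.array([np.exp(-1.0)])) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError, match="positive"):
            to_optical_depth(np.array([0.0, 0.5]))

    def test_pipeline_reproduces_line_integrals_all_in_focus(
        self, two_sphere_volumes, ideal_optics, small_spiral
    ):
        att, _ = two_sphere_volumes
        frame = next(iter(simulate_spiral(att, ideal_optics, small_spiral, seed=0,
                                          quantize=False)))
        corr = correction_frames(ideal_optics, frame.pixels.shape)
        od = to_optical_depth(correct_projection(frame.pixels, corr))
        assert np.abs(od - project_attenuation(att, frame.angle_deg)).max() < 1e-6


class TestSinograms:
    def test_row_reshaping_contract(self):
        rng = np.random.default_rng(0)
        data = rng.random((12, 7, 9)).astype(np.float32)
        pset = ProjectionSet(data, np.arange(12) * 30.0, 30.0)
        sinos = build_sinograms(pset)
        assert len(sinos) == 7
        assert sinos[3].values.shape == (12, 9)
        np.testing.assert_array_equal(sinos[3].values, data[:, 3, :])

    def test_centered_point_gives_constant_column(self):
        v = np.zeros((3, 33, 33), np.float32)
        v[1, 16, 16] = 1.0
        vol = Volume(v, 1.0)
        angles = np.arange(0, 360, 30.0)
        data = np.stack([project_attenuation(vol, a) for a in angles])
        cols = np.argmax(data[:, 1, :], axis=1)
        assert np.all(cols == 16)

    def test_off_axis_point_traces_sinusoid_of_its_radius(self):
        v = np.zeros((3, 65, 65), np.float32)
        v[1, 32 + 10, 32] = 1.0  # radius 10 px, phase 0
        vol = Volume(v, 1.0)
        angles = np.arange(0, 360, 15.0)
        data = np.stack([project_attenuation(vol, a) for a in angles])
        peaks = np.argmax(data[:, 1, :], axis=1).astype(float)
        expected = 32 + 10 * np.cos(np.radians(angles))
        assert np.abs(peaks - expected).max() <= 1.0


class TestFBP:
    def test_zero_sinogram_reconstructs_to_zero(self):
        sino = Sinogram(np.zeros((360, 32)), np.arange(360.0), 0)
        assert not fbp_slice(sino).any()

    def test_uniform_disk_recovers_attenuation_coefficient(self):
        sino = _disk_sinogram()
        rec = fbp_slice(sino)
        s = np.arange(128) - 63.5
        R = np.hypot(s[:, None], s[None, :])
        interior = R < 0.9 * 40
        assert abs(rec[interior].mean() - 0.01) / 0.01 < 0.03
        assert np.sqrt(np.mean((rec[interior] - 0.01) ** 2)) / 0.01 < 0.05

    def test_full_turn_equals_average_of_half_turn_subsets(self):
        sino = _disk_sinogram(n_angles=360)
        full = fbp_slice(sino)
        h1 = fbp_slice(Sinogram(sino.values[:180], sino.angles_deg[:180], 0))
        h2 = fbp_slice(Sinogram(sino.values[180:], sino.angles_deg[180:], 0))
        assert np.abs(full - (h1 + h2) / 2.0).max() < 1e-6

    def test_linearity(self):
        rng = np.random.default_rng(1)
        angles = np.arange(0, 360, 3.0)
        s1 = rng.random((120, 48)).astype(np.float32)
        s2 = rng.random((120, 48)).astype(np.float32)
        a, b = 0.7, -1.3
        combo = fbp_slice(Sinogram(a * s1 + b * s2, angles, 0))
        parts = a * fbp_slice(Sinogram(s1, angles, 0)) + b * fbp_slice(
            Sinogram(s2, angles, 0)
        )
        assert np.abs(combo - parts).max() < 1e-5

    def test_agrees_with_independent_iradon_implementation(self):
        from skimage.transform import iradon

        sino = _disk_sinogram(width=96, radius=30.0, n_angles=180)
        mine = fbp_slice(sino)
        other = iradon(
            sino.values.T, theta=sino.angles_deg, filter_name="ramp", circle=False,
            output_size=96,
        ).T
        s = np.arange(96) - 47.5
        interior = np.hypot(s[:, None], s[None, :]) < 27
        np.testing.assert_allclose(mine[interior], other[interior], atol=5e-4)

    def test_non_uniform_angles_rejected(self):
        angles = np.concatenate([np.arange(0, 90, 1.0), np.arange(90, 360, 2.0)])
        sino = Sinogram(np.zeros((len(angles), 16)), angles, 0)
        with pytest.raises(ValueError, match="uniform"):
            fbp_slice(sino)


class TestAxisEstimate:
    def test_centered_acquisition_estimates_zero(self, two_sphere_volumes):
        att, _ = two_sphere_volumes
        angles = np.arange(0, 360, 3.0)
        data = np.stack([project_attenuation(att, a) for a in angles])
        pset = ProjectionSet(data, angles, 3.0, pixel_size_um=VOX)
        est = estimate_axis(build_sinograms(pset, [35, 48, 60]), search_range=5)
        assert abs(est.offset_x) < 0.25

    def test_five_pixel_offset_recovered(self, two_sphere_volumes):
        att, _ = two_sphere_volumes
        angles = np.arange(0, 360, 3.0)
        data = np.stack(
            [project_attenuation(att, a, axis_offset_x_px=5.0) for a in angles]
        )
        pset = ProjectionSet(data, angles, 3.0, pixel_size_um=VOX)
        est = estimate_axis(build_sinograms(pset, [35, 48, 60]), search_range=9)
        assert abs(est.offset_x - 5.0) < 0.5
        # the variance curve has a single interior peak and falls off
        # monotonically in its neighbourhood
        m = est.metric
        peak = int(np.argmax(m))
        assert 0 < peak < len(m) - 1
        lo, hi = max(0, peak - 3), min(len(m), peak + 4)
        assert np.all(np.diff(m[lo : peak + 1]) > 0)
        assert np.all(np.diff(m[peak:hi]) < 0)

    def test_boundary_maximum_advises_wider_range(self, two_sphere_volumes):
        att, _ = two_sphere_volumes
        angles = np.arange(0, 360, 6.0)
        data = np.stack(
            [project_attenuation(att, a, axis_offset_x_px=6.0) for a in angles]
        )
        pset = ProjectionSet(data, angles, 6.0, pixel_size_um=VOX)
        with pytest.raises(ValueError, match="search_range"):
            estimate_axis(build_sinograms(pset, [48]), search_range=3)


class TestReconstructVolume:
    def _ideal_pset(self, att, step=3.0):
        angles = np.arange(0, 360, step)
        data = np.stack([project_attenuation(att, a) for a in angles])
        return ProjectionSet(data, angles, step, pixel_size_um=att.voxel_size_um)

    def test_recovers_sphere_geometry_and_correlates_with_truth(
        self, two_sphere_volumes
    ):
        from spiraltomo import detect_spheres

        att, _ = two_sphere_volumes
        pset = self._ideal_pset(att)
        vol = reconstruct_volume(pset, corr=None, axis="auto", log=False,
                                 search_range=5)
        assert vol.voxel_size_um == VOX
        assert np.corrcoef(vol.voxels.ravel(), att.voxels.ravel())[0, 1] > 0.9
        dets = detect_spheres(vol, r_min=5, r_max=14, n_best=2)
        got = sorted([d.center for d in dets], key=lambda c: c[0])
        # ground truth in (x, y, z) voxels
        gt = [np.array([35, 40, 48]), np.array([60, 55, 48])]
        radii = sorted([d.radius for d in dets], reverse=True)
        assert np.linalg.norm(got[0] - gt[0]) < 2.0
        assert np.linalg.norm(got[1] - gt[1]) < 2.0
        assert abs(radii[0] - 10.0) <= 1.0 and abs(radii[1] - 7.0) <= 1.0

    def test_rotating_the_phantom_rotates_the_reconstruction(self):
        ext, c = 128.0, 64.0
        p1, p2 = (40.0, 64.0, 64.0), (64.0, 64.0, 90.0)

        def quarter_turn(p):  # +90 deg about the axis, counter-clockwise
            x, y, z = p
            return (c + (z - c), y, c - (x - c))

        spec1 = PhantomSpec(
            [Primitive.sphere(p1, 12, attenuation=0.01),
             Primitive.sphere(p2, 8, attenuation=0.02)],
            (ext,) * 3,
        )
        spec2 = PhantomSpec(
            [Primitive.sphere(quarter_turn(p1), 12, attenuation=0.01),
             Primitive.sphere(quarter_turn(p2), 8, attenuation=0.02)],
            (ext,) * 3,
        )
        att1, _ = make_phantom(spec1, VOX)
        att2, _ = make_phantom(spec2, VOX)
        r1 = reconstruct_volume(self._ideal_pset(att1), corr=None, axis=0.0, log=False)
        r2 = reconstruct_volume(self._ideal_pset(att2), corr=None, axis=0.0, log=False)
        rotated = rotate_volume(r1.voxels, 90.0)
        assert np.corrcoef(r2.voxels.ravel(), rotated.ravel())[0, 1] > 0.9

    def test_mass_conservation_of_noiseless_sinograms(self, two_sphere_volumes):
        att, _ = two_sphere_volumes
        pset = self._ideal_pset(att, step=15.0)
        sums = pset.data.sum(axis=(1, 2))
        assert (sums.max() - sums.min()) / sums.mean() < 0.01
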