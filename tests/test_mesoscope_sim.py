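"""Phantom generation, excitation/shadows, rendering and the time model."""

import numpy as np
import pytest
from scipy import stats

from mesosheet.beam_models import GaussianSheetSpec
from mesosheet.mesoscope_sim import (
    AcquisitionSpec,
    CameraModel,
    acquisition_time,
    excitation_map,
    expected_signal,
    generate_phantom,
    nyquist_pixel_budget,
    render_plane,
    simulate_stack,
)


class TestPhantom:
    def test_deterministic_for_seed(self):
        p1 = generate_phantom(11, 50, (100, 100, 50), n_occluders=3)
        p2 = generate_phantom(11, 50, (100, 100, 50), n_occluders=3)
        assert np.array_equal(p1.nuclei_centers, p2.nuclei_centers)
        assert np.array_equal(p1.occluder_centers, p2.occluder_centers)

    def test_empty_phantom(self):
        p = generate_phantom(0, 0, (10, 10, 10))
        assert p.n_nuclei == 0

    def test_nearest_neighbour_distances_match_uniform_null(self):
        """Toroidal nearest-neighbour distances follow the Poisson CDF
        1 - exp(-rho 4/3 pi r^3) (KS test, alpha = 0.01)."""
        extent = np.array([400.0, 400.0, 100.0])
        p = generate_phantom(5, 1000, extent)
        pts = p.nuclei_centers
        # periodic wrap removes edge effects, making the null exact
        diff = np.abs(pts[:, None, :] - pts[None, :, :])
        diff = np.minimum(diff, extent - diff)
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        rho = 1000 / np.prod(extent)
        cdf = lambda r: 1.0 - np.exp(-rho * 4.0 / 3.0 * np.pi * r**3)
        assert stats.kstest(nn, cdf).pvalue > 0.01

    def test_objects_outside_extent_rejected(self):
        with pytest.raises(ValueError):
            p = generate_phantom(0, 1, (10, 10, 10))
            p.nuclei_centers[0] = [20, 5, 5]
            p.__post_init__()


class TestExcitation:
    def test_no_occluders_uniform_along_propagation(self, gaussian_sheet_3mm):
        sheet = GaussianSheetSpec(gaussian_sheet_3mm.waist_radius,
                                  gaussian_sheet_3mm.medium,
                                  focus_position=50.0)
        p = generate_phantom(0, 0, (100, 100, 60))
        exc = excitation_map(p, sheet, 30.0, "+y", pitch=1.0)
        # focused at mid-volume: divergence over +-50 um of a 1.5 mm zR
        # sheet is negligible, so the map is uniform
        assert exc.max() == pytest.approx(1.0, abs=1e-3)
        assert exc.min() == pytest.approx(1.0, abs=1e-3)

    def test_opaque_occluder_zeroes_geometric_shadow(self, airy_sheet):
        p = generate_phantom(0, 0, (100, 100, 60))
        p.occluder_centers = np.array([[50.0, 30.0, 30.0]])
        p.occluder_radii = np.array([10.0])
        p.occluder_density = np.array([1e6])
        exc = excitation_map(p, airy_sheet, 30.0, "+y", pitch=1.0,
                             shadow_model="ray")
        clear = excitation_map(generate_phantom(0, 0, (100, 100, 60)),
                               airy_sheet, 30.0, "+y", pitch=1.0,
                               shadow_model="ray")
        assert exc[60:, 50].max() == 0.0             # downstream, shadowed
        assert np.allclose(exc[:, :40], clear[:, :40])  # off-shadow columns

    def test_stripes_run_along_illumination_direction(self, airy_sheet):
        p = generate_phantom(0, 0, (100, 100, 60))
        p.occluder_centers = np.array([[50.0, 50.0, 30.0]])
        p.occluder_radii = np.array([8.0])
        p.occluder_density = np.array([10.0])
        for direction, axis_shadow in [("+y", 0), ("-y", 0),
                                       ("+x", 1), ("-x", 1)]:
            exc = excitation_map(p, airy_sheet, 30.0, direction, pitch=1.0,
                                 shadow_model="ray")
            mask = exc < 0.5
            ys, xs = np.nonzero(mask)
            span_y = np.ptp(ys) if ys.size else 0
            span_x = np.ptp(xs) if xs.size else 0
            if axis_shadow == 0:   # stripe along y: tall, narrow
                assert span_y > 3 * span_x
            else:
                assert span_x > 3 * span_y
            # shadow on the correct side of the occluder
            if direction == "+y":
                assert ys.min() >= 42
            elif direction == "-y":
                assert ys.max() <= 58
        with pytest.raises(ValueError):
            excitation_map(p, airy_sheet, 30.0, "up", pitch=1.0)

    def test_airy_stripes_weaker_than_gaussian(self, airy_sheet,
                                               gaussian_sheet_3mm):
        """Self-healing: an occluder thin relative to the Gaussian sheet
        casts a weaker stripe through the Airy sheet (side-lobe energy
        bypasses it)."""
        extent = (100.0, 100.0, 60.0)
        clear = generate_phantom(0, 0, extent)
        shadowed = generate_phantom(0, 0, extent)
        shadowed.occluder_centers = np.array([[50.0, 30.0, 30.0]])
        shadowed.occluder_radii = np.array([8.0])  # thin vs the 30 um sheet
        shadowed.occluder_density = np.array([2.0])
        contrasts = {}
        for name, sheet in [("airy", airy_sheet), ("gauss", gaussian_sheet_3mm)]:
            exc = excitation_map(shadowed, sheet, 30.0, "+y", pitch=1.0)
            ref = excitation_map(clear, sheet, 30.0, "+y", pitch=1.0)
            contrasts[name] = 1.0 - (exc[:, 50] / ref[:, 50]).min()
        assert contrasts["airy"] < contrasts["gauss"]


class TestRenderPlane:
    def test_zero_brightness_gives_offset_background(self, airy_sheet):
        p = generate_phantom(3, 10, (40, 40, 40))
        p.nuclei_brightness[:] = 0.0
        camera = CameraModel(pixel_pitch=0.672, sensor_positions=1)
        plane, info = render_plane(p, airy_sheet, camera, 20.0,
                                   rng=np.random.default_rng(0))
        assert plane.mean() == pytest.approx(camera.offset, abs=1.0)
        assert info["clipped_pixels"] == 0

    def test_single_in_focus_nucleus_peaks_at_center(self, airy_sheet):
        p = generate_phantom(0, 0, (40, 40, 40))
        p.nuclei_centers = np.array([[20.0, 20.0, 20.0]])
        p.nuclei_radii = np.array([2.0])
        p.nuclei_brightness = np.array([5000.0])
        camera = CameraModel(pixel_pitch=0.672, sensor_positions=1, offset=0.0)
        plane, _ = render_plane(p, airy_sheet, camera, 20.0, add_noise=False)
        iy, ix = np.unravel_index(np.argmax(plane), plane.shape)
        pitch = camera.effective_pitch
        assert abs((ix + 0.5) * pitch - 20.0) < 2 * pitch
        assert abs((iy + 0.5) * pitch - 20.0) < 2 * pitch

    def test_sidelobe_contribution_suppressed_by_detection_gate(self, airy_sheet):
        """A nucleus sitting on the first side lobe (~11 um off-plane)
        contributes < 5% of an in-focus nucleus once the detection
        response (sigma_z = 3 um) gates the signal."""
        extent = (40.0, 40.0, 80.0)
        in_focus = generate_phantom(0, 0, extent)
        in_focus.nuclei_centers = np.array([[20.0, 20.0, 40.0]])
        in_focus.nuclei_radii = np.array([2.0])
        in_focus.nuclei_brightness = np.array([1000.0])
        off = generate_phantom(0, 0, extent)
        off.nuclei_centers = np.array([[20.0, 20.0, 51.0]])  # first side lobe
        off.nuclei_radii = np.array([2.0])
        off.nuclei_brightness = np.array([1000.0])
        sig_main = expected_signal(in_focus, airy_sheet, 40.0, 3.0, pitch=0.672)
        sig_side = expected_signal(off, airy_sheet, 40.0, 3.0, pitch=0.672)
        assert sig_side.sum() < 0.05 * sig_main.sum()

    def test_photon_conservation_before_noise(self, airy_sheet):
        p = generate_phantom(9, 25, (60, 60, 60))
        sig = expected_signal(p, airy_sheet, 30.0, 3.0, pitch=0.672)
        dz = p.nuclei_centers[:, 2] - 30.0
        exc = np.array([float(airy_sheet.intensity(d, y))
                        for d, y in zip(dz, p.nuclei_centers[:, 1])])
        expected = (p.nuclei_brightness * exc
                    * np.exp(-dz**2 / (2 * 3.0**2))).sum()
        assert sig.sum() == pytest.approx(expected, rel=1e-3)

    def test_hot_pixels_and_clipping_flagged(self, airy_sheet):
        p = generate_phantom(0, 0, (30, 30, 30))
        camera = CameraModel(pixel_pitch=0.672, sensor_positions=1,
                             hot_pixel_rate=0.01)
        plane, info = render_plane(p, airy_sheet, camera, 15.0,
                                   rng=np.random.default_rng(5))
        assert (plane == camera.full_scale).sum() > 0


class TestAcquisitionTime:
    def test_confocal_mesoscale_worked_example(self):
        # 4.4 x 3 mm at 4 px/um, 1 us dwell, average 2, 1000 planes
        spec = AcquisitionSpec("confocal", 4400.0, 3000.0, 1000,
                               pixels_per_um=4.0, dwell_time=1e-6,
                               frame_average=2)
        est = acquisition_time(spec, CameraModel())
        assert est.total_seconds == pytest.approx(422400.0, rel=1e-12)
        assert est.hours == pytest.approx(117.33, abs=0.01)

    def test_lightsheet_mesoscale_worked_example(self):
        spec = AcquisitionSpec("lightsheet", 4400.0, 3000.0, 1000)
        camera = CameraModel(sensor_positions=9, exposure_per_position=0.1,
                             transfer_time=25.0)
        est = acquisition_time(spec, camera)
        assert est.total_seconds == pytest.approx(25900.0, rel=1e-12)
        assert est.hours < 8.5

    def test_lightsheet_615_planes(self):
        spec = AcquisitionSpec("lightsheet", 4400.0, 3000.0, 615)
        est = acquisition_time(spec, CameraModel())
        assert est.total_seconds == pytest.approx(15928.5, rel=1e-12)

    def test_linearity_in_planes_dwell_average(self):
        base = AcquisitionSpec("confocal", 1000.0, 1000.0, 100,
                               pixels_per_um=2.0, dwell_time=2e-6,
                               frame_average=2)
        t0 = acquisition_time(base, CameraModel()).total_seconds
        for field, factor in [("n_planes", 3), ("dwell_time", 5),
                              ("frame_average", 4)]:
            kwargs = dict(mode="confocal", fov_x=1000.0, fov_y=1000.0,
                          n_planes=100, pixels_per_um=2.0, dwell_time=2e-6,
                          frame_average=2)
            kwargs[field] = kwargs[field] * factor
            t = acquisition_time(AcquisitionSpec(**kwargs),
                                 CameraModel()).total_seconds
            assert t == pytest.approx(factor * t0, rel=1e-12)

    def test_missing_confocal_fields_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec("confocal", 100.0, 100.0, 10)


class TestNyquistBudget:
    def test_mesoscale_field_megapixels(self):
        # ceil(4400/0.224) * ceil(3000/0.224) = 19643 * 13393 px
        assert nyquist_pixel_budget(4400.0, 3000.0, 0.224) == pytest.approx(
            263.0787, abs=1e-3)

    def test_pitch_doubling_quarters_count(self):
        fine = nyquist_pixel_budget(1000.0, 1000.0, 0.25)
        coarse = nyquist_pixel_budget(1000.0, 1000.0, 0.5)
        assert fine == pytest.approx(4 * coarse, rel=1e-6)

    def test_unit_field(self):
        assert nyquist_pixel_budget(1000.0, 1000.0, 1.0) == pytest.approx(1.0)


class TestSimulateStack:
    def test_inclusive_plane_count(self, airy_sheet):
        p = generate_phantom(0, 2, (20, 20, 160))
        camera = CameraModel(pixel_pitch=0.672, sensor_positions=1)
        stack = simulate_stack(p, airy_sheet, camera, (5.0, 155.0), 1.5, seed=1)
        assert stack.n_planes == 101

    def test_same_seed_bit_identical(self, airy_sheet):
        p = generate_phantom(2, 8, (30, 30, 30))
        camera = CameraModel(pixel_pitch=0.672, sensor_positions=1,
                             hot_pixel_rate=1e-4)
        s1 = simulate_stack(p, airy_sheet, camera, (10.0, 20.0), 2.0, seed=9)
        s2 = simulate_stack(p, airy_sheet, camera, (10.0, 20.0), 2.0, seed=9)
        assert np.array_equal(s1.planes, s2.planes)

    def test_sensor_positions_set_pitch_and_pixel_count(self, airy_sheet):
        p = generate_phantom(1, 3, (30, 30, 30))
        c9 = CameraModel(pixel_pitch=0.672, sensor_positions=9)
        c1 = CameraModel(pixel_pitch=0.672, sensor_positions=1)
        s9 = simulate_stack(p, airy_sheet, c9, (15.0, 15.0), 1.0, seed=0)
        s1 = simulate_stack(p, airy_sheet, c1, (15.0, 15.0), 1.0, seed=0)
        assert c1.effective_pitch == 3 * c9.effective_pitch
        assert s9.planes[0].size == 9 * s1.planes[0].size

    def test_empty_z_range_rejected(self, airy_sheet):
        p = generate_phantom(0, 1, (20, 20, 20))
        camera = CameraModel(pixel_pitch=0.672, sensor_positions=1)
        with pytest.raises(ValueError):
            simulate_stack(p, airy_sheet, camera, (15.0, 5.0), 1.0)
        with pytest.raises(ValueError):
            simulate_stack(p, airy_sheet, camera, (5.0, 15.0), -1.0)
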