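"""Forward model: analytic projections, filament renders, worm-like
chains, micrographs, cross-sections and class libraries."""

import numpy as np
import pytest

from kerafil import helix, profiles, simulate
from kerafil.contour import Contour
from kerafil.simulate import CrossSectionSpec, FilamentSpec

PX = 2.206


def rasterized_annulus_projection(outer_r_A, inner_r_A, core_r_A=0.0,
                                  core_density=1.0, grid_A=0.05):
    """Independent numeric line-integral oracle: rasterize the annulus
    (+ core rod) cross-section on a fine grid and sum along one axis."""
    half = outer_r_A * 1.5
    n = int(2 * half / grid_A)
    x = (np.arange(n) - (n - 1) / 2) * grid_A
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx, yy)
    density = ((r <= outer_r_A) & (r >= inner_r_A)).astype(float)
    density += core_density * (r <= core_r_A)
    return x, density.sum(axis=0) * grid_A


class TestHollowCylinderProjection:
    def test_solid_cylinder_peak_at_center(self):
        prof = simulate.project_hollow_cylinder(5.0, 0.0, pixel_size_A=1.0)
        mid = len(prof.intensity) // 2
        assert np.argmax(prof.intensity) == mid
        # chord through the center of a disk of radius R is 2R
        assert prof.intensity[mid] == pytest.approx(2 * 50.0, rel=1e-6)

    def test_annulus_edge_maxima_match_rasterized_oracle(self):
        prof = simulate.project_hollow_cylinder(5.0, 3.0, pixel_size_A=0.25)
        x_o, y_o = rasterized_annulus_projection(50.0, 30.0)
        # both should peak at the inner-radius offset, dip at the center
        peak_analytic = abs(prof.positions_A[np.argmax(prof.intensity)])
        peak_oracle = abs(x_o[np.argmax(y_o)])
        assert peak_analytic == pytest.approx(30.0, abs=0.5)
        assert peak_oracle == pytest.approx(30.0, abs=0.5)
        mid = len(prof.intensity) // 2
        assert prof.intensity[mid] < prof.intensity.max()

    def test_annulus_with_core_has_central_local_maximum(self):
        prof = simulate.project_hollow_cylinder(5.0, 3.0, core_r_nm=1.0,
                                                pixel_size_A=0.25)
        y = prof.intensity
        mid = len(y) // 2
        k_inner = int(30.0 / 0.25)
        # edge maxima remain global, but the center is a local maximum
        assert y.max() == pytest.approx(y[mid + k_inner], rel=1e-2)
        assert y[mid] > y[mid + k_inner // 2]
        # oracle shows the same shape
        x_o, y_o = rasterized_annulus_projection(50.0, 30.0, core_r_A=10.0)
        mid_o = len(y_o) // 2
        assert y_o[mid_o] > y_o[mid_o + int(15.0 / 0.05)]

    def test_inner_ge_outer_rejected(self):
        with pytest.raises(ValueError):
            simulate.project_hollow_cylinder(3.0, 5.0)


class TestFilamentImage:
    def test_dominant_axial_frequency_is_one_over_pitch(self):
        spec = FilamentSpec(pitch_A=163.0)
        img = simulate.generate_filament_image(spec, 256, PX)
        axial = img.pixels.mean(axis=1)
        axial -= axial.mean()
        spectrum = np.abs(np.fft.rfft(axial))
        freqs = np.fft.rfftfreq(len(axial), d=PX)
        f_peak = freqs[np.argmax(spectrum)]
        df = freqs[1] - freqs[0]   # one discrete frequency bin
        assert abs(f_peak - 1 / 163.0) <= df

    def test_diameter_recovered_from_zero_noise_render(self):
        spec = FilamentSpec(diameter_nm=12.0)
        img = simulate.generate_filament_image(spec, 256, 1.075)
        d = profiles.measure_diameter(profiles.lateral_profile(img))
        assert d == pytest.approx(12.0, abs=0.3)

    def test_seed_determinism(self):
        spec = FilamentSpec(noise_sigma=0.3, seed=42)
        a = simulate.generate_filament_image(spec, 128, PX)
        b = simulate.generate_filament_image(spec, 128, PX)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate.generate_filament_image(FilamentSpec(pitch_A=3.0),
                                             64, PX)


class TestWormLikeChain:
    def test_point_count_and_spacing(self):
        c = simulate.generate_wlc_contour(300.0, 100.0, 1.0, seed=0)
        assert len(c) == 101
        np.testing.assert_allclose(np.diff(c.arc_s), 1.0, atol=1e-12)

    def test_infinite_stiffness_limit_is_straight(self):
        c = simulate.generate_wlc_contour(1e12, 100.0, 1.0, seed=3)
        assert np.max(np.abs(c.points[:, 1])) < 1e-3
        assert c.length == pytest.approx(100.0, abs=1e-6)

    def test_tangent_correlation_decay_recovers_2lp(self):
        # 2D convention: <cos dtheta(s)> = exp(-s / 2 Lp)
        contours = [simulate.generate_wlc_contour(300.0, 600.0, 5.0, seed=i)
                    for i in range(400)]
        decay = 0.0
        decay = __import__("kerafil.persistence", fromlist=["x"]) \
            .fit_tangent_correlation(contours)
        assert decay == pytest.approx(600.0, rel=0.10)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_wlc_contour(-1.0, 100.0, 1.0)


class TestMicrograph:
    def test_horizontal_filament_psi_90(self):
        spec = FilamentSpec(contour=simulate.line_contour((20, 128),
                                                          (236, 128)))
        _, table = simulate.generate_micrograph([spec], 256, PX)
        for rec in table:
            assert abs(rec.psi_deg) == pytest.approx(90.0, abs=1.0)

    def test_tube_ids_assigned_in_order(self):
        specs = [
            FilamentSpec(contour=simulate.line_contour((60, 20), (60, 236))),
            FilamentSpec(contour=simulate.line_contour((180, 20), (180, 236))),
        ]
        _, table = simulate.generate_micrograph(specs, 256, PX)
        assert table.tube_ids() == [0, 1]

    def test_superposition_of_individual_renders(self):
        specs = [
            FilamentSpec(contour=simulate.line_contour((60, 20), (60, 236))),
            FilamentSpec(contour=simulate.line_contour((180, 20), (180, 236))),
        ]
        both, _ = simulate.generate_micrograph(specs, 256, PX)
        singles = [simulate.generate_micrograph([s], 256, PX)[0].pixels
                   for s in specs]
        summed = singles[0] + singles[1]
        c = np.corrcoef(both.pixels.ravel(), summed.ravel())[0, 1]
        assert c > 0.99


class TestCrossSection:
    def test_six_blobs_give_six_angular_maxima(self):
        from kerafil import xsection
        img = simulate.generate_cross_section(CrossSectionSpec(), 64, PX)
        _, prof = xsection.angular_profile(img, None, 2.7, 4.3, n_bins=120)
        # count local maxima on the circular profile; symmetric bin
        # placement can produce two-bin plateaus, counted once
        up = prof > np.roll(prof, 1)
        down = prof >= np.roll(prof, -1)
        assert int(np.sum(up & down)) == 6

    def test_empty_spec_is_blank(self):
        img = simulate.generate_cross_section(
            CrossSectionSpec(n_proto=0, has_core=False), 64, PX)
        assert np.all(img.pixels == 0)

    def test_blobs_outside_box_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_cross_section(
                CrossSectionSpec(ring_radius_nm=10.0), 64, PX)


class TestClassLibrary:
    def test_one_class_per_spec(self):
        specs = [FilamentSpec(pitch_A=p) for p in (132.0, 150.0, 163.0)]
        classes, cmap = simulate.generate_class_library(specs, 128, PX)
        assert len(classes) == 3
        assert cmap == {0: 1, 1: 2, 2: 3}

    def test_background_is_zero(self):
        classes, _ = simulate.generate_class_library(
            [FilamentSpec()], 128, PX)
        corners = classes[0].pixels[:, :5]
        assert np.allclose(corners, 0.0)

    def test_pitch_self_consistency(self):
        classes, _ = simulate.generate_class_library(
            [FilamentSpec(pitch_A=163.0)], 250, PX)
        sp = helix.axial_autocorrelation(classes[0])
        assert sp.peak_lag_A == pytest.approx(163.0, abs=PX)
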