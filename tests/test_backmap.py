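"""Back-mapping reconstitution, contour fitting and straightening."""

import numpy as np
import pytest

from kerafil import backmap, helix, simulate
from kerafil.backmap import (compose_reconstitution, fit_contour,
                             inverse_transform_class, straighten)
from kerafil.contour import Contour
from kerafil.core import Image2D, ParticleRecord, ParticleTable

PX = 2.206


@pytest.fixture
def straight_scene():
    """Noise-free vertical filament, its picks, and per-segment classes."""
    size = 480
    spec = simulate.FilamentSpec(
        pitch_A=150.0, contour=simulate.line_contour((200, 30), (200, 450)))
    mic, table = simulate.generate_micrograph([spec], size, PX)
    library = simulate.generate_segment_class_library(mic, table, 250)
    return mic, table, library


class TestInverseTransform:
    def test_zero_psi_full_mask_is_identity(self):
        rng = np.random.default_rng(0)
        img = Image2D(rng.normal(size=(64, 64)), PX)
        out = inverse_transform_class(img, 0.0, mask_width_A=64 * PX,
                                      edge_px=0)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_rotate_and_unrotate_round_trip(self):
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(1)
        img = Image2D(gaussian_filter(rng.normal(size=(128, 128)), 3), PX)
        masked = inverse_transform_class(img, 0.0, mask_width_A=132.0)
        fwd = inverse_transform_class(img, 25.0, mask_width_A=132.0)
        back = inverse_transform_class(fwd, -25.0, mask_width_A=132.0)
        # compare inside the doubly masked central band only
        inner = (slice(40, 88), slice(50, 78))
        m2 = inverse_transform_class(masked, 0.0, mask_width_A=132.0)
        c = np.corrcoef(back.pixels[inner].ravel(),
                        m2.pixels[inner].ravel())[0, 1]
        assert c > 0.98

    def test_mask_width_in_pixels(self):
        # 132 Å at 2.206 Å/px retains a band of about 60 px
        img = Image2D(np.ones((100, 100)), PX)
        out = inverse_transform_class(img, 0.0, mask_width_A=132.0,
                                      edge_px=0)
        band = np.sum(out.pixels[50] > 0.5)
        assert band == pytest.approx(132.0 / PX, abs=1.5)

    def test_mask_wider_than_box_rejected(self):
        img = Image2D(np.ones((64, 64)), PX)
        with pytest.raises(ValueError):
            inverse_transform_class(img, 0.0, mask_width_A=200 * PX)


class TestCompose:
    def test_single_particle_places_one_class(self):
        cls = Image2D(np.ones((64, 64)), PX)
        rec = ParticleRecord("m", 100.0, 100.0, 0.0, 0, 0, class_id=1)
        table = ParticleTable([rec], PX)
        recon = compose_reconstitution(table, {1: cls}, 200,
                                       mask_width_A=100.0)
        assert recon.coverage.max() == 1
        assert recon.image.pixels[100, 100] != 0.0
        assert recon.image.pixels[10, 10] == 0.0

    def test_round_trip_correlates_with_ground_truth(self, straight_scene):
        mic, table, library = straight_scene
        recon = compose_reconstitution(table, library, 480)
        mask = recon.coverage > 0
        c = np.corrcoef(recon.image.pixels[mask], mic.pixels[mask])[0, 1]
        assert c > 0.9

    def test_coverage_bound(self, straight_scene):
        _, table, library = straight_scene
        recon = compose_reconstitution(table, library, 480)
        assert recon.coverage.max() <= backmap.MAX_OVERLAP

    def test_normalized_tube_mean_is_unity(self, straight_scene):
        _, table, library = straight_scene
        recon = compose_reconstitution(table, library, 480)
        footprint = recon.coverage > 0
        assert recon.image.pixels[footprint].mean() == pytest.approx(
            1.0, abs=1e-6)

    def test_missing_class_rejected(self):
        rec = ParticleRecord("m", 50.0, 50.0, 0.0, 0, 0, class_id=9)
        with pytest.raises(ValueError, match="not in the library"):
            compose_reconstitution(ParticleTable([rec], PX), {}, 100)


class TestFitContour:
    def test_collinear_picks_fit_a_line(self):
        recs = [ParticleRecord("m", 10.0 + 3 * i, 20.0 + 4 * i, 0.0, 0, i)
                for i in range(10)]
        c = fit_contour(recs)
        # all points on the line through (10,20) with direction (3,4)
        d = np.abs((c.points[:, 0] - 10) * 4 - (c.points[:, 1] - 20) * 3) / 5
        assert d.max() < 0.1

    def test_circle_curvature_within_5_percent(self):
        R = 150.0
        t = np.linspace(0, np.pi / 2, 12)
        recs = [ParticleRecord("m", R * np.cos(a), R * np.sin(a), 0.0, 0, i)
                for i, a in enumerate(t)]
        c = fit_contour(recs)
        from kerafil.contour import tangent_angles
        theta = tangent_angles(c)
        slope = abs(np.polyfit(c.arc_s[5:-5], theta[5:-5], 1)[0])
        assert abs(slope - 1 / R) / (1 / R) < 0.05

    def test_arc_length_at_least_chord(self):
        recs = [ParticleRecord("m", float(x), float((x / 30.0) ** 2), 0.0,
                               0, i)
                for i, x in enumerate(range(0, 200, 20))]
        c = fit_contour(recs)
        chord = np.linalg.norm(c.points[-1] - c.points[0])
        assert c.length >= chord - 1e-6

    def test_fewer_than_two_segments_rejected(self):
        with pytest.raises(ValueError):
            fit_contour([ParticleRecord("m", 0, 0, 0, 0, 0)])


class TestStraighten:
    def test_already_straight_filament_is_identity_crop(self):
        spec = simulate.FilamentSpec(
            pitch_A=150.0,
            contour=simulate.line_contour((128, 20), (128, 236)))
        mic, _ = simulate.generate_micrograph([spec], 256, PX)
        contour = simulate.line_contour((128, 30), (128, 226))
        st = straighten(mic, contour, width_A=120.0)
        n_lat = st.image.shape[1]
        crop = mic.pixels[30:30 + st.image.shape[0],
                          128 - n_lat // 2:128 + n_lat // 2 + 1]
        c = np.corrcoef(st.image.pixels.ravel(), crop.ravel())[0, 1]
        assert c > 0.99

    def test_quarter_circle_maps_to_arc_length(self):
        R = 100.0
        t = np.linspace(0, np.pi / 2, 120)
        contour = Contour.from_points(
            np.column_stack([120 + R * np.cos(t), 230 - R * np.sin(t)]))
        st = straighten(Image2D(np.zeros((300, 300)), 2.0), contour,
                        width_A=40.0)
        assert st.image.shape[0] == pytest.approx(np.pi * R / 2, abs=1.5)

    def test_pitch_preserved_through_bending(self):
        R = 600.0
        ang = np.linspace(np.pi / 2 - 0.33, np.pi / 2 + 0.33, 80)
        contour = Contour.from_points(
            np.column_stack([240 + R * np.cos(ang), 640 - R * np.sin(ang)]))
        spec = simulate.FilamentSpec(pitch_A=150.0, contour=contour)
        mic, _ = simulate.generate_micrograph([spec], 480, PX)
        st = straighten(mic, contour, width_A=132.0)
        sp = helix.axial_autocorrelation(st.image)
        assert sp.peak_lag_A == pytest.approx(150.0, abs=3.0)

    def test_contour_outside_image_rejected(self):
        contour = simulate.line_contour((10, 10), (400, 400))
        with pytest.raises(ValueError, match="exits"):
            straighten(Image2D(np.zeros((100, 100)), 1.0), contour, 20.0)
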