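"""Phantom generator: geometry, ground truth and photon statistics."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import cisternatex as ct
from cisternatex.phantoms import cisterna_occupancy, full_frame_region


class TestTubuleNetwork:
    def test_no_junction_case_is_single_open_segment(self, small_spec):
        layout = ct.make_tubule_network(small_spec, n_junctions=0)
        assert len(layout.segments) == 1
        assert layout.n_junctions() == 0

    def test_requested_junction_count_matches_degree_census(self, small_spec):
        layout = ct.make_tubule_network(small_spec, n_junctions=4)
        degrees = layout.node_degrees()
        assert sum(1 for d in degrees.values() if d == 3) == 4
        # internal nodes are exactly degree 3; all others are endpoints
        assert set(degrees.values()) <= {1, 3}

    def test_default_tubule_diameter_is_40nm(self, small_spec):
        layout = ct.make_tubule_network(small_spec, n_junctions=1)
        assert layout.tubule_diameter_nm == 40.0

    def test_reproducible_under_seed(self, small_spec):
        a = ct.make_tubule_network(small_spec, n_junctions=3)
        b = ct.make_tubule_network(small_spec, n_junctions=3)
        assert a.segments == b.segments

    def test_tiny_region_raises_placement_error(self, small_spec):
        tiny = Polygon([(0, 0), (50, 0), (50, 50), (0, 50)])
        with pytest.raises(ct.PlacementError):
            ct.make_tubule_network(small_spec, n_junctions=2, region=tiny)


def _square(cx, cy, half):
    return Polygon([(cx - half, cy - half), (cx + half, cy - half),
                    (cx + half, cy + half), (cx - half, cy + half)])


class TestCisternaOccupancy:
    def _grid(self, poly, step=10.0):
        minx, miny, maxx, maxy = poly.bounds
        xs = np.arange(minx + step / 2, maxx, step)
        ys = np.arange(miny + step / 2, maxy, step)
        X, Y = np.meshgrid(xs, ys)
        return X, Y

    def test_sac_occupancy_is_one_everywhere(self, small_spec):
        layout = ct.make_tubule_network(small_spec, 0)
        poly = _square(3000, 3000, 600)
        layout = ct.add_cisterna(layout, "sac", {"polygon": poly})
        X, Y = self._grid(poly)
        occ = cisterna_occupancy(layout.cisternae[0], X, Y)
        assert np.all(occ == 1.0)

    def test_nanohole_area_fraction_matches_analytic(self, small_spec):
        layout = ct.make_tubule_network(small_spec, 0)
        half = 1000.0
        poly = _square(3000, 3000, half)
        r = 80.0
        # regular grid of well-separated holes, fully interior
        centers = [(2500 + i * 250.0, 2500 + j * 250.0)
                   for i in range(5) for j in range(5)]
        layout = ct.add_cisterna(layout, "sac_nanoholes", {
            "polygon": poly, "hole_radius_nm": r, "hole_centers": centers})
        X, Y = self._grid(poly, step=4.0)
        occ = cisterna_occupancy(layout.cisternae[0], X, Y)
        expected_fraction = len(centers) * math.pi * r ** 2 / (2 * half) ** 2
        measured = 1.0 - occ.mean()
        assert measured == pytest.approx(expected_fraction, rel=0.05)

    def test_merged_nanoholes_record_warning_not_error(self, small_spec):
        layout = ct.make_tubule_network(small_spec, 0)
        poly = _square(3000, 3000, 300)
        layout = ct.add_cisterna(layout, "sac_nanoholes", {
            "polygon": poly, "hole_radius_nm": 280.0,
            "hole_centers": [(3000.0, 3000.0)]})
        assert any("nanohole" in w for w in layout.warnings)

    def test_matrix_centre_occupancy_below_edge_band(self, small_spec):
        layout = ct.make_tubule_network(small_spec, 0)
        poly = _square(3000, 3000, 800)
        layout = ct.add_cisterna(layout, "tubular_matrix", {"polygon": poly})
        cist = layout.cisternae[0]
        X, Y = self._grid(poly, step=5.0)
        occ = cisterna_occupancy(cist, X, Y)
        edge_d = np.minimum.reduce([np.abs(X - 2200), np.abs(X - 3800),
                                    np.abs(Y - 2200), np.abs(Y - 3800)])
        central = occ[(np.abs(X - 3000) < 400) & (np.abs(Y - 3000) < 400)]
        edge = occ[edge_d <= cist.params["edge_band_nm"]]
        assert central.mean() < edge.mean()
        assert edge.mean() == 1.0

    def test_unknown_substructure_rejected(self, small_spec):
        layout = ct.make_tubule_network(small_spec, 0)
        with pytest.raises(ValueError):
            ct.add_cisterna(layout, "vesicle", {"polygon": _square(0, 0, 10)})


class TestRenderER:
    def test_noiseless_unblurred_render_equals_occupancy(self, noiseless_spec):
        layout = ct.make_er_scene(noiseless_spec, n_cisternae=5)
        img, gt = ct.render_er_image(layout, noiseless_spec, noise=False,
                                     supersample=1)
        expected = noiseless_spec.photon_scale * gt.lumen_occupancy
        np.testing.assert_allclose(img.channel("lumen"), expected)

    def test_rendered_tubule_fwhm_matches_psf(self):
        # an isolated horizontal tubule: the rendered line-spread FWHM should
        # match the PSF FWHM convolved with the 40 nm tubule width
        spec = ct.PhantomSpec(image_shape=(64, 64), pixel_size_nm=46.0,
                              psf_fwhm_nm=140.0, seed=0)
        y = 32 * 46.0
        layout = ct.ERPhantomLayout(segments=[((200.0, y), (2700.0, y))])
        img, _ = ct.render_er_image(layout, spec, noise=False, supersample=4)
        profile = img.channel("lumen")[:, 32] - spec.background_level
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        fwhm_px = above[-1] - above[0] + 1
        sigma_expected = math.sqrt(
            (140.0 / 2.355) ** 2 + (40.0 ** 2 / 12.0))  # line width variance
        fwhm_expected_px = 2.355 * sigma_expected / 46.0
        assert fwhm_px == pytest.approx(fwhm_expected_px, abs=1.2)

    def test_byte_identical_under_same_spec_and_seed(self, small_spec):
        layout = ct.make_er_scene(small_spec, n_cisternae=5)
        a, ga = ct.render_er_image(layout, small_spec)
        b, gb = ct.render_er_image(layout, small_spec)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ga.label_map, gb.label_map)

    def test_rendering_conserves_ground_truth_geometry(self, small_spec):
        layout = ct.make_er_scene(small_spec, n_cisternae=5)
        _, gt1 = ct.render_er_image(layout, small_spec)
        _, gt2 = ct.render_er_image(layout, small_spec,
                                    channels=["lumen", "membrane"])
        assert gt1.lumen_occupancy.sum() == gt2.lumen_occupancy.sum()
        assert gt1.lumen_occupancy.min() >= 0
        assert gt1.lumen_occupancy.max() <= 1

    def test_poisson_plus_read_noise_variance(self):
        # per-pixel sample variance across seeds approximates the Poisson
        # mean plus the read-noise variance
        layouts = ct.ERPhantomLayout(segments=[((0.0, 200.0), (500.0, 200.0))])
        imgs = []
        for seed in range(250):
            spec = ct.PhantomSpec(image_shape=(10, 10), photon_scale=80.0,
                                  read_noise_sd=3.0, background_level=20.0,
                                  seed=seed)
            img, _ = ct.render_er_image(layouts, spec, supersample=1)
            imgs.append(img.channel("lumen"))
        stack = np.stack(imgs)
        mean = stack.mean(axis=0)
        var = stack.var(axis=0, ddof=1)
        expected = mean + 3.0 ** 2
        ratio = var.sum() / expected.sum()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_undersampled_psf_warns_but_renders(self):
        spec = ct.PhantomSpec(image_shape=(32, 32), psf_fwhm_nm=20.0, seed=0)
        layout = ct.ERPhantomLayout(segments=[((100.0, 500.0), (1000.0, 500.0))])
        with pytest.warns(UserWarning, match="undersampled"):
            img, _ = ct.render_er_image(layout, spec)
        assert img.data.shape == (1, 32, 32)

    def test_unknown_channel_rejected(self, small_spec):
        layout = ct.make_tubule_network(small_spec, 0)
        with pytest.raises(ValueError):
            ct.render_er_image(layout, small_spec, channels=["golgi"])


class TestGolgiPhantom:
    def test_straight_phantom_parallel_edges_zero_curvature(self):
        gp = ct.make_golgi_phantom(math.inf, n_cisternae=1, seed=0)
        a, b = gp.edge_pairs[0]
        assert gp.true_curvature_nm == 0.0
        assert np.allclose(a[:, 1], a[0, 1])
        assert np.allclose(b[:, 1] - a[:, 1], -27.0)

    def test_arc_curvature_is_reciprocal_radius(self):
        gp = ct.make_golgi_phantom(500.0, seed=0)
        assert gp.true_curvature_nm == pytest.approx(0.002)

    def test_swelling_exceeding_width_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            ct.make_golgi_phantom(500.0, base_width_nm=27.0,
                                  swelling_amplitude_nm=27.0)

    def test_width_profile_bounded_by_swelling(self):
        gp = ct.make_golgi_phantom(800.0, base_width_nm=27.0,
                                   swelling_amplitude_nm=10.0, seed=3)
        for w in gp.true_width_profiles:
            assert w.min() >= 27.0 - 1e-9 or w.min() >= 0.2 * 27.0
            assert w.max() <= 37.0 + 1e-9


class TestRatioPair:
    def test_noiseless_unit_ratio_channels_identical(self):
        spec = ct.PhantomSpec(image_shape=(32, 32), seed=0,
                              read_noise_sd=0.0)
        img, _ = ct.make_ratio_pair(1.0, spec, noise=False)
        np.testing.assert_allclose(img.channel("405"), img.channel("488"))

    def test_ground_truth_stores_ratio_and_bleed(self):
        spec = ct.PhantomSpec(image_shape=(16, 16), seed=0)
        img, gt = ct.make_ratio_pair(0.7, spec, bleed_coeff=0.2)
        assert np.all(gt.true_params["true_ratio"] == 0.7)
        assert gt.true_params["bleed_coeff"] == 0.2

    def test_invalid_ratio_and_bleed_rejected(self):
        spec = ct.PhantomSpec(image_shape=(8, 8), seed=0)
        with pytest.raises(ValueError):
            ct.make_ratio_pair(0.0, spec)
        with pytest.raises(ValueError):
            ct.make_ratio_pair(1.0, spec, bleed_coeff=1.0)


class TestCellScene:
    def test_noiseless_fraction_recovered_exactly_at_50(self):
        spec = ct.PhantomSpec(image_shape=(192, 192), seed=4,
                              psf_fwhm_nm=0.0, read_noise_sd=0.0)
        img, rois, _ = ct.make_cell_scene(50.0, 5, 1.0, spec, noise=False)
        res = ct.golgi_transport_fraction(img.data[0], rois)
        assert res.golgi_percent == pytest.approx(50.0, abs=1e-9)

    def test_zero_fraction_puts_golgi_rois_at_background(self):
        spec = ct.PhantomSpec(image_shape=(192, 192), seed=4,
                              psf_fwhm_nm=0.0, read_noise_sd=0.0)
        img, rois, _ = ct.make_cell_scene(0.0, 5, 1.0, spec, noise=False)
        bg = ct.mean_roi_intensity(img.data[0], rois.background[0])
        for g in rois.golgi:
            assert ct.mean_roi_intensity(img.data[0], g) == pytest.approx(bg)

    def test_zero_golgi_with_positive_fraction_invalid(self, small_spec):
        with pytest.raises(ValueError):
            ct.make_cell_scene(30.0, 0, 1.0, small_spec)

    def test_roi_set_round_trips_through_json(self, small_spec):
        _, rois, _ = ct.make_cell_scene(30.0, 5, 2.0, small_spec)
        again = ct.ROISet.from_json(rois.to_json())
        assert len(again.golgi) == 3 and len(again.er) == 3
        assert again.cell_boundary.equals_exact(rois.cell_boundary, 1e-9)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"pixel_size_nm": 0.0},
        {"psf_fwhm_nm": -1.0},
        {"image_shape": (0, 10)},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ct.PhantomSpec(**kwargs)

    def test_pixel_scaling_interpretations(self):
        assert ct.pixel_size_from_scaling(0.046) == pytest.approx(46.0)
        assert ct.pixel_size_from_scaling(0.046, "area") == pytest.approx(
            math.sqrt(0.046) * 1000.0)

    def test_region_helper_fits_inside_frame(self, small_spec):
        region = full_frame_region(small_spec)
        h, w = small_spec.extent_nm
        assert region.bounds[2] <= w and region.bounds[3] <= h
        assert region.contains(Point(w / 2, h / 2))
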