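"""Illumination fitting, residual thresholding, component filtering and
spot integration."""

import math

import numpy as np
import pytest

from tlcquant.densitometry import (
    CoordNorm,
    IlluminationModel,
    ResidualImage,
    Spot,
    SpotComponent,
    add_manual_spot,
    compute_residual,
    constant_illumination,
    disk_pixels,
    filter_components,
    find_components,
    fit_illumination,
    integrate_spot,
    locate_spot,
    quartic_design_matrix,
    threshold_residual,
)
from tlcquant.errors import DensitometryError
from tlcquant.imaging import LINEAR, RasterImage


def _quartic_surface(coeffs, w, h):
    norm = CoordNorm(w, h)
    xx, yy = np.meshgrid(np.arange(w), np.arange(h))
    xn, yn = norm.normalize(xx, yy)
    return (quartic_design_matrix(xn.ravel(), yn.ravel()) @ coeffs).reshape(h, w)


def _residual(arr):
    return ResidualImage(np.asarray(arr, float))


class TestIlluminationFit:
    def test_constant_image_fits_constant(self):
        model = fit_illumination(RasterImage(np.full((40, 40), 0.6), LINEAR))
        expected = np.zeros(15)
        expected[14] = 0.6
        assert np.allclose(model.coeffs, expected, atol=1e-9)
        assert np.allclose(model.evaluate_grid(), 0.6, atol=1e-9)

    @pytest.mark.parametrize("factor", [1, 4])
    def test_exact_on_generated_quartic(self, rng, factor):
        """OLS on the spanning basis reproduces a generating quartic surface
        pointwise to 1e-6."""
        coeffs = rng.normal(0, 0.05, 15)
        coeffs[14] = 0.6
        surf = np.clip(_quartic_surface(coeffs, 180, 140), 0, 1)
        model = fit_illumination(RasterImage(surf, LINEAR), downsample_factor=factor)
        assert np.abs(model.evaluate_grid() - surf).max() < 1e-6

    def test_small_spot_perturbs_fit_by_its_projection_only(self, rng):
        """The fit is linear: adding a dark spot shifts the fitted surface by
        exactly the basis projection of the spot, which is bounded well below
        the spot amplitude for a small spot."""
        coeffs = rng.normal(0, 0.03, 15)
        coeffs[14] = 0.7
        w, h = 160, 120
        surf = np.clip(_quartic_surface(coeffs, w, h), 0.2, 1)
        xx, yy = np.meshgrid(np.arange(w), np.arange(h))
        amp = 0.3
        spot = amp * np.exp(-((xx - 80.0) ** 2 + (yy - 60.0) ** 2) / (2 * 4.0**2))
        fit_clean = fit_illumination(RasterImage(surf, LINEAR)).evaluate_grid()
        fit_spotted = fit_illumination(
            RasterImage(np.clip(surf - spot, 0, 1), LINEAR)
        ).evaluate_grid()
        delta = fit_clean - fit_spotted
        # brute-force oracle: project the spot image alone onto the basis
        spot_model = fit_illumination(RasterImage(spot / amp, LINEAR))
        projection = amp * spot_model.evaluate_grid()
        assert np.allclose(delta, projection, atol=1e-9)
        assert np.abs(delta).max() < 0.1 * amp

    def test_refit_shrinks_spot_leverage_on_background(self, rng):
        """Excluding above-threshold pixels and refitting removes most of a
        spot's pull on the background surface (the sub-threshold Gaussian
        tails keep it from being exact)."""
        coeffs = rng.normal(0, 0.03, 15)
        coeffs[14] = 0.7
        w, h = 160, 120
        surf = np.clip(_quartic_surface(coeffs, w, h), 0.2, 1)
        xx, yy = np.meshgrid(np.arange(w), np.arange(h))
        spot = 0.3 * np.exp(-((xx - 80.0) ** 2 + (yy - 60.0) ** 2) / (2 * 5.0**2))
        img = RasterImage(np.clip(surf - spot, 0, 1), LINEAR)
        err_single = np.abs(
            fit_illumination(img).evaluate_grid() - surf
        ).max()
        err_refit = np.abs(
            fit_illumination(img, refit_exclude_spots=True).evaluate_grid() - surf
        ).max()
        assert err_refit < err_single / 3
        assert err_refit < 5e-3

    def test_too_small_inputs_raise(self):
        with pytest.raises(DensitometryError):
            fit_illumination(RasterImage(np.full((4, 4), 0.5), LINEAR))
        with pytest.raises(DensitometryError):
            fit_illumination(RasterImage(np.full((10, 10), 0.5), LINEAR), downsample_factor=8)

    def test_color_input_rejected(self):
        with pytest.raises(DensitometryError):
            fit_illumination(RasterImage(np.full((20, 20, 3), 0.5), LINEAR))

    def test_coefficient_count_enforced(self):
        with pytest.raises(DensitometryError):
            IlluminationModel(np.zeros(14), CoordNorm(10, 10))


class TestResidual:
    def test_exact_cancellation(self):
        img = RasterImage(np.full((40, 40), 0.5), LINEAR)
        model = fit_illumination(img)
        res = compute_residual(img, model)
        assert np.abs(res.pixels).max() < 1e-12
        assert res.mean == pytest.approx(0.0, abs=1e-12)

    def test_background_minus_image_makes_dark_spots_positive(self):
        img = np.full((40, 40), 0.5)
        img[10:14, 10:14] = 0.3  # dark (quenching) patch
        model = constant_illumination(RasterImage(np.full((40, 40), 0.5), LINEAR))
        res = compute_residual(RasterImage(img, LINEAR), model)
        assert res.pixels[11, 11] > 0

    def test_mean_matches_independent_computation(self, rng):
        img = RasterImage(rng.uniform(0.2, 0.8, (32, 48)), LINEAR)
        model = fit_illumination(img)
        res = compute_residual(img, model)
        assert res.mean == pytest.approx(float(np.mean(res.pixels)))

    def test_dimension_mismatch(self):
        model = constant_illumination(RasterImage(np.full((40, 40), 0.5), LINEAR))
        with pytest.raises(DensitometryError):
            compute_residual(RasterImage(np.full((30, 40), 0.5), LINEAR), model)


class TestThreshold:
    def test_constant_residual_is_all_ones(self):
        mask = threshold_residual(_residual(np.full((5, 5), 0.2)))
        assert mask.all()  # v >= mu is inclusive

    def test_half_and_half(self):
        arr = np.zeros((4, 8))
        arr[:, 4:] = 1.0
        mask = threshold_residual(_residual(arr))
        assert np.array_equal(mask, arr == 1.0)

    def test_count_matches_brute_force(self, rng):
        arr = rng.normal(0, 1, (30, 40))
        mask = threshold_residual(_residual(arr))
        brute = sum(1 for v in arr.ravel() if v >= arr.mean())
        assert mask.sum() == brute


class TestComponents:
    def test_empty_mask(self):
        assert find_components(np.zeros((10, 10), bool)) == []

    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        comps = find_components(mask)
        assert sorted(c.area for c in comps) == [9, 9]

    def test_diagonal_chain_is_one_component(self):
        mask = np.eye(8, dtype=bool)
        comps = find_components(mask)
        assert len(comps) == 1 and comps[0].area == 8


class TestFilter:
    def _component(self, rows, cols):
        coords = np.array([(r, c) for r in rows for c in cols])
        return SpotComponent(
            coords, (min(rows), min(cols), max(rows), max(cols))
        )

    def test_pencil_line_removed_by_aspect(self):
        line = self._component(range(50, 54), range(100, 300))  # 200 x 4 bbox
        assert filter_components([line], (1000, 1000)) == []

    def test_oversized_component_removed(self):
        big = self._component(range(0, 60), range(0, 60))  # > quarter of 100x100
        assert filter_components([big], (100, 100)) == []

    def test_single_pixel_removed_compact_blob_kept(self):
        # ~1 megapixel plate: scaled minimum area is ~2 px (floored at 4)
        plate = (1000, 1000)
        single = self._component([5], [5])
        blob = self._component(range(100, 123), range(200, 222))  # area 506
        kept = filter_components([single, blob], plate)
        assert [id(c) for c in kept] == [id(blob)]

    def test_boundary_behaviour_matches_brute_force(self, rng):
        plate = (400, 400)
        comps = []
        for _ in range(30):
            h = int(rng.integers(1, 40))
            w = int(rng.integers(1, 40))
            r0 = int(rng.integers(0, 300))
            c0 = int(rng.integers(0, 300))
            comps.append(self._component(range(r0, r0 + h), range(c0, c0 + w)))
        kept = filter_components(comps, plate)
        amin = max(4.0, 25.0 * 400 * 400 / 12_000_000)
        brute = [
            c
            for c in comps
            if 1 / 3 <= c.aspect_ratio <= 3 and amin <= c.area <= 400 * 400 / 4
        ]
        assert {id(c) for c in kept} == {id(c) for c in brute}

    def test_survivors_in_reading_order(self):
        a = self._component(range(10, 20), range(50, 60))
        b = self._component(range(10, 20), range(5, 15))
        c = self._component(range(40, 50), range(5, 15))
        kept = filter_components([a, c, b], (100, 100))
        assert [id(x) for x in kept] == [id(b), id(a), id(c)]


class TestLocateSpot:
    def test_weighted_centroid_formula(self):
        comp = SpotComponent(np.array([[0, 0], [0, 2]]), (0, 0, 0, 2))
        res = _residual(np.array([[1.0, 0.0, 3.0]]))
        spot = locate_spot(comp, res)
        assert spot.center == pytest.approx((1.5, 0.0))

    def test_symmetric_spot_center_independent_of_amplitude(self):
        yy, xx = np.mgrid[0:21, 0:21]
        g = np.exp(-((xx - 10.0) ** 2 + (yy - 10.0) ** 2) / 8.0)
        mask = g > 0.1
        comp = find_components(mask)[0]
        for amp in (0.1, 0.7):
            spot = locate_spot(comp, _residual(amp * g))
            assert spot.center == pytest.approx((10.0, 10.0), abs=1e-9)

    def test_radius_is_max_distance_plus_margin(self):
        comp = SpotComponent(np.array([[0, 0], [0, 4]]), (0, 0, 0, 4))
        res = _residual(np.array([[3.0, 0, 0, 0, 1.0]]))
        spot = locate_spot(comp, res)
        # centroid x = (0*3 + 4*1)/4 = 1; farthest member at x=4 -> dist 3
        assert spot.center == pytest.approx((1.0, 0.0))
        assert spot.radius == pytest.approx(4.0)

    def test_nonpositive_residuals_raise(self):
        comp = SpotComponent(np.array([[0, 0], [0, 1]]), (0, 0, 0, 1))
        with pytest.raises(DensitometryError):
            locate_spot(comp, _residual(np.array([[-1.0, 0.0]])))


def _brute_force_top_fraction(residual, center, radius, frac=0.15):
    """Independent oracle: enumerate disk pixels, sort, sum the top slice."""
    h, w = residual.shape
    vals = []
    for r in range(h):
        for c in range(w):
            if (c - center[0]) ** 2 + (r - center[1]) ** 2 <= radius**2:
                vals.append(residual[r, c])
    vals.sort(reverse=True)
    n_top = max(1, math.ceil(frac * len(vals)))
    return float(sum(vals[:n_top]))


class TestIntegrateSpot:
    def test_zero_residual_integrates_to_zero(self):
        spot = Spot((10.0, 10.0), 5.0)
        assert integrate_spot(spot, _residual(np.zeros((21, 21)))) == 0.0

    def test_uniform_disk_sums_top_fraction_count(self):
        res = _residual(np.full((41, 41), 0.2))
        spot = Spot((20.0, 20.0), 9.0)
        rows, _ = disk_pixels(spot.center, spot.radius, res.shape)
        n = rows.size
        value = integrate_spot(spot, res)
        assert value == pytest.approx(math.ceil(0.15 * n) * 0.2)

    def test_matches_brute_force_oracle_on_random_disks(self, rng):
        res = rng.normal(0.0, 0.3, (60, 80))
        residual = _residual(res)
        for _ in range(200):
            cx = float(rng.uniform(-5, 85))
            cy = float(rng.uniform(-5, 65))
            radius = float(rng.uniform(1.0, 12.0))
            rows, _ = disk_pixels((cx, cy), radius, res.shape)
            if rows.size == 0:
                continue
            spot = Spot((cx, cy), radius)
            assert integrate_spot(spot, residual) == pytest.approx(
                _brute_force_top_fraction(res, (cx, cy), radius)
            )

    def test_disk_outside_image_raises(self):
        with pytest.raises(DensitometryError):
            integrate_spot(Spot((200.0, 200.0), 3.0), _residual(np.zeros((50, 50))))


class TestManualSpot:
    def test_congruent_disk_gives_identical_value(self, rng):
        res = _residual(rng.normal(0, 0.2, (50, 50)))
        auto = Spot((25.0, 25.0), 8.0, detection="auto")
        integrate_spot(auto, res)
        manual = add_manual_spot((25.0, 25.0), 8.0, res)
        assert manual.detection == "manual"
        assert manual.integration_value == auto.integration_value

    def test_blank_background_integrates_to_near_zero(self):
        spec_noise = 1e-3
        rng = np.random.default_rng(0)
        res = _residual(rng.normal(0, spec_noise, (80, 80)))
        manual = add_manual_spot((40.0, 40.0), 10.0, res)
        rows, _ = disk_pixels((40.0, 40.0), 10.0, res.shape)
        n_top = max(1, math.ceil(0.15 * rows.size))
        # top-fraction of pure noise is bounded by a few noise sigmas per pixel
        assert abs(manual.integration_value) <= 4 * spec_noise * n_top

    def test_fully_outside_disk_raises(self):
        with pytest.raises(DensitometryError):
            add_manual_spot((500.0, 500.0), 4.0, _residual(np.zeros((50, 50))))
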