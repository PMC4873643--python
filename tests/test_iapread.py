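"""Image normalization, cell detection and intensity-to-impedance inference."""

import numpy as np
import pytest

from isofocus import gradient, iapread, media, synthdata

UL_PER_MIN = 1e-9 / 60.0


@pytest.fixture(scope="module")
def cal(model):
    return iapread.IntensityCalibration(
        polynomial=media.conversion_polynomial_from_model(model, 10.0, 36.0),
        c_side=10.0,
        c_center=36.0,
    )


def simple_image_set(ny=100, nx=50, offset=100.0, gain=1000.0, r_value=0.5):
    bg = np.full((ny, nx), offset)
    ref = np.full((ny, nx), offset + gain)
    grad = np.full((ny, nx), offset + gain * r_value)
    return iapread.ImageSet(gradient=grad, background=bg, reference=ref, cell_images=[])


class TestNormalizeGradient:
    @pytest.mark.parametrize("r_value", [0.0, 0.5, 1.0])
    def test_uniform_ratios(self, r_value):
        images = simple_image_set(r_value=r_value)
        r = iapread.normalize_gradient(images)
        assert np.allclose(np.ma.filled(r, np.nan), r_value)

    def test_affine_invariance(self):
        """Global camera gain/offset cancels in the ratio."""
        base = simple_image_set(r_value=0.37)
        scaled = iapread.ImageSet(
            gradient=2.5 * base.gradient + 40.0,
            background=2.5 * base.background + 40.0,
            reference=2.5 * base.reference + 40.0,
            cell_images=[],
        )
        r1 = iapread.normalize_gradient(base)
        r2 = iapread.normalize_gradient(scaled)
        assert np.allclose(np.ma.filled(r1, -1), np.ma.filled(r2, -1))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iapread.ImageSet(
                gradient=np.zeros((10, 10)),
                background=np.zeros((10, 11)),
                reference=np.ones((10, 10)),
            )

    def test_low_signal_pixels_masked(self):
        images = simple_image_set()
        images.reference[:10, :] = images.background[:10, :]  # dead rows
        r = iapread.normalize_gradient(images)
        assert np.ma.getmaskarray(r)[:10, :].all()

    def test_heavy_clipping_warns(self):
        images = simple_image_set(r_value=1.5)  # gradient brighter than reference
        with pytest.warns(UserWarning, match="clipped"):
            iapread.normalize_gradient(images)


class TestColumnProfile:
    def test_x_uniform_field_equals_single_column(self):
        col = np.linspace(0, 1, 64)
        r = np.ma.MaskedArray(np.repeat(col[:, None], 20, axis=1))
        prof = iapread.column_profile(r)
        assert np.allclose(prof.values, col)
        assert not prof.has_gaps

    def test_noise_averaging(self):
        rng = np.random.default_rng(4)
        col = np.linspace(0, 1, 64)
        r = np.ma.MaskedArray(
            np.repeat(col[:, None], 200, axis=1) + rng.normal(0, 0.05, (64, 200))
        )
        prof = iapread.column_profile(r)
        assert np.max(np.abs(prof.values - col)) < 0.01

    def test_single_column_identity(self):
        col = np.linspace(0, 1, 64)
        prof = iapread.column_profile(np.ma.MaskedArray(col[:, None]))
        assert np.allclose(prof.values, col)

    def test_fully_masked_row_flagged(self):
        r = np.ma.MaskedArray(np.ones((8, 4)), mask=np.zeros((8, 4), bool))
        r.mask[3, :] = True
        prof = iapread.column_profile(r)
        assert prof.has_gaps
        assert prof.counts[3] == 0


class TestDetectCells:
    def test_blank_image_empty(self):
        assert iapread.detect_cells(np.full((64, 64), 7.0)) == []

    def test_spots_recovered_with_subpixel_accuracy(self):
        """10 rendered spots at SNR ~10 are each found within half a pixel."""
        rng = np.random.default_rng(8)
        ny, nx, peak, sigma = 128, 128, 100.0, 2.0
        yy, xx = np.mgrid[0:ny, 0:nx]
        truth = np.column_stack(
            [rng.uniform(12, ny - 12, 10), rng.uniform(12, nx - 12, 10)]
        )
        # keep spots well separated so none merge
        for _ in range(200):
            d = np.linalg.norm(truth[:, None] - truth[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() > 14:
                break
            i = np.unravel_index(np.argmin(d), d.shape)[0]
            truth[i] = [rng.uniform(12, ny - 12), rng.uniform(12, nx - 12)]
        img = np.zeros((ny, nx))
        for cy, cx in truth:
            img += peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        img += rng.normal(0, peak / 10.0, img.shape)
        detections = iapread.detect_cells(img)
        assert len(detections) == 10
        for det in detections:
            dist = np.min(np.hypot(truth[:, 0] - det.y_px, truth[:, 1] - det.x_px))
            assert dist < 0.5

    def test_close_spots_merge_with_warning(self):
        """A lone spot and a sub-resolution pair in one frame: pair flagged merged."""
        ny = nx = 64
        yy, xx = np.mgrid[0:ny, 0:nx]
        img = np.zeros((ny, nx))
        for cy, cx in [(30.0, 30.0), (30.0, 33.0), (12.0, 50.0)]:  # pair < 2 sigma apart
            img += 100.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
        plain = iapread.detect_cells(img)
        assert len(plain) == 2  # the close pair has merged into one region
        single_area = min(d.area for d in plain)
        with pytest.warns(UserWarning, match="merged"):
            dets = iapread.detect_cells(img, iapread.DetectionParams(typical_area=single_area))
        assert any(d.merged for d in dets)


class TestInference:
    def _images_with_profile(self, model, cal, t=6.0):
        geom = gradient.ChannelGeometry()
        flow = gradient.FlowConfig(total=8 * UL_PER_MIN, central=4 * UL_PER_MIN)
        prof = gradient.initial_profile(flow, geom, 10.0, 36.0)
        if t > 0:
            prof = gradient.evolve(prof, t)
        images = synthdata.render_images(prof, cal, [], geom, seed=0)
        return geom, prof, images

    def test_endpoint_ratios(self, model, cal):
        # the un-evolved lamination has exact r=0 at the walls and r=1 centrally
        geom, _, images = self._images_with_profile(model, cal, t=0.0)
        profile = iapread.column_profile(iapread.normalize_gradient(images))
        det_wall = iapread.Detection(y_px=2.0, x_px=10.0, total_intensity=1.0, area=5)
        det_mid = iapread.Detection(y_px=images.gradient.shape[0] / 2.0, x_px=10.0, total_intensity=1.0, area=5)
        res_wall = iapread.infer_cell_impedance(det_wall, profile, cal, images)
        res_mid = iapread.infer_cell_impedance(det_mid, profile, cal, images)
        assert res_wall.ratio == pytest.approx(0.0, abs=0.01)
        assert res_wall.z_cell == pytest.approx(float(cal.polynomial(10.0)), rel=2e-3)
        assert res_mid.censored == "at center"
        assert res_mid.z_cell > res_wall.z_cell

    def test_monotone_ratio_to_impedance(self, cal):
        r = np.linspace(0.0, 1.0, 50)
        z = cal.impedance(r)
        assert np.all(np.diff(z) > 0)

    def test_wall_censoring(self, model, cal):
        geom, _, images = self._images_with_profile(model, cal)
        det = iapread.Detection(y_px=3.0, x_px=5.0, total_intensity=1.0, area=5)
        res = iapread.infer_cell_impedance(det, iapread.column_profile(iapread.normalize_gradient(images)), cal, images)
        assert res.censored == "at wall"

    def test_outside_channel_rejected(self, model, cal):
        _, _, images = self._images_with_profile(model, cal)
        det = iapread.Detection(y_px=1e4, x_px=5.0, total_intensity=1.0, area=5)
        with pytest.raises(ValueError):
            iapread.infer_cell_impedance(det, iapread.column_profile(iapread.normalize_gradient(images)), cal, images)


class TestPopulationStats:
    def _result(self, z, t=None):
        return iapread.IAPResult(
            cell_id="c", y_px=0.0, y_m=1e-4, ratio=0.5, concentration=20.0, z_cell=z,
            censored="", time=t,
        )

    def test_constant_population(self):
        results = [self._result(1.68e6, t=float(i)) for i in range(20)]
        stats = iapread.population_stats(results)
        assert stats.sd == 0.0
        assert stats.drift_slope == pytest.approx(0.0, abs=1e-12)

    def test_seeded_normal_sample_summary(self):
        """Median and 5-95 span of a large normal sample match the sampling oracle."""
        rng = np.random.default_rng(123)
        mu, sigma, n = 1.68e6, 0.014e6, 1450
        z = rng.normal(mu, sigma, n)
        stats = iapread.population_stats([self._result(v) for v in z])
        assert stats.median == pytest.approx(mu, abs=0.001e6)
        span = stats.p95 - stats.p5
        assert span == pytest.approx(2 * 1.645 * sigma, rel=0.1)

    def test_two_point_percentiles(self):
        stats = iapread.population_stats([self._result(1.6e6), self._result(1.7e6)])
        # numpy linear interpolation between order statistics
        assert stats.p5 == pytest.approx(1.6e6 + 0.05 * 1e5)
        assert stats.median == pytest.approx(1.65e6)

    def test_all_censored_flagged(self):
        censored = iapread.IAPResult(
            cell_id="c", y_px=0.0, y_m=0.0, ratio=1.0, concentration=36.0, z_cell=1.82e6,
            censored="at center",
        )
        stats = iapread.population_stats([censored, censored])
        assert stats.empty


class TestCensoringEndToEnd:
    def test_high_impedance_cells_collect_at_center(self, model, cal):
        """Cells above Z(36%) can only be reported as center-censored bounds."""
        from isofocus import transport
        from .conftest import make_field

        geom = gradient.ChannelGeometry()
        flow = gradient.FlowConfig(total=8 * UL_PER_MIN, central=4 * UL_PER_MIN)
        prof = gradient.initial_profile(flow, geom, 10.0, 36.0)
        field = make_field(geom, 15.0)
        hot = [
            transport.CellModel.from_impedance(1.90e6, model, label="hot", y0=f * geom.width)
            for f in (0.1, 0.2, 0.85)
        ]
        df = transport.simulate_population(hot, field, prof, model, 30.0)
        assert (df.censored == "center").all()
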