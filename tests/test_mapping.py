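"""Window planning, inverse-distance stitching, probability quantization, and
lossless tile round trips."""

import numpy as np
import pytest

from forestmap.geo import Affine
from forestmap.mapping import (
    D_MIN_M,
    ProbabilityMap,
    WindowPrediction,
    dequantize,
    plan_windows,
    quantize,
    read_tiles,
    stitch,
    write_tiles,
)


def stitch_oracle(predictions):
    """Independent scalar re-implementation: explicit loops over pixels."""
    ps = 10.0
    x0 = min(p.transform.c for p in predictions)
    y1 = max(p.transform.f for p in predictions)
    x1 = max(p.transform.c + p.tile.shape[1] * ps for p in predictions)
    y0 = min(p.transform.f - p.tile.shape[0] * ps for p in predictions)
    rows, cols = round((y1 - y0) / ps), round((x1 - x0) / ps)
    out = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            px, py = x0 + (c + 0.5) * ps, y1 - (r + 0.5) * ps
            num = den = 0.0
            for p in predictions:
                side = p.tile.shape[0]
                cc = (px - p.transform.c) / ps - 0.5
                rr = (p.transform.f - py) / ps - 0.5
                ci, ri = round(cc), round(rr)
                if 0 <= ci < side and 0 <= ri < side:
                    d = np.hypot(px - p.center[0], py - p.center[1])
                    w = 1.0 / max(d, D_MIN_M)
                    num += w * p.tile[ri, ci]
                    den += w
            if den:
                out[r, c] = num / den
    return out


class TestPlanWindows:
    def test_region_of_one_window_gives_one_center(self):
        centers = plan_windows((0, 0, 1280, 1280))
        assert centers == [(640.0, 640.0)]

    def test_stride_arithmetic(self):
        centers = plan_windows((0, 0, 1280 + 210, 1280 + 210), stride=210)
        xs = sorted({c[0] for c in centers})
        ys = sorted({c[1] for c in centers})
        assert len(xs) == 2 and len(ys) == 2
        assert xs == [640.0, 850.0]

    @pytest.mark.parametrize("span", [(400, 730), (1000, 411), (350, 350)])
    def test_every_interior_pixel_is_covered(self, span):
        window, stride, ps = 200.0, 70.0, 10.0
        bounds = (0.0, 0.0, float(span[0]), float(span[1]))
        centers = plan_windows(bounds, stride=stride, window=window)
        xs = np.arange(ps / 2, span[0], ps)
        ys = np.arange(ps / 2, span[1], ps)
        for x in xs:
            assert any(abs(x - cx) <= window / 2 for cx, _ in centers)
        for y in ys:
            assert any(abs(y - cy) <= window / 2 for _, cy in centers)


class TestStitch:
    def test_single_window_is_identity(self, rng):
        tile = rng.random((8, 8))
        out = stitch([WindowPrediction(center=(40.0, 40.0), tile=tile)])
        assert np.allclose(out.data, tile)
        assert out.valid.all()

    def test_constant_windows_stitch_to_constant(self):
        preds = [
            WindowPrediction(center=(40.0, 40.0), tile=np.full((8, 8), 0.37)),
            WindowPrediction(center=(70.0, 40.0), tile=np.full((8, 8), 0.37)),
        ]
        out = stitch(preds)
        assert np.allclose(out.data[out.valid], 0.37)

    def test_matches_independent_scalar_oracle(self, rng):
        preds = [
            WindowPrediction(center=(20.0, 30.0), tile=rng.random((4, 4))),
            WindowPrediction(center=(40.0, 30.0), tile=rng.random((4, 4))),
            WindowPrediction(center=(30.0, 50.0), tile=rng.random((4, 4))),
        ]
        out = stitch(preds)
        oracle = stitch_oracle(preds)
        assert np.allclose(out.data[out.valid], oracle[out.valid])
        assert np.array_equal(out.valid, ~np.isnan(oracle))

    def test_two_window_hand_case(self):
        # two 2x2 windows sharing one column; hand-set values
        a = WindowPrediction(center=(10.0, 10.0), tile=np.array([[0.2, 0.4], [0.2, 0.4]]))
        b = WindowPrediction(center=(20.0, 10.0), tile=np.array([[0.8, 0.6], [0.8, 0.6]]))
        out = stitch([a, b])
        # overlap columns are at x=5..15 and 15..25? windows span x 0..20 and 10..30
        # pixel at x=12.5? grid pixels: x centers 5,15,25; shared column x=15:
        # from a: tile col 1 (0.4), d_a = hypot(5, 5); from b: col 0 (0.8), d_b = hypot(-5,5)
        d = np.hypot(5.0, 5.0)
        w = 1.0 / d
        expected_mid = (w * 0.4 + w * 0.8) / (2 * w)
        assert out.data[0, 1] == pytest.approx(expected_mid)
        assert out.data[0, 0] == pytest.approx(0.2)  # only window a covers it
        assert out.data[0, 2] == pytest.approx(0.6)

    def test_convex_combination_bound(self, rng):
        preds = [
            WindowPrediction(
                center=(float(cx), float(cy)), tile=rng.random((6, 6))
            )
            for cx, cy in [(30, 30), (60, 40), (40, 60), (70, 70)]
        ]
        out = stitch(preds)
        lo = np.full(out.data.shape, np.inf)
        hi = np.full(out.data.shape, -np.inf)
        ps = 10.0
        for p in preds:
            r0 = round((out.transform.f - p.transform.f) / ps)
            c0 = round((p.transform.c - out.transform.c) / ps)
            sl = (slice(r0, r0 + 6), slice(c0, c0 + 6))
            lo[sl] = np.minimum(lo[sl], p.tile)
            hi[sl] = np.maximum(hi[sl], p.tile)
        v = out.valid
        assert (out.data[v] >= lo[v] - 1e-12).all()
        assert (out.data[v] <= hi[v] + 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stitch([])


class TestQuantization:
    def test_endpoints_and_recommended_threshold_are_exact(self):
        assert quantize(1.0) == 250 and dequantize(250) == 1.0
        assert quantize(0.52) == 130 and dequantize(130) == 0.52
        assert quantize(0.0) == 0

    def test_round_trip_error_bounded_by_half_step(self):
        p = np.linspace(0, 1, 100_001)
        err = np.abs(p - dequantize(quantize(p)))
        assert err.max() <= 0.002 * (1 + 1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.array([1.2]))
        with pytest.raises(ValueError):
            dequantize(np.array([251]))

    def test_threshold_invariant_to_monotone_rescaling(self, rng):
        p = rng.random(1000)
        t = 0.52
        p = p[np.abs(p - t) > 1e-6]  # ties excluded
        f = lambda x: x**3 / (x**3 + (1 - x) ** 3)  # strictly monotone on [0,1]
        assert np.array_equal(p >= t, f(p) >= f(t))


class TestQuantizationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_error_within_half_step_for_any_probability(self, p):
        back = float(dequantize(quantize(p)))
        assert abs(back - p) <= 0.002 * (1 + 1e-9)
        assert 0.0 <= back <= 1.0

    @given(st.integers(min_value=0, max_value=250))
    @settings(derandomize=True, max_examples=100)
    def test_quantize_inverts_dequantize_exactly_on_the_grid(self, q):
        assert int(quantize(float(dequantize(q)))) == q


class TestTileIO:
    @staticmethod
    def _pmap(rng, rows=40, cols=52):
        data = rng.random((rows, cols))
        valid = np.ones((rows, cols), bool)
        valid[0, :5] = False
        return ProbabilityMap(
            data=data,
            transform=Affine.from_origin(500_000.0, 6_000_000.0, 10.0, 10.0),
            crs="EPSG:32633",
            valid=valid,
        )

    def test_write_read_round_trip_is_lossless(self, tmp_path, rng):
        pmap = self._pmap(rng)
        write_tiles(pmap, tmp_path)
        back = read_tiles(tmp_path)
        q = np.where(pmap.valid, quantize(pmap.data), 255)
        assert np.array_equal(back.data, q.astype(np.uint8))
        assert back.transform == pmap.transform
        assert back.crs == pmap.crs
        assert np.array_equal(back.valid, pmap.valid)

    def test_mosaic_of_tiles_equals_pre_split_raster(self, tmp_path, rng):
        from forestmap.mapping import TilingConfig

        pmap = self._pmap(rng, 64, 64)
        write_tiles(pmap, tmp_path, TilingConfig(tile_rows=32, tile_cols=32))
        assert len(list(tmp_path.glob("tile_*.tif"))) == 4
        back = read_tiles(tmp_path)
        assert np.array_equal(back.data[back.valid], quantize(pmap.data)[pmap.valid])

    def test_written_values_never_exceed_250_except_nodata(self, tmp_path, rng):
        import tifffile

        write_tiles(self._pmap(rng), tmp_path)
        for f in tmp_path.glob("tile_*.tif"):
            arr = tifffile.imread(f)
            assert arr.dtype == np.uint8
            assert arr[arr != 255].max() <= 250

    def test_crs_mismatch_on_mosaic_read_raises(self, tmp_path, rng):
        import json

        import tifffile

        pmap = self._pmap(rng)
        paths = write_tiles(pmap, tmp_path, tiling=None)
        # rewrite one tile with a different CRS
        other = self._pmap(rng)
        other.crs = "EPSG:32634"
        sub = tmp_path / "mixed"
        sub.mkdir()
        write_tiles(pmap, sub)
        arr = tifffile.imread(paths[0])
        meta = {"transform": [10, 0, 0, 0, -10, 0], "crs": "EPSG:4326", "nodata": 255}
        tifffile.imwrite(sub / "tile_zzz.tif", arr, description=json.dumps(meta))
        # glob picks it up only if it matches the pattern
        (sub / "tile_zzz.tif").rename(sub / "tile_999999_000000.tif")
        with pytest.raises(ValueError, match="CRS"):
            read_tiles(sub)

    def test_probability_map_invariants(self, rng):
        with pytest.raises(ValueError):
            ProbabilityMap(
                data=np.array([[1.5]]),
                transform=Affine.from_origin(0, 0, 10, 10),
            ).validate()
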