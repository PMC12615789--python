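"""Overlapping-window inference, inverse-distance stitching, and tile I/O.

A region is covered by 1280 m windows whose centres sit on a regular grid
(default stride 210 m, giving heavy overlap). Predictions for a pixel seen
by several windows are averaged with weights 1 / max(d, 5 m), where d is
the Euclidean distance from the pixel centre to the window centre — the
5 m floor (half a pixel) removes the singularity at the centre pixel.
Probabilities are quantized to 0-250 for storage (resolution 1/250 = 0.4%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geo import Affine
from .model import Model, ensemble_predict
from .synthetic import PIXEL_SIZE
from .types import NATURAL_FOREST, SceneSample

WINDOW_M = 1280.0
DEFAULT_STRIDE_M = 210.0
D_MIN_M = 5.0
NODATA = 255


@dataclass
class ProbabilityMap:
    """Georeferenced natural-forest probability raster.

    ``data`` is float in [0, 1] or quantized uint8 in 0..250; ``valid``
    marks pixels covered by at least one window.
    """

    data: np.ndarray
    transform: Affine
    crs: str = "EPSG:32633"
    valid: np.ndarray | None = None

    def validate(self) -> None:
        if self.data.dtype == np.uint8:
            if self.data[self.mask_valid()].max(initial=0) > 250:
                raise ValueError("quantized values must not exceed 250")
        else:
            v = self.data[self.mask_valid()]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("probabilities must lie in [0, 1]")

    def mask_valid(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.data.shape, bool)
        return self.valid


@dataclass
class WindowPrediction:
    """One inference window: class-1 probability tile plus its placement."""

    center: tuple[float, float]          # map coordinates (m)
    tile: np.ndarray                     # (side, side) probability
    transform: Affine = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.transform is None:
            side = self.tile.shape[0]
            half = side * PIXEL_SIZE / 2.0
            self.transform = Affine.from_origin(
                self.center[0] - half, self.center[1] + half, PIXEL_SIZE, PIXEL_SIZE
            )


def plan_windows(
    bounds: tuple[float, float, float, float],
    stride: float = DEFAULT_STRIDE_M,
    window: float = WINDOW_M,
) -> list[tuple[float, float]]:
    """Regular grid of window centres covering the region interior.

    Centres step by ``stride`` from the region's min corner; a final centre
    is clamped to the max edge whenever the stride grid would leave a strip
    uncovered. A region smaller than one window gets a single centred
    window.
    """
    xmin, ymin, xmax, ymax = bounds

    def axis_centers(lo: float, hi: float) -> list[float]:
        span = hi - lo
        if span <= window:
            return [(lo + hi) / 2.0]
        centers = list(np.arange(lo + window / 2.0, hi - window / 2.0 + 1e-9, stride))
        if centers[-1] < hi - window / 2.0 - 1e-9:
            centers.append(hi - window / 2.0)
        return centers

    return [(x, y) for y in axis_centers(ymin, ymax) for x in axis_centers(xmin, xmax)]


def predict_windows(
    models: list[Model],
    scene_for_center,
    centers: list[tuple[float, float]],
) -> list[WindowPrediction]:
    """Run the ensemble at every window centre.

    ``scene_for_center(cx, cy) -> SceneSample`` supplies the input window;
    the stored tile is the natural-forest class probability.
    """
    preds = []
    for cx, cy in centers:
        sample: SceneSample = scene_for_center(cx, cy)
        probs = ensemble_predict(models, sample)
        preds.append(WindowPrediction(center=(cx, cy), tile=probs[:, :, NATURAL_FOREST - 1]))
    return preds


def _window_weights(side: int, pixel: float = PIXEL_SIZE) -> np.ndarray:
    """Inverse-distance weights of a window's pixels to its own centre."""
    idx = (np.arange(side) - (side - 1) / 2.0) * pixel
    d = np.hypot(idx[:, None], idx[None, :])
    return 1.0 / np.maximum(d, D_MIN_M)


def stitch(predictions: list[WindowPrediction], crs: str = "EPSG:32633") -> ProbabilityMap:
    """Inverse-distance weighted average of overlapping window predictions.

    Output pixels covered by no window are flagged invalid (nodata).
    """
    if not predictions:
        raise ValueError("no window predictions to stitch")
    ps = PIXEL_SIZE
    x0 = min(p.transform.c for p in predictions)
    y1 = max(p.transform.f for p in predictions)
    x1 = max(p.transform.c + p.tile.shape[1] * ps for p in predictions)
    y0 = min(p.transform.f - p.tile.shape[0] * ps for p in predictions)
    cols = int(round((x1 - x0) / ps))
    rows = int(round((y1 - y0) / ps))

    def placement(p: WindowPrediction) -> tuple[int, int]:
        r_off = (y1 - p.transform.f) / ps
        c_off = (p.transform.c - x0) / ps
        if abs(r_off - round(r_off)) > 1e-6 or abs(c_off - round(c_off)) > 1e-6:
            raise ValueError("window grids must share one pixel lattice")
        return int(round(r_off)), int(round(c_off))

    # Weighted mean computed as anchor + sum(w * (p - anchor)) / sum(w),
    # where the anchor is the first window covering each pixel: identical to
    # the plain weighted mean, but exactly value-preserving for pixels seen
    # by one window only and for constant fields (zero inter-window seams).
    anchor = np.zeros((rows, cols))
    covered = np.zeros((rows, cols), bool)
    for p in predictions:
        side_r, side_c = p.tile.shape
        if side_r != side_c:
            raise ValueError("window tiles must be square")
        r0, c0 = placement(p)
        sl = (slice(r0, r0 + side_r), slice(c0, c0 + side_c))
        new = ~covered[sl]
        anchor[sl][new] = p.tile[new]
        covered[sl] = True
    acc = np.zeros((rows, cols))
    wsum = np.zeros((rows, cols))
    for p in predictions:
        side = p.tile.shape[0]
        r0, c0 = placement(p)
        sl = (slice(r0, r0 + side), slice(c0, c0 + side))
        w = _window_weights(side)
        acc[sl] += w * (p.tile - anchor[sl])
        wsum[sl] += w
    valid = covered
    data = anchor.copy()
    data[valid] += acc[valid] / wsum[valid]
    data[valid] = np.clip(data[valid], 0.0, 1.0)
    out = ProbabilityMap(
        data=data, transform=Affine.from_origin(x0, y1, ps, ps), crs=crs, valid=valid
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# quantization

def quantize(p: np.ndarray | float) -> np.ndarray:
    """Probability in [0, 1] -> integer 0..250, round half to even."""
    arr = np.asarray(p, dtype=np.float64)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.round(arr * 250.0).astype(np.uint8)


def dequantize(q: np.ndarray | int) -> np.ndarray:
    """Integer 0..250 -> probability q / 250."""
    arr = np.asarray(q)
    if arr.size and arr.max(initial=0) > 250:
        raise ValueError("quantized values must lie in 0..250")
    return arr.astype(np.float64) / 250.0


# ---------------------------------------------------------------------------
# tile I/O

@dataclass
class TilingConfig:
    tile_rows: int = 256
    tile_cols: int = 256


def write_tiles(pmap: ProbabilityMap, directory, tiling: TilingConfig | None = None) -> list[Path]:
    """Persist a probability map as quantized uint8 tiles (nodata 255).

    Each tile is a tiled TIFF carrying its affine transform, CRS and nodata
    value in a JSON description tag; the round trip through
    :func:`read_tiles` is lossless on the quantized band.
    """
    tiling = tiling or TilingConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if pmap.data.dtype == np.uint8:
        q = pmap.data.copy()
    else:
        q = quantize(pmap.data)
    q[~pmap.mask_valid()] = NODATA
    ps_x, ps_y = pmap.transform.a, -pmap.transform.e
    paths = []
    rows, cols = q.shape
    for r0 in range(0, rows, tiling.tile_rows):
        for c0 in range(0, cols, tiling.tile_cols):
            block = q[r0 : r0 + tiling.tile_rows, c0 : c0 + tiling.tile_cols]
            x, y = pmap.transform.xy(r0, c0, offset="ul")
            meta = {
                "transform": Affine.from_origin(x, y, ps_x, ps_y).to_list(),
                "crs": pmap.crs,
                "nodata": NODATA,
            }
            path = directory / f"tile_{r0:06d}_{c0:06d}.tif"
            kwargs = {"tile": (256, 256)} if min(block.shape) >= 16 else {}
            tifffile.imwrite(path, block, description=json.dumps(meta), **kwargs)
            paths.append(path)
    return paths


def read_tiles(directory) -> ProbabilityMap:
    """Mosaic quantized tiles back into one uint8 probability map."""
    directory = Path(directory)
    paths = sorted(directory.glob("tile_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no tiles found under {directory}")
    tiles = []
    crs = None
    for path in paths:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            meta = json.loads(page.description)
            if crs is None:
                crs = meta["crs"]
            elif meta["crs"] != crs:
                raise ValueError(f"CRS mismatch in mosaic: {meta['crs']} vs {crs}")
            tiles.append((Affine.from_list(meta["transform"]), page.asarray()))
    ps = tiles[0][0].a
    x0 = min(t.c for t, _ in tiles)
    y1 = max(t.f for t, _ in tiles)
    x1 = max(t.c + arr.shape[1] * ps for t, arr in tiles)
    y0 = min(t.f - arr.shape[0] * ps for t, arr in tiles)
    rows = int(round((y1 - y0) / ps))
    cols = int(round((x1 - x0) / ps))
    data = np.full((rows, cols), NODATA, np.uint8)
    for t, arr in tiles:
        r0 = int(round((y1 - t.f) / ps))
        c0 = int(round((t.c - x0) / ps))
        data[r0 : r0 + arr.shape[0], c0 : c0 + arr.shape[1]] = arr
    valid = data != NODATA
    out = ProbabilityMap(
        data=data, transform=Affine.from_origin(x0, y1, ps, ps), crs=crs, valid=valid
    )
    out.validate()
    return out
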