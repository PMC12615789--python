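"""Seeded synthetic scenes, label-source stacks, and stratified validation sets.

The generator emulates the statistical structure the mapping method relies
on, without any geographic realism: land-cover classes form contiguous
blobs, each class follows its own seasonal mean spectrum with spatially
correlated noise, plantation-like classes carry periodic row/grid texture
while natural forest carries unstructured correlated texture, and the label
sources are the true class maps corrupted at configurable false-positive /
false-negative rates. Everything is a pure function of (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import correlate, gaussian_filter

from .geo import Affine
from .types import (
    NATURAL_FOREST,
    PLANTED_FOREST,
    SceneSample,
    SourceStack,
    StrataSpec,
    TREE_CROPS,
    ValidationPlot,
)

PIXEL_SIZE = 10.0  # metres
PLOT_PIXELS = 10   # 100 m plot side at 10 m pixels

#: pixel-level class fractions the generator targets by default, shaped after
#: the training-data composition (natural forest ~34%, hard negatives ~38%).
DEFAULT_FRACTIONS: dict[int, float] = {
    1: 0.34, 2: 0.10, 3: 0.08, 4: 0.20, 5: 0.06, 6: 0.10, 7: 0.04, 8: 0.08,
}


def _seasonal_spectra() -> np.ndarray:
    """Mean reflectance per (class 0..8, season DJF..SON, band B2..B12)."""
    spec = np.zeros((9, 4, 10), np.float64)
    # base spectra: visible (B2-B4), red edge (B5-B7), NIR (B8, B8A), SWIR (B11, B12)
    base = {
        0: [0.10, 0.10, 0.10, 0.12, 0.15, 0.18, 0.20, 0.20, 0.15, 0.12],
        1: [0.03, 0.05, 0.04, 0.08, 0.18, 0.26, 0.30, 0.32, 0.16, 0.08],  # natural forest
        2: [0.03, 0.05, 0.04, 0.09, 0.21, 0.30, 0.35, 0.37, 0.18, 0.09],  # planted forest
        3: [0.05, 0.07, 0.06, 0.11, 0.22, 0.28, 0.33, 0.34, 0.22, 0.12],  # tree crops
        4: [0.06, 0.09, 0.08, 0.14, 0.24, 0.30, 0.36, 0.38, 0.26, 0.16],  # other vegetation
        5: [0.16, 0.17, 0.18, 0.19, 0.20, 0.21, 0.22, 0.22, 0.24, 0.23],  # built
        6: [0.05, 0.04, 0.03, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02],  # water
        7: [0.60, 0.62, 0.60, 0.58, 0.55, 0.52, 0.50, 0.48, 0.08, 0.05],  # ice/snow
        8: [0.22, 0.26, 0.30, 0.32, 0.33, 0.34, 0.34, 0.35, 0.40, 0.38],  # bare/sparse
    }
    # per-class seasonal modulation (phenology amplitude; strongest for
    # seasonal vegetation, flat for water/built/bare)
    amp = {0: 0.02, 1: 0.05, 2: 0.04, 3: 0.08, 4: 0.15, 5: 0.00, 6: 0.00, 7: 0.10, 8: 0.02}
    season_factor = np.array([-1.0, 0.2, 1.0, 0.0])  # DJF, MAM, JJA, SON (north)
    veg_weight = np.array([0, 0, 0, 0.2, 0.5, 0.8, 1.0, 1.0, 0.4, 0.2])
    for c in range(9):
        for t in range(4):
            spec[c, t] = np.asarray(base[c]) * (1.0 + amp[c] * season_factor[t] * veg_weight)
    return spec


CLASS_SPECTRA = _seasonal_spectra()


@dataclass
class LayoutConfig:
    """Scene layout: target class fractions, texture/noise/separation dials.

    ``noise_sigma`` is the standard deviation of spatially correlated
    reflectance noise; ``separation`` scales every class spectrum away from
    (>1) or towards (<1) the all-class mean; ``source_fp``/``source_fn`` are
    the per-layer flip rates used to corrupt the label sources.
    """

    size: int = 128
    class_fractions: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    noise_sigma: float = 0.02
    correlation_length: float = 4.0
    separation: float = 1.0
    texture_amplitude: float = 0.03
    texture_period: float = 6.0
    source_fp: float = 0.02
    source_fn: float = 0.02
    water_nir_swir_ceiling: float = 0.08
    latitude: float | None = None

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {total:.3f} > 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if any(not 1 <= c <= 8 for c in self.class_fractions):
            raise ValueError("class fraction codes must lie in 1..8")


def high_separation_layout(size: int = 128, **kw) -> LayoutConfig:
    """Preset with widely separated class spectra and noiseless sources,
    used for learning checks where label quality must not be the bottleneck."""
    return LayoutConfig(
        size=size, noise_sigma=0.0, separation=2.0, texture_amplitude=0.02,
        source_fp=0.0, source_fn=0.0, **kw,
    )


# ---------------------------------------------------------------------------
# topography

_HORN_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], np.float64)


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated Gaussian field."""
    f = gaussian_filter(rng.standard_normal((size, size)), sigma=sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def horn_slope_aspect(elevation: np.ndarray, cell: float = PIXEL_SIZE) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and downslope aspect (degrees clockwise from north).

    3x3 weighted finite differences on a regular grid; flat pixels take
    aspect 0 by convention. Rows increase southward.
    """
    dzdx = correlate(elevation, _HORN_X / (8.0 * cell), mode="nearest")          # east
    dzdy_north = correlate(elevation, -_HORN_X.T / (8.0 * cell), mode="nearest")  # north
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy_north)))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy_north)) % 360.0
    aspect[slope == 0.0] = 0.0
    return slope, aspect


def generate_topography(seed: int, size: int) -> np.ndarray:
    """Terrain stack (1, size, size, 3): elevation (m), slope (deg), aspect (deg)."""
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    elevation = 600.0 + 250.0 * _smooth_field(rng, size, sigma=size / 8.0)
    slope, aspect = horn_slope_aspect(elevation)
    return np.stack([elevation, slope, aspect], axis=-1)[None]


# ---------------------------------------------------------------------------
# scenes

def _blob_labels(rng: np.random.Generator, cfg: LayoutConfig) -> np.ndarray:
    """Contiguous class blobs whose realized fractions track the targets.

    Level sets of a smooth random field are partitioned at the target
    cumulative fractions, so realized areas are exact to within ties and the
    regions are spatially contiguous blobs.
    """
    s = cfg.size
    f = _smooth_field(rng, s, sigma=s / 10.0)
    ranks = f.ravel().argsort().argsort() / (s * s)
    labels = np.zeros(s * s, np.int64)
    lo = 0.0
    for c, frac in cfg.class_fractions.items():
        labels[(ranks >= lo) & (ranks < lo + frac)] = c
        lo += frac
    return labels.reshape(s, s)


def _corrupt(mask: np.ndarray, fp: float, fn: float, rng: np.random.Generator) -> np.ndarray:
    """Flip a boolean layer at the configured false-positive/negative rates."""
    u = rng.random(mask.shape)
    out = mask.copy()
    out[~mask & (u < fp)] = True
    out[mask & (u < fn)] = False
    return out


def _latlon_to_unit(lat: float, lon: float) -> np.ndarray:
    la, lo = np.radians(lat), np.radians(lon)
    v = np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])
    return v / np.linalg.norm(v)


def generate_scene(seed: int, layout: LayoutConfig | None = None) -> tuple[SceneSample, SourceStack]:
    """One synthetic scene plus the label-source stack derived from its truth."""
    cfg = layout or LayoutConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    s = cfg.size

    labels = _blob_labels(rng, cfg)
    lat = cfg.latitude if cfg.latitude is not None else float(rng.uniform(-60.0, 70.0))
    lon = float(rng.uniform(-180.0, 180.0))

    # class spectra, pulled towards/away from the all-class mean by the
    # separation dial, with the phenology phase flipped south of the equator
    spectra = CLASS_SPECTRA.copy()
    mean_spec = spectra[1:].mean(axis=0, keepdims=True)
    spectra = np.clip(mean_spec + cfg.separation * (spectra - mean_spec), 0.0, 1.0)
    if lat < 0:
        spectra = np.roll(spectra, 2, axis=1)  # swap summer/winter composites

    s2 = spectra[labels]                # (s, s, 4, 10)
    s2 = s2.transpose(2, 0, 1, 3)       # (4, s, s, 10)

    # plantation row texture / tree-crop grid texture / natural heterogeneity
    ri, ci = np.mgrid[0:s, 0:s].astype(np.float64)
    theta = rng.uniform(0.0, np.pi)
    rows_pat = np.sin(2 * np.pi * (ci * np.cos(theta) + ri * np.sin(theta)) / cfg.texture_period)
    grid_pat = np.sin(2 * np.pi * ci / cfg.texture_period) * np.sin(2 * np.pi * ri / cfg.texture_period)
    natural_pat = _smooth_field(rng, s, sigma=2.0)
    texture = (
        rows_pat * (labels == PLANTED_FOREST)
        + grid_pat * (labels == TREE_CROPS)
        + natural_pat * (labels == NATURAL_FOREST)
    )
    for band in (2, 6, 7):  # red + NIR bands carry the canopy texture
        s2[:, :, :, band] += cfg.texture_amplitude * texture

    if cfg.noise_sigma > 0:
        for t in range(4):
            for b in range(10):
                s2[t, :, :, b] += cfg.noise_sigma * _smooth_field(rng, s, cfg.correlation_length)
    s2 = np.clip(s2, 0.0, 1.0)

    topo = generate_topography(int(rng.integers(2**31)), s)
    transform = Affine.from_origin(300000.0, 6000000.0, PIXEL_SIZE, PIXEL_SIZE)
    sample = SceneSample(
        s2=s2.astype(np.float32),
        topo=topo.astype(np.float32),
        loc=_latlon_to_unit(lat, lon).astype(np.float32),
        labels=labels,
        transform=transform,
    )

    fp, fn = cfg.source_fp, cfg.source_fn
    natural = labels == NATURAL_FOREST
    stack = SourceStack(
        natural_sources={
            "tmf_natural": _corrupt(natural, fp, fn, rng),
            "sbtn_natural": _corrupt(natural, fp, fn, rng),
        },
        planted_sources={"sdpt_planted": _corrupt(labels == PLANTED_FOREST, fp, fn, rng)},
        treecrop_sources={"crop_polygons": _corrupt(labels == TREE_CROPS, fp, fn, rng)},
        other_sources={
            4: {
                "worldcover_veg": _corrupt(labels == 4, fp, fn, rng),
                "sbtn_nonforest": _corrupt(labels == 4, fp, fn, rng),
            },
            5: {"worldcover_built": _corrupt(labels == 5, fp, fn, rng)},
            6: {"worldcover_water": _corrupt(labels == 6, fp, fn, rng)},
            7: {"worldcover_ice": _corrupt(labels == 7, fp, fn, rng)},
            8: {"worldcover_bare": _corrupt(labels == 8, fp, fn, rng)},
        },
        forest_type=_corrupt(np.isin(labels, (1, 2)), fp, fn, rng),
        tree_height=np.where(
            natural, 18.0 + 4.0 * _smooth_field(rng, s, 6.0),
            np.where(labels == PLANTED_FOREST, 14.0 + 2.0 * _smooth_field(rng, s, 6.0),
                     np.where(labels == TREE_CROPS, 4.0, 0.5)),
        ).clip(0.0, None),
        loss_year=np.zeros((s, s), np.int64),
        driver_class=np.zeros((s, s), np.int64),
        gfm_p_natural=np.where(_corrupt(natural, fp, fn, rng), 0.9, 0.05),
        tree_cover_2000=np.where(np.isin(labels, (1, 2)), 80.0,
                                 np.where(labels == TREE_CROPS, 40.0, 2.0)),
    )
    return sample, stack


# ---------------------------------------------------------------------------
# stratified validation sampling

class InsufficientPopulationError(ValueError):
    """A stratum holds fewer population units than the requested sample."""


def generate_validation_set(
    seed: int,
    strata_spec: StrataSpec,
    truth_map: np.ndarray,
    n_per_stratum: int | dict[int, int],
    transform: Affine | None = None,
) -> list[ValidationPlot]:
    """Sample plots uniformly without replacement within each stratum.

    The plot population is the grid of non-overlapping 10x10-pixel (100 m)
    footprints; a plot's stratum is read from ``strata_spec.raster`` at the
    footprint centre and its reference label is the strict majority of
    natural-forest truth within the footprint. ``strata_spec.sizes`` is
    filled with the census population counts when empty.
    """
    if strata_spec.raster is None:
        raise ValueError("strata_spec.raster is required to place plots")
    if strata_spec.raster.shape != truth_map.shape:
        raise ValueError("strata raster must share the truth-map grid")
    rng = np.random.default_rng(seed)
    rows, cols = truth_map.shape
    gr, gc = rows // PLOT_PIXELS, cols // PLOT_PIXELS
    if transform is None:
        transform = Affine.from_origin(0.0, rows * PIXEL_SIZE, PIXEL_SIZE, PIXEL_SIZE)

    block_stratum = strata_spec.raster[
        PLOT_PIXELS // 2 :: PLOT_PIXELS, PLOT_PIXELS // 2 :: PLOT_PIXELS
    ][:gr, :gc]
    strata = np.unique(block_stratum)
    census = {int(h): int((block_stratum == h).sum()) for h in strata}
    if not strata_spec.sizes:
        strata_spec.sizes = {h: float(n) for h, n in census.items()}

    plots: list[ValidationPlot] = []
    for h in sorted(census):
        n_h = n_per_stratum[h] if isinstance(n_per_stratum, dict) else n_per_stratum
        if n_h < 2:
            raise ValueError("n_per_stratum must be >= 2 for variance estimation")
        candidates = np.flatnonzero(block_stratum.ravel() == h)
        if n_h > candidates.size:
            raise InsufficientPopulationError(
                f"stratum {h} holds {candidates.size} plots, {n_h} requested"
            )
        chosen = rng.choice(candidates, size=n_h, replace=False)
        for k, flat in enumerate(np.sort(chosen)):
            br, bc = divmod(int(flat), gc)
            r0, c0 = br * PLOT_PIXELS, bc * PLOT_PIXELS
            footprint = truth_map[r0 : r0 + PLOT_PIXELS, c0 : c0 + PLOT_PIXELS]
            ref = int((footprint == NATURAL_FOREST).mean() > 0.5)
            x, y = transform.xy(r0 + PLOT_PIXELS / 2 - 0.5, c0 + PLOT_PIXELS / 2 - 0.5)
            plots.append(
                ValidationPlot(
                    plot_id=f"s{h}_{k:05d}", lon=x, lat=y, ref_label=ref, stratum=int(h)
                )
            )
    return plots


# ---------------------------------------------------------------------------
# persistence (multi-band TIFF + YAML sidecar)

def save_scene(sample: SceneSample, directory) -> None:
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "s2.tif", sample.s2)
    tifffile.imwrite(directory / "topo.tif", sample.topo)
    tifffile.imwrite(directory / "labels.tif", sample.labels.astype(np.uint8))
    sidecar = {
        "loc": [float(v) for v in sample.loc],
        "transform": sample.transform.to_list(),
        "crs": sample.crs,
    }
    (directory / "scene.yaml").write_text(yaml.safe_dump(sidecar))


def load_scene(directory) -> SceneSample:
    import tifffile

    directory = Path(directory)
    meta = yaml.safe_load((directory / "scene.yaml").read_text())
    return SceneSample(
        s2=tifffile.imread(directory / "s2.tif"),
        topo=tifffile.imread(directory / "topo.tif"),
        loc=np.asarray(meta["loc"], np.float32),
        labels=tifffile.imread(directory / "labels.tif").astype(np.int64),
        transform=Affine.from_list(meta["transform"]),
        crs=meta["crs"],
    )
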