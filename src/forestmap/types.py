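"""Core domain containers shared across the mapping pipeline.

The land-cover legend uses nine codes: 0 marks pixels whose label could not
be established from the available sources ("unknown") and is never a
prediction target; codes 1-8 are the eight mapped classes, with natural
forest (1) the class of interest, planted forest (2) and tree crops (3) the
hard negatives, and the remaining codes the spectrally distinct covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .geo import Affine

UNKNOWN = 0
NATURAL_FOREST = 1
PLANTED_FOREST = 2
TREE_CROPS = 3
OTHER_VEGETATION = 4
BUILT = 5
WATER = 6
ICE_SNOW = 7
BARE_SPARSE = 8

CLASS_NAMES: dict[int, str] = {
    UNKNOWN: "unknown",
    NATURAL_FOREST: "natural forest",
    PLANTED_FOREST: "planted forest",
    TREE_CROPS: "tree crops",
    OTHER_VEGETATION: "other vegetation",
    BUILT: "built",
    WATER: "water",
    ICE_SNOW: "ice/snow",
    BARE_SPARSE: "bare/sparse",
}

N_CLASSES = 8  # prediction targets, codes 1..8 -> logit index 0..7

#: Sentinel-2 band order used throughout (10 land-cover-sensitive bands).
S2_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

#: Forest-loss driver codes carried by the driver layer.
DRIVER_PERMANENT_AGRICULTURE = 1
DRIVER_HARD_COMMODITIES = 2
DRIVER_SHIFTING_CULTIVATION = 3
DRIVER_LOGGING = 4
DRIVER_WILDFIRE = 5
DRIVER_SETTLEMENTS = 6
DRIVER_OTHER_NATURAL = 7

NATURAL_DISTURBANCE_DRIVERS = frozenset({DRIVER_WILDFIRE, DRIVER_OTHER_NATURAL})
PERMANENT_CONVERSION_DRIVERS = frozenset(
    {DRIVER_PERMANENT_AGRICULTURE, DRIVER_HARD_COMMODITIES, DRIVER_SETTLEMENTS}
)


@dataclass
class SceneSample:
    """One 10 m training/inference unit.

    s2
        Seasonal surface-reflectance stack, shape (4, rows, cols, 10),
        unitless reflectance in [0, 1], seasons ordered DJF/MAM/JJA/SON.
    topo
        Terrain stack, shape (1, rows, cols, 3): elevation (m), slope
        (degrees, >= 0), aspect (degrees clockwise from north, 0 on flats).
    loc
        Unit-sphere Cartesian coordinates of the scene centre.
    labels
        Integer raster (rows, cols) with values 0..8.
    """

    s2: np.ndarray
    topo: np.ndarray
    loc: np.ndarray
    labels: np.ndarray
    transform: Affine
    crs: str = "EPSG:32633"

    @property
    def size(self) -> int:
        return self.labels.shape[0]

    def validate(self) -> None:
        t, r, c, b = self.s2.shape
        if (t, b) != (4, 10):
            raise ValueError(f"s2 must be (4, rows, cols, 10), got {self.s2.shape}")
        if self.topo.shape != (1, r, c, 3):
            raise ValueError(f"topo must be (1, {r}, {c}, 3), got {self.topo.shape}")
        if self.labels.shape != (r, c):
            raise ValueError("labels grid inconsistent with s2")
        if not np.isfinite(self.s2).all() or self.s2.min() < 0 or self.s2.max() > 1:
            raise ValueError("s2 reflectance must be finite and in [0, 1]")
        if abs(float(np.linalg.norm(self.loc)) - 1.0) > 1e-9:
            raise ValueError("loc must have unit Euclidean norm")
        if self.labels.min() < 0 or self.labels.max() > 8:
            raise ValueError("labels must lie in 0..8")
        if (self.topo[0, :, :, 1] < 0).any():
            raise ValueError("slope must be non-negative")


@dataclass
class SourceStack:
    """Named label-source and supporting rasters aligned to one scene grid.

    Boolean layers mimic rasterized source datasets (tropical-moist-forest
    types, natural-land maps, planted-tree databases, land-cover products);
    supporting layers carry canopy height, loss year, loss driver, the
    managed-forest-model natural probability, and year-2000 tree cover.
    """

    natural_sources: Mapping[str, np.ndarray]
    planted_sources: Mapping[str, np.ndarray]
    treecrop_sources: Mapping[str, np.ndarray]
    # class code (4..8) -> {source name -> boolean raster}
    other_sources: Mapping[int, Mapping[str, np.ndarray]]
    forest_type: np.ndarray        # boolean forest-type layer
    tree_height: np.ndarray        # metres
    loss_year: np.ndarray          # 0 = no loss, else 2001..2020
    driver_class: np.ndarray       # 0 = none, else 1..7
    gfm_p_natural: np.ndarray      # probability in [0, 1]
    tree_cover_2000: np.ndarray    # percent 0..100

    def grid_shape(self) -> tuple[int, int]:
        return self.tree_height.shape

    def validate(self) -> None:
        shape = self.grid_shape()
        layers: list[np.ndarray] = [
            self.forest_type, self.tree_height, self.loss_year,
            self.driver_class, self.gfm_p_natural, self.tree_cover_2000,
        ]
        for group in (self.natural_sources, self.planted_sources, self.treecrop_sources):
            layers.extend(group.values())
        for group in self.other_sources.values():
            layers.extend(group.values())
        for lyr in layers:
            if lyr.shape != shape:
                raise ValueError("all source layers must share the scene grid")
        if self.gfm_p_natural.min() < 0 or self.gfm_p_natural.max() > 1:
            raise ValueError("gfm_p_natural must lie in [0, 1]")


@dataclass(frozen=True)
class ValidationPlot:
    """A 100 x 100 m reference plot with a binary natural-forest label."""

    plot_id: str
    lon: float
    lat: float
    ref_label: int           # 1 = natural forest, 0 = other
    stratum: int
    region: Optional[str] = None


@dataclass
class StrataSpec:
    """Population stratum sizes N_h for design-based estimation.

    ``sizes`` maps stratum index -> population size (plot counts or area
    units); ``raster`` optionally carries a per-pixel stratum map used when
    drawing validation samples from a synthetic truth raster.
    """

    sizes: dict[int, float] = field(default_factory=dict)
    raster: Optional[np.ndarray] = None

    def validate(self) -> None:
        for h, n in self.sizes.items():
            if n <= 0:
                raise ValueError(f"stratum {h} has non-positive population size")
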