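"""Fuse heterogeneous label-source rasters into 0-8 training labels.

The assignment is an ordered rule cascade: a candidate natural-forest layer
is built as the union of the natural sources (plus wildfire-loss areas,
assumed to regrow naturally), pruned of pixels with permanent-conversion
loss or a low managed-forest natural probability, and intersected with a
forest mask; planted forest and tree crops come from their own sources
(planted intersected with the forest mask, tree crops not — crops need not
meet the forest definition); conflicting forest claims become unknown; the
remaining covers are assigned only outside the forest mask, other
vegetation only where every relevant source agrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    NATURAL_DISTURBANCE_DRIVERS,
    PERMANENT_CONVERSION_DRIVERS,
    SourceStack,
)

#: managed-forest-model natural-probability support / veto thresholds
GFM_SUPPORT = 0.5
GFM_VETO = 0.3

#: minimum canopy height (m) for the forest definition; strictly greater-than
FOREST_HEIGHT_M = 5.0

#: year-2000 tree-cover percentage above which a pixel counts as tree-covered
TREE_COVER_PCT = 10.0

#: assignment priority for overlapping non-forest sources (first wins)
SOFT_NEGATIVE_PRIORITY = (6, 7, 5, 8)  # water > ice > built > bare; veg last


@dataclass
class LabelRaster:
    """Fused labels plus, per class, which rule populated it."""

    labels: np.ndarray
    provenance: dict[int, str] = field(default_factory=dict)


def _require(stack: SourceStack, name: str) -> np.ndarray:
    layer = getattr(stack, name, None)
    if layer is None:
        raise ValueError(f"source stack is missing required layer: {name}")
    return layer


def _recent_loss(stack: SourceStack) -> np.ndarray:
    loss_year = _require(stack, "loss_year")
    return (loss_year >= 2001) & (loss_year <= 2020)


def build_forest_mask(stack: SourceStack) -> np.ndarray:
    """Pixels meeting the forest definition.

    True where canopy height strictly exceeds 5 m, or a 2001-2020 loss was
    driven by wildfire/other natural disturbance (stand expected to regrow),
    or the forest-type layer marks forest.
    """
    height = _require(stack, "tree_height")
    driver = _require(stack, "driver_class")
    forest_type = _require(stack, "forest_type")
    natural_loss = np.isin(driver, list(NATURAL_DISTURBANCE_DRIVERS)) & _recent_loss(stack)
    return (height > FOREST_HEIGHT_M) | natural_loss | forest_type.astype(bool)


def _union(layers) -> np.ndarray:
    arrs = list(layers)
    if not arrs:
        raise ValueError("no source layers configured for this class")
    out = np.zeros(arrs[0].shape, bool)
    for a in arrs:
        out |= a.astype(bool)
    return out


def _intersection(layers) -> np.ndarray:
    arrs = list(layers)
    if not arrs:
        raise ValueError("no source layers configured for this class")
    out = np.ones(arrs[0].shape, bool)
    for a in arrs:
        out &= a.astype(bool)
    return out


def assign_classes(stack: SourceStack) -> LabelRaster:
    """Ordered fusion of the source stack into one 0-8 label raster."""
    stack.validate()
    provenance: dict[int, str] = {}
    recent_loss = _recent_loss(stack)
    driver = stack.driver_class
    forest_mask = build_forest_mask(stack)

    # (1) candidate natural forest: union of natural sources, the
    # managed-forest model at high natural probability, and wildfire loss
    natural_claim = _union(stack.natural_sources.values())
    natural_claim |= stack.gfm_p_natural > GFM_SUPPORT
    natural_claim |= np.isin(driver, list(NATURAL_DISTURBANCE_DRIVERS)) & recent_loss
    # (2) remove permanent-conversion loss and low natural probability
    permanent = np.isin(driver, list(PERMANENT_CONVERSION_DRIVERS)) & recent_loss
    natural = natural_claim & ~permanent
    natural &= stack.gfm_p_natural >= GFM_VETO
    # (3) forest definition
    natural &= forest_mask
    provenance[1] = "union(natural sources) + wildfire loss; minus permanent loss / low p(natural); in forest mask"

    # (4) planted forest (forest mask applies) and tree crops (it does not)
    planted = _union(stack.planted_sources.values()) & forest_mask
    crops = _union(stack.treecrop_sources.values())
    provenance[2] = "union(planted sources) in forest mask"
    provenance[3] = "union(tree-crop sources)"

    # (5) overlapping forest claims are ambiguous -> unknown; the natural
    # side is judged on the raw claim (before removals) so that adding loss
    # can only ever demote a pixel, never promote a competing forest class
    ambiguous = (natural_claim & (planted | crops)) | (planted & crops)
    natural &= ~ambiguous
    planted &= ~ambiguous
    crops &= ~ambiguous

    labels = np.zeros(stack.grid_shape(), np.int64)
    labels[natural] = 1
    labels[planted] = 2
    labels[crops] = 3

    # (7) spectrally distinct covers, outside the forest mask, fixed priority
    unclaimed = labels == 0
    for code in SOFT_NEGATIVE_PRIORITY:
        sources = stack.other_sources.get(code, {})
        if not sources:
            continue
        claim = _union(sources.values()) & ~forest_mask & unclaimed & ~ambiguous
        labels[claim] = code
        unclaimed &= ~claim
        provenance[code] = "union(sources) outside forest mask"

    # (6) other vegetation: conservative, all relevant sources must agree and
    # neither the year-2000 tree cover nor the forest mask may indicate trees
    veg_sources = stack.other_sources.get(4, {})
    if veg_sources:
        veg = (
            _intersection(veg_sources.values())
            & ~forest_mask
            & (stack.tree_cover_2000 <= TREE_COVER_PCT)
            & unclaimed
            & ~ambiguous
        )
        labels[veg] = 4
        provenance[4] = "all vegetation sources agree; no tree cover; outside forest mask"

    # (8) everything else remains unknown (class 0)
    return LabelRaster(labels=labels, provenance=provenance)


def class_distribution(labels: np.ndarray | LabelRaster) -> dict[int, float]:
    """Pixel fraction per class code 0..8 (fractions sum to 1)."""
    arr = labels.labels if isinstance(labels, LabelRaster) else labels
    if arr.size == 0:
        raise ValueError("empty label raster")
    counts = np.bincount(arr.ravel(), minlength=9)
    return {c: counts[c] / arr.size for c in range(9)}
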