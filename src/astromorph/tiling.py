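"""Patch extraction from annotated ROIs.

Whole-slide annotations are free-form polygons; the patch classifier
consumes fixed-size square tiles.  Candidate tile origins lie on a stride
lattice anchored to slide coordinates (multiples of the stride), so tiling
is invariant to translating an ROI by whole strides.  A candidate is kept
iff its intersection with the ROI polygon covers at least
``min_intersection_fraction`` of the tile — margin tiles mostly outside the
annotation are discarded.  Intersections are computed in continuous
geometry (polygon clipping), never by rasterization.

Defaults follow common whole-slide practice: 512 px tiles, stride 256
(half-overlap), 50% minimum intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

__all__ = [
    "ROIAnnotation",
    "TilingConfig",
    "Patch",
    "patch_area_fraction",
    "tile_roi",
    "tile_annotations",
]


@dataclass(frozen=True)
class ROIAnnotation:
    """A labeled region of interest: a simple polygon on a slide."""

    roi_id: str
    category: str
    polygon: tuple[tuple[float, float], ...]
    slide_id: str = ""

    def __post_init__(self):
        poly = Polygon(self.polygon)
        if poly.area <= 0:
            raise ValueError(f"ROI {self.roi_id}: polygon has zero area")
        if not poly.is_valid:
            raise ValueError(f"ROI {self.roi_id}: polygon is not simple/valid")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class TilingConfig:
    patch_size: int = 512
    stride: int = 256
    min_intersection_fraction: float = 0.5
    slide_width: int = 0
    slide_height: int = 0

    def __post_init__(self):
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not 0 < self.stride <= self.patch_size:
            raise ValueError("stride must satisfy 0 < stride <= patch_size")
        if not 0 < self.min_intersection_fraction <= 1:
            raise ValueError("min_intersection_fraction must lie in (0, 1]")
        if self.slide_width < self.patch_size or self.slide_height < self.patch_size:
            raise ValueError("slide must be at least patch_size in each dimension")


@dataclass(frozen=True)
class Patch:
    """One kept tile: 0-based top-left origin, half-open extent."""

    x0: int
    y0: int
    size: int
    roi_id: str
    category: str
    intersection_fraction: float
    slide_id: str = ""


def patch_area_fraction(x0: float, y0: float, size: float, polygon) -> float:
    """Fraction of a size×size tile at (x0, y0) covered by ``polygon``.

    Exact polygon clipping; the tile is the half-open square
    [x0, x0+size) × [y0, y0+size) treated as a closed region of equal area.
    """
    poly = polygon if isinstance(polygon, Polygon) else Polygon(polygon)
    rect = box(x0, y0, x0 + size, y0 + size)
    return float(rect.intersection(poly).area / rect.area)


def tile_roi(roi: ROIAnnotation, cfg: TilingConfig) -> list[Patch]:
    """All kept tiles for one ROI, sorted row-major (y, then x).

    Candidate origins are the stride-lattice tiles covering the ROI
    bounding box snapped to stride multiples, restricted to tiles fully
    inside the slide; the intersection-fraction filter keeps a tile iff
    fraction >= min_intersection_fraction (boundary inclusive).
    """
    poly = roi.shapely
    if poly.area <= 0:
        warnings.warn(f"ROI {roi.roi_id} has zero area; no patches generated")
        return []
    minx, miny, maxx, maxy = poly.bounds
    s, p = cfg.stride, cfg.patch_size

    def origins(lo: float, hi: float, limit: int) -> range:
        # lattice covering the bbox span [lo, hi] snapped to stride multiples:
        # anchored at the snapped-down low edge, tiles fitting the snapped-up
        # high edge; clipped so no patch extends past the slide
        a = int(np.floor(lo / s)) * s
        b = int(np.ceil(hi / s)) * s
        last = max(a, b - p)
        a = max(a, 0)
        last = min(last, ((limit - p) // s) * s)
        return range(a, last + 1, s) if last >= a else range(0)

    patches = []
    for y0 in origins(miny, maxy, cfg.slide_height):
        for x0 in origins(minx, maxx, cfg.slide_width):
            frac = patch_area_fraction(x0, y0, p, poly)
            if frac >= cfg.min_intersection_fraction:
                patches.append(
                    Patch(
                        x0=x0,
                        y0=y0,
                        size=p,
                        roi_id=roi.roi_id,
                        category=roi.category,
                        intersection_fraction=frac,
                        slide_id=roi.slide_id,
                    )
                )
    return patches


def tile_annotations(rois, cfg: TilingConfig) -> pd.DataFrame:
    """Tile a collection of ROIs into one patch-index table.

    Each patch is attributed to the ROI that generated it; overlapping ROIs
    can therefore yield coincident patches under different roi_ids.
    """
    rows = [
        {
            "slide_id": p.slide_id,
            "roi_id": p.roi_id,
            "category": p.category,
            "x0": p.x0,
            "y0": p.y0,
            "size": p.size,
            "fraction": p.intersection_fraction,
        }
        for roi in rois
        for p in tile_roi(roi, cfg)
    ]
    return pd.DataFrame(
        rows, columns=["slide_id", "roi_id", "category", "x0", "y0", "size", "fraction"]
    )
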