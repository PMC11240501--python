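"""File formats: GeoJSON ROI annotations, PNG/TIFF masks and images, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .tiling import ROIAnnotation

__all__ = [
    "read_annotations_geojson",
    "write_annotations_geojson",
    "read_label_mask",
    "write_label_mask",
    "read_intensity",
    "write_intensity",
]


def write_annotations_geojson(rois, path) -> None:
    """ROIs as a GeoJSON FeatureCollection (pixel coordinates, 'category' property)."""
    features = []
    for roi in rois:
        ring = [list(map(float, v)) for v in roi.polygon]
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "roi_id": roi.roi_id,
                    "category": roi.category,
                    "slide_id": roi.slide_id,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_annotations_geojson(path) -> list[ROIAnnotation]:
    data = json.loads(Path(path).read_text())
    rois = []
    for i, feat in enumerate(data["features"]):
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"feature {i}: expected Polygon, got {geom['type']}")
        ring = geom["coordinates"][0]
        if ring[0] == ring[-1]:
            ring = ring[:-1]
        props = feat.get("properties", {})
        rois.append(
            ROIAnnotation(
                roi_id=str(props.get("roi_id", f"roi_{i}")),
                category=str(props["category"]),
                polygon=tuple((float(x), float(y)) for x, y in ring),
                slide_id=str(props.get("slide_id", "")),
            )
        )
    return rois


def write_label_mask(mask: np.ndarray, path) -> None:
    """16-bit single-channel label mask as PNG or TIFF (by extension)."""
    Image.fromarray(np.asarray(mask, dtype=np.uint16)).save(path)


def read_label_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path)).astype(np.uint16)


def write_intensity(img: np.ndarray, path) -> None:
    """8-bit grayscale intensity image as PNG."""
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def read_intensity(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))
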