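"""Readers/writers for the package's on-disk formats.

Annotations and segmentations travel as GeoJSON FeatureCollections in slide
pixel coordinates (the QuPath-style dialect): each Feature carries a Polygon
geometry and a ``category`` property; segmentation features additionally
carry ``certainty``. Images are PNG, resolution metadata lives in a JSON
sidecar ``{"mpp_x": ..., "mpp_y": ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import mapping, shape

from .errors import InputError
from .types import (
    AnnotationRegion,
    Category,
    SegmentedObject,
    SlideImage,
    SlideSegmentation,
)


# ---------------------------------------------------------------- images ---

def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0,1] float raster as an 8-bit PNG (deterministic encoder)."""
    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8)).save(path, format="PNG")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster to a [0,1] float array of shape (H, W, 3)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr


def write_mpp_sidecar(path: str | Path, mpp_x: float, mpp_y: float) -> None:
    Path(path).write_text(json.dumps({"mpp_x": mpp_x, "mpp_y": mpp_y}) + "\n")


def read_mpp_sidecar(path: str | Path) -> tuple[float, float]:
    meta = json.loads(Path(path).read_text())
    try:
        return float(meta["mpp_x"]), float(meta["mpp_y"])
    except KeyError as exc:  # pragma: no cover - malformed sidecar
        raise InputError(f"mpp sidecar {path} missing key {exc}") from exc


def read_slide(image_path: str | Path, sidecar_path: str | Path | None = None,
               slide_id: str | None = None) -> SlideImage:
    """Load an image + mpp sidecar into a SlideImage.

    The sidecar defaults to ``<image stem>.mpp.json`` next to the image.
    """
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix("").with_suffix(".mpp.json")
    mpp_x, mpp_y = read_mpp_sidecar(sidecar_path)
    return SlideImage(
        pixels=read_image(image_path),
        mpp_x=mpp_x,
        mpp_y=mpp_y,
        slide_id=slide_id or image_path.stem,
    )


# --------------------------------------------------------------- geojson ---

def _feature(polygon, properties: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": mapping(polygon),
        "properties": properties,
    }


def regions_to_geojson(regions: list[AnnotationRegion]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            _feature(r.polygon, {"category": r.category.value}) for r in regions
        ],
    }


def regions_from_geojson(doc: dict) -> list[AnnotationRegion]:
    regions = []
    for feat in doc.get("features", []):
        poly = shape(feat["geometry"])
        cat = Category(feat["properties"]["category"])
        regions.append(AnnotationRegion(polygon=poly, category=cat))
    return regions


def segmentation_to_geojson(seg: SlideSegmentation) -> dict:
    return {
        "type": "FeatureCollection",
        "slide_id": seg.slide_id,
        "tissue_area_mm2": seg.tissue_area_mm2,
        "features": [
            _feature(
                o.polygon,
                {"category": o.category.value, "certainty": o.certainty},
            )
            for o in seg.objects
        ],
    }


def segmentation_from_geojson(doc: dict, mpp_x: float, mpp_y: float) -> SlideSegmentation:
    objects = []
    for feat in doc.get("features", []):
        poly = shape(feat["geometry"])
        props = feat["properties"]
        objects.append(
            SegmentedObject.from_polygon(
                poly, Category(props["category"]), float(props["certainty"]),
                mpp_x, mpp_y,
            )
        )
    return SlideSegmentation(
        slide_id=doc.get("slide_id", "slide"),
        objects=objects,
        tissue_area_mm2=float(doc.get("tissue_area_mm2", 0.0)),
    )


def dump_json(doc: dict, path: str | Path) -> None:
    """Deterministic JSON serialization (sorted keys, newline-terminated)."""
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
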