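"""Core domain types for whole-slide risk screening.

Conventions used throughout the package:

* rasters are numpy arrays of shape ``(height, width, 3)`` with float channel
  values in ``[0, 1]``; ``x`` indexes columns, ``y`` indexes rows, origin at
  the top-left, half-open pixel intervals;
* areas in pixels convert to mm^2 through the microns-per-pixel (mpp)
  metadata: ``area_mm2 = area_px * mpp_x * mpp_y * 1e-6``;
* the positive ("high risk") class is dysplasia or malignancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from shapely.geometry import Polygon

from .errors import InputError


class Category(str, Enum):
    """The seven histological categories a gland segmentation can emit."""

    BENIGN_GLAND = "benign_gland"
    ADENOCA_OR_HGD = "adenoca_or_hgd"
    LOW_GRADE_DYSPLASIA = "low_grade_dysplasia"
    BLOOD_VESSEL = "blood_vessel"
    NECROSIS = "necrosis"
    MUCIN = "mucin"
    INFLAMMATION = "inflammation"


#: Categories whose presence makes a region/slide "high risk".
HIGH_RISK_CATEGORIES = frozenset(
    {Category.ADENOCA_OR_HGD, Category.LOW_GRADE_DYSPLASIA}
)

#: Stable ordering of the seven categories (row/column order of flip matrices).
CATEGORIES: tuple[Category, ...] = tuple(Category)


class RiskLabel(str, Enum):
    """Binary slide- or tile-level triage label."""

    LOW = "low_risk"
    HIGH = "high_risk"


def px_to_mm2(area_px: float, mpp_x: float, mpp_y: float) -> float:
    """Convert a pixel area to mm^2 given square or rectangular pixel pitch."""
    return float(area_px) * mpp_x * mpp_y * 1e-6


@dataclass
class SlideImage:
    """An RGB raster with resolution metadata.

    ``pixels`` is ``(H, W, 3)`` float in ``[0, 1]``; ``mpp_x``/``mpp_y`` are
    microns per pixel along x (columns) and y (rows).
    """

    pixels: np.ndarray
    mpp_x: float
    mpp_y: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.dtype not in (np.float32, np.float64):
            p = p.astype(np.float64)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise InputError("pixels must be a (H, W, 3) array with H, W >= 1")
        if float(p.min()) < 0.0 or float(p.max()) > 1.0:
            raise InputError("channel values must lie in [0, 1]")
        if not (self.mpp_x > 0 and self.mpp_y > 0):
            raise InputError("mpp_x and mpp_y must be positive")
        self.pixels = p

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TissueMask:
    """Boolean raster flagging tissue pixels, aligned with one SlideImage."""

    mask: np.ndarray
    mpp_x: float
    mpp_y: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            raise InputError("mask must be a 2-D boolean array")
        if not (self.mpp_x > 0 and self.mpp_y > 0):
            raise InputError("mpp_x and mpp_y must be positive")
        self.mask = m

    @property
    def tissue_area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def tissue_area_mm2(self) -> float:
        return px_to_mm2(self.tissue_area_px, self.mpp_x, self.mpp_y)


@dataclass(frozen=True)
class Tile:
    """One fixed-size grid cell of a slide.

    The extent is the half-open box ``[x0, x0+width) x [y0, y0+height)`` in
    slide pixel coordinates; ``tissue_fraction`` is the fraction of its pixels
    inside the tissue mask.
    """

    row: int
    col: int
    x0: int
    y0: int
    width: int
    height: int
    tissue_fraction: float

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def box(self) -> Polygon:
        """The tile extent as a shapely box (slide coordinates)."""
        from shapely.geometry import box

        return box(self.x0, self.y0, self.x1, self.y1)


@dataclass
class AnnotationRegion:
    """An expert ground-truth polygon with one of the seven categories."""

    polygon: Polygon
    category: Category

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon) or self.polygon.is_empty:
            raise InputError("region polygon must be a non-empty shapely Polygon")
        if self.polygon.area <= 0:
            raise InputError("region polygon must have positive area")
        self.category = Category(self.category)


@dataclass
class SegmentedObject:
    """A model-predicted gland: polygon + category + prediction certainty."""

    polygon: Polygon
    category: Category
    certainty: float
    area_px: float
    area_mm2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.certainty <= 1.0):
            raise InputError("certainty must lie in [0, 1]")
        if self.area_px <= 0:
            raise InputError("area_px must be positive")
        self.category = Category(self.category)

    @classmethod
    def from_polygon(
        cls,
        polygon: Polygon,
        category: Category,
        certainty: float,
        mpp_x: float,
        mpp_y: float,
    ) -> "SegmentedObject":
        """Build an object whose areas are derived from its polygon and mpp."""
        area_px = float(polygon.area)
        return cls(
            polygon=polygon,
            category=Category(category),
            certainty=float(certainty),
            area_px=area_px,
            area_mm2=px_to_mm2(area_px, mpp_x, mpp_y),
        )


@dataclass
class SlideSegmentation:
    """All segmented objects of one slide plus its tissue area."""

    slide_id: str
    objects: list[SegmentedObject] = field(default_factory=list)
    tissue_area_mm2: float = 0.0

    def __post_init__(self) -> None:
        if self.objects and not (self.tissue_area_mm2 > 0):
            raise InputError(
                "tissue_area_mm2 must be positive when objects are present"
            )


@dataclass(frozen=True)
class SlideFeatureVector:
    """The four slide-level aggregation features fed to the classifier.

    ``f_area_pct``
        high-certainty (> 70%) high-risk area as a percentage of tissue area;
    ``f_wmean``
        area-weighted mean certainty over high-risk-category objects;
    ``f_flag``
        1 iff very-high-certainty (> 85%) high-risk predictions cover at
        least 0.1 mm^2 cumulatively;
    ``f_wpctl1``
        area-weighted bottom 1-percentile of high-risk certainties.

    All four are 0 when the slide has no high-risk-category object.
    """

    f_area_pct: float
    f_wmean: float
    f_flag: int
    f_wpctl1: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_area_pct, self.f_wmean, float(self.f_flag), self.f_wpctl1]
        )


#: Column order of the feature matrix everywhere (CSV, classifier input).
FEATURE_COLUMNS = ("f_area_pct", "f_wmean", "f_flag", "f_wpctl1")
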