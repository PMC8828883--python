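"""Tile-level risk labelling and the four slide-level aggregation features.

A tile is high-risk if any high-risk-category geometry overlaps it with
positive area ("any amount" rule). A slide's segmentation collapses to four
numbers: the fraction of tissue covered by confident (> 70%) high-risk
predictions, the area-weighted mean certainty of all high-risk predictions,
a Boolean flag for >= 0.1 mm^2 of very confident (> 85%) high-risk area,
and the area-weighted bottom 1-percentile certainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .types import (
    AnnotationRegion,
    Category,
    FEATURE_COLUMNS,
    HIGH_RISK_CATEGORIES,
    RiskLabel,
    SegmentedObject,
    SlideFeatureVector,
    SlideSegmentation,
    Tile,
)


@dataclass
class FeatureConfig:
    """Thresholds of the slide-feature aggregation.

    Defaults are the screening pipeline's: the area feature counts objects
    with certainty strictly greater than 0.70; the flag requires strictly
    more than 0.85 certainty over a cumulative 0.1 mm^2; the percentile
    feature uses the bottom 1-percentile.
    """

    certainty_threshold: float = 0.70
    flag_certainty: float = 0.85
    flag_area_mm2: float = 0.1
    percentile: float = 1.0
    high_risk_categories: frozenset[Category] = field(
        default_factory=lambda: HIGH_RISK_CATEGORIES
    )

    def __post_init__(self) -> None:
        for name in ("certainty_threshold", "flag_certainty"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if not self.flag_area_mm2 > 0:
            raise ConfigError("flag_area_mm2 must be positive")
        if not 0.0 < self.percentile < 100.0:
            raise ConfigError("percentile must lie in (0, 100)")
        self.high_risk_categories = frozenset(
            Category(c) for c in self.high_risk_categories
        )


def label_tile(
    tile: Tile,
    geometries: Iterable[AnnotationRegion | SegmentedObject],
    high_risk_categories: frozenset[Category] = HIGH_RISK_CATEGORIES,
) -> RiskLabel:
    """High-risk iff any high-risk geometry overlaps the tile with positive area.

    Applies identically to ground-truth regions and to predicted objects.
    Boundary contact without interior overlap does not count (half-open
    tile extents).
    """
    box = tile.box()
    for geom in geometries:
        if geom.category not in high_risk_categories:
            continue
        if geom.polygon.intersects(box) and geom.polygon.intersection(box).area > 0:
            return RiskLabel.HIGH
    return RiskLabel.LOW


def weighted_percentile(
    values: Sequence[float], weights: Sequence[float], p: float
) -> float:
    """Left-continuous inverse CDF of a weighted sample, no interpolation.

    Sort by value ascending; return the smallest value whose cumulative
    normalized weight reaches ``p/100``.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise InputError("weighted_percentile requires at least one value")
    if v.shape != w.shape:
        raise InputError("values and weights must have equal length")
    if (w <= 0).any():
        raise InputError("weights must be strictly positive")
    if not 0.0 < p < 100.0:
        raise InputError("percentile must lie in (0, 100)")
    order = np.argsort(v, kind="stable")
    cumw = np.cumsum(w[order]) / w.sum()
    idx = int(np.searchsorted(cumw, p / 100.0 - 1e-12, side="left"))
    idx = min(idx, v.size - 1)
    return float(v[order][idx])


def compute_slide_features(
    seg: SlideSegmentation, config: FeatureConfig | None = None
) -> SlideFeatureVector:
    """Aggregate one slide's segmentation into the four-feature vector.

    All four features are exactly 0 when the slide carries no
    high-risk-category object.
    """
    config = config or FeatureConfig()
    high = [o for o in seg.objects if o.category in config.high_risk_categories]
    if not high:
        return SlideFeatureVector(0.0, 0.0, 0, 0.0)
    if not seg.tissue_area_mm2 > 0:
        raise InputError(
            f"slide {seg.slide_id!r} has high-risk objects but zero tissue area"
        )
    areas = np.array([o.area_mm2 for o in high])
    certs = np.array([o.certainty for o in high])
    confident_area = float(areas[certs > config.certainty_threshold].sum())
    f_area_pct = 100.0 * confident_area / seg.tissue_area_mm2
    f_wmean = float((certs * areas).sum() / areas.sum())
    flag_area = float(areas[certs > config.flag_certainty].sum())
    f_flag = int(flag_area >= config.flag_area_mm2)
    f_wpctl1 = weighted_percentile(certs, areas, config.percentile)
    return SlideFeatureVector(f_area_pct, f_wmean, f_flag, f_wpctl1)


def features_table(
    segmentations: Iterable[SlideSegmentation], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """One feature row per slide, order-stable by slide_id.

    Columns: ``slide_id`` followed by :data:`crcscreen.types.FEATURE_COLUMNS`.
    Duplicate slide ids are rejected.
    """
    rows = []
    for seg in segmentations:
        fv = compute_slide_features(seg, config)
        rows.append(
            {
                "slide_id": seg.slide_id,
                "f_area_pct": fv.f_area_pct,
                "f_wmean": fv.f_wmean,
                "f_flag": fv.f_flag,
                "f_wpctl1": fv.f_wpctl1,
            }
        )
    table = pd.DataFrame(rows, columns=["slide_id", *FEATURE_COLUMNS])
    if table["slide_id"].duplicated().any():
        dupes = table.loc[table["slide_id"].duplicated(), "slide_id"].tolist()
        raise InputError(f"duplicate slide ids: {dupes}")
    return table.sort_values("slide_id", kind="stable").reset_index(drop=True)


def rasterized_high_risk_area_pct(
    seg: SlideSegmentation,
    image_shape: tuple[int, int],
    mpp_x: float,
    mpp_y: float,
    config: FeatureConfig | None = None,
) -> float:
    """Brute-force pixel-rasterization analogue of ``f_area_pct``.

    Rasterizes every qualifying high-risk polygon onto the slide grid and
    counts pixels. Serves as an independent cross-check of the
    polygon-analytic area computation (agreement expected within ~1%).
    """
    from skimage.draw import polygon as draw_polygon

    config = config or FeatureConfig()
    canvas_area_px = 0
    for o in seg.objects:
        if o.category not in config.high_risk_categories:
            continue
        if not o.certainty > config.certainty_threshold:
            continue
        xs, ys = o.polygon.exterior.coords.xy
        rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape=image_shape)
        canvas_area_px += len(rr)
    from .types import px_to_mm2

    return 100.0 * px_to_mm2(canvas_area_px, mpp_x, mpp_y) / seg.tissue_area_mm2
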