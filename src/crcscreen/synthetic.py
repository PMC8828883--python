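"""Seeded synthetic slides with gland-like structure and known truth.

Each synthetic slide is a near-white canvas carrying one large pale-pink
"tissue" blob (an ellipse) on which non-overlapping gland-like ellipses are
rendered in fixed per-category colours. The generator records, per slide:

* the rendered image plus mpp metadata,
* the ground-truth annotation polygons with their categories,
* the true high/low-risk label (high iff >= 1 high-risk-category region),
* a simulated segmentation output, produced by running the oracle
  corruption model over the annotations.

The default corruption model gives correctly-recognized high-risk glands
certainties ~ Beta(16, 2) (mean ~0.89) while benign glands are occasionally
mislabelled as high-risk with certainties ~ Beta(2, 8) (mean 0.2) — false
objects that make low-risk slides separable from high-risk slides clearly
but not perfectly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .errors import ConfigError
from .segmentation import OracleCorruption, derive_rng, oracle_segment
from .types import (
    CATEGORIES,
    AnnotationRegion,
    Category,
    HIGH_RISK_CATEGORIES,
    RiskLabel,
    SlideImage,
    SlideSegmentation,
    px_to_mm2,
)

#: Fixed rendering colours (RGB in [0,1]); arbitrary but documented constants
#: chosen so the tissue mask and tiling see realistic structure.
CATEGORY_COLORS: dict[Category, tuple[float, float, float]] = {
    Category.BENIGN_GLAND: (0.45, 0.62, 0.45),
    Category.ADENOCA_OR_HGD: (0.72, 0.30, 0.30),
    Category.LOW_GRADE_DYSPLASIA: (0.85, 0.55, 0.30),
    Category.BLOOD_VESSEL: (0.85, 0.50, 0.65),
    Category.NECROSIS: (0.45, 0.40, 0.50),
    Category.MUCIN: (0.60, 0.75, 0.80),
    Category.INFLAMMATION: (0.80, 0.78, 0.40),
}
TISSUE_COLOR = (0.90, 0.72, 0.83)
BACKGROUND_COLOR = (0.97, 0.97, 0.97)

_HIGH_RISK_SORTED = tuple(sorted(HIGH_RISK_CATEGORIES, key=lambda c: c.value))


def default_category_weights() -> dict[RiskLabel, dict[Category, float]]:
    """Annotation category mixtures per true slide label.

    Low-risk slides put zero mass on high-risk categories (the slide label
    is defined by their presence); high-risk slides mix malignant/dysplastic
    glands with benign context.
    """
    return {
        RiskLabel.HIGH: {
            Category.BENIGN_GLAND: 0.38,
            Category.ADENOCA_OR_HGD: 0.25,
            Category.LOW_GRADE_DYSPLASIA: 0.15,
            Category.BLOOD_VESSEL: 0.08,
            Category.NECROSIS: 0.04,
            Category.MUCIN: 0.04,
            Category.INFLAMMATION: 0.06,
        },
        RiskLabel.LOW: {
            Category.BENIGN_GLAND: 0.60,
            Category.ADENOCA_OR_HGD: 0.0,
            Category.LOW_GRADE_DYSPLASIA: 0.0,
            Category.BLOOD_VESSEL: 0.12,
            Category.NECROSIS: 0.03,
            Category.MUCIN: 0.07,
            Category.INFLAMMATION: 0.18,
        },
    }


def default_corruption(false_high_risk_rate: float = 0.3, seed: int = 0) -> OracleCorruption:
    """The study-condition corruption model.

    Benign glands flip to a high-risk category with probability
    ``false_high_risk_rate`` (split evenly between the two high-risk
    categories); all other categories are preserved. Correct high-risk
    detections draw certainty from Beta(16, 2); incorrect ("false object")
    high-risk detections from Beta(2, 8); everything else from Beta(6, 3).
    """
    flip = np.eye(len(CATEGORIES))
    i_benign = CATEGORIES.index(Category.BENIGN_GLAND)
    flip[i_benign, i_benign] = 1.0 - false_high_risk_rate
    for cat in _HIGH_RISK_SORTED:
        flip[i_benign, CATEGORIES.index(cat)] = false_high_risk_rate / 2.0
    certainty: dict[tuple[Category, bool], tuple[float, float]] = {}
    for cat in _HIGH_RISK_SORTED:
        certainty[(cat, True)] = (16.0, 2.0)
        certainty[(cat, False)] = (2.0, 8.0)
    return OracleCorruption(
        label_flip_matrix=flip,
        certainty=certainty,
        default_certainty=(6.0, 3.0),
        seed=seed,
    )


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults render 2325 x 1566 px slides (a 3 x 3 grid of 775 x 522 tiles)
    at 4.0 microns per pixel, ~12 glands per slide with log-normal areas
    around 0.12 mm^2, and the default corruption model's certainty laws.
    """

    n_slides: int = 100
    high_risk_prevalence: float = 0.5
    image_size: tuple[int, int] = (2325, 1566)  # (width, height) px
    mpp: float = 4.0
    object_count_mean: dict[RiskLabel, float] = field(
        default_factory=lambda: {RiskLabel.HIGH: 12.0, RiskLabel.LOW: 10.0}
    )
    category_weights: dict[RiskLabel, dict[Category, float]] = field(
        default_factory=default_category_weights
    )
    area_lognormal: tuple[float, float] = (math.log(0.12), 0.45)  # mm^2 scale
    false_high_risk_rate: float = 0.3
    high_risk_certainty: tuple[float, float] = (16.0, 2.0)
    false_object_certainty: tuple[float, float] = (2.0, 8.0)
    other_certainty: tuple[float, float] = (6.0, 3.0)
    tissue_scale: float = 1.0  # shrinks the tissue blob (biopsy-like slides)
    slide_id_prefix: str = "slide"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides < 0:
            raise ConfigError("n_slides must be >= 0")
        if not 0.0 <= self.high_risk_prevalence <= 1.0:
            raise ConfigError("high_risk_prevalence must lie in [0, 1]")
        w, h = self.image_size
        if w < 16 or h < 16:
            raise ConfigError("image_size must be at least 16 x 16 px")
        if not self.mpp > 0:
            raise ConfigError("mpp must be positive")
        for label, mean in self.object_count_mean.items():
            if mean <= 0:
                raise ConfigError(f"object_count_mean[{label}] must be positive")
        if self.area_lognormal[1] <= 0:
            raise ConfigError("area_lognormal sigma must be positive")
        if not 0.0 <= self.false_high_risk_rate <= 1.0:
            raise ConfigError("false_high_risk_rate must lie in [0, 1]")
        for name in ("high_risk_certainty", "false_object_certainty", "other_certainty"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} Beta parameters must be positive")
        if not 0.0 < self.tissue_scale <= 1.0:
            raise ConfigError("tissue_scale must lie in (0, 1]")
        for label in (RiskLabel.HIGH, RiskLabel.LOW):
            weights = self.category_weights[label]
            total = sum(weights.values())
            if total <= 0 or any(v < 0 for v in weights.values()):
                raise ConfigError(f"category_weights[{label}] must be a non-negative mixture")
            if label is RiskLabel.LOW and any(
                weights.get(c, 0.0) > 0 for c in HIGH_RISK_CATEGORIES
            ):
                raise ConfigError(
                    "category_weights[low_risk] must put zero mass on high-risk categories"
                )

    def corruption(self) -> OracleCorruption:
        corr = default_corruption(self.false_high_risk_rate, seed=self.seed)
        certainty: dict[tuple[Category, bool], tuple[float, float]] = {}
        for cat in _HIGH_RISK_SORTED:
            certainty[(cat, True)] = self.high_risk_certainty
            certainty[(cat, False)] = self.false_object_certainty
        corr.certainty = certainty
        corr.default_certainty = self.other_certainty
        return corr


@dataclass
class SyntheticSlide:
    """One generated slide: image, truth, and simulated segmentation."""

    image: SlideImage
    regions: list[AnnotationRegion]
    true_label: RiskLabel
    seg: SlideSegmentation
    tissue_mask_true: np.ndarray  # ground-truth blob raster (H, W) bool

    @property
    def slide_id(self) -> str:
        return self.image.slide_id


def ellipse_polygon(
    cx: float, cy: float, rx: float, ry: float, theta: float, n_vertices: int = 64
) -> Polygon:
    """An n-gon inscribed in a rotated ellipse (area within 0.2% of pi*rx*ry)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = cx + rx * ct * math.cos(theta) - ry * st * math.sin(theta)
    y = cy + rx * ct * math.sin(theta) + ry * st * math.cos(theta)
    return Polygon(zip(x, y))


def _rasterize(poly: Polygon, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = poly.exterior.coords.xy
    return draw_polygon(np.asarray(ys), np.asarray(xs), shape=shape)


def _ellipse_raster(
    shape: tuple[int, int], cx: float, cy: float, rx: float, ry: float, theta: float
) -> np.ndarray:
    """Boolean raster of a rotated ellipse by its quadratic form (pixel centres)."""
    h, w = shape
    yy, xx = np.ogrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = (dx * math.cos(theta) + dy * math.sin(theta)) / rx
    v = (-dx * math.sin(theta) + dy * math.cos(theta)) / ry
    return u * u + v * v <= 1.0


def _place_glands(
    rng: np.random.Generator,
    categories: list[Category],
    areas_mm2: np.ndarray,
    blob: Polygon,
    mpp: float,
    must_place: set[int],
) -> list[tuple[Polygon, Category]]:
    """Rejection-sample non-overlapping ellipses inside the tissue blob.

    Each gland gets up to 100 placement attempts at its drawn area; glands
    whose placement matters for the slide label (``must_place``) shrink and
    retry so the label bookkeeping invariant always holds.
    """
    placed: list[tuple[Polygon, Category]] = []
    minx, miny, maxx, maxy = blob.bounds
    for i, (cat, area_mm2) in enumerate(zip(categories, areas_mm2)):
        area = float(area_mm2)
        success = False
        for _shrink in range(7):
            area_px = area * 1e6 / (mpp * mpp)
            aspect = rng.uniform(0.55, 0.95)
            rx = math.sqrt(area_px / (math.pi * aspect))
            ry = rx * aspect
            theta = rng.uniform(0.0, math.pi)
            for _attempt in range(100):
                cx = rng.uniform(minx, maxx)
                cy = rng.uniform(miny, maxy)
                candidate = ellipse_polygon(cx, cy, rx, ry, theta)
                if not blob.contains(candidate):
                    continue
                if any(candidate.intersects(p) for p, _ in placed):
                    continue
                placed.append((candidate, cat))
                success = True
                break
            if success or i not in must_place:
                break
            area *= 0.5  # shrink the mandatory gland until it fits
        # a non-mandatory gland that never fit is silently skipped
    return placed


def generate_slide(config: SyntheticConfig, slide_index: int) -> SyntheticSlide:
    """Deterministically generate one synthetic slide.

    Identical ``(config.seed, slide_index)`` yield bit-identical outputs.
    """
    if not 0 <= slide_index < max(config.n_slides, 1):
        raise ConfigError(f"slide_index {slide_index} out of range for n_slides={config.n_slides}")
    rng = derive_rng(config.seed, "slide", slide_index)
    width, height = config.image_size
    slide_id = f"{config.slide_id_prefix}_{slide_index:04d}"

    true_label = (
        RiskLabel.HIGH if rng.random() < config.high_risk_prevalence else RiskLabel.LOW
    )

    # --- tissue blob -------------------------------------------------------
    scale = config.tissue_scale
    cx = width / 2.0 + rng.uniform(-0.02, 0.02) * width
    cy = height / 2.0 + rng.uniform(-0.02, 0.02) * height
    rx = 0.44 * width * scale * rng.uniform(0.95, 1.0)
    ry = 0.44 * height * scale * rng.uniform(0.95, 1.0)
    blob_theta = rng.uniform(-0.15, 0.15)
    blob = ellipse_polygon(cx, cy, rx, ry, blob_theta, n_vertices=128)
    tissue_mask_true = _ellipse_raster((height, width), cx, cy, rx, ry, blob_theta)

    pixels = np.empty((height, width, 3), dtype=np.float32)
    pixels[:] = BACKGROUND_COLOR
    pixels[tissue_mask_true] = TISSUE_COLOR

    # --- glands ------------------------------------------------------------
    weights = config.category_weights[true_label]
    prob = np.array([weights.get(c, 0.0) for c in CATEGORIES], dtype=float)
    prob = prob / prob.sum()
    n_objects = int(rng.poisson(config.object_count_mean[true_label]))
    if true_label is RiskLabel.HIGH and n_objects == 0:
        n_objects = 1
    cats = [CATEGORIES[int(i)] for i in rng.choice(len(CATEGORIES), size=n_objects, p=prob)]
    must_place: set[int] = set()
    if true_label is RiskLabel.HIGH and not any(c in HIGH_RISK_CATEGORIES for c in cats):
        cats[0] = _HIGH_RISK_SORTED[int(rng.integers(len(_HIGH_RISK_SORTED)))]
    if true_label is RiskLabel.HIGH:
        # every high-risk gland is mandatory until one of them is placed;
        # simplest sufficient rule: mark the first high-risk gland mandatory
        must_place.add(next(i for i, c in enumerate(cats) if c in HIGH_RISK_CATEGORIES))
    mu, sigma = config.area_lognormal
    areas = rng.lognormal(mu, sigma, size=n_objects)
    placed = _place_glands(rng, cats, areas, blob, config.mpp, must_place)

    regions: list[AnnotationRegion] = []
    for poly, cat in placed:
        rr, cc = _rasterize(poly, (height, width))
        pixels[rr, cc] = CATEGORY_COLORS[cat]
        regions.append(AnnotationRegion(polygon=poly, category=cat))

    image = SlideImage(
        pixels=pixels,  # all rendering colours are constants inside [0, 1]
        mpp_x=config.mpp,
        mpp_y=config.mpp,
        slide_id=slide_id,
    )

    # --- simulated segmentation -------------------------------------------
    tissue_area_mm2 = px_to_mm2(int(tissue_mask_true.sum()), config.mpp, config.mpp)
    seg = oracle_segment(
        regions,
        config.corruption(),
        config.mpp,
        config.mpp,
        tissue_area_mm2=tissue_area_mm2,
        slide_id=slide_id,
        rng=derive_rng(config.seed, "seg", slide_index),
    )
    return SyntheticSlide(
        image=image,
        regions=regions,
        true_label=true_label,
        seg=seg,
        tissue_mask_true=tissue_mask_true,
    )


def iter_slides(config: SyntheticConfig):
    """Yield the cohort one slide at a time (images can be large)."""
    for index in range(config.n_slides):
        yield generate_slide(config, index)


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[SyntheticSlide], pd.DataFrame]:
    """Generate the full cohort and optionally persist it.

    When ``out_dir`` is given, writes per slide: a PNG image, an mpp JSON
    sidecar, annotation and segmentation GeoJSON files, plus a cohort
    manifest CSV (slide_id, true_label, image, annotations, segmentation).
    """
    from . import geojson_io as gio

    rows = []
    slides: list[SyntheticSlide] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for slide in iter_slides(config):
        slides.append(slide)
        row = {"slide_id": slide.slide_id, "true_label": slide.true_label.value}
        if out_dir is not None:
            image_path = out_dir / f"{slide.slide_id}.png"
            ann_path = out_dir / f"{slide.slide_id}.annotations.geojson"
            seg_path = out_dir / f"{slide.slide_id}.segmentation.geojson"
            gio.write_image(image_path, slide.image.pixels)
            gio.write_mpp_sidecar(
                out_dir / f"{slide.slide_id}.mpp.json",
                slide.image.mpp_x,
                slide.image.mpp_y,
            )
            gio.dump_json(gio.regions_to_geojson(slide.regions), ann_path)
            gio.dump_json(gio.segmentation_to_geojson(slide.seg), seg_path)
            row.update(
                image=image_path.name,
                annotations=ann_path.name,
                segmentation=seg_path.name,
            )
        else:
            row.update(image="", annotations="", segmentation="")
        rows.append(row)
    manifest = pd.DataFrame(
        rows, columns=["slide_id", "true_label", "image", "annotations", "segmentation"]
    )
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return slides, manifest
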