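"""Segmentation backend contract and the annotation-corrupting oracle.

The screening pipeline consumes per-slide instance segmentations (polygons
with a category and a prediction certainty). Any model satisfying the
:class:`SegmentationBackend` contract can plug in; the package ships an
oracle backend that derives "predictions" from ground-truth annotations
under a configurable corruption model (label flips, drops, spurious
detections, certainty laws), so the downstream aggregation, classification
and evaluation stages can be exercised with known truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
from shapely.geometry import Point

from .errors import ConfigError, InputError
from .types import (
    CATEGORIES,
    AnnotationRegion,
    Category,
    HIGH_RISK_CATEGORIES,
    SegmentedObject,
    SlideImage,
    SlideSegmentation,
    TissueMask,
)

#: Certainty law: either a constant in [0, 1] or Beta(alpha, beta) parameters.
CertaintyLaw = float | tuple[float, float]


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract every gland-segmentation model must satisfy."""

    def segment(self, image: SlideImage, mask: TissueMask) -> SlideSegmentation:
        """Segment one slide; objects must lie on tissue with certainties in [0, 1]."""
        ...


def _identity_flip_matrix() -> np.ndarray:
    return np.eye(len(CATEGORIES))


@dataclass
class OracleCorruption:
    """How the oracle degrades ground truth into 'predictions'.

    ``label_flip_matrix``
        7x7 row-stochastic matrix over :data:`crcscreen.types.CATEGORIES`;
        row = true category, column = predicted category.
    ``drop_rate``
        probability an annotation yields no object at all.
    ``spurious_rate``
        expected (Poisson) count of false objects per slide, placed on
        tissue with a high-risk category and the "incorrect" certainty law.
    ``certainty``
        law per ``(predicted category, correct?)``; anything missing falls
        back to ``default_certainty``.
    """

    label_flip_matrix: np.ndarray = field(default_factory=_identity_flip_matrix)
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    certainty: dict[tuple[Category, bool], CertaintyLaw] = field(default_factory=dict)
    default_certainty: CertaintyLaw = (6.0, 3.0)
    spurious_area_mm2: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.label_flip_matrix, dtype=float)
        n = len(CATEGORIES)
        if m.shape != (n, n):
            raise ConfigError(f"label_flip_matrix must be {n}x{n}, got {m.shape}")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("label_flip_matrix rows must be non-negative and sum to 1")
        if not 0.0 <= self.drop_rate <= 1.0:
            raise ConfigError("drop_rate must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ConfigError("spurious_rate must be >= 0")
        if self.spurious_area_mm2 <= 0:
            raise ConfigError("spurious_area_mm2 must be positive")
        for law in list(self.certainty.values()) + [self.default_certainty]:
            _validate_law(law)
        self.label_flip_matrix = m

    @classmethod
    def none(cls) -> "OracleCorruption":
        """Zero corruption: identity labels, no drops/spurious, certainty 1."""
        return cls(drop_rate=0.0, spurious_rate=0.0, default_certainty=1.0)

    def certainty_law(self, category: Category, correct: bool) -> CertaintyLaw:
        return self.certainty.get((category, correct), self.default_certainty)


def _validate_law(law: CertaintyLaw) -> None:
    if isinstance(law, tuple):
        if len(law) != 2 or law[0] <= 0 or law[1] <= 0:
            raise ConfigError(f"Beta parameters must be positive, got {law}")
    elif not 0.0 <= float(law) <= 1.0:
        raise ConfigError(f"constant certainty must lie in [0, 1], got {law}")


def _draw_certainty(law: CertaintyLaw, rng: np.random.Generator) -> float:
    if isinstance(law, tuple):
        return float(rng.beta(*law))
    return float(law)


def derive_rng(seed: int, *tokens: str | int) -> np.random.Generator:
    """A child generator deterministically keyed by (seed, tokens)."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(entropy)


def oracle_segment(
    regions: list[AnnotationRegion],
    corruption: OracleCorruption,
    mpp_x: float,
    mpp_y: float,
    tissue_area_mm2: float,
    slide_id: str = "slide",
    tissue_mask: TissueMask | None = None,
    rng: np.random.Generator | None = None,
) -> SlideSegmentation:
    """Turn ground-truth annotations into corrupted predicted objects.

    Each surviving annotation keeps its polygon; its predicted category is
    sampled from the flip-matrix row of the true category and its certainty
    from the configured law for (predicted category, predicted == true).
    Spurious circular objects (Poisson count) are centred on random tissue
    pixels; generating them requires ``tissue_mask``.
    """
    if rng is None:
        rng = derive_rng(corruption.seed, slide_id)
    n_cat = len(CATEGORIES)
    objects: list[SegmentedObject] = []
    for region in regions:
        if corruption.drop_rate > 0 and rng.random() < corruption.drop_rate:
            continue
        row = corruption.label_flip_matrix[CATEGORIES.index(region.category)]
        predicted = CATEGORIES[int(rng.choice(n_cat, p=row))]
        law = corruption.certainty_law(predicted, predicted == region.category)
        objects.append(
            SegmentedObject.from_polygon(
                region.polygon, predicted, _draw_certainty(law, rng), mpp_x, mpp_y
            )
        )
    n_spurious = int(rng.poisson(corruption.spurious_rate)) if corruption.spurious_rate else 0
    if n_spurious > 0:
        if tissue_mask is None:
            raise InputError("spurious objects require a tissue_mask for placement")
        ys, xs = np.nonzero(tissue_mask.mask)
        if len(xs) > 0:
            radius_px = float(
                np.sqrt(corruption.spurious_area_mm2 * 1e6 / (mpp_x * mpp_y) / np.pi)
            )
            high_risk = sorted(HIGH_RISK_CATEGORIES, key=lambda c: c.value)
            for _ in range(n_spurious):
                i = int(rng.integers(len(xs)))
                poly = Point(float(xs[i]), float(ys[i])).buffer(radius_px, quad_segs=16)
                cat = high_risk[int(rng.integers(len(high_risk)))]
                law = corruption.certainty_law(cat, False)
                objects.append(
                    SegmentedObject.from_polygon(
                        poly, cat, _draw_certainty(law, rng), mpp_x, mpp_y
                    )
                )
    return SlideSegmentation(
        slide_id=slide_id, objects=objects, tissue_area_mm2=tissue_area_mm2
    )


class OracleBackend:
    """A :class:`SegmentationBackend` backed by ground-truth annotations.

    Holds per-slide annotations and a corruption model; ``segment`` derives
    the tissue area from the supplied mask and corrupts the slide's
    annotations under a slide-keyed deterministic stream.
    """

    def __init__(
        self,
        annotations: Mapping[str, list[AnnotationRegion]],
        corruption: OracleCorruption | None = None,
    ) -> None:
        self.annotations = dict(annotations)
        self.corruption = corruption if corruption is not None else OracleCorruption.none()

    def segment(self, image: SlideImage, mask: TissueMask) -> SlideSegmentation:
        regions = self.annotations.get(image.slide_id, [])
        return oracle_segment(
            regions,
            self.corruption,
            image.mpp_x,
            image.mpp_y,
            tissue_area_mm2=mask.tissue_area_mm2,
            slide_id=image.slide_id,
            tissue_mask=mask,
        )


def check_backend_conformance(
    backend: SegmentationBackend, image: SlideImage, mask: TissueMask
) -> SlideSegmentation:
    """Run a backend on one slide and verify the contract's postconditions."""
    seg = backend.segment(image, mask)
    if seg.slide_id != image.slide_id:
        raise InputError("backend returned a segmentation for the wrong slide")
    for obj in seg.objects:
        if not 0.0 <= obj.certainty <= 1.0:
            raise InputError("backend returned certainty outside [0, 1]")
        minx, miny, maxx, maxy = obj.polygon.bounds
        sub = mask.mask[
            max(int(miny), 0) : int(np.ceil(maxy)) + 1,
            max(int(minx), 0) : int(np.ceil(maxx)) + 1,
        ]
        if sub.size == 0 or not sub.any():
            raise InputError("backend returned an object off tissue")
    return seg
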