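"""Tile labelling rule, weighted percentile, and the four slide features."""

import numpy as np
import pytest
from shapely.geometry import box

from crcscreen.errors import ConfigError, InputError
from crcscreen.features import (
    FeatureConfig,
    compute_slide_features,
    features_table,
    label_tile,
    rasterized_high_risk_area_pct,
    weighted_percentile,
)
from crcscreen.types import (
    AnnotationRegion,
    Category,
    RiskLabel,
    SegmentedObject,
    SlideSegmentation,
    Tile,
)

MPP = 4.0


def _object(category, certainty, area_mm2, x0=0.0, y0=0.0):
    side_px = np.sqrt(area_mm2 * 1e6 / (MPP * MPP))
    poly = box(x0, y0, x0 + side_px, y0 + side_px)
    return SegmentedObject.from_polygon(poly, category, certainty, MPP, MPP)


def _seg(objects, tissue=10.0):
    return SlideSegmentation(slide_id="s", objects=objects, tissue_area_mm2=tissue)


def replicate_percentile(values, int_weights, p):
    """Independent oracle: expand integer weights into replicate points."""
    pts = np.sort(np.repeat(np.asarray(values, dtype=float), int_weights))
    k = max(int(np.ceil(len(pts) * p / 100.0 - 1e-9)), 1)
    return float(pts[k - 1])


class TestLabelTile:
    TILE = Tile(0, 0, 100, 100, 775, 522, 1.0)

    def test_no_overlap_is_low_risk(self):
        region = AnnotationRegion(box(0, 0, 50, 50), Category.ADENOCA_OR_HGD)
        assert label_tile(self.TILE, [region]) is RiskLabel.LOW

    def test_single_pixel_overlap_is_high_risk(self):
        """'Any amount' of high-risk overlap flips the tile to high risk."""
        region = AnnotationRegion(box(99, 99, 101, 101), Category.LOW_GRADE_DYSPLASIA)
        assert label_tile(self.TILE, [region]) is RiskLabel.HIGH

    def test_boundary_touch_without_area_does_not_count(self):
        region = AnnotationRegion(box(50, 50, 100, 100), Category.ADENOCA_OR_HGD)
        assert label_tile(self.TILE, [region]) is RiskLabel.LOW

    def test_benign_coverage_stays_low_risk(self):
        region = AnnotationRegion(box(0, 0, 2000, 2000), Category.BENIGN_GLAND)
        assert label_tile(self.TILE, [region]) is RiskLabel.LOW

    def test_monotone_in_annotations(self):
        base = [AnnotationRegion(box(0, 0, 50, 50), Category.ADENOCA_OR_HGD)]
        extra = base + [AnnotationRegion(box(200, 200, 300, 300), Category.ADENOCA_OR_HGD)]
        assert label_tile(self.TILE, base) is RiskLabel.LOW
        assert label_tile(self.TILE, extra) is RiskLabel.HIGH

    def test_applies_to_predicted_objects_too(self):
        obj = _object(Category.ADENOCA_OR_HGD, 0.2, 0.5, x0=150, y0=150)
        assert label_tile(self.TILE, [obj]) is RiskLabel.HIGH


class TestWeightedPercentile:
    def test_single_value(self):
        assert weighted_percentile([0.42], [3.0], 1) == 0.42
        assert weighted_percentile([0.42], [3.0], 99) == 0.42

    def test_uniform_weights_bottom_percentile(self):
        values = list(range(1, 101))
        assert weighted_percentile(values, [1.0] * 100, 1) == 1.0

    def test_tiny_weight_below_cutoff_is_skipped(self):
        # cumulative weight at 0.2 is 0.005 < 0.01, so the 1-percentile is 0.9
        assert weighted_percentile([0.2, 0.9], [0.005, 0.995], 1) == 0.9
        assert replicate_percentile([0.2, 0.9], [5, 995], 1) == 0.9

    def test_matches_replicate_oracle_on_random_cases(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            values = np.round(rng.uniform(0, 1, n), 2)
            weights = rng.integers(1, 20, n)
            p = float(rng.uniform(0.5, 99.5))
            assert weighted_percentile(values, weights.astype(float), p) == \
                replicate_percentile(values, weights, p)

    def test_input_validation(self):
        with pytest.raises(InputError):
            weighted_percentile([], [], 1)
        with pytest.raises(InputError):
            weighted_percentile([1.0], [0.0], 1)
        with pytest.raises(InputError):
            weighted_percentile([1.0], [1.0, 2.0], 1)


class TestSlideFeatures:
    def test_hand_computed_single_object(self):
        seg = _seg([_object(Category.ADENOCA_OR_HGD, 0.9, 1.0)], tissue=10.0)
        fv = compute_slide_features(seg)
        assert fv.f_area_pct == pytest.approx(10.0, rel=1e-6)
        assert fv.f_wmean == pytest.approx(0.9)
        assert fv.f_flag == 1
        assert fv.f_wpctl1 == pytest.approx(0.9)

    def test_no_high_risk_objects_is_all_zero(self):
        seg = _seg([_object(Category.BENIGN_GLAND, 0.99, 2.0)])
        fv = compute_slide_features(seg)
        assert (fv.f_area_pct, fv.f_wmean, fv.f_flag, fv.f_wpctl1) == (0, 0, 0, 0)

    def test_certainty_exactly_at_threshold_excluded(self):
        """The 70% area filter is a strict inequality."""
        seg = _seg([_object(Category.ADENOCA_OR_HGD, 0.70, 1.0)])
        fv = compute_slide_features(seg)
        assert fv.f_area_pct == 0.0
        assert fv.f_wmean == pytest.approx(0.70)  # features 2 and 4 keep it

    def test_flag_area_is_cumulative(self):
        # two 0.06 mm^2 objects above 85%: together they reach 0.1 mm^2
        seg = _seg(
            [
                _object(Category.ADENOCA_OR_HGD, 0.9, 0.06),
                _object(Category.LOW_GRADE_DYSPLASIA, 0.95, 0.06, x0=500),
            ]
        )
        assert compute_slide_features(seg).f_flag == 1
        solo = _seg([_object(Category.ADENOCA_OR_HGD, 0.9, 0.06)])
        assert compute_slide_features(solo).f_flag == 0

    def test_weighted_mean_uses_all_high_risk_objects(self):
        seg = _seg(
            [
                _object(Category.ADENOCA_OR_HGD, 0.9, 3.0),
                _object(Category.LOW_GRADE_DYSPLASIA, 0.3, 1.0, x0=600),
            ]
        )
        fv = compute_slide_features(seg)
        assert fv.f_wmean == pytest.approx((0.9 * 3 + 0.3 * 1) / 4.0, rel=1e-6)
        assert fv.f_wpctl1 == pytest.approx(0.3)

    def test_adding_high_risk_object_never_decreases_area_or_flag(self):
        base = [_object(Category.ADENOCA_OR_HGD, 0.95, 0.04)]
        more = base + [_object(Category.ADENOCA_OR_HGD, 0.99, 0.08, x0=700)]
        fv0 = compute_slide_features(_seg(base))
        fv1 = compute_slide_features(_seg(more))
        assert fv1.f_area_pct >= fv0.f_area_pct
        assert fv1.f_flag >= fv0.f_flag

    def test_zero_tissue_with_objects_rejected(self):
        seg = SlideSegmentation(
            slide_id="s",
            objects=[_object(Category.ADENOCA_OR_HGD, 0.9, 1.0)],
            tissue_area_mm2=1.0,
        )
        seg.tissue_area_mm2 = 0.0
        with pytest.raises(InputError):
            compute_slide_features(seg)

    def test_feature_config_validation(self):
        with pytest.raises(ConfigError):
            FeatureConfig(certainty_threshold=1.0)
        with pytest.raises(ConfigError):
            FeatureConfig(flag_area_mm2=0.0)

    def test_analytic_area_matches_rasterization_oracle(self, default_cohort_20):
        """Polygon-analytic f_area_pct vs brute-force pixel counting, <= 1%."""
        checked = 0
        for slide in default_cohort_20:
            fv = compute_slide_features(slide.seg)
            oracle = rasterized_high_risk_area_pct(
                slide.seg,
                (slide.image.height, slide.image.width),
                slide.image.mpp_x,
                slide.image.mpp_y,
            )
            if fv.f_area_pct == 0.0:
                assert oracle == 0.0
            else:
                assert oracle == pytest.approx(fv.f_area_pct, rel=0.01)
                checked += 1
        assert checked >= 3  # the cohort must actually exercise the comparison


class TestFeaturesTable:
    def test_empty_input_gives_header_only(self):
        table = features_table([])
        assert list(table.columns) == [
            "slide_id", "f_area_pct", "f_wmean", "f_flag", "f_wpctl1",
        ]
        assert len(table) == 0

    def test_rows_sorted_by_slide_id(self):
        segs = [
            SlideSegmentation(slide_id=sid, objects=[], tissue_area_mm2=1.0)
            for sid in ("b", "a", "c")
        ]
        table = features_table(segs)
        assert list(table["slide_id"]) == ["a", "b", "c"]

    def test_duplicate_slide_id_rejected(self):
        segs = [
            SlideSegmentation(slide_id="x", objects=[], tissue_area_mm2=1.0),
            SlideSegmentation(slide_id="x", objects=[], tissue_area_mm2=1.0),
        ]
        with pytest.raises(InputError):
            features_table(segs)
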