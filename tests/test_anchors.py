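"""Anchor pyramid generation, ground-pixel ratios and the depth filter."""

import math
import warnings

import numpy as np
import pytest

from depthprop import (
    GROUND,
    INVALID,
    NON_GROUND,
    LabeledAnchor,
    apply_depth_filter,
    generate_anchor_shapes,
    ground_ratio,
    ground_ratios,
    tile_anchors,
)
from depthprop.anchors import _raster_bounds
from depthprop.geometry import GroundMask


def random_mask(rng, h=30, w=40, p_invalid=0.1):
    labels = rng.choice(
        [GROUND, NON_GROUND, INVALID], size=(h, w), p=[0.45, 0.45, p_invalid]
    ).astype(np.uint8)
    return GroundMask(labels=labels, t_f=0.1)


def oracle_ratio(box, mask):
    """Brute-force per-pixel loop with the half-open pixel convention."""
    h, w = mask.labels.shape
    x1, y1, x2, y2 = box
    n_g = n_v = 0
    for r in range(h):
        for c in range(w):
            if x1 <= c < x2 and y1 <= r < y2:
                if mask.labels[r, c] != INVALID:
                    n_v += 1
                    if mask.labels[r, c] == GROUND:
                        n_g += 1
    return None if n_v == 0 else n_g / n_v


class TestAnchorShapes:
    def test_default_pyramid_has_fifteen_shapes(self):
        shapes = generate_anchor_shapes()
        assert len(shapes) == 15
        assert len({(s.scale, s.ratio) for s in shapes}) == 15
        # each area owns exactly one pyramid level
        assert {s.level for s in shapes} == {"P2", "P3", "P4", "P5", "P6"}

    def test_square_shape(self):
        (s,) = [x for x in generate_anchor_shapes([16], [1.0])]
        assert s.width == s.height == 16

    def test_area_preserved_under_aspect_ratio(self):
        (s,) = generate_anchor_shapes([32], [0.5])
        assert s.width == pytest.approx(math.sqrt(1024 * 0.5))  # ~22.63
        assert s.height == pytest.approx(math.sqrt(1024 / 0.5))  # ~45.25
        assert s.width * s.height == pytest.approx(1024)

    @pytest.mark.parametrize("scales,ratios", [([], [1]), ([16], []), ([-4], [1]), ([16], [0])])
    def test_invalid_inputs_rejected(self, scales, ratios):
        with pytest.raises(ValueError):
            generate_anchor_shapes(scales, ratios)


class TestTiling:
    def test_single_cell_centred(self):
        (shape,) = generate_anchor_shapes([16], [1.0])
        boxes = tile_anchors(shape, (1, 1), 16)
        np.testing.assert_allclose(boxes, [[0, 0, 16, 16]])

    def test_grid_pitch_equals_stride(self):
        (shape,) = generate_anchor_shapes([16], [1.0])
        boxes = tile_anchors(shape, (2, 2), 16)
        assert len(boxes) == 4
        centres = (boxes[:, :2] + boxes[:, 2:]) / 2
        np.testing.assert_allclose(sorted(centres[:, 0]), [8, 8, 24, 24])

    def test_cardinality(self):
        (shape,) = generate_anchor_shapes([32], [2.0])
        assert len(tile_anchors(shape, (7, 5), 8)) == 35


class TestGroundRatio:
    def test_direct_count(self):
        labels = np.array([[GROUND, NON_GROUND], [GROUND, NON_GROUND]], dtype=np.uint8)
        mask = GroundMask(labels=labels, t_f=0.1)
        assert ground_ratio((0, 0, 2, 2), mask) == 0.5

    def test_matches_pixel_loop_oracle(self, rng):
        mask = random_mask(rng)
        for _ in range(50):
            x1 = rng.uniform(-5, 38)
            y1 = rng.uniform(-5, 28)
            box = (x1, y1, x1 + rng.uniform(0.5, 20), y1 + rng.uniform(0.5, 20))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    got = ground_ratio(box, mask)
            except ValueError:
                continue
            assert got == oracle_ratio(box, mask)

    def test_batch_matches_scalar(self, rng):
        mask = random_mask(rng)
        boxes = np.column_stack([
            rng.uniform(0, 30, 64), rng.uniform(0, 20, 64),
            rng.uniform(0, 30, 64), rng.uniform(0, 20, 64),
        ])
        boxes[:, 2:] = boxes[:, :2] + np.abs(boxes[:, 2:] - boxes[:, :2]) + 0.5
        batch = ground_ratios(boxes, mask)
        for b, got in zip(boxes, batch):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                want = ground_ratio(tuple(b), mask)
            if want is None:
                assert np.isnan(got)
            else:
                assert got == want

    def test_fully_outside_box_is_an_error(self, rng):
        mask = random_mask(rng)
        with pytest.raises(ValueError, match="outside"):
            ground_ratio((100, 100, 120, 120), mask)

    def test_no_valid_pixels_returns_none_with_warning(self):
        labels = np.full((4, 4), INVALID, dtype=np.uint8)
        mask = GroundMask(labels=labels, t_f=0.1)
        with pytest.warns(UserWarning, match="undefined"):
            assert ground_ratio((0, 0, 4, 4), mask) is None

    def test_raster_bounds_half_open(self):
        assert _raster_bounds(0.0, 2.0, 10) == (0, 2)
        assert _raster_bounds(0.2, 0.8, 10) == (1, 1)  # empty
        assert _raster_bounds(-3.0, 2.5, 10) == (0, 3)


def anchor(rp, label=1, score=0.9):
    return LabeledAnchor(box=(0, 0, 10, 10), score=score, softmax_label=label, r_p=rp)


class TestDepthFilter:
    def test_positive_over_ground_is_revised_negative(self):
        (out,) = apply_depth_filter([anchor(0.8, label=1)], t_d=0.5, rule="text_consistent")
        assert out.final_label == 0 and out.revised

    def test_negative_off_ground_is_forced_positive(self):
        (out,) = apply_depth_filter([anchor(0.1, label=0)], t_d=0.5, rule="text_consistent")
        assert out.final_label == 1 and out.revised

    def test_literal_rule_keeps_ground_dominated_positive(self):
        (out,) = apply_depth_filter([anchor(0.8, label=1)], t_d=0.5, rule="eq7_literal")
        assert out.final_label == 1 and not out.revised

    def test_undefined_ratio_passes_through(self):
        (out,) = apply_depth_filter([anchor(None, label=1)], t_d=0.5)
        assert out.final_label == 1 and not out.revised

    def test_idempotent(self, rng):
        anchors = [anchor(float(r), label=int(l)) for r, l in
                   zip(rng.random(50), rng.integers(0, 2, 50))]
        once = apply_depth_filter(anchors, 0.4)
        twice = apply_depth_filter(once, 0.4)
        assert [a.final_label for a in once] == [a.final_label for a in twice]

    def test_raising_threshold_never_flips_positive_to_negative(self, rng):
        anchors = [anchor(float(r)) for r in rng.random(100)]
        lo = apply_depth_filter(anchors, 0.3)
        hi = apply_depth_filter(anchors, 0.7)
        for a, b in zip(lo, hi):
            assert not (a.final_label == 1 and b.final_label == 0)

    def test_dialect_duality_away_from_threshold(self, rng):
        anchors = [anchor(float(r)) for r in rng.random(100) if abs(r - 0.5) > 1e-9]
        text = apply_depth_filter(anchors, 0.5, "text_consistent")
        lit = apply_depth_filter(anchors, 0.5, "eq7_literal")
        for a, b in zip(text, lit):
            assert a.final_label != b.final_label

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="t_d"):
            apply_depth_filter([anchor(0.5)], t_d=1.5)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            LabeledAnchor(box=(5, 5, 5, 10), score=0.5, softmax_label=0)
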