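"""FPN anchor pyramid generation and the depth filter on proposal labels.

The detector places 15 anchor shapes — five areas {16^2, 32^2, 64^2,
128^2, 256^2}, one per pyramid level P2-P6, times three aspect ratios
{1:1, 1:2, 2:1} — densely over the image. Each anchor carries a binary
classifier (softmax) label; the *depth filter* revises that label from
the fraction ``R_p`` of ground-classified pixels inside the anchor,
against a threshold ``t_d``.

Boxes are 0-based, half-open ``[x1, x2) x [y1, y2)`` in image pixels.
Anchor widths/heights are kept real-valued; rounding happens only when a
box is rasterised for pixel counting (a pixel with integer index (r, c)
lies inside iff ``x1 <= c < x2`` and ``y1 <= r < y2``).

Two filter rule dialects exist because the printed revision formula and
the accompanying prose disagree:

``text_consistent`` (default)
    final label 1 iff ``R_p < t_d`` — a stalk anchor should *not* be
    ground-dominated.
``eq7_literal``
    final label 1 iff ``R_p > t_d`` — the revision formula as printed.

Both override the softmax label entirely; a ``revised`` flag records
when the two disagree.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GROUND, INVALID, GroundMask

DEFAULT_SCALES = (16.0, 32.0, 64.0, 128.0, 256.0)
DEFAULT_RATIOS = (1.0, 0.5, 2.0)  # w:h of 1:1, 1:2, 2:1
#: pyramid level and feature stride owning each default scale
LEVEL_STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32, "P6": 64}
SCALE_LEVELS = {16.0: "P2", 32.0: "P3", 64.0: "P4", 128.0: "P5", 256.0: "P6"}


class FilterRule(str, enum.Enum):
    TEXT_CONSISTENT = "text_consistent"
    EQ7_LITERAL = "eq7_literal"


@dataclass(frozen=True)
class AnchorShape:
    """One (area, aspect ratio) anchor template.

    ``width * height`` equals the nominal area ``scale**2`` exactly;
    values stay real-valued until rasterisation.
    """

    scale: float  # side of the square of equal area (area = scale**2)
    ratio: float  # w : h
    width: float
    height: float
    level: str | None = None

    @property
    def area(self) -> float:
        return self.scale * self.scale


@dataclass
class LabeledAnchor:
    """Axis-aligned box with classifier score/label and the filter's verdict."""

    box: tuple[float, float, float, float]
    score: float
    softmax_label: int
    r_p: float | None = None
    final_label: int | None = None
    revised: bool = False

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")


def generate_anchor_shapes(
    scales=DEFAULT_SCALES, ratios=DEFAULT_RATIOS
) -> list[AnchorShape]:
    """Cartesian product of scales x ratios; default 5 x 3 = 15 shapes.

    For area ``a = scale**2`` and ratio ``r = w/h``: ``w = sqrt(a r)``,
    ``h = sqrt(a / r)``, preserving area exactly.
    """
    if len(scales) == 0 or len(ratios) == 0:
        raise ValueError("scales and ratios must be non-empty")
    shapes = []
    for s in scales:
        if s <= 0:
            raise ValueError(f"nonpositive scale {s}")
        for r in ratios:
            if r <= 0:
                raise ValueError(f"nonpositive ratio {r}")
            area = float(s) * float(s)
            w = math.sqrt(area * r)
            h = math.sqrt(area / r)
            shapes.append(
                AnchorShape(
                    scale=float(s),
                    ratio=float(r),
                    width=w,
                    height=h,
                    level=SCALE_LEVELS.get(float(s)),
                )
            )
    return shapes


def tile_anchors(
    shape: AnchorShape, feature_size: tuple[int, int], stride: int
) -> np.ndarray:
    """Place one anchor per feature cell, centred at ``((c+.5)s, (r+.5)s)``.

    Returns an (rows*cols, 4) array of (x1, y1, x2, y2). Anchors may
    exceed image bounds; clipping is a separate, optional step.
    """
    rows, cols = feature_size
    cx = (np.arange(cols, dtype=np.float64) + 0.5) * stride
    cy = (np.arange(rows, dtype=np.float64) + 0.5) * stride
    cxg, cyg = np.meshgrid(cx, cy)
    hw, hh = shape.width / 2.0, shape.height / 2.0
    boxes = np.stack(
        [cxg - hw, cyg - hh, cxg + hw, cyg + hh], axis=-1
    ).reshape(-1, 4)
    return boxes


def tile_pyramid(
    image_size: tuple[int, int],
    scales=DEFAULT_SCALES,
    ratios=DEFAULT_RATIOS,
) -> np.ndarray:
    """Tile all anchor shapes over their pyramid levels for a whole image.

    ``image_size`` is (height, width). Each scale is tiled at the stride
    of its level (P2: 4 ... P6: 64) with feature size ``ceil(dim/stride)``.
    Returns an (N, 4) box array.
    """
    h, w = image_size
    all_boxes = []
    for shape in generate_anchor_shapes(scales, ratios):
        if shape.level is None:
            raise ValueError(f"scale {shape.scale} has no assigned pyramid level")
        stride = LEVEL_STRIDES[shape.level]
        fsize = (math.ceil(h / stride), math.ceil(w / stride))
        all_boxes.append(tile_anchors(shape, fsize, stride))
    return np.concatenate(all_boxes, axis=0)


def _raster_bounds(lo: float, hi: float, size: int) -> tuple[int, int]:
    """Half-open integer pixel range covered by [lo, hi), clipped to [0, size)."""
    lo_i = max(int(math.ceil(lo)), 0)
    hi_i = min(int(math.ceil(hi)), size)
    return lo_i, hi_i


def ground_ratio(box, mask: GroundMask) -> float | None:
    """Fraction ``R_p`` of ground pixels among valid pixels inside a box.

    The box is clipped to the image first. Returns None (undefined) when
    the clipped box contains no valid pixel; raises if the box lies fully
    outside the image.
    """
    h, w = mask.labels.shape
    x1, y1, x2, y2 = box
    if x2 <= 0 or y2 <= 0 or x1 >= w or y1 >= h:
        raise ValueError(f"box {tuple(box)} lies fully outside the {w}x{h} image")
    c1, c2 = _raster_bounds(x1, x2, w)
    r1, r2 = _raster_bounds(y1, y2, h)
    sub = mask.labels[r1:r2, c1:c2]
    n_valid = int(np.count_nonzero(sub != INVALID))
    if n_valid == 0:
        warnings.warn(
            f"box {tuple(box)} contains no valid pixel; R_p undefined", stacklevel=2
        )
        return None
    n_ground = int(np.count_nonzero(sub == GROUND))
    return n_ground / n_valid


def ground_ratios(boxes: np.ndarray, mask: GroundMask) -> np.ndarray:
    """Vectorised ``R_p`` for an (N, 4) box array via summed-area tables.

    Pixel-count semantics are identical to :func:`ground_ratio`. Boxes
    with no valid pixel (including boxes fully outside the image) get NaN.
    """
    h, w = mask.labels.shape
    gint = np.zeros((h + 1, w + 1), dtype=np.int64)
    vint = np.zeros((h + 1, w + 1), dtype=np.int64)
    gint[1:, 1:] = np.cumsum(np.cumsum(mask.labels == GROUND, axis=0), axis=1)
    vint[1:, 1:] = np.cumsum(np.cumsum(mask.labels != INVALID, axis=0), axis=1)

    boxes = np.asarray(boxes, dtype=np.float64)
    c1 = np.clip(np.ceil(boxes[:, 0]).astype(np.int64), 0, w)
    c2 = np.clip(np.ceil(boxes[:, 2]).astype(np.int64), 0, w)
    r1 = np.clip(np.ceil(boxes[:, 1]).astype(np.int64), 0, h)
    r2 = np.clip(np.ceil(boxes[:, 3]).astype(np.int64), 0, h)
    c2 = np.maximum(c2, c1)
    r2 = np.maximum(r2, r1)

    def rect_sum(tab, r1, r2, c1, c2):
        return tab[r2, c2] - tab[r1, c2] - tab[r2, c1] + tab[r1, c1]

    n_ground = rect_sum(gint, r1, r2, c1, c2)
    n_valid = rect_sum(vint, r1, r2, c1, c2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rp = n_ground / n_valid
    return np.where(n_valid > 0, rp, np.nan)


def apply_depth_filter(
    anchors: list[LabeledAnchor],
    t_d: float = 0.5,
    rule: FilterRule | str = FilterRule.TEXT_CONSISTENT,
) -> list[LabeledAnchor]:
    """Set each anchor's final label from its ground-pixel ratio.

    Anchors whose ``r_p`` is None (no valid pixels) pass through with
    their softmax label unchanged. The operation is idempotent: the final
    label depends only on (``r_p``, ``t_d``, rule).
    """
    if not 0.0 <= t_d <= 1.0:
        raise ValueError(f"t_d must lie in [0, 1], got {t_d}")
    rule = FilterRule(rule)
    out = []
    for a in anchors:
        if a.r_p is None:
            final = a.softmax_label
        elif rule is FilterRule.TEXT_CONSISTENT:
            final = 1 if a.r_p < t_d else 0
        else:
            final = 1 if a.r_p > t_d else 0
        out.append(replace(a, final_label=final, revised=(final != a.softmax_label)))
    return out
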