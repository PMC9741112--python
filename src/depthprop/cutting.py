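"""3D cutting-point localisation for detected stalks.

The harvester blade needs the 3D camera-frame coordinate at which to
sever a stalk. Given an instance mask, the per-pixel point map and the
ground test at a *stricter* tolerance than the one used for anchor
filtering (default half of it), the mask pixels closest (in 2D image
distance) to ground-classified pixels are selected — up to 20 — and the
cutting point is the arithmetic mean of their 3D coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import CameraModel
from .geometry import Dialect, GroundMask, PointMap, ground_mask

#: number of near-ground mask pixels averaged into the cutting point
DEFAULT_K = 20
#: stricter tolerance = this factor times the anchor-level t_f
STRICT_FACTOR = 0.5


@dataclass
class CutPoint:
    """A 3D cutting point (metres, camera frame) and its provenance."""

    x: float
    y: float
    z: float
    n_pixels_used: int
    pixels: list[tuple[int, int]]  # (row, col) of the averaged pixels

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def near_ground_pixels(
    mask: np.ndarray,
    point_map: PointMap,
    camera: CameraModel,
    t_f_strict: float,
    k: int = DEFAULT_K,
    dialect: Dialect | str = Dialect.PLANE_DISTANCE,
    ground: GroundMask | None = None,
) -> list[tuple[int, int]]:
    """Rank valid mask pixels by 2D distance to the nearest ground pixel.

    Ground membership is evaluated at the strict tolerance ``t_f_strict``
    (pass a precomputed ``ground`` mask to skip re-classification).
    Returns the k nearest (row, col) pixels in ascending distance order;
    ties break toward larger row (lower in the image), then larger
    column. If fewer than k valid pixels exist, all are returned with a
    warning.

    Raises
    ------
    ValueError
        If the mask is empty, or the image contains no ground pixel at
        the strict tolerance (the stalk cannot be positioned).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != point_map.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match point map {point_map.shape}"
        )
    if not mask.any():
        raise ValueError("instance mask is empty")
    if ground is None:
        ground = ground_mask(point_map, camera, t_f_strict, dialect)
    is_ground = ground.is_ground
    if not is_ground.any():
        raise ValueError(
            "no ground pixels at the strict tolerance; stalk cannot be positioned"
        )
    # Euclidean distance (pixel centres) from every pixel to the ground set;
    # a mask pixel that is itself ground-classified has distance 0.
    dist = ndimage.distance_transform_edt(~is_ground)

    cand = mask & point_map.valid
    if not cand.any():
        raise ValueError("instance mask has no valid-depth pixel")
    rows, cols = np.nonzero(cand)
    d = dist[rows, cols]
    order = np.lexsort((-cols, -rows, d))  # distance asc, then row desc, col desc
    n_avail = len(order)
    if n_avail < k:
        warnings.warn(
            f"only {n_avail} valid mask pixels available (< k={k}); using all",
            stacklevel=2,
        )
    sel = order[: min(k, n_avail)]
    return [(int(rows[i]), int(cols[i])) for i in sel]


def cutting_point(pixels, point_map: PointMap) -> CutPoint:
    """Component-wise mean 3D coordinate of the selected pixels."""
    if len(pixels) == 0:
        raise ValueError("pixel list is empty")
    rows = np.array([p[0] for p in pixels])
    cols = np.array([p[1] for p in pixels])
    if not point_map.valid[rows, cols].all():
        raise ValueError("all selected pixels must be valid in the point map")
    return CutPoint(
        x=float(point_map.x[rows, cols].mean()),
        y=float(point_map.y[rows, cols].mean()),
        z=float(point_map.z[rows, cols].mean()),
        n_pixels_used=len(pixels),
        pixels=[(int(r), int(c)) for r, c in pixels],
    )


def locate_cutting_point(
    mask: np.ndarray,
    point_map: PointMap,
    camera: CameraModel,
    t_f: float = 0.1,
    k: int = DEFAULT_K,
    dialect: Dialect | str = Dialect.PLANE_DISTANCE,
    ground: GroundMask | None = None,
) -> CutPoint:
    """Convenience wrapper: strict-tolerance pixel selection + averaging.

    ``t_f`` is the anchor-level tolerance; the pixel selection runs at
    ``STRICT_FACTOR * t_f``.
    """
    pixels = near_ground_pixels(
        mask, point_map, camera, STRICT_FACTOR * t_f, k=k, dialect=dialect, ground=ground
    )
    return cutting_point(pixels, point_map)


def filter_small_stalks(
    detections,
    min_mask_pixels: int = 0,
    min_height_m: float = 0.0,
):
    """Drop detections of small stalks (not worth cutting).

    Each detection is a mapping with a boolean ``mask`` and optionally a
    ``height_m`` estimate. A detection survives if its mask has at least
    ``min_mask_pixels`` pixels and (when it carries a height) its height
    is at least ``min_height_m``. Thresholds default to 0 (identity).
    """
    kept = []
    for det in detections:
        n = int(np.count_nonzero(np.asarray(det["mask"], dtype=bool)))
        if n < min_mask_pixels:
            continue
        h = det.get("height_m")
        if h is not None and h < min_height_m:
            continue
        kept.append(det)
    return kept
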