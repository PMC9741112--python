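"""Depth back-projection and ground / non-ground pixel classification.

A depth image (millimetres, 0 = missing) is back-projected through the
pinhole model to a per-pixel 3D :class:`PointMap` in the camera frame.
Each valid point is then classified *ground* (member of ``P_g``) or
*non-ground* (``P_n``) from the mounting geometry alone, under a
relative tolerance factor ``t_f``.

Two classification dialects are provided:

``piecewise``
    The piecewise trigonometric test: for x < 0 the slope ratio
    ``z / (|x_g| - |x|)`` must fall inside ``[(1-t_f) tan(a), (1+t_f) tan(a)]``;
    for x >= 0 the ratio ``(h_c + x cos(a)) / z`` must fall inside
    ``[(1-t_f) sin(a), (1+t_f) sin(a)]``. The x >= 0 branch is algebraically
    exact on the plane ``z sin(a) - x cos(a) = h_c``; the x < 0 branch is
    a distinct construction and is kept verbatim (see docs/methods.md).

``plane_distance``
    The self-consistent alternative: a point is ground iff its
    perpendicular distance to the plane is at most ``t_f * h_c``.

Band endpoints are inclusive, so ``t_f = 0`` accepts exactly-on-band
points.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel

# ternary per-pixel states shared with the PNG encoding in io.py
NON_GROUND = 0
GROUND = 1
INVALID = 2


class Dialect(str, enum.Enum):
    """Which formulation of the ground test to apply."""

    PIECEWISE = "piecewise"
    PLANE_DISTANCE = "plane_distance"


@dataclass
class PointMap:
    """Per-pixel 3D coordinates (metres, camera frame) with validity flags.

    ``x``, ``y``, ``z`` and ``valid`` all share the source depth image
    shape. Invalid pixels (depth 0) carry NaN coordinates.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def __post_init__(self) -> None:
        if not (self.x.shape == self.y.shape == self.z.shape == self.valid.shape):
            raise ValueError("PointMap component shapes differ")


@dataclass
class GroundMask:
    """Ternary ground / non-ground / invalid partition of an image.

    ``labels`` holds :data:`GROUND`, :data:`NON_GROUND` or :data:`INVALID`
    per pixel; every valid pixel is in exactly one of P_g, P_n.
    """

    labels: np.ndarray
    t_f: float
    dialect: Dialect = Dialect.PIECEWISE

    @property
    def is_ground(self) -> np.ndarray:
        return self.labels == GROUND

    @property
    def is_valid(self) -> np.ndarray:
        return self.labels != INVALID

    @property
    def n_ground(self) -> int:
        return int(np.count_nonzero(self.labels == GROUND))

    @property
    def n_non_ground(self) -> int:
        return int(np.count_nonzero(self.labels == NON_GROUND))


def backproject(depth_mm: np.ndarray, camera: CameraModel) -> PointMap:
    """Back-project a depth image (millimetres) to camera-frame points.

    The stored depth is the z coordinate in the camera frame. For a pixel
    (u, v) with depth z metres: ``x = (u - cx) z / fx``,
    ``y = (v - cy) z / fy``. Zero depth marks a missing measurement.

    Raises
    ------
    ValueError
        If the image shape does not match the camera, or depths are negative.
    """
    depth_mm = np.asarray(depth_mm)
    expected = (camera.height, camera.width)
    if depth_mm.shape != expected:
        raise ValueError(
            f"depth image shape {depth_mm.shape} does not match camera image size {expected}"
        )
    if np.any(depth_mm < 0):
        raise ValueError("depth values must be >= 0")

    z = depth_mm.astype(np.float64) / 1000.0
    valid = z > 0
    u = np.arange(camera.width, dtype=np.float64)[None, :]
    v = np.arange(camera.height, dtype=np.float64)[:, None]
    with np.errstate(invalid="ignore"):
        x = (u - camera.cx) * z / camera.fx
        y = (v - camera.cy) * z / camera.fy
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    zz = np.where(valid, z, np.nan)
    return PointMap(x=x, y=y, z=zz, valid=valid)


def plane_signed_distance(x, z, camera: CameraModel):
    """Signed perpendicular distance to the ground plane (metres).

    Positive beyond the plane (away from the camera), negative between the
    plane and the camera; the plane normal is unit length so the expression
    ``z sin(a) - x cos(a) - h_c`` is already metric.
    """
    a = camera.alpha
    return z * math.sin(a) - x * math.cos(a) - camera.h_c


def classify_ground_pixel(
    point,
    camera: CameraModel,
    t_f: float,
    dialect: Dialect | str = Dialect.PIECEWISE,
    x_g: float | None = None,
) -> bool:
    """Classify a single valid 3D point as ground (True) or non-ground.

    Parameters
    ----------
    point : sequence of 3 floats
        (x, y, z) in metres, camera frame; z must be positive. The y
        coordinate is ignored (the test lives in the sagittal plane).
    t_f : float
        Tolerance factor (relative half-width of the acceptance band).
    dialect : Dialect
        Formulation to use; see module docstring.
    x_g : float, optional
        x coordinate of the ground reference point used by the x < 0
        branch of the piecewise test. Defaults to the z = 0 intercept
        of the sagittal ground line, ``-h_c / cos(alpha)``.
    """
    x, _, z = float(point[0]), float(point[1]), float(point[2])
    if not z > 0:
        raise ValueError(f"point must have z > 0, got z={z}")
    if t_f < 0:
        raise ValueError(f"t_f must be >= 0, got {t_f}")
    dialect = Dialect(dialect)
    a = camera.alpha

    if dialect is Dialect.PLANE_DISTANCE:
        return abs(plane_signed_distance(x, z, camera)) <= t_f * camera.h_c

    if x < 0:
        xg = camera.x_ground_intercept if x_g is None else x_g
        denom = abs(xg) - abs(x)
        if denom <= 0:
            warnings.warn(
                f"x={x:.4f} lies at or beyond the ground intercept x_g={xg:.4f}; "
                "classifying non-ground",
                stacklevel=2,
            )
            return False
        ratio = z / denom
        t = math.tan(a)
        return (1 - t_f) * t <= ratio <= (1 + t_f) * t
    ratio = (camera.h_c + x * math.cos(a)) / z
    s = math.sin(a)
    return (1 - t_f) * s <= ratio <= (1 + t_f) * s


def ground_mask(
    point_map: PointMap,
    camera: CameraModel,
    t_f: float = 0.1,
    dialect: Dialect | str = Dialect.PIECEWISE,
    x_g: float | None = None,
) -> GroundMask:
    """Vectorised ground classification of every valid pixel of a point map.

    Invalid pixels are marked :data:`INVALID`; valid pixels land in exactly
    one of P_g / P_n. Semantics per pixel are identical to
    :func:`classify_ground_pixel`.
    """
    if t_f < 0:
        raise ValueError(f"t_f must be >= 0, got {t_f}")
    dialect = Dialect(dialect)
    a = camera.alpha
    x, z, valid = point_map.x, point_map.z, point_map.valid

    labels = np.full(point_map.shape, INVALID, dtype=np.uint8)
    with np.errstate(invalid="ignore", divide="ignore"):
        if dialect is Dialect.PLANE_DISTANCE:
            dist = np.abs(z * math.sin(a) - x * math.cos(a) - camera.h_c)
            is_g = dist <= t_f * camera.h_c
        else:
            is_g = np.zeros(point_map.shape, dtype=bool)
            neg = valid & (x < 0)
            pos = valid & (x >= 0)
            if np.any(neg):
                xg = camera.x_ground_intercept if x_g is None else x_g
                denom = abs(xg) - np.abs(x)
                bad = neg & (denom <= 0)
                if np.any(bad):
                    warnings.warn(
                        f"{int(np.count_nonzero(bad))} pixel(s) lie at or beyond the "
                        f"ground intercept x_g={xg:.4f}; classified non-ground",
                        stacklevel=2,
                    )
                ratio = z / denom
                t = math.tan(a)
                is_g |= neg & ~bad & ((1 - t_f) * t <= ratio) & (ratio <= (1 + t_f) * t)
            if np.any(pos):
                ratio = (camera.h_c + x * math.cos(a)) / z
                s = math.sin(a)
                is_g |= pos & ((1 - t_f) * s <= ratio) & (ratio <= (1 + t_f) * s)

    labels[valid & is_g] = GROUND
    labels[valid & ~is_g] = NON_GROUND
    return GroundMask(labels=labels, t_f=t_f, dialect=dialect)
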