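"""Pinhole camera model with harvester mounting geometry.

The camera looks forward along its z axis and is mounted above a planar
(loess) ground. ``h_c`` is the distance from the camera origin to the
ground plane and ``alpha`` the acute angle between the ground and the
optical (z) axis. The sagittal plane of the machine is the camera's xCz
plane; y points out of that plane and plays no role in the ground test.

In the camera frame the ground plane is::

    z * sin(alpha) - x * cos(alpha) = h_c

with unit normal ``n = (-cos(alpha), 0, sin(alpha))``; the camera origin
lies on the side ``n . p = 0 < h_c``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class CameraModel:
    """Intrinsics plus mounting geometry.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels (must be positive).
    cx, cy : float
        Principal point in pixels.
    width, height : int
        Image size in pixels.
    h_c : float
        Camera-origin-to-ground distance in metres (positive).
    alpha : float
        Acute angle between the ground and the camera z axis, radians,
        in (0, pi/2).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    h_c: float
    alpha: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if self.width < 1 or self.height < 1:
            raise ValueError(f"invalid image size {self.width}x{self.height}")
        if self.h_c <= 0:
            raise ValueError(f"h_c must be positive, got {self.h_c}")
        if not 0.0 < self.alpha < math.pi / 2:
            raise ValueError(f"alpha must lie in (0, pi/2), got {self.alpha}")

    @property
    def beta(self) -> float:
        """Complement of the tilt angle, ``pi/2 - alpha`` (always derived)."""
        return math.pi / 2 - self.alpha

    @property
    def x_ground_intercept(self) -> float:
        """x-intercept of the sagittal ground line at z = 0: ``-h_c / cos(alpha)``."""
        return -self.h_c / math.cos(self.alpha)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
            "h_c_m": self.h_c,
            "alpha_deg": math.degrees(self.alpha),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            width=int(d["width"]),
            height=int(d["height"]),
            h_c=float(d["h_c_m"]),
            alpha=math.radians(float(d["alpha_deg"])),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "CameraModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_camera() -> CameraModel:
    """Camera used throughout the synthetic experiments.

    640 x 480 with a ~59 degree horizontal field of view (fx = fy = 570),
    mounted 0.45 m above the ground, tilted 35 degrees. With this mounting
    the whole image lies below the ground horizon and ground depths span
    roughly 0.45-4 m, matching a low-mounted harvester camera.
    """
    return CameraModel(
        fx=570.0,
        fy=570.0,
        cx=319.5,
        cy=239.5,
        width=640,
        height=480,
        h_c=0.45,
        alpha=math.radians(35.0),
    )
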