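"""Quantization-free regional feature aggregation (ROI Align).

A continuous box on a feature map is split into an output grid of equal
sub-regions; each sub-region is summarised by the mean of a regular grid
of bilinear samples. No coordinate is ever rounded, which removes the
two quantization steps of ROI Pooling.

Convention: pixel (i, j) of the feature map has its centre at continuous
coordinate (x=j, y=i); boxes are given in the same frame. Samples
falling outside the grid clamp to the border values, and a sample point
is accepted anywhere within half a pixel beyond the border
(``[-0.5, width-0.5] x [-0.5, height-0.5]``).
"""

from __future__ import annotations

import numpy as np


def _bilinear(feature: np.ndarray, x: float, y: float) -> float:
    h, w = feature.shape
    x0 = int(np.floor(x))
    y0 = int(np.floor(y))
    dx = x - x0
    dy = y - y0
    # clamp the four interpolation nodes to the grid (border extension)
    x0c, x1c = np.clip(x0, 0, w - 1), np.clip(x0 + 1, 0, w - 1)
    y0c, y1c = np.clip(y0, 0, h - 1), np.clip(y0 + 1, 0, h - 1)
    return float(
        feature[y0c, x0c] * (1 - dx) * (1 - dy)
        + feature[y0c, x1c] * dx * (1 - dy)
        + feature[y1c, x0c] * (1 - dx) * dy
        + feature[y1c, x1c] * dx * dy
    )


def bilinear_sample(feature: np.ndarray, point) -> float:
    """Bilinearly interpolate the feature map at a continuous (x, y) point.

    The value is computed from the four nearest pixel centres; at an
    exact pixel centre it equals that pixel's value.

    Raises
    ------
    ValueError
        If the point lies outside the half-pixel-padded domain.
    """
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim != 2 or feature.shape[0] < 1 or feature.shape[1] < 1:
        raise ValueError(f"feature map must be a 2D grid, got shape {feature.shape}")
    x, y = float(point[0]), float(point[1])
    h, w = feature.shape
    if not (-0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5):
        raise ValueError(
            f"sample point ({x}, {y}) outside padded domain "
            f"[-0.5, {w - 0.5}] x [-0.5, {h - 0.5}]"
        )
    return _bilinear(feature, x, y)


def roi_align(
    feature: np.ndarray,
    box,
    output_size: tuple[int, int],
    samples_per_bin: int = 2,
) -> np.ndarray:
    """Aggregate a continuous box into a fixed (rows, cols) grid.

    The box is split into ``rows x cols`` equal sub-regions; each output
    cell is the mean of ``samples_per_bin**2`` regularly spaced bilinear
    samples inside its sub-region (sample k of n sits at fraction
    ``(k + 0.5) / n`` of the bin extent). Samples beyond the feature grid
    clamp to border values.
    """
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim != 2:
        raise ValueError(f"feature map must be 2D, got shape {feature.shape}")
    x1, y1, x2, y2 = (float(v) for v in box)
    if not (x2 > x1 and y2 > y1):
        raise ValueError(f"box {tuple(box)} has nonpositive area")
    rows, cols = output_size
    if rows < 1 or cols < 1:
        raise ValueError(f"output size must be >= 1x1, got {output_size}")
    n = int(samples_per_bin)
    if n < 1:
        raise ValueError(f"samples_per_bin must be >= 1, got {samples_per_bin}")

    bin_w = (x2 - x1) / cols
    bin_h = (y2 - y1) / rows
    frac = (np.arange(n) + 0.5) / n
    out = np.empty((rows, cols), dtype=np.float64)
    for i in range(rows):
        ys = y1 + bin_h * (i + frac)
        for j in range(cols):
            xs = x1 + bin_w * (j + frac)
            acc = 0.0
            for yy in ys:
                for xx in xs:
                    acc += _bilinear(feature, xx, yy)
            out[i, j] = acc / (n * n)
    return out
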