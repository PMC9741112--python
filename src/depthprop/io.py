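"""File formats: 16-bit depth PNGs, mask PNGs, anchor JSON-lines and
COCO-style instance JSON.

Depth files are single-channel 16-bit PNGs holding millimetres, 0 =
invalid. Ground masks are 8-bit PNGs with 0 = non-ground, 255 = ground,
128 = invalid. Instance annotations are a COCO-style JSON dict
(``{"instances": [{"id", "bbox" [x, y, w, h], "segmentation"
[[x1, y1, x2, y2, ...]]}]}``) or an 8-bit label PNG (0 = background,
i = instance i).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon as sk_polygon

from .anchors import LabeledAnchor
from .geometry import GROUND, INVALID, NON_GROUND, GroundMask

_MASK_ENCODE = {NON_GROUND: 0, GROUND: 255, INVALID: 128}
_MASK_DECODE = {0: NON_GROUND, 255: GROUND, 128: INVALID}


def write_depth_png(path, depth_mm: np.ndarray) -> None:
    arr = np.asarray(depth_mm)
    if np.any(arr < 0) or np.any(arr > 65535):
        raise ValueError("depth values must fit uint16 millimetres")
    iio.imwrite(str(path), np.round(arr).astype(np.uint16), extension=".png")


def read_depth_png(path) -> np.ndarray:
    arr = iio.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"depth PNG must be single-channel, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_rgb_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(str(path), np.asarray(rgb, dtype=np.uint8), extension=".png")


def write_ground_mask_png(path, mask: GroundMask) -> None:
    out = np.zeros(mask.labels.shape, dtype=np.uint8)
    for state, value in _MASK_ENCODE.items():
        out[mask.labels == state] = value
    iio.imwrite(str(path), out, extension=".png")


def read_ground_mask_png(path, t_f: float = float("nan")) -> GroundMask:
    arr = iio.imread(str(path))
    labels = np.full(arr.shape, INVALID, dtype=np.uint8)
    for value, state in _MASK_DECODE.items():
        labels[arr == value] = state
    return GroundMask(labels=labels, t_f=t_f)


def write_anchors_jsonl(path, anchors: list[LabeledAnchor]) -> None:
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(
                json.dumps(
                    {
                        "box": [float(v) for v in a.box],
                        "score": a.score,
                        "softmax_label": a.softmax_label,
                        "R_p": a.r_p,
                        "final_label": a.final_label,
                        "revised": a.revised,
                    }
                )
                + "\n"
            )


def read_anchors_jsonl(path) -> list[LabeledAnchor]:
    anchors = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        anchors.append(
            LabeledAnchor(
                box=tuple(d["box"]),
                score=float(d["score"]),
                softmax_label=int(d["softmax_label"]),
                r_p=d.get("R_p"),
                final_label=d.get("final_label"),
                revised=bool(d.get("revised", False)),
            )
        )
    return anchors


def masks_to_instances_json(masks: list[np.ndarray]) -> dict:
    """Encode boolean instance masks as COCO-style polygon instances.

    Polygons are extracted as the convex traversal of each mask's
    contour via marching squares (one polygon per instance).
    """
    from skimage import measure

    instances = []
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        rr, cc = np.nonzero(mask)
        if len(rr) == 0:
            continue
        bbox = [float(cc.min()), float(rr.min()), float(cc.max() - cc.min() + 1), float(rr.max() - rr.min() + 1)]
        contours = measure.find_contours(mask.astype(float), 0.5)
        segs = []
        for contour in contours:
            # contour rows/cols -> flat [x1, y1, x2, y2, ...]
            seg = np.empty(contour.shape[0] * 2)
            seg[0::2] = contour[:, 1]
            seg[1::2] = contour[:, 0]
            segs.append([float(v) for v in seg])
        instances.append({"id": i + 1, "bbox": bbox, "segmentation": segs})
    return {"instances": instances}


def instances_json_to_masks(data: dict, image_size: tuple[int, int]) -> list[np.ndarray]:
    """Rasterise COCO-style polygon instances to boolean masks.

    ``image_size`` is (height, width).
    """
    h, w = image_size
    masks = []
    for inst in data["instances"]:
        mask = np.zeros((h, w), dtype=bool)
        for seg in inst["segmentation"]:
            xs = np.asarray(seg[0::2], dtype=float)
            ys = np.asarray(seg[1::2], dtype=float)
            rr, cc = sk_polygon(ys, xs, shape=(h, w))
            mask[rr, cc] = True
        masks.append(mask)
    return masks


def read_instance_masks(path, image_size: tuple[int, int]) -> list[np.ndarray]:
    """Read instance masks from COCO-style JSON or an 8-bit label PNG."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return instances_json_to_masks(json.loads(path.read_text()), image_size)
    arr = iio.imread(str(path))
    return [arr == i for i in range(1, int(arr.max()) + 1)]


def save_scene(scene, out_dir) -> None:
    """Write a simulated scene to a directory: rgb.png, depth.png,
    ground.png (truth labels), camera.json, instances.json, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene.config.camera.save_json(out / "camera.json")
    write_rgb_png(out / "rgb.png", scene.rgb)
    write_depth_png(out / "depth.png", scene.depth_mm)
    write_ground_mask_png(out / "ground.png", scene.true_ground_mask())
    (out / "instances.json").write_text(json.dumps(masks_to_instances_json(scene.masks)))
    truth = {
        "condition": scene.condition,
        "boxes": scene.boxes.tolist(),
        "cut_points_m": scene.cut_points.tolist(),
        "camera": scene.config.camera.to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
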