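"""Fundus-image preprocessing and the 30-variant augmentation catalogue.

Preprocessing follows resize (bilinear) -> median filter -> CLAHE, the
standard chain for normalizing heterogeneous-resolution retinal
photographs before segmentation.  Augmentation expands a labeled dataset
sevenfold: each source image contributes itself plus six operations
sampled without replacement from a catalogue of thirty parameterized
variants (sharpen, emboss, Gaussian blur, rotation, edge enhancement,
skew, flip, shear).

Images are carried as float arrays in [0, 1], grayscale (r, c) or RGB
(r, c, 3), inside :class:`ImageRecord` together with their class label and
an append-only provenance trail.  Geometric operations keep the input
canvas (reflection padding), so shapes are stable down the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import convolve, median_filter
from skimage import exposure, filters, transform

__all__ = [
    "ImageRecord",
    "AugmentationOp",
    "preprocess_image",
    "augmentation_catalogue",
    "apply_augmentation",
    "sevenfold_augment",
    "split_counts",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


@dataclass
class ImageRecord:
    """An image with its label and an append-only provenance trail."""

    pixels: np.ndarray
    label: object = None
    source_id: str = ""
    provenance: tuple = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D grayscale or 3-D RGB")
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = np.clip(p, 0.0, 1.0)

    def with_pixels(self, pixels: np.ndarray, op_tag: str) -> "ImageRecord":
        return ImageRecord(
            pixels=np.clip(pixels, 0.0, 1.0),
            label=self.label,
            source_id=self.source_id,
            provenance=self.provenance + (op_tag,),
        )


@dataclass(frozen=True)
class AugmentationOp:
    """A named augmentation with one parameter (level, angle, direction or
    axis, depending on the operation)."""

    name: str
    parameter: object


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _per_channel(pixels: np.ndarray, fn) -> np.ndarray:
    if pixels.ndim == 2:
        return fn(pixels)
    return np.dstack([fn(pixels[..., c]) for c in range(pixels.shape[2])])


def preprocess_image(
    img: ImageRecord,
    out_size: tuple[int, int],
    median_k: int = 3,
    clahe: Optional[tuple[float, int]] = (2.0, 8),
) -> ImageRecord:
    """Resize (bilinear) -> median filter -> CLAHE, in that order.

    Parameters
    ----------
    out_size
        Target (height, width); resizing is skipped when it already matches.
    median_k
        Odd median-filter window; 1 disables filtering.
    clahe
        ``(clip_limit, tiles)`` for contrast-limited adaptive histogram
        equalization (applied per channel), or ``None`` to disable.
    """
    if not isinstance(img, ImageRecord):
        raise TypeError("preprocess_image expects an ImageRecord")
    h, w = out_size
    if h < 1 or w < 1:
        raise ValueError("out_size must be positive")
    if median_k < 1 or median_k % 2 == 0:
        raise ValueError("median_k must be an odd integer >= 1")
    pixels = img.pixels
    if pixels.shape[:2] != (h, w):
        pixels = transform.resize(
            pixels, (h, w), order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    if median_k > 1:
        pixels = _per_channel(pixels, lambda ch: median_filter(ch, size=median_k))
    if clahe is not None:
        clip, tiles = clahe
        kernel = (max(1, h // tiles), max(1, w // tiles))
        pixels = _per_channel(
            pixels,
            lambda ch: exposure.equalize_adapthist(
                np.clip(ch, 0, 1), kernel_size=kernel, clip_limit=clip
            ),
        )
    tag = f"preprocess(size={h}x{w},median={median_k},clahe={clahe})"
    return img.with_pixels(pixels, tag)


# ---------------------------------------------------------------------------
# augmentation catalogue
# ---------------------------------------------------------------------------

_SHARPEN_LEVELS = (0.5, 1.0, 1.5, 2.0)
_EMBOSS_LEVELS = (0.5, 1.0, 1.5, 2.0)
_BLUR_SCALES = (0.25, 0.5, 1.0, 2.0)
_ROTATE_ANGLES = (45, 90, 135, 180)
_EDGE_LEVELS = (0.25, 0.5, 0.75, 1.0)
_SKEW_DIRECTIONS = ("left", "right", "forward", "backward")
_FLIP_AXES = ("left", "right", "top", "bottom")
_SHEAR_AXES = ("x", "y")
_SHEAR_DEGREES = 10.0  # stated magnitude, reused for skew


def augmentation_catalogue() -> list[AugmentationOp]:
    """The full 30-operation catalogue: 4 sharpen + 4 emboss + 4 blur +
    4 rotate + 4 edge + 4 skew + 4 flip + 2 shear."""
    ops: list[AugmentationOp] = []
    ops += [AugmentationOp("sharpen", v) for v in _SHARPEN_LEVELS]
    ops += [AugmentationOp("emboss", v) for v in _EMBOSS_LEVELS]
    ops += [AugmentationOp("gaussian_blur", v) for v in _BLUR_SCALES]
    ops += [AugmentationOp("rotate", v) for v in _ROTATE_ANGLES]
    ops += [AugmentationOp("edge", v) for v in _EDGE_LEVELS]
    ops += [AugmentationOp("skew", v) for v in _SKEW_DIRECTIONS]
    ops += [AugmentationOp("flip", v) for v in _FLIP_AXES]
    ops += [AugmentationOp("shear", v) for v in _SHEAR_AXES]
    return ops


_EMBOSS_KERNEL = np.array([[-1.0, -1.0, 0.0], [-1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])


def _sharpen(pixels: np.ndarray, level: float) -> np.ndarray:
    blurred = filters.gaussian(
        pixels, sigma=1.0, channel_axis=-1 if pixels.ndim == 3 else None
    )
    return pixels + level * (pixels - blurred)


def _emboss(pixels: np.ndarray, level: float) -> np.ndarray:
    embossed = _per_channel(
        pixels, lambda ch: convolve(ch, _EMBOSS_KERNEL, mode="reflect") + 0.5
    )
    return (1.0 - level) * pixels + level * embossed


def _edge(pixels: np.ndarray, level: float) -> np.ndarray:
    edges = _per_channel(pixels, filters.sobel)
    return (1.0 - level) * pixels + level * edges


def _rotate(pixels: np.ndarray, angle: int) -> np.ndarray:
    # exact array rotation for multiples of 90 deg when the canvas permits,
    # so involution/period identities hold without interpolation error
    if angle % 180 == 0:
        return np.rot90(pixels, k=angle // 90, axes=(0, 1))
    if angle % 90 == 0 and pixels.shape[0] == pixels.shape[1]:
        return np.rot90(pixels, k=angle // 90, axes=(0, 1))
    return transform.rotate(pixels, angle, resize=False, mode="symmetric")


def _affine_shear(pixels: np.ndarray, degrees_x: float, degrees_y: float) -> np.ndarray:
    h, w = pixels.shape[:2]
    sx = math.tan(math.radians(degrees_x))
    sy = math.tan(math.radians(degrees_y))
    center = np.array([w / 2.0, h / 2.0])
    mat = np.array([[1.0, sx, 0.0], [sy, 1.0, 0.0], [0.0, 0.0, 1.0]])
    offset = center - mat[:2, :2] @ center
    mat[:2, 2] = offset
    tform = transform.AffineTransform(matrix=mat)
    return transform.warp(pixels, tform.inverse, mode="symmetric", preserve_range=True)


_SKEW_ANGLES = {
    "left": (-_SHEAR_DEGREES, 0.0),
    "right": (_SHEAR_DEGREES, 0.0),
    "forward": (0.0, -_SHEAR_DEGREES),
    "backward": (0.0, _SHEAR_DEGREES),
}


def apply_augmentation(img: ImageRecord, op: AugmentationOp) -> ImageRecord:
    """Apply one catalogue operation; the output keeps the input shape and
    value range, with the operation appended to provenance."""
    pixels = img.pixels
    if op.name == "sharpen":
        out = _sharpen(pixels, float(op.parameter))
    elif op.name == "emboss":
        out = _emboss(pixels, float(op.parameter))
    elif op.name == "gaussian_blur":
        out = filters.gaussian(
            pixels, sigma=float(op.parameter),
            channel_axis=-1 if pixels.ndim == 3 else None,
        )
    elif op.name == "rotate":
        out = _rotate(pixels, int(op.parameter))
    elif op.name == "edge":
        out = _edge(pixels, float(op.parameter))
    elif op.name == "skew":
        if op.parameter not in _SKEW_ANGLES:
            raise ValueError(f"unknown skew direction {op.parameter!r}")
        dx, dy = _SKEW_ANGLES[op.parameter]
        out = _affine_shear(pixels, dx, dy)
    elif op.name == "flip":
        if op.parameter in ("left", "right"):
            out = pixels[:, ::-1].copy()
        elif op.parameter in ("top", "bottom"):
            out = pixels[::-1].copy()
        else:
            raise ValueError(f"unknown flip axis {op.parameter!r}")
    elif op.name == "shear":
        if op.parameter == "x":
            out = _affine_shear(pixels, _SHEAR_DEGREES, 0.0)
        elif op.parameter == "y":
            out = _affine_shear(pixels, 0.0, _SHEAR_DEGREES)
        else:
            raise ValueError(f"unknown shear axis {op.parameter!r}")
    else:
        raise ValueError(f"unknown augmentation {op.name!r}")
    return img.with_pixels(out, f"{op.name}({op.parameter})")


def sevenfold_augment(
    dataset: Sequence[ImageRecord], rng: np.random.Generator
) -> list[ImageRecord]:
    """Expand a dataset exactly sevenfold: each source image contributes
    itself plus six catalogue operations sampled without replacement."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    catalogue = augmentation_catalogue()
    out: list[ImageRecord] = []
    for record in dataset:
        out.append(record)
        picks = rng.choice(len(catalogue), size=6, replace=False)
        for k in picks:
            out.append(apply_augmentation(record, catalogue[int(k)]))
    return out


def split_counts(
    class_counts: Mapping,
    train_frac: float = 0.7,
    test_overrides: Optional[Mapping] = None,
) -> dict:
    """Per-class (train, test) counts.

    Default rule: test = floor((1 - train_frac) * count), train = rest.
    ``test_overrides`` pins the test count of chosen classes explicitly
    (useful to reproduce a published split table exactly).
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    out = {}
    for cls, count in class_counts.items():
        if count < 1:
            raise ValueError(f"count for {cls!r} must be >= 1")
        if test_overrides is not None and cls in test_overrides:
            test = int(test_overrides[cls])
            if test > count:
                raise ValueError(f"test override {test} exceeds count {count} for {cls!r}")
        else:
            test = int(math.floor((1.0 - train_frac) * count))
        out[cls] = (count - test, test)
    return out


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------

def read_image(path, label=None) -> ImageRecord:
    """Read an 8-bit PNG as an ImageRecord with values in [0, 1]."""
    arr = np.asarray(Image.open(path), dtype=float) / 255.0
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return ImageRecord(pixels=arr, label=label, source_id=str(Path(path).name))


def write_image(record: ImageRecord, path) -> None:
    arr = np.clip(np.round(record.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path) -> np.ndarray:
    """Read a mask PNG, binarizing at threshold 128 (0/1 output)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    arr = (np.asarray(mask, dtype=np.uint8) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
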