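"""Synthetic fixtures: benchmark objectives, feature tables, image/mask pairs.

Everything downstream is exercised without external data.  The
classification generator emulates the tabular feature matrices a CNN
feature extractor would produce from segmented fundus images: a handful of
class-informative columns (class-conditional Gaussians with a controlled
mean separation) padded with pure-noise columns, so wrapper feature
selection has a known ground truth to recover.  The segmentation generator
produces blob-like "lesions" (unions of random disks) on a smooth textured
background, so mask-overlap fitness functions and the architecture-search
loop can be tested end to end.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "BenchmarkFunction",
    "SyntheticClassificationTask",
    "SyntheticSegmentationTask",
    "benchmark_suite",
    "make_classification_data",
    "make_segmentation_data",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named test objective with its standard box and known optimum."""

    name: str
    objective: Callable[[np.ndarray], float]
    default_bounds: tuple[float, float]  # per-dimension (lo, hi)
    global_minimum: float
    minimizer: float  # every coordinate of the global minimizer


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x, dtype=float) ** 2))


def _schwefel222(x: np.ndarray) -> float:
    ax = np.abs(np.asarray(x, dtype=float))
    return float(np.sum(ax) + np.prod(ax))


def _rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * len(x) + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def _ackley(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    s1 = np.sum(x**2) / n
    s2 = np.sum(np.cos(2.0 * np.pi * x)) / n
    return float(-20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e)


def _griewank(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    i = np.arange(1, len(x) + 1, dtype=float)
    return float(np.sum(x**2) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


_SUITE = {
    "sphere": BenchmarkFunction("sphere", _sphere, (-100.0, 100.0), 0.0, 0.0),
    "schwefel222": BenchmarkFunction("schwefel222", _schwefel222, (-10.0, 10.0), 0.0, 0.0),
    "rosenbrock": BenchmarkFunction("rosenbrock", _rosenbrock, (-5.0, 10.0), 0.0, 1.0),
    "rastrigin": BenchmarkFunction("rastrigin", _rastrigin, (-5.12, 5.12), 0.0, 0.0),
    "ackley": BenchmarkFunction("ackley", _ackley, (-32.0, 32.0), 0.0, 0.0),
    "griewank": BenchmarkFunction("griewank", _griewank, (-600.0, 600.0), 0.0, 0.0),
}


def benchmark_suite() -> dict[str, BenchmarkFunction]:
    """The catalogue of unimodal (sphere, schwefel222, rosenbrock) and
    multimodal (rastrigin, ackley, griewank) optimizer test functions."""
    return dict(_SUITE)


@dataclass
class SyntheticClassificationTask:
    """Labeled feature table with a known informative/noise column split."""

    x: np.ndarray
    y: np.ndarray
    informative_indices: np.ndarray
    class_sep: float
    seed: int


def make_classification_data(
    n: int,
    k_informative: int,
    k_noise: int,
    class_sep: float,
    n_classes: int = 2,
    seed: int = 0,
) -> SyntheticClassificationTask:
    """Balanced class-conditional Gaussian table with noise padding.

    Informative columns: each class center is a distinct sign pattern with
    equal-magnitude components (so every informative column carries signal,
    not just the ones a random direction happens to load on), rescaled so
    that the minimum pairwise center distance equals ``class_sep`` (in
    units of the within-class standard deviation, which is 1).  Noise
    columns are standard normal, independent of the label.  Classes are
    balanced; ``n`` is rounded down to a multiple of ``n_classes``.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if n < 10 * n_classes:
        raise ValueError(f"n must be >= 10 * n_classes, got {n}")
    if k_informative < 1 or k_noise < 0:
        raise ValueError("k_informative >= 1 and k_noise >= 0 required")
    if n_classes > 2**k_informative:
        raise ValueError("n_classes exceeds the number of distinct sign patterns")
    rng = np.random.default_rng(seed)
    per_class = n // n_classes
    n = per_class * n_classes

    # distinct +/-1 sign patterns; the first two are the antipodal pair so
    # the 2-class case spreads its separation evenly over every column
    patterns = [np.ones(k_informative), -np.ones(k_informative)]
    seen = {patterns[0].tobytes(), patterns[1].tobytes()}
    while len(patterns) < n_classes:
        cand = rng.choice([-1.0, 1.0], size=k_informative)
        if cand.tobytes() not in seen:
            seen.add(cand.tobytes())
            patterns.append(cand)
    centers = np.vstack(patterns[:n_classes]) / (2.0 * np.sqrt(k_informative))
    if class_sep > 0:
        dmin = min(
            np.linalg.norm(centers[i] - centers[j])
            for i in range(n_classes)
            for j in range(i + 1, n_classes)
        )
        centers *= class_sep / dmin
    else:
        centers[:] = 0.0

    xs, ys = [], []
    for c in range(n_classes):
        xs.append(centers[c] + rng.normal(size=(per_class, k_informative)))
        ys.append(np.full(per_class, c))
    x_inf = np.vstack(xs)
    y = np.concatenate(ys)
    x_noise = rng.normal(size=(n, k_noise))
    x = np.hstack([x_inf, x_noise])

    perm = rng.permutation(n)
    return SyntheticClassificationTask(
        x=x[perm],
        y=y[perm].astype(int),
        informative_indices=np.arange(k_informative),
        class_sep=class_sep,
        seed=seed,
    )


@dataclass
class SyntheticSegmentationTask:
    """Image/mask pairs: disk-union lesions on a textured background."""

    images: list = field(default_factory=list)
    truths: list = field(default_factory=list)
    blob_count_range: tuple[int, int] = (1, 4)
    radius_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 0.05
    seed: int = 0


_FG, _BG, _TEXTURE_AMP = 0.85, 0.15, 0.10  # keeps midpoint threshold exact at sd=0


def make_segmentation_data(
    n: int,
    size: tuple[int, int] = (64, 64),
    blob_count_range: tuple[int, int] = (1, 4),
    radius_range: tuple[float, float] = (4.0, 12.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticSegmentationTask:
    """Generate ``n`` image/mask pairs of shape ``size``.

    Each truth mask is a union of ``blob_count`` random disks (guaranteed
    nonempty); the image is foreground/background intensity plus a smooth
    texture (Gaussian-filtered noise, amplitude 0.1) and i.i.d. Gaussian
    pixel noise of standard deviation ``noise_sd``.  With ``noise_sd=0``,
    thresholding at 0.5 recovers the truth exactly.
    """
    r, c = size
    if r < 32 or c < 32:
        raise ValueError("size must be at least 32x32")
    if n < 1:
        raise ValueError("n must be >= 1")
    if blob_count_range[0] < 1 or radius_range[0] <= 0:
        raise ValueError("invalid blob or radius range")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:r, 0:c]
    images, truths = [], []
    for _ in range(n):
        mask = np.zeros((r, c), dtype=np.uint8)
        n_blobs = int(rng.integers(blob_count_range[0], blob_count_range[1] + 1))
        for _ in range(n_blobs):
            radius = rng.uniform(*radius_range)
            cy = rng.uniform(radius, r - radius)
            cx = rng.uniform(radius, c - radius)
            mask |= ((rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2).astype(np.uint8)
        texture = gaussian_filter(rng.normal(size=(r, c)), sigma=8.0)
        span = np.max(np.abs(texture))
        if span > 0:
            texture *= _TEXTURE_AMP / span
        img = np.where(mask == 1, _FG, _BG) + texture
        if noise_sd > 0:
            img = img + rng.normal(scale=noise_sd, size=(r, c))
        images.append(img)
        truths.append(mask)
    return SyntheticSegmentationTask(
        images=images,
        truths=truths,
        blob_count_range=blob_count_range,
        radius_range=radius_range,
        noise_sd=noise_sd,
        seed=seed,
    )
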