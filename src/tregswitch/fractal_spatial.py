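"""Box-counting fractal dimension and lacunarity of binary marker images.

Metrics operate on a single binary mask. A fixed, origin-anchored grid of
non-overlapping boxes is laid over the image at each scale; partial edge
boxes are included (zero-padded). The fractal dimension is the negative
slope of the ordinary least-squares fit of ln N(eps) against ln eps, and
lacunarity at a scale is ``var(mass)/mean(mass)**2 + 1`` over all grid
boxes, summarized as the unweighted mean across scales.

Gliding boxes and multiple grid orientations are deliberately not
emulated; the single fixed grid keeps every value reproducible and
testable against a brute-force counter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress
from skimage.filters import threshold_otsu

from . import cohort_stats
from .errors import (
    DegenerateThresholdError,
    EmptyForegroundError,
    InsufficientScalesError,
    ParameterError,
)


@dataclass
class BinaryImage:
    """Boolean foreground mask plus a free-form provenance label."""

    pixels: np.ndarray
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ParameterError("BinaryImage requires a 2-D pixel grid")
        if min(self.pixels.shape) < 2:
            raise ParameterError("BinaryImage requires >= 2 pixels per side")

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass
class BoxCountCurve:
    """Per-scale occupancy and mass moments of the fixed-grid tiling."""

    box_sizes: np.ndarray  # strictly increasing eps
    occupied: np.ndarray  # N(eps)
    mass_mean: np.ndarray  # mean foreground pixels per box (all boxes)
    mass_var: np.ndarray  # population variance of per-box mass
    n_boxes: np.ndarray  # total boxes in the tiling at each eps


@dataclass
class FractalMetrics:
    fd: float = float("nan")
    lacunarity: float = float("nan")
    r2: float = float("nan")
    provenance: str | None = None


@dataclass
class GroupComparison:
    measure: str
    u: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def segment(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    provenance: str | None = None,
) -> BinaryImage:
    """Threshold a grayscale image into a foreground mask.

    ``otsu`` derives the threshold from the histogram; ``fixed`` requires an
    explicit one. Foreground is strictly above the threshold, which makes
    the operation idempotent on {0,1} or {0,255} binary inputs.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ParameterError("cannot segment an empty image")
    if method == "fixed":
        if threshold is None:
            raise ParameterError("fixed segmentation requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if image.max() == image.min():
            raise DegenerateThresholdError(
                "otsu thresholding is undefined for a constant image"
            )
        thr = float(threshold_otsu(np.asarray(image, dtype=float)))
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")
    return BinaryImage(pixels=image > thr, provenance=provenance)


def treg_mask(cd4_mask: BinaryImage, foxp3_mask: BinaryImage) -> BinaryImage:
    """Intersection of CD4+ and FOXP3+ masks (double-positive cells)."""
    if cd4_mask.pixels.shape != foxp3_mask.pixels.shape:
        raise ParameterError("masks must share a shape")
    return BinaryImage(
        pixels=cd4_mask.pixels & foxp3_mask.pixels,
        provenance=cd4_mask.provenance,
    )


def default_box_sizes(shape: tuple[int, int], base: int = 2) -> np.ndarray:
    """Geometric ladder of box sizes: powers of ``base`` from 1 to min_side/base."""
    if base < 2:
        raise ParameterError("base must be >= 2")
    limit = min(shape) // base
    sizes = []
    eps = 1
    while eps <= max(limit, 1):
        sizes.append(eps)
        eps *= base
    return np.array(sizes, dtype=int)


def _box_masses(pixels: np.ndarray, eps: int) -> np.ndarray:
    """Per-box foreground mass for the origin-anchored eps-tiling (flat array)."""
    h, w = pixels.shape
    ph = (-h) % eps
    pw = (-w) % eps
    padded = np.pad(pixels.astype(np.int64), ((0, ph), (0, pw)))
    bh, bw = padded.shape[0] // eps, padded.shape[1] // eps
    return padded.reshape(bh, eps, bw, eps).sum(axis=(1, 3)).ravel()


def box_count(
    img: BinaryImage, box_sizes: Sequence[int] | None = None, base: int = 2
) -> BoxCountCurve:
    """Tile the image with non-overlapping boxes at each scale.

    Records N(eps) (boxes containing foreground) and the mean/variance of
    per-box mass over **all** boxes of the tiling, empty ones included.
    """
    if img.n_foreground == 0:
        raise EmptyForegroundError("box_count requires at least one foreground pixel")
    if box_sizes is None:
        sizes = default_box_sizes(img.pixels.shape, base=base)
    else:
        sizes = np.asarray(sorted(set(int(s) for s in box_sizes)), dtype=int)
    if sizes.size == 0 or sizes[0] < 1 or sizes[-1] > min(img.pixels.shape):
        raise ParameterError("box sizes must satisfy 1 <= eps <= min image side")

    occupied = np.empty(sizes.size, dtype=int)
    mass_mean = np.empty(sizes.size)
    mass_var = np.empty(sizes.size)
    n_boxes = np.empty(sizes.size, dtype=int)
    for i, eps in enumerate(sizes):
        masses = _box_masses(img.pixels, int(eps))
        occupied[i] = int((masses > 0).sum())
        mass_mean[i] = masses.mean()
        mass_var[i] = masses.var()
        n_boxes[i] = masses.size
    return BoxCountCurve(
        box_sizes=sizes,
        occupied=occupied,
        mass_mean=mass_mean,
        mass_var=mass_var,
        n_boxes=n_boxes,
    )


def fractal_dimension(curve: BoxCountCurve) -> FractalMetrics:
    """FD = -slope of the OLS fit of ln N(eps) on ln eps, with its r^2."""
    usable = curve.occupied >= 1
    if usable.sum() < 3:
        raise InsufficientScalesError("fractal_dimension needs >= 3 usable scales")
    ln_eps = np.log(curve.box_sizes[usable].astype(float))
    ln_n = np.log(curve.occupied[usable].astype(float))
    if np.ptp(ln_n) == 0:  # constant N(eps): slope 0 exactly, r2 undefined -> 0
        return FractalMetrics(fd=0.0, r2=0.0)
    res = linregress(ln_eps, ln_n)
    return FractalMetrics(fd=-float(res.slope), r2=float(res.rvalue**2))


def lacunarity(curve: BoxCountCurve) -> FractalMetrics:
    """Mean over scales of lambda(eps) = var/mean^2 + 1 of per-box mass."""
    lambdas = []
    for mean, var in zip(curve.mass_mean, curve.mass_var):
        if mean <= 0:
            continue  # scale carries no mass; skip
        lambdas.append(var / mean**2 + 1.0)
    if not lambdas:
        raise EmptyForegroundError("no scale with positive mean mass")
    return FractalMetrics(lacunarity=float(np.mean(lambdas)))


def lacunarity_per_scale(curve: BoxCountCurve) -> np.ndarray:
    """lambda(eps) for every scale with positive mean mass (NaN otherwise)."""
    out = np.full(curve.box_sizes.size, np.nan)
    pos = curve.mass_mean > 0
    out[pos] = curve.mass_var[pos] / curve.mass_mean[pos] ** 2 + 1.0
    return out


def compute_metrics(
    img: BinaryImage, box_sizes: Sequence[int] | None = None, base: int = 2
) -> FractalMetrics:
    """Convenience: box-count once, populate fd, r2 and lacunarity together."""
    curve = box_count(img, box_sizes=box_sizes, base=base)
    fd_part = fractal_dimension(curve)
    lc_part = lacunarity(curve)
    return FractalMetrics(
        fd=fd_part.fd,
        r2=fd_part.r2,
        lacunarity=lc_part.lacunarity,
        provenance=img.provenance,
    )


def compare_groups(
    metrics_a: Sequence[FractalMetrics],
    metrics_b: Sequence[FractalMetrics],
    measure: str = "fd",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of one metric between image sets."""
    if measure not in ("fd", "lacunarity"):
        raise ParameterError("measure must be 'fd' or 'lacunarity'")
    if len(metrics_a) < 2 or len(metrics_b) < 2:
        raise ParameterError("each group needs >= 2 images")
    a = np.array([getattr(m, measure) for m in metrics_a], dtype=float)
    b = np.array([getattr(m, measure) for m in metrics_b], dtype=float)
    res = cohort_stats.mann_whitney_u(a, b)
    return GroupComparison(
        measure=measure,
        u=res.u,
        p=res.p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=a.size,
        n_b=b.size,
    )
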