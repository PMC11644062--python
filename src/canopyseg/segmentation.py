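"""Maximum between-class-variance (Otsu) thresholding and mask post-processing.

Given a gray-level histogram with proportions p_i over levels 0..L-1, a
threshold vector {t_1 < ... < t_k} splits the levels into k+1 contiguous
classes.  With class probabilities P_i, class mean gray levels mu_i and the
global mean mu_0 = sum_i i*p_i, the between-class variance

    sigma^2 = sum_i P_i * (mu_i - mu_0)^2

is maximized by exhaustive search over threshold vectors; the maximizing
vector separates the gray populations best.  k=1 is classic Otsu; k=2
(double threshold) separates background / shadowed leaf / normal leaf.

Also provided: morphological opening for noise removal, merging of leaf
label classes into a binary canopy mask, and masking a hyperspectral cube by
a binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage

from .enhance_fuse import GrayHistogram, quantize
from .hypercube_io import GrayImage, HyperCube

__all__ = [
    "ThresholdVector",
    "ClassStats",
    "LabelMask",
    "class_stats",
    "between_class_variance",
    "otsu_single",
    "otsu_multi",
    "apply_thresholds",
    "open_binary",
    "merge_leaf_classes",
    "mask_cube",
]


@dataclass
class ThresholdVector:
    """Ascending gray-level thresholds plus the variance they achieve."""

    thresholds: tuple[int, ...]
    L: int
    sigma2: float

    def __post_init__(self) -> None:
        t = tuple(int(v) for v in self.thresholds)
        if len(t) < 1 or len(t) >= self.L:
            raise ValueError("need 1 <= k < L thresholds")
        if any(v < 0 or v > self.L - 1 for v in t):
            raise ValueError("thresholds must lie in [0, L-1]")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly ascending")
        self.thresholds = t

    @property
    def k(self) -> int:
        return len(self.thresholds)


@dataclass
class ClassStats:
    """Per-class probability and mean gray level under a threshold vector."""

    proportions: np.ndarray  # P_i, one per class, sums to 1
    means: np.ndarray  # mu_i; 0 for empty classes
    mu0: float  # global mean gray level

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("class proportions must sum to 1")
        mix = float(np.sum(self.proportions * self.means))
        if abs(mix - self.mu0) > 1e-9:
            raise ValueError("class means inconsistent with global mean")


@dataclass
class LabelMask:
    """Per-pixel class labels 0..k, monotone in gray value (0 = darkest)."""

    labels: np.ndarray
    thresholds: tuple[int, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")


def _class_bounds(tvec: ThresholdVector) -> list[tuple[int, int]]:
    """Inclusive level ranges [lo, hi] of the k+1 classes."""
    edges = [-1, *tvec.thresholds, tvec.L - 1]
    return [(lo + 1, hi) for lo, hi in zip(edges[:-1], edges[1:])]


def class_stats(hist: GrayHistogram, tvec: ThresholdVector) -> ClassStats:
    """Class probabilities P_i and mean gray levels mu_i for *tvec*.

    Empty classes (no mass between consecutive thresholds) get mu_i = 0; the
    global mean mu_0 is always taken over the full level range.
    """
    if tvec.L != hist.L:
        raise ValueError(f"threshold vector L={tvec.L} does not match histogram L={hist.L}")
    p = hist.proportions
    levels = np.arange(hist.L)
    mu0 = float(np.sum(levels * p))
    props, means = [], []
    for lo, hi in _class_bounds(tvec):
        mass = float(p[lo : hi + 1].sum())
        props.append(mass)
        means.append(float(np.sum(levels[lo : hi + 1] * p[lo : hi + 1]) / mass) if mass > 0 else 0.0)
    return ClassStats(proportions=np.array(props), means=np.array(means), mu0=mu0)


def between_class_variance(stats: ClassStats) -> float:
    """sigma^2 = sum_i P_i (mu_i - mu_0)^2 over classes with positive mass."""
    mask = stats.proportions > 0
    dev = stats.means[mask] - stats.mu0
    return float(np.sum(stats.proportions[mask] * dev**2))


def _prefix_sums(hist: GrayHistogram) -> tuple[np.ndarray, np.ndarray, float]:
    p = hist.proportions
    levels = np.arange(hist.L)
    cum_p = np.cumsum(p)
    cum_m = np.cumsum(levels * p)
    return cum_p, cum_m, float(cum_m[-1])


def otsu_single(hist: GrayHistogram) -> ThresholdVector:
    """Exhaustive single-threshold search; ties resolved to the lowest t."""
    if len(hist.nonzero_levels()) < 2:
        raise ValueError("histogram has fewer than 2 occupied levels; nothing to segment")
    cum_p, cum_m, mu0 = _prefix_sums(hist)
    p1 = cum_p  # P(class <= t) for every t
    m1 = cum_m
    p2 = 1.0 - p1
    sigma = np.zeros(hist.L)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = np.where(p1 > 0, m1 / p1, 0.0)
        mu2 = np.where(p2 > 0, (mu0 - m1) / p2, 0.0)
    sigma = np.where(p1 > 0, p1 * (mu1 - mu0) ** 2, 0.0)
    sigma += np.where(p2 > 0, p2 * (mu2 - mu0) ** 2, 0.0)
    best = int(np.argmax(sigma))  # argmax returns the first (lowest) maximizer
    return ThresholdVector(thresholds=(best,), L=hist.L, sigma2=float(sigma[best]))


def _otsu_double(hist: GrayHistogram) -> ThresholdVector:
    """Vectorized exhaustive search over all t1 < t2 pairs."""
    cum_p, cum_m, mu0 = _prefix_sums(hist)
    L = hist.L
    # Class masses/moments for every (t1, t2): rows t1, cols t2.
    p1 = cum_p[:, None]
    m1 = cum_m[:, None]
    p2 = cum_p[None, :] - cum_p[:, None]
    m2 = cum_m[None, :] - cum_m[:, None]
    p3 = 1.0 - cum_p[None, :]
    m3 = mu0 - cum_m[None, :]
    sigma = np.zeros((L, L))
    for pp, mm in ((p1, m1), (p2, m2), (p3, m3)):
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(pp > 0, mm / np.where(pp > 0, pp, 1.0), 0.0)
        sigma += np.where(pp > 0, pp * (mu - mu0) ** 2, 0.0)
    sigma[np.tril_indices(L)] = -np.inf  # enforce t1 < t2
    flat = int(np.argmax(sigma))  # first maximizer = lexicographically smallest
    t1, t2 = divmod(flat, L)
    return ThresholdVector(thresholds=(t1, t2), L=L, sigma2=float(sigma[t1, t2]))


def otsu_multi(hist: GrayHistogram, k: int) -> ThresholdVector:
    """Exhaustive k-threshold search; ties -> lexicographically smallest.

    k=1 reduces exactly to :func:`otsu_single`; k=2 uses a vectorized
    double-loop over prefix sums; larger k enumerates combinations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(hist.nonzero_levels()) < k + 1:
        raise ValueError(f"histogram needs at least {k + 1} occupied levels for k={k}")
    if k == 1:
        return otsu_single(hist)
    if k == 2:
        return _otsu_double(hist)
    best_vec, best_sigma = None, -1.0
    for combo in combinations(range(hist.L), k):
        tv = ThresholdVector(thresholds=combo, L=hist.L, sigma2=0.0)
        s = between_class_variance(class_stats(hist, tv))
        if s > best_sigma:
            best_vec, best_sigma = combo, s
    return ThresholdVector(thresholds=best_vec, L=hist.L, sigma2=best_sigma)


def apply_thresholds(image: GrayImage, hist: GrayHistogram, tvec: ThresholdVector) -> LabelMask:
    """Label each pixel with the number of thresholds strictly below its level.

    *hist* must have been derived from *image* (checked by re-counting), so
    the quantization used here matches the one the thresholds refer to.
    """
    levels = quantize(image.data, hist.value_range, hist.L)
    counts = np.bincount(levels.ravel(), minlength=hist.L)
    if not np.array_equal(counts, hist.counts):
        raise ValueError("histogram was not derived from this image")
    labels = np.searchsorted(np.asarray(tvec.thresholds), levels, side="left")
    return LabelMask(labels=labels, thresholds=tvec.thresholds)


def open_binary(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a square element.

    The structuring element has side 2*radius + 1; opening removes foreground
    speckle smaller than the element while preserving large regions.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius < 1:
        return mask.copy()
    struct = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    return ndimage.binary_opening(mask, structure=struct)


def merge_leaf_classes(mask: LabelMask | np.ndarray, leaf_labels) -> np.ndarray:
    """Union of the named label classes as a binary canopy mask."""
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    leaf_labels = sorted(int(v) for v in leaf_labels)
    observed = np.unique(labels)
    unknown = [v for v in leaf_labels if v not in observed]
    if unknown:
        raise ValueError(f"labels {unknown} not present in mask (observed {list(observed)})")
    return np.isin(labels, leaf_labels)


def mask_cube(cube: HyperCube, mask: np.ndarray) -> HyperCube:
    """Zero background pixels across all bands and update the validity mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} != cube spatial shape {cube.shape[:2]}")
    data = cube.data * mask[:, :, None]
    valid = np.ones(cube.shape, dtype=bool) if cube.valid is None else cube.valid.copy()
    valid &= mask[:, :, None]
    return HyperCube(data=data, wavelengths=cube.wavelengths.copy(),
                     meta={**cube.meta, "masked": True}, valid=valid)
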