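"""Gray-image enhancement and multi-band fusion.

Characteristic-wavelength images are denoised with a 3x3 median filter (which
removes impulse/spike artefacts while preserving edges), fused by plain
elementwise summation, and quantized into gray-level histograms for the
threshold-segmentation stage.  A first-principal-component (PC1) image over
the same band images is provided as the standard comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .hypercube_io import GrayImage

__all__ = [
    "GrayHistogram",
    "quantize",
    "median3x3",
    "fuse_sum",
    "histogram",
    "pc1_image",
]


@dataclass
class GrayHistogram:
    """Gray-level histogram of an image quantized to L levels.

    Quantization is linear over the image's own [min, max] range (recorded in
    ``value_range``); ``proportions[i]`` is the fraction of pixels at level i.
    """

    L: int
    counts: np.ndarray
    proportions: np.ndarray
    value_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.counts) != self.L or len(self.proportions) != self.L:
            raise ValueError("counts/proportions length must equal L")
        if self.counts.sum() > 0 and abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def nonzero_levels(self) -> np.ndarray:
        return np.flatnonzero(self.counts)


def quantize(data: np.ndarray, value_range: tuple[float, float], L: int) -> np.ndarray:
    """Map values linearly from *value_range* onto integer levels 0..L-1.

    A degenerate range (max <= min, e.g. a constant image) maps everything to
    level 0.  The same function is used when building histograms and when
    applying thresholds, so level assignment is always consistent.
    """
    vmin, vmax = value_range
    if vmax <= vmin:
        return np.zeros(np.shape(data), dtype=np.int64)
    levels = np.floor((np.asarray(data, dtype=float) - vmin) / (vmax - vmin) * L)
    return np.clip(levels, 0, L - 1).astype(np.int64)


def median3x3(image: GrayImage, border_mode: str = "reflect") -> GrayImage:
    """3x3 sliding-window median filter.

    Each pixel is replaced by the median of its 3x3 neighbourhood; borders
    use edge reflection by default so no artificial dark rim biases the
    subsequent threshold search.  Images smaller than the template are
    rejected.
    """
    if image.data.shape[0] < 3 or image.data.shape[1] < 3:
        raise ValueError("image smaller than the 3x3 template")
    out = ndimage.median_filter(image.data, size=3, mode=border_mode)
    return GrayImage(data=out, source_wavelength_nm=image.source_wavelength_nm)


def fuse_sum(images: Sequence[GrayImage], normalize: bool = False) -> GrayImage:
    """Fuse exactly three wavelength images by elementwise summation.

    No rescaling is applied by default (the fused gray levels are summed
    reflectances); ``normalize=True`` divides by three to yield the
    arithmetic mean instead.
    """
    if len(images) != 3:
        raise ValueError(f"fusion takes exactly 3 images, got {len(images)}")
    shape = images[0].data.shape
    for img in images[1:]:
        if img.data.shape != shape:
            raise ValueError("images to fuse must share one shape")
    out = images[0].data + images[1].data + images[2].data
    if normalize:
        out = out / 3.0
    return GrayImage(data=out)


def histogram(image: GrayImage, L: int = 256) -> GrayHistogram:
    """Quantize *image* to L levels over its own min-max range and count."""
    if L < 2:
        raise ValueError("need at least 2 gray levels")
    vmin = float(image.data.min())
    vmax = float(image.data.max())
    levels = quantize(image.data, (vmin, vmax), L)
    counts = np.bincount(levels.ravel(), minlength=L)
    return GrayHistogram(
        L=L,
        counts=counts,
        proportions=counts / counts.sum(),
        value_range=(vmin, vmax),
    )


def pc1_image(images: Sequence[GrayImage]) -> GrayImage:
    """First principal component of per-pixel vectors across band images.

    Each image is mean-centred, the k x k covariance across pixels is
    eigendecomposed, and pixels are projected on the leading eigenvector.
    The sign is fixed so the projection correlates positively with the mean
    of the inputs (bright-canopy convention).  All-constant stacks (zero
    variance) are rejected.
    """
    if len(images) < 2:
        raise ValueError("PC1 needs at least 2 images")
    shape = images[0].data.shape
    for img in images[1:]:
        if img.data.shape != shape:
            raise ValueError("images must share one shape")
    stack = np.stack([img.data.ravel() for img in images])  # (k, npix)
    centred = stack - stack.mean(axis=1, keepdims=True)
    cov = centred @ centred.T / centred.shape[1]
    if np.allclose(cov, 0):
        raise ValueError("all images are constant; PC1 undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    w = eigvecs[:, -1]
    proj = w @ centred
    mean_img = stack.mean(axis=0)
    corr = float(np.dot(proj, mean_img - mean_img.mean()))
    if corr < 0:
        proj = -proj
    return GrayImage(data=proj.reshape(shape))
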