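"""Segmentation scoring (AOM / ME) and the end-to-end pipeline comparison.

Two standard region-agreement metrics compare an algorithm mask S1 against a
manual (ground-truth) mask S2:

    AOM = |S1 n S2| / |S1 u S2|        (area overlap measure, 1 is perfect)
    ME  = (|S1 u S2| - |S1 n S2|) / |S1|   (misclassification error, 0 is perfect)

ME's denominator is the algorithm region as the formula is conventionally
printed; a ``denominator="manual"`` option divides by |S2| instead for the
verbal "fraction of manually segmented pixels" reading.  Note ME can exceed
1 when S2 is much larger than S1.

``run_pipeline`` executes the full comparison on one scene: characteristic-
wavelength selection, median filtering, then each of {three single-band
images, their fused sum, the PC1 image} segmented with single and double
thresholds, opened, leaf classes merged, and scored against the manual mask
— ten method rows in total, aggregable over a batch into summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_selection import SelectionConfig, SelectionResult, select_bands
from .enhance_fuse import fuse_sum, histogram, median3x3, pc1_image
from .hypercube_io import HyperCube, band_image
from .segmentation import apply_thresholds, merge_leaf_classes, open_binary, otsu_multi
from .synthetic_scene import SceneLayout

__all__ = [
    "MaskPair",
    "SegScore",
    "BatchStats",
    "PipelineConfig",
    "PipelineReport",
    "aom",
    "me",
    "score_masks",
    "batch_stats",
    "run_pipeline",
    "batch_report",
]


@dataclass
class MaskPair:
    """Algorithm mask S1 and manual reference mask S2 of identical shape."""

    algorithm: np.ndarray
    manual: np.ndarray

    def __post_init__(self) -> None:
        self.algorithm = np.asarray(self.algorithm, dtype=bool)
        self.manual = np.asarray(self.manual, dtype=bool)
        if self.algorithm.shape != self.manual.shape:
            raise ValueError(
                f"mask shapes differ: {self.algorithm.shape} vs {self.manual.shape}"
            )


@dataclass
class SegScore:
    """AOM and ME for one algorithm-vs-manual comparison."""

    aom: float
    me: float


@dataclass
class BatchStats:
    """Summary of one metric over a batch: extremes, mean and dispersion.

    Both the sample standard deviation and the sample variance are reported;
    dispersion tables in the field sometimes label one as the other, so
    each is carried under its own name.
    """

    maximum: float
    minimum: float
    mean: float
    std: float
    var: float
    n: int


def aom(pair: MaskPair) -> float:
    """Area overlap measure |S1 n S2| / |S1 u S2|.

    Two empty masks are identical segmentations, scored 1.
    """
    inter = np.logical_and(pair.algorithm, pair.manual).sum()
    union = np.logical_or(pair.algorithm, pair.manual).sum()
    if union == 0:
        return 1.0
    return float(inter) / float(union)


def me(pair: MaskPair, denominator: str = "algorithm") -> float:
    """Misclassification error (|S1 u S2| - |S1 n S2|) / |S1|.

    The numerator counts under- plus over-segmented pixels.  With
    ``denominator="manual"`` the reference region |S2| is used instead.
    Raises when the chosen denominator region is empty, except that two
    empty masks score 0 (identical segmentations).
    """
    inter = np.logical_and(pair.algorithm, pair.manual).sum()
    union = np.logical_or(pair.algorithm, pair.manual).sum()
    if union == 0:
        return 0.0
    denom = pair.algorithm.sum() if denominator == "algorithm" else pair.manual.sum()
    if denominator not in ("algorithm", "manual"):
        raise ValueError("denominator must be 'algorithm' or 'manual'")
    if denom == 0:
        raise ValueError(f"ME undefined: {denominator} mask is empty")
    return float(union - inter) / float(denom)


def score_masks(algorithm: np.ndarray, manual: np.ndarray,
                denominator: str = "algorithm") -> SegScore:
    """Convenience wrapper computing both metrics for a mask pair."""
    pair = MaskPair(algorithm=algorithm, manual=manual)
    return SegScore(aom=aom(pair), me=me(pair, denominator=denominator))


def batch_stats(values) -> BatchStats:
    """Max/min/mean plus sample std and variance (ddof=1) of a score list."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one score")
    ddof = 1 if arr.size > 1 else 0
    return BatchStats(
        maximum=float(arr.max()),
        minimum=float(arr.min()),
        mean=float(arr.mean()),
        std=float(arr.std(ddof=ddof)),
        var=float(arr.var(ddof=ddof)),
        n=int(arr.size),
    )


@dataclass
class PipelineConfig:
    """Settings for the end-to-end comparison."""

    k_bands: int = 3
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    L: int = 256
    open_radius: int = 1
    me_denominator: str = "algorithm"
    include_single_bands: bool = True


@dataclass
class PipelineReport:
    """Scores per (feature image, threshold mode) plus selection provenance."""

    scores: dict[tuple[str, str], SegScore]
    thresholds: dict[tuple[str, str], tuple[int, ...]]
    selection: SelectionResult
    masks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


class PipelineError(RuntimeError):
    """Error from one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - tag and re-raise with stage context
        raise PipelineError(name, exc) from exc


def run_pipeline(
    cube: HyperCube,
    labels: SceneLayout | np.ndarray,
    manual: np.ndarray,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Full method comparison on one scene.

    Selects characteristic wavelengths from *cube* and *labels*, median-
    filters the corresponding band images, and scores every feature image
    ({each single band, fused sum, PC1} x {single, double threshold}) against
    the *manual* canopy mask.  Deterministic for fixed inputs.
    """
    cfg = config or PipelineConfig()
    manual = np.asarray(manual, dtype=bool)

    selection = _stage("select_bands", select_bands, cube, labels, cfg.k_bands, cfg.selection)
    band_imgs = [
        _stage("band_image", band_image, cube, wl) for wl in selection.wavelengths
    ]
    filtered = [_stage("median3x3", median3x3, img) for img in band_imgs]

    features: list[tuple[str, object]] = []
    if cfg.include_single_bands:
        # Positional names keep report rows aggregable across scenes whose
        # selected wavelengths differ; the actual values live in .selection.
        features += [(f"band_{i + 1}", img) for i, img in enumerate(filtered)]
    features.append(("fused", _stage("fuse_sum", fuse_sum, filtered)))
    # PCA runs on the unfiltered band images; its PC1 image is then median
    # filtered (the fusion pathway filters first, then sums).
    pc1 = _stage("pc1_image", pc1_image, band_imgs)
    features.append(("pc1", _stage("median3x3", median3x3, pc1)))

    scores: dict[tuple[str, str], SegScore] = {}
    thresholds: dict[tuple[str, str], tuple[int, ...]] = {}
    masks: dict[tuple[str, str], np.ndarray] = {}
    for name, img in features:
        hist = _stage("histogram", histogram, img, cfg.L)
        for mode, k in (("single", 1), ("double", 2)):
            tvec = _stage("otsu", otsu_multi, hist, k)
            lab = _stage("apply_thresholds", apply_thresholds, img, hist, tvec)
            leaf_labels = [lbl for lbl in range(1, k + 1) if lbl in np.unique(lab.labels)]
            if not leaf_labels:
                leaf_labels = [int(lab.labels.max())]
            canopy = _stage("merge_leaf_classes", merge_leaf_classes, lab, leaf_labels)
            canopy = _stage("open_binary", open_binary, canopy, cfg.open_radius)
            scores[(name, mode)] = _stage(
                "score", score_masks, canopy, manual, cfg.me_denominator
            )
            thresholds[(name, mode)] = tvec.thresholds
            masks[(name, mode)] = canopy
    return PipelineReport(scores=scores, thresholds=thresholds, selection=selection, masks=masks)


def batch_report(reports) -> pd.DataFrame:
    """Aggregate per-scene reports into a method-by-statistics table.

    One row per (feature image, threshold mode); columns hold max, min, mean
    and dispersion (sample std and variance) of AOM and ME over the batch.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    keys = list(reports[0].scores.keys())
    rows = []
    for key in keys:
        aoms = batch_stats([r.scores[key].aom for r in reports])
        mes = batch_stats([r.scores[key].me for r in reports])
        rows.append(
            {
                "feature": key[0],
                "mode": key[1],
                "aom_max": aoms.maximum,
                "aom_min": aoms.minimum,
                "aom_mean": aoms.mean,
                "aom_std": aoms.std,
                "aom_var": aoms.var,
                "me_max": mes.maximum,
                "me_min": mes.minimum,
                "me_mean": mes.mean,
                "me_std": mes.std,
                "me_var": mes.var,
                "n": aoms.n,
            }
        )
    return pd.DataFrame(rows).set_index(["feature", "mode"])
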