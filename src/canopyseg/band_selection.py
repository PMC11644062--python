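"""Characteristic-wavelength selection by the spectral-ratio method.

Workflow: compute each region's mean reflectance spectrum, form the ratio of
the leaf spectrum to each background spectrum, take the highest local maxima
of every ratio curve (the wavelengths where leaf and background differ most),
pool the picks, drop effectively duplicate bands by image correlation, and
keep the top ``k`` by ratio value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hypercube_io import HyperCube
from .synthetic_scene import CLASS_IDS, SceneLayout

__all__ = [
    "RegionSpectra",
    "RatioCurve",
    "BandPick",
    "SelectionConfig",
    "SelectionResult",
    "region_mean_spectra",
    "ratio_curves",
    "top_peaks",
    "prune_correlated",
    "select_bands",
]


@dataclass
class RegionSpectra:
    """Mean reflectance spectrum and pixel count per labelled region."""

    regions: list[int]
    mean_spectra: dict[int, np.ndarray]
    pixel_counts: dict[int, int]
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        nb = len(self.wavelengths)
        for rid in self.regions:
            if self.pixel_counts[rid] <= 0:
                raise ValueError(f"region {rid} has no pixels")
            if len(self.mean_spectra[rid]) != nb:
                raise ValueError(f"region {rid} spectrum length != band count")


@dataclass
class RatioCurve:
    """Leaf-mean over background-mean reflectance ratio per wavelength."""

    background_region: int
    values: np.ndarray
    wavelengths: np.ndarray


@dataclass(frozen=True)
class BandPick:
    """One candidate characteristic wavelength."""

    wavelength_nm: float
    ratio_value: float
    background_region: int
    band_index: int
    flagged: bool = False  # True when the source curve had no interior maximum


@dataclass
class SelectionConfig:
    """Knobs of the end-to-end selection.

    ``r_threshold`` prunes candidate bands whose gray images are effectively
    the same measurement: in low-texture scenes all informative bands are
    globally near-collinear (one dominant canopy-vs-background contrast
    axis), so the threshold is set very close to 1 and removes only
    duplicate/adjacent-band picks while keeping genuinely distinct spectral
    features.
    """

    leaf_region: int = CLASS_IDS["normal_leaf"]
    background_regions: tuple[int, ...] = (
        CLASS_IDS["stage"],
        CLASS_IDS["soil"],
        CLASS_IDS["pot"],
    )
    include_shadow_as_background: bool = False
    peaks_per_curve: int = 2
    r_threshold: float = 0.999
    floor: float = 1e-4
    # Robustness of peak picking on empirical (noisy) ratio curves: ignore
    # local maxima whose prominence is below this fraction of the curve's
    # range, and never return two maxima closer than this many bands.
    min_prominence_frac: float = 0.05
    min_separation_bands: int = 6

    def backgrounds(self) -> tuple[int, ...]:
        if self.include_shadow_as_background:
            return self.background_regions + (CLASS_IDS["shadow_leaf"],)
        return self.background_regions


@dataclass
class SelectionResult:
    """Selected wavelengths plus provenance; flagged when fewer than k survive."""

    wavelengths: list[float]
    picks: list[BandPick]
    flagged: bool = False
    curves: list[RatioCurve] = field(default_factory=list)


def region_mean_spectra(cube: HyperCube, labels: SceneLayout | np.ndarray) -> RegionSpectra:
    """Arithmetic mean full-spectrum vector of every labelled region.

    Invalid cube entries (validity mask False) are excluded from the means.
    Raises on spatial shape mismatch or an empty region.
    """
    lab = labels.labels if isinstance(labels, SceneLayout) else np.asarray(labels)
    if lab.shape != cube.shape[:2]:
        raise ValueError(f"label shape {lab.shape} != cube spatial shape {cube.shape[:2]}")
    region_ids = [int(r) for r in np.unique(lab)]
    means: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    valid = cube.valid
    for rid in region_ids:
        sel = lab == rid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"region {rid} is empty")
        block = cube.data[sel, :].astype(float)
        if valid is None:
            means[rid] = block.mean(axis=0)
        else:
            vb = valid[sel, :]
            n_ok = vb.sum(axis=0)
            if (n_ok == 0).any():
                raise ValueError(f"region {rid} has bands with no valid pixels")
            means[rid] = (block * vb).sum(axis=0) / n_ok
        counts[rid] = n
    return RegionSpectra(
        regions=region_ids,
        mean_spectra=means,
        pixel_counts=counts,
        wavelengths=cube.wavelengths.copy(),
    )


def ratio_curves(
    spectra: RegionSpectra,
    leaf_region: int,
    background_regions: tuple[int, ...] | list[int],
    floor: float = 1e-4,
) -> list[RatioCurve]:
    """Leaf/background ratio, one curve per background region.

    The background mean is floored at *floor* so the ratio stays finite even
    where the background reflectance vanishes.
    """
    if leaf_region not in spectra.mean_spectra:
        raise KeyError(f"unknown leaf region {leaf_region}")
    leaf = spectra.mean_spectra[leaf_region]
    out = []
    for bg in background_regions:
        if bg not in spectra.mean_spectra:
            raise KeyError(f"unknown background region {bg}")
        values = leaf / np.maximum(spectra.mean_spectra[bg], floor)
        out.append(
            RatioCurve(background_region=int(bg), values=values,
                       wavelengths=spectra.wavelengths)
        )
    return out


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of interior local maxima; a flat plateau strictly above both
    flanks counts once, at its centre (ties broken to the lower index)."""
    n = len(values)
    maxima: list[int] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        # run values[i..j]; interior iff flanks exist and are strictly lower
        if i - 1 >= 0 and j + 1 < n and values[i - 1] < values[i] and values[j + 1] < values[i]:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def _prominence(values: np.ndarray, peak: int) -> float:
    """Topographic prominence of a local maximum: height above the higher of
    the two valley floors separating it from higher terrain (curve ends act
    as terrain boundaries)."""
    v = values[peak]
    bases = []
    for step in (-1, 1):
        lowest = v
        i = peak + step
        while 0 <= i < len(values) and values[i] <= v:
            lowest = min(lowest, values[i])
            i += step
        bases.append(lowest)
    return float(v - max(bases))


def top_peaks(
    curve: RatioCurve,
    n_peaks: int = 2,
    min_prominence: float = 0.0,
    min_separation: int = 1,
) -> list[BandPick]:
    """The *n_peaks* local maxima of a ratio curve with the highest values.

    Returned in descending ratio order (ratio ties broken toward the lower
    wavelength).  Maxima with topographic prominence below *min_prominence*
    are ignored, and of two maxima closer than *min_separation* bands only
    the higher survives — both guards suppress noise wiggles on empirical
    curves (defaults are permissive and keep every strict local maximum).
    A curve with no qualifying local maximum (e.g. monotone) yields a single
    flagged pick at its global maximum.
    """
    if len(curve.values) < 3:
        raise ValueError("ratio curve needs at least 3 bands")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    idx = _local_maxima(curve.values)
    if min_prominence > 0:
        idx = [i for i in idx if _prominence(curve.values, i) >= min_prominence]
    if not idx:
        warnings.warn(
            f"ratio curve for region {curve.background_region} has no interior "
            "local maximum; falling back to its global maximum",
            stacklevel=2,
        )
        i = int(np.argmax(curve.values))
        return [
            BandPick(
                wavelength_nm=float(curve.wavelengths[i]),
                ratio_value=float(curve.values[i]),
                background_region=curve.background_region,
                band_index=i,
                flagged=True,
            )
        ]
    idx.sort(key=lambda i: (-curve.values[i], curve.wavelengths[i]))
    chosen: list[int] = []
    for i in idx:
        if len(chosen) >= n_peaks:
            break
        if all(abs(i - j) >= min_separation for j in chosen):
            chosen.append(i)
    return [
        BandPick(
            wavelength_nm=float(curve.wavelengths[i]),
            ratio_value=float(curve.values[i]),
            background_region=curve.background_region,
            band_index=int(i),
        )
        for i in chosen
    ]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0  # constant images carry no distinguishing information
    return float(np.corrcoef(a, b)[0, 1])


def prune_correlated(
    picks: list[BandPick], cube: HyperCube, r_threshold: float = 0.999
) -> list[BandPick]:
    """Greedy de-duplication of picks by band-image correlation.

    Picks are visited in descending ratio order; a pick survives only if the
    Pearson correlation between its band image and every already-kept band
    image is below *r_threshold*.
    """
    if not picks:
        raise ValueError("need at least one pick")
    ordered = sorted(picks, key=lambda p: (-p.ratio_value, p.wavelength_nm))
    kept: list[BandPick] = []
    for pick in ordered:
        img = cube.data[:, :, pick.band_index]
        if all(
            _pearson(img, cube.data[:, :, k.band_index]) < r_threshold for k in kept
        ):
            kept.append(pick)
    return kept


def select_bands(
    cube: HyperCube,
    labels: SceneLayout | np.ndarray,
    k: int = 3,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """End-to-end characteristic-wavelength selection.

    Composes region means -> per-background ratio curves -> top local maxima
    per curve -> pooled picks -> correlation pruning -> truncation to the
    *k* highest-ratio survivors.  Deterministic; flagged (with a warning)
    when fewer than *k* picks survive pruning.
    """
    cfg = config or SelectionConfig()
    spectra = region_mean_spectra(cube, labels)
    curves = ratio_curves(spectra, cfg.leaf_region, cfg.backgrounds(), cfg.floor)
    pooled: list[BandPick] = []
    for curve in curves:
        rng = float(curve.values.max() - curve.values.min())
        pooled.extend(
            top_peaks(
                curve,
                cfg.peaks_per_curve,
                min_prominence=cfg.min_prominence_frac * rng,
                min_separation=cfg.min_separation_bands,
            )
        )
    kept = prune_correlated(pooled, cube, cfg.r_threshold)
    flagged = len(kept) < k
    if flagged:
        warnings.warn(
            f"only {len(kept)} uncorrelated picks survive; requested k={k}",
            stacklevel=2,
        )
    chosen = kept[:k]
    return SelectionResult(
        wavelengths=[p.wavelength_nm for p in chosen],
        picks=chosen,
        flagged=flagged,
        curves=curves,
    )
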