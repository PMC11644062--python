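"""Synthetic hyperspectral potted-plant scenes with ground truth.

Generates reproducible 5-region scenes (normal leaf, shadow leaf, soil,
flowerpot, dark stage) over a visible/NIR wavelength grid, so that the whole
segmentation pipeline — band selection, fusion, thresholding, evaluation —
can be exercised and validated without real captures.

The spectral library is parametric but vegetation-like: the leaf curve has a
green reflectance peak near 553 nm, a chlorophyll absorption minimum in the
red, a steep red edge and an NIR plateau; shadowed leaves are a scaled-down
copy of the normal-leaf curve; soil is a dark monotone ramp; the pot has its
own spectral features; the stage is dark and flat.  Background curves are
shaped so that each leaf/background reflectance-ratio curve attains sharp,
analytically-determined maxima ("planted peaks") whose wavelengths the
library documents — these are the recovery targets for the band-selection
stage.

Scene radiometry: per-pixel spectrum = class curve x smooth multiplicative
illumination field (uneven-lighting emulation), plus i.i.d. Gaussian noise
and optional salt-and-pepper impulses (sensor spike emulation, the kind of
artefact a median filter removes).  A consistent raw/white/dark capture trio
is emitted alongside, so black/white calibration reproduces the reflectance
cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hypercube_io import CalibrationSet, HyperCube

__all__ = [
    "CLASS_IDS",
    "CLASS_NAMES",
    "SpectralLibrary",
    "SceneLayout",
    "SceneParams",
    "default_library",
    "generate_layout",
    "render",
]

CLASS_IDS = {"stage": 0, "soil": 1, "pot": 2, "normal_leaf": 3, "shadow_leaf": 4}
CLASS_NAMES = {v: k for k, v in CLASS_IDS.items()}

_BACKGROUNDS = ("stage", "soil", "pot")


def _gauss(w: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / sd) ** 2)


def _logistic(w: np.ndarray, center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(w - center) / scale))


@dataclass
class SpectralLibrary:
    """Per-class reflectance curves on a shared wavelength grid.

    ``planted_peaks`` maps each background class name to the wavelengths (nm)
    of the two highest local maxima of the leaf/background ratio curve,
    in descending ratio order — the first entry is the curve's global
    maximum.  These are the wavelengths a correct band-selection stage
    should rediscover from rendered scenes.
    """

    wavelengths: np.ndarray
    curves: dict[str, np.ndarray]
    shadow_scale: float = 0.5
    planted_peaks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        w = self.wavelengths
        for name in CLASS_IDS:
            if name not in self.curves:
                raise ValueError(f"library missing curve for class {name!r}")
            curve = np.asarray(self.curves[name], dtype=float)
            if curve.shape != w.shape:
                raise ValueError(f"curve {name!r} length mismatch with grid")
            if curve.min() < 0 or curve.max() > 1:
                raise ValueError(f"curve {name!r} outside [0, 1]")
            self.curves[name] = curve
        leaf = self.curves["normal_leaf"]
        if not (0.3 < self.shadow_scale < 0.7):
            raise ValueError("shadow_scale must lie in (0.3, 0.7)")
        if not np.allclose(self.curves["shadow_leaf"], self.shadow_scale * leaf):
            raise ValueError("shadow_leaf must be shadow_scale x normal_leaf")
        stage = self.curves["stage"]
        if stage.max() >= 0.08:
            raise ValueError("stage curve must stay below 0.08")
        # Vegetation shape checks: green peak, red absorption, red edge.
        green = (w >= 540) & (w <= 570)
        red = (w >= 660) & (w <= 690)
        edge = (w >= 690) & (w <= 760)
        if green.any() and red.any():
            if leaf[green].max() <= leaf[red].min():
                raise ValueError("leaf curve lacks green peak above red minimum")
        if edge.sum() >= 2 and not np.all(np.diff(leaf[edge]) > 0):
            raise ValueError("leaf curve must rise monotonically on 690-760 nm")

    @property
    def planted_peak_set(self) -> np.ndarray:
        """All distinct planted peak wavelengths, sorted ascending."""
        vals = np.concatenate([np.asarray(v, dtype=float) for v in self.planted_peaks.values()])
        return np.unique(np.round(vals, 6))

    def spectrum_for_labels(self, labels: np.ndarray) -> np.ndarray:
        """(H, W, B) array of noiseless class spectra for a label image."""
        table = np.stack([self.curves[CLASS_NAMES[i]] for i in range(len(CLASS_IDS))])
        return table[labels]


@dataclass
class SceneLayout:
    """Label image over the five scene classes plus the canopy ground truth."""

    labels: np.ndarray
    canopy_truth: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.canopy_truth = np.asarray(self.canopy_truth, dtype=bool)
        if self.labels.ndim != 2 or self.canopy_truth.shape != self.labels.shape:
            raise ValueError("labels and canopy_truth must be matching 2-D images")
        expected = np.isin(self.labels, (CLASS_IDS["normal_leaf"], CLASS_IDS["shadow_leaf"]))
        if not np.array_equal(expected, self.canopy_truth):
            raise ValueError("canopy_truth must equal the union of the leaf classes")

    def class_fractions(self) -> dict[str, float]:
        n = self.labels.size
        return {name: float((self.labels == cid).sum()) / n for name, cid in CLASS_IDS.items()}


@dataclass
class SceneParams:
    """Scene geometry, noise and illumination settings.

    Defaults give a 128x128x176 cube over 400-1000 nm with mild Gaussian
    noise (sd 0.01 reflectance), a +/-20% smooth illumination gradient, a
    quarter of the canopy in shadow and 0.2% impulse pixels.
    """

    height: int = 128
    width: int = 128
    bands: int = 176
    noise_sd: float = 0.01
    illum_amplitude: float = 0.2
    shadow_fraction: float = 0.25
    impulse_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bands < 8:
            raise ValueError("need at least 8 bands")
        if not (0 <= self.illum_amplitude < 0.5):
            raise ValueError("illum_amplitude must lie in [0, 0.5)")
        if not (0 <= self.shadow_fraction < 1):
            raise ValueError("shadow_fraction must lie in [0, 1)")
        if not (0 <= self.impulse_fraction < 0.05):
            raise ValueError("impulse_fraction must lie in [0, 0.05)")

    def wavelength_grid(self) -> np.ndarray:
        return np.linspace(400.0, 1000.0, self.bands)


def default_library(wavelengths: np.ndarray, shadow_scale: float = 0.5) -> SpectralLibrary:
    """Build the default vegetation-like spectral library on *wavelengths*.

    The grid must be ascending and lie within 350-1100 nm.  Curve recipe:

    * ``normal_leaf`` — baseline + green Gaussian bump (553 nm), red
      absorption dip (670 nm), logistic red edge (centre 715 nm) with a
      well-defined NIR reflectance maximum near 772 nm and a decline beyond
      it.
    * ``shadow_leaf`` — ``shadow_scale`` x normal leaf.
    * ``soil`` — dark monotone ramp whose slope steepens sharply near
      750 nm; this plants a sharp leaf/soil ratio maximum near 733 nm.
    * ``pot`` — dark base with a mild green-region bump and a sharp
      reflectance step at ~718 nm; plants a leaf/pot ratio maximum near
      708 nm (plus a secondary one at the leaf NIR peak).
    * ``stage`` — flat and dark; its ratio curve peaks where the leaf curve
      does, near 772 nm.

    The three background classes stay close to each other in reflectance at
    the planted peaks, so their summed (fused) gray levels cluster well
    below the shadowed-leaf level — the property the fusion stage exploits.

    The exact planted-peak wavelengths are computed from the curves on the
    supplied grid and recorded in ``planted_peaks``.
    """
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or len(w) < 8 or not np.all(np.diff(w) > 0):
        raise ValueError("wavelength grid must be 1-D, ascending, length >= 8")
    if w[0] < 350 or w[-1] > 1100:
        raise ValueError("wavelength grid must lie within 350-1100 nm")

    nir = 0.46 * _logistic(w, 715.0, 12.0)
    nir = nir * (1.0 - 0.0012 * np.maximum(w - 772.0, 0.0)) + 0.08 * _gauss(w, 772.0, 8.0)
    leaf = 0.05 + 0.13 * _gauss(w, 553.0, 28.0) - 0.02 * _gauss(w, 670.0, 18.0) + nir
    soil = 0.04 + 0.02 * (w - 400.0) / 600.0 + 0.09 * _logistic(w, 750.0, 6.0)
    pot = 0.04 + 0.03 * _gauss(w, 520.0, 60.0) + 0.08 * _logistic(w, 718.0, 7.0)
    stage = np.full_like(w, 0.07)

    curves = {
        "normal_leaf": np.clip(leaf, 0.0, 1.0),
        "shadow_leaf": np.clip(leaf, 0.0, 1.0) * shadow_scale,
        "soil": np.clip(soil, 0.0, 1.0),
        "pot": np.clip(pot, 0.0, 1.0),
        "stage": stage,
    }
    planted = {
        bg: _top_two_ratio_peaks(w, curves["normal_leaf"], curves[bg]) for bg in _BACKGROUNDS
    }
    return SpectralLibrary(
        wavelengths=w, curves=curves, shadow_scale=shadow_scale, planted_peaks=planted
    )


def _top_two_ratio_peaks(w: np.ndarray, leaf: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Wavelengths of the two highest interior local maxima of leaf/bg."""
    r = leaf / np.maximum(bg, 1e-6)
    interior = np.flatnonzero((r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])) + 1
    if len(interior) == 0:
        return np.array([w[int(np.argmax(r))]])
    order = interior[np.argsort(-r[interior], kind="stable")]
    return w[order[:2]].copy()


# ---------------------------------------------------------------------------
# Layout generation
# ---------------------------------------------------------------------------

def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_layout(params: SceneParams) -> SceneLayout:
    """Deterministic random scene layout for *params*.

    Stage fills the frame; a pot annulus sits centred with soil inside it;
    the canopy is a union of random overlapping ellipses around the centre,
    with shadow patches carved out of it at roughly ``shadow_fraction`` of
    the canopy area.  Raises ``ValueError`` if the frame is too small to
    place all five classes with at least 0.5% of the pixels each.
    """
    h, w = params.height, params.width
    m = min(h, w)
    if m < 48:
        raise ValueError("scene too small to place all five classes (need >= 48 px)")
    rng = np.random.default_rng(params.seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    labels = np.full((h, w), CLASS_IDS["stage"], dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    r_outer = 0.44 * m
    ring = max(4.0, 0.055 * m)
    labels[rr <= r_outer] = CLASS_IDS["pot"]
    labels[rr <= r_outer - ring] = CLASS_IDS["soil"]

    # Canopy: overlapping ellipses whose reach stays inside the soil disc,
    # so soil and pot remain partly visible on every draw.
    canopy = np.zeros((h, w), dtype=bool)
    for _ in range(7):
        ecy = cy + rng.uniform(-0.16, 0.16) * m
        ecx = cx + rng.uniform(-0.16, 0.16) * m
        a = rng.uniform(0.095, 0.17) * m
        b = rng.uniform(0.095, 0.17) * m
        theta = rng.uniform(0, np.pi)
        canopy |= _ellipse_mask(h, w, ecy, ecx, a, b, theta)
    # Regularize the outline to a joint fixed point of the 3x3 binary median
    # and the 3x3 opening, so the truth mask carries no sub-template-scale
    # boundary structure (both operators then leave a correct mask intact).
    struct = np.ones((3, 3), dtype=bool)
    for _ in range(10):
        prev = canopy
        canopy = ndimage.median_filter(canopy.astype(np.uint8), size=3, mode="reflect") > 0
        canopy = ndimage.binary_opening(canopy, structure=struct)
        if np.array_equal(canopy, prev):
            break
    labels[canopy] = CLASS_IDS["normal_leaf"]

    # Shadow patches: small ellipses intersected with the canopy until the
    # requested area fraction is reached.
    target = params.shadow_fraction * canopy.sum()
    shadow = np.zeros_like(canopy)
    for _ in range(200):
        if shadow.sum() >= target:
            break
        idx = np.flatnonzero(canopy)
        pick = idx[rng.integers(len(idx))]
        py, px = divmod(int(pick), w)
        patch = _ellipse_mask(
            h, w, py, px,
            rng.uniform(0.04, 0.09) * m, rng.uniform(0.04, 0.09) * m,
            rng.uniform(0, np.pi),
        )
        shadow |= patch & canopy
    labels[shadow] = CLASS_IDS["shadow_leaf"]

    floor = 0.005 * h * w
    counts = np.bincount(labels.ravel(), minlength=5)
    if (counts < floor).any():
        missing = [CLASS_NAMES[i] for i in np.flatnonzero(counts < floor)]
        raise ValueError(f"scene too small: classes below 0.5% of pixels: {missing}")
    return SceneLayout(labels=labels, canopy_truth=canopy)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _illumination_field(h: int, w: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * f with f in [-1, 1]."""
    if amplitude == 0:
        return np.ones((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    gy, gx = rng.normal(size=2)
    f = gy * (yy - h / 2) / h + gx * (xx - w / 2) / w
    by, bx = rng.uniform(0.2, 0.8, size=2)
    sigma = 0.4 * min(h, w)
    f = f + rng.normal() * 0.5 * np.exp(
        -((yy - by * h) ** 2 + (xx - bx * w) ** 2) / (2 * sigma**2)
    )
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def render(
    layout: SceneLayout, lib: SpectralLibrary, params: SceneParams
) -> tuple[HyperCube, CalibrationSet]:
    """Render *layout* with *lib* into a reflectance cube plus capture trio.

    The returned calibration trio (raw, white, dark) is constructed so that
    black/white correction of it reproduces the reflectance cube.
    """
    h, w = layout.labels.shape
    if (h, w) != (params.height, params.width):
        raise ValueError("layout dimensions do not match params")
    if len(lib.wavelengths) != params.bands:
        raise ValueError("library grid length does not match params.bands")
    rng = np.random.default_rng(params.seed)

    reflect = lib.spectrum_for_labels(layout.labels)
    illum = _illumination_field(h, w, params.illum_amplitude, rng)
    reflect = reflect * illum[:, :, None]
    if params.noise_sd > 0:
        reflect = reflect + rng.normal(0.0, params.noise_sd, size=reflect.shape)
    if params.impulse_fraction > 0:
        n_imp = int(round(params.impulse_fraction * reflect.size))
        if n_imp > 0:
            flat = rng.choice(reflect.size, size=n_imp, replace=False)
            vals = np.where(rng.random(n_imp) < 0.5, 0.0, 1.0)
            reflect.ravel()[flat] = vals
    reflect = np.clip(reflect, 0.0, None)

    wl = lib.wavelengths.copy()
    meta = {"seed": params.seed, "synthetic": True}
    cube = HyperCube(data=reflect, wavelengths=wl, meta=meta)

    dark_level, white_level = 0.02, 0.97
    dark = HyperCube(np.full_like(reflect, dark_level), wl.copy(), {"role": "dark"})
    white = HyperCube(np.full_like(reflect, white_level), wl.copy(), {"role": "white"})
    raw = HyperCube(
        dark_level + reflect * (white_level - dark_level), wl.copy(), {"role": "raw"}
    )
    return cube, CalibrationSet(raw=raw, white=white, dark=dark)
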