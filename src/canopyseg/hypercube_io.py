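"""Hyperspectral cube container, ENVI-style I/O and reflectance calibration.

A :class:`HyperCube` is a ``height x width x bands`` reflectance array with an
ascending wavelength axis in nanometres.  Cubes are stored on disk in the
de-facto hyperspectral exchange format: a small text header (``.hdr``) next to
a raw binary payload, with band-sequential (BSQ), band-interleaved-by-line
(BIL) or band-interleaved-by-pixel (BIP) ordering.

Reflectance is obtained from raw sensor counts by black/white correction

    R = (I - B) / (W - B)

where ``I`` is the raw capture, ``W`` a white-reference capture and ``B`` a
dark-current capture.  Pixels where the white/dark difference is too small to
divide by are flagged in an explicit validity mask rather than propagated as
non-finite values, so downstream gray-level histograms stay well defined.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HyperCube",
    "CalibrationSet",
    "GrayImage",
    "read_envi",
    "write_envi",
    "calibrate",
    "average_replicates",
    "band_image",
]

# ENVI numeric codes for the dtypes this dialect supports (little-endian).
_DTYPE_TO_CODE = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}
_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperCube:
    """Reflectance cube: ``data[row, col, band]`` plus wavelength axis in nm.

    ``valid`` marks entries that carry meaningful reflectance; ``None`` means
    everything is valid.  All stored values are finite by construction.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (H, W, B), got {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values; use the validity mask")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("validity mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_spacing(self) -> float:
        """Nominal (median) spacing of the wavelength axis in nm."""
        if len(self.wavelengths) < 2:
            return 0.0
        return float(np.median(np.diff(self.wavelengths)))


@dataclass
class CalibrationSet:
    """Raw / white-reference / dark-current capture trio sharing one geometry."""

    raw: HyperCube
    white: HyperCube
    dark: HyperCube

    def __post_init__(self) -> None:
        for name, cube in (("white", self.white), ("dark", self.dark)):
            if cube.shape != self.raw.shape:
                raise ValueError(f"{name} cube shape {cube.shape} != raw {self.raw.shape}")
            if not np.allclose(cube.wavelengths, self.raw.wavelengths):
                raise ValueError(f"{name} cube wavelength axis differs from raw")


@dataclass
class GrayImage:
    """Single 2-D intensity image, optionally tagged with its wavelength."""

    data: np.ndarray
    source_wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("gray image must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("gray image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# ENVI-style I/O
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` lines of an ENVI header."""
    # Brace-delimited values may span lines; normalise those first.
    fields: dict[str, str] = {}
    buf = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in buf.splitlines():
        line = line.strip()
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str | os.PathLike) -> HyperCube:
    """Read a cube written in the supported ENVI dialect.

    The raw payload is looked up next to the header (same stem, ``.raw`` or
    no extension).  Raises ``FileNotFoundError`` for a missing companion,
    ``ValueError`` for unsupported dtype/interleave or a payload whose size
    disagrees with the declared dimensions.
    """
    header_path = os.fspath(header_path)
    with open(header_path, "r") as fh:
        fields = _parse_header(fh.read())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("only little-endian (byte order = 0) payloads are supported")
    if code not in _CODE_TO_DTYPE:
        raise ValueError(f"unsupported ENVI data type code {code}")
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = _CODE_TO_DTYPE[code]

    stem = header_path[:-4] if header_path.endswith(".hdr") else header_path
    for candidate in (stem + ".raw", stem, stem + ".img"):
        if os.path.isfile(candidate):
            payload_path = candidate
            break
    else:
        raise FileNotFoundError(f"no companion payload found for {header_path}")

    flat = np.fromfile(payload_path, dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise ValueError(
            f"payload has {flat.size} values but header declares "
            f"{lines}x{samples}x{bands} = {expected}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        data = flat.reshape(lines, samples, bands)

    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().strip("{}")
        wavelengths = np.array([float(v) for v in wl_text.split(",") if v.strip()])
    else:
        wavelengths = np.arange(bands, dtype=float)
    meta = {"source": payload_path, "interleave": interleave}
    if "description" in fields:
        meta["description"] = fields["description"].strip("{} ")
    return HyperCube(data=np.ascontiguousarray(data), wavelengths=wavelengths, meta=meta)


def write_envi(
    cube: HyperCube,
    header_path: str | os.PathLike,
    interleave: str = "bsq",
    dtype: np.dtype | type = np.float32,
) -> str:
    """Write *cube* as ``.hdr`` + raw payload; returns the payload path."""
    header_path = os.fspath(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_TO_CODE:
        raise ValueError(f"unsupported dtype {dtype}")
    h, w, b = cube.shape
    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:
        arr = cube.data
    stem = header_path[:-4] if header_path.endswith(".hdr") else header_path
    payload_path = stem + ".raw"
    np.ascontiguousarray(arr, dtype=dtype).tofile(payload_path)
    wl = ", ".join(f"{v:.4f}" for v in cube.wavelengths)
    header = (
        "ENVI\n"
        "file type = ENVI Standard\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        f"data type = {_DTYPE_TO_CODE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path if header_path.endswith(".hdr") else stem + ".hdr", "w") as fh:
        fh.write(header)
    return payload_path


# ---------------------------------------------------------------------------
# Calibration and band access
# ---------------------------------------------------------------------------

def calibrate(cs: CalibrationSet, epsilon: float = 1e-6) -> HyperCube:
    """Black/white reflectance correction R = (I - B) / (W - B).

    Entries where ``W - B <= epsilon`` cannot be normalised; they are set to 0
    and flagged invalid.  Negative reflectance (noise below the dark
    reference) is clipped to 0; values above 1 (specular highlights,
    overexposed leaves) are retained.
    """
    raw = cs.raw.data.astype(float)
    white = cs.white.data.astype(float)
    dark = cs.dark.data.astype(float)
    denom = white - dark
    ok = denom > epsilon
    out = np.zeros_like(raw)
    np.divide(raw - dark, denom, out=out, where=ok)
    np.clip(out, 0.0, None, out=out)
    out[~ok] = 0.0
    meta = dict(cs.raw.meta)
    meta["calibrated"] = True
    return HyperCube(data=out, wavelengths=cs.raw.wavelengths.copy(), meta=meta, valid=ok)


def average_replicates(cubes: Sequence[HyperCube]) -> HyperCube:
    """Elementwise mean of repeated captures of the same sample."""
    if len(cubes) == 0:
        raise ValueError("need at least one cube to average")
    first = cubes[0]
    for c in cubes[1:]:
        if c.shape != first.shape:
            raise ValueError("replicate cubes must share the same shape")
        if not np.allclose(c.wavelengths, first.wavelengths):
            raise ValueError("replicate cubes must share the same wavelength axis")
    stacked = np.stack([c.data.astype(float) for c in cubes])
    return HyperCube(
        data=stacked.mean(axis=0),
        wavelengths=first.wavelengths.copy(),
        meta={"n_replicates": len(cubes), **first.meta},
    )


def band_image(cube: HyperCube, wavelength_nm: float, tolerance: float | None = None) -> GrayImage:
    """Extract the band whose centre wavelength is nearest *wavelength_nm*.

    Requests farther than *tolerance* (default: one nominal band spacing)
    outside the axis range raise ``ValueError``.  The returned image records
    the wavelength actually used.
    """
    wl = cube.wavelengths
    if tolerance is None:
        tolerance = cube.band_spacing()
    if wavelength_nm < wl[0] - tolerance or wavelength_nm > wl[-1] + tolerance:
        raise ValueError(
            f"requested {wavelength_nm} nm outside axis range "
            f"[{wl[0]}, {wl[-1]}] nm (tolerance {tolerance} nm)"
        )
    idx = int(np.argmin(np.abs(wl - wavelength_nm)))
    return GrayImage(data=cube.data[:, :, idx].astype(float), source_wavelength_nm=float(wl[idx]))
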