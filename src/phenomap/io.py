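"""Hypercube container, ENVI raster I/O and reflectance calibration.

A hypercube is an ``(lines, samples, bands)`` array bound to a strictly
increasing wavelength grid in nanometres and a sensor-range tag
(``VISNIR`` covering 400-1,000 nm or ``SWIR`` covering 900-2,500 nm).
Raw sensor counts are converted to relative reflectance with the
white/dark reference correction

    R = (I_raw - I_dark) / (I_white - I_dark)

where the white reference is a near-perfect (>99 %) diffuse reflector and
the dark frame is acquired with the shutter closed.

The on-disk format is the ENVI header dialect: a text ``.hdr`` next to a
flat binary raster, interleaves ``bsq``/``bil``/``bip``, data types 4
(float32) and 12 (uint16), little-endian.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    CorruptFileError,
    DegenerateReferenceError,
    EmptyRangeError,
    FormatError,
    InvalidGridError,
)

logger = logging.getLogger(__name__)

RANGE_SPANS = {"VISNIR": (400.0, 1000.0), "SWIR": (900.0, 2500.0)}

#: reflectance clipping window applied after calibration
REFLECTANCE_CLIP = (0.0, 1.5)

_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_ENVI_CODES = {np.dtype("float32"): 4, np.dtype("uint16"): 12}


def validate_grid(wavelengths_nm: np.ndarray, range_tag: str) -> np.ndarray:
    """Check a wavelength grid is strictly increasing and inside its range."""
    grid = np.asarray(wavelengths_nm, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise InvalidGridError("wavelength grid must be a 1-D non-empty array")
    if np.any(np.diff(grid) <= 0):
        raise InvalidGridError("wavelength grid must be strictly increasing")
    if range_tag not in RANGE_SPANS:
        raise InvalidGridError(f"unknown range tag {range_tag!r}")
    lo, hi = RANGE_SPANS[range_tag]
    if grid[0] < lo or grid[-1] > hi:
        raise InvalidGridError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] nm outside {range_tag} span [{lo:g}, {hi:g}] nm"
        )
    return grid


@dataclass
class Hypercube:
    """An ``(H, W, B)`` spectral image on a wavelength grid.

    Parameters
    ----------
    data : ndarray, shape (H, W, B)
        Raw counts or reflectance.
    wavelengths_nm : ndarray, shape (B,)
        Strictly increasing band centres in nm.
    range_tag : {"VISNIR", "SWIR"}
    calibrated : bool
        True once the white/dark correction has been applied.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    range_tag: str
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = validate_grid(self.wavelengths_nm, self.range_tag)
        if self.data.ndim != 3:
            raise InvalidGridError("hypercube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise InvalidGridError(
                f"band axis ({self.data.shape[2]}) does not match wavelength "
                f"count ({self.wavelengths_nm.size})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferenceFrames:
    """White and dark reference frames, ``(H, W, B)`` or ``(1, W, B)``."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise DegenerateReferenceError("white and dark frames must share a shape")

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean over acquisition lines -> per (sample, band) reference spectra."""
        return self.white.mean(axis=0), self.dark.mean(axis=0)


# ---------------------------------------------------------------------------
# ENVI I/O


def _format_header(cube: Hypercube, interleave: str, dtype_code: int) -> str:
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.3f}" for x in cube.wavelengths_nm)
    return (
        "ENVI\n"
        "description = {phenomap hypercube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"phenomap range tag = {cube.range_tag}\n"
        f"phenomap calibrated = {int(cube.calibrated)}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )


def write_envi(cube: Hypercube, path: str | Path, interleave: str = "bil") -> tuple[Path, Path]:
    """Write *cube* as an ENVI ``.hdr``/``.raw`` pair.

    Returns the (header, raster) paths. ``path`` may carry either
    extension or none; siblings are derived from its stem.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    base = Path(path)
    if base.suffix in (".hdr", ".raw", ".img"):
        base = base.with_suffix("")
    hdr_path, raw_path = base.with_suffix(".hdr"), base.with_suffix(".raw")

    arr = np.ascontiguousarray(cube.data)
    if arr.dtype not in _ENVI_CODES:
        arr = arr.astype(np.float32)
    code = _ENVI_CODES[arr.dtype]

    # on disk: bsq=(B,H,W), bil=(H,B,W), bip=(H,W,B)
    if interleave == "bsq":
        ordered = np.transpose(arr, (2, 0, 1))
    elif interleave == "bil":
        ordered = np.transpose(arr, (0, 2, 1))
    else:
        ordered = arr
    raw_path.write_bytes(np.ascontiguousarray(ordered).astype(ordered.dtype.newbyteorder("<")).tobytes())
    hdr_path.write_text(_format_header(cube, interleave, code))
    return hdr_path, raw_path


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # join brace-delimited blocks onto one logical line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI ``.hdr``/raster pair written by :func:`write_envi`.

    Raises :class:`FormatError` on a malformed header and
    :class:`CorruptFileError` when the raster size contradicts the header.
    """
    hdr_path = Path(header_path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    fields = _parse_header(hdr_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"header missing required field: {exc}") from exc
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) rasters supported")
    wl_block = fields.get("wavelength")
    if wl_block is None:
        raise FormatError("header missing wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in wl_block.strip("{} ").replace(",", " ").split()], dtype=float
    )
    if wavelengths.size != b:
        raise FormatError(
            f"header declares bands={b} but {wavelengths.size} wavelengths"
        )

    dtype = _ENVI_DTYPES[code]
    raw_path = None
    for ext in (".raw", ".img", ".dat"):
        cand = hdr_path.with_suffix(ext)
        if cand.exists():
            raw_path = cand
            break
    if raw_path is None:
        raise FormatError(f"no raster file next to {hdr_path}")
    payload = raw_path.read_bytes()
    expected = h * w * b * dtype.itemsize
    if len(payload) != expected:
        raise CorruptFileError(
            f"raster is {len(payload)} bytes; header implies {expected} "
            f"({interleave}, {h}x{w}x{b}, dtype {code})"
        )
    flat = np.frombuffer(payload, dtype=dtype)
    if interleave == "bsq":
        data = np.transpose(flat.reshape(b, h, w), (1, 2, 0))
    elif interleave == "bil":
        data = np.transpose(flat.reshape(h, b, w), (0, 2, 1))
    else:
        data = flat.reshape(h, w, b)
    return Hypercube(
        data=np.ascontiguousarray(data),
        wavelengths_nm=wavelengths,
        range_tag=fields.get("phenomap range tag", "SWIR").strip(),
        calibrated=bool(int(fields.get("phenomap calibrated", "0"))),
    )


# ---------------------------------------------------------------------------
# Reflectance correction


def calibrate_reflectance(
    raw: Hypercube,
    refs: ReferenceFrames,
    eps: float = 1e-9,
    clip: tuple[float, float] | None = REFLECTANCE_CLIP,
) -> Hypercube:
    """White/dark reflectance correction ``(raw - dark)/(white - dark)``.

    Reference frames are averaged over acquisition lines before the
    correction to suppress shot noise. Out-of-range reflectances are
    clipped to ``clip`` and the clipped-voxel count is logged.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    white, dark = refs.averaged()  # (W, B) or broadcastable
    denom = white - dark
    if np.any(denom <= eps):
        raise DegenerateReferenceError(
            "white and dark references coincide at some sample/band"
        )
    refl = (raw.data.astype(float) - dark[None, :, :]) / denom[None, :, :]
    if clip is not None:
        n_clip = int(np.count_nonzero((refl < clip[0]) | (refl > clip[1])))
        if n_clip:
            logger.info("clipped %d voxels outside [%g, %g]", n_clip, *clip)
        refl = np.clip(refl, *clip)
    return Hypercube(refl, raw.wavelengths_nm, raw.range_tag, calibrated=True)


def trim_wavelengths(obj, lo: float, hi: float):
    """Retain exactly the bands with ``lo <= wavelength <= hi``.

    Accepts a :class:`Hypercube` or any object with ``spectra`` and
    ``wavelengths_nm`` attributes (a spectra table); returns the same kind.
    """
    if lo >= hi:
        raise EmptyRangeError("trim requires lo < hi")
    if isinstance(obj, Hypercube):
        grid = obj.wavelengths_nm
        keep = (grid >= lo) & (grid <= hi)
        if not keep.any():
            raise EmptyRangeError(f"no bands in [{lo:g}, {hi:g}] nm")
        return Hypercube(obj.data[:, :, keep], grid[keep], obj.range_tag, obj.calibrated)
    grid = np.asarray(obj.wavelengths_nm, dtype=float)
    keep = (grid >= lo) & (grid <= hi)
    if not keep.any():
        raise EmptyRangeError(f"no bands in [{lo:g}, {hi:g}] nm")
    return replace(obj, spectra=obj.spectra[:, keep], wavelengths_nm=grid[keep])
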