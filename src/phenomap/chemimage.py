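"""Chemical concentration mapping over the plant mask.

The fitted regression vector is applied at every masked pixel,

    map(px) = ( preprocess(x_px) - mean_x ) . K * L + intercept

giving an H x W image of predicted total phenolic content (mg/g DW) over
the canopy and a sentinel (NaN) elsewhere. ``L`` is a display-scaling
constant and defaults to 1 so the map stays quantitative; the model's
centering and intercept are always included so the units remain mg/g.

Per-pixel preprocessing mirrors the training pretreatment exactly (same
frozen MSC reference, same derivative window); pixels on which a
pretreatment degenerates (e.g. SNV of a constant spectrum) are flagged,
logged and set to the sentinel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, PngImagePlugin

from .errors import DegenerateSpectrumError, EmptyMapError, GridMismatchError
from .io import Hypercube
from .plsr import PLSRegressionNIPALS
from .segmentation import PlantMask

logger = logging.getLogger(__name__)

__all__ = ["ChemicalImage", "apply_model_to_cube", "plant_prediction", "render_map"]

SENTINEL = float("nan")


@dataclass
class ChemicalImage:
    """Spatial map of predicted concentration (mg/g DW) over a mask."""

    map: np.ndarray
    scale_constant: float = 1.0
    model_ref: str = ""
    colormap_range: tuple[float, float] | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.map)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def _transform_rows(preprocessor, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted row-wise transform; flag rows it degenerates on."""
    if preprocessor is None:
        return X.copy(), np.ones(X.shape[0], dtype=bool)
    try:
        return np.asarray(preprocessor.transform(X), dtype=float), np.ones(
            X.shape[0], dtype=bool
        )
    except DegenerateSpectrumError:
        pass
    out = np.zeros_like(X)
    ok = np.ones(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        try:
            out[i] = preprocessor.transform(X[i : i + 1])[0]
        except DegenerateSpectrumError:
            ok[i] = False
    logger.warning("preprocessing degenerated on %d pixels", int((~ok).sum()))
    return out, ok


def apply_model_to_cube(
    cube: Hypercube,
    mask: PlantMask | np.ndarray,
    model: PLSRegressionNIPALS,
    preprocessor=None,
    scale_constant: float = 1.0,
    model_wavelengths_nm: np.ndarray | None = None,
) -> ChemicalImage:
    """Predict concentration at every mask pixel of a calibrated cube.

    The cube must already be trimmed/reduced to the model's wavelength
    grid (checked against ``model_wavelengths_nm`` when given).
    """
    m = mask.mask if isinstance(mask, PlantMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.shape[:2]:
        raise ValueError("mask and cube disagree on spatial shape")
    if model_wavelengths_nm is not None and (
        len(model_wavelengths_nm) != cube.n_bands
        or not np.allclose(cube.wavelengths_nm, model_wavelengths_nm, atol=1e-3)
    ):
        raise GridMismatchError("cube wavelengths differ from the model's grid")
    if cube.n_bands != model.coef_.shape[0] and preprocessor is None:
        raise GridMismatchError(
            f"cube has {cube.n_bands} bands, model expects {model.coef_.shape[0]}"
        )

    pixels = cube.data[m]  # (N, B)
    pre, ok = _transform_rows(preprocessor, pixels.astype(float))
    values = np.full(pixels.shape[0], SENTINEL)
    if ok.any():
        centred = pre[ok] - model.x_mean_
        values[ok] = centred @ model.coef_ * scale_constant + model.intercept_
    out = np.full(m.shape, SENTINEL)
    out[m] = values
    return ChemicalImage(map=out, scale_constant=scale_constant)


def plant_prediction(image: ChemicalImage) -> tuple[float, float]:
    """Whole-plant summary: (mean, SD) over valid map pixels, mg/g DW."""
    vals = image.map[image.valid]
    if vals.size == 0:
        raise EmptyMapError("chemical image has no valid pixels")
    return float(vals.mean()), float(vals.std())


_BLUE_RED_STOPS = np.array(
    [[0.0, 0.0, 0.55], [0.0, 0.45, 1.0], [0.85, 0.85, 0.85], [1.0, 0.45, 0.0], [0.8, 0.0, 0.0]]
)


def _blue_red_lut(n: int = 256) -> np.ndarray:
    """Deterministic blue-to-red lookup table (n, 3) uint8."""
    x = np.linspace(0, 1, n)
    stops = np.linspace(0, 1, _BLUE_RED_STOPS.shape[0])
    lut = np.stack(
        [np.interp(x, stops, _BLUE_RED_STOPS[:, c]) for c in range(3)], axis=1
    )
    return (lut * 255).round().astype(np.uint8)


def render_map(
    image: ChemicalImage,
    out_path: str | Path,
    value_range: tuple[float, float] | None = None,
    background_grey: int = 230,
) -> Path:
    """Render the map to a PNG, blue (low) to red (high), sentinel neutral.

    The value range used for the colour scale is annotated in the PNG
    text metadata and an adjacent ``.json`` sidecar. Rendering is fully
    deterministic: identical image + range give a byte-identical file.
    """
    valid = image.valid
    if not valid.any():
        raise EmptyMapError("nothing to render")
    vals = image.map[valid]
    if value_range is None:
        vr = (float(vals.min()), float(vals.max()))
    else:
        vr = (float(value_range[0]), float(value_range[1]))
    lo, hi = vr
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((image.map - lo) / span, 0.0, 1.0)
    lut = _blue_red_lut()
    idx = np.nan_to_num(norm * 255.0, nan=0.0).round().astype(int)
    rgb = lut[idx]
    rgb[~valid] = background_grey

    out_path = Path(out_path)
    meta = PngImagePlugin.PngInfo()
    meta.add_text("phenomap:value_range_mg_per_g", f"{lo:.6g},{hi:.6g}")
    meta.add_text("phenomap:scale_constant", f"{image.scale_constant:.6g}")
    Image.fromarray(rgb.astype(np.uint8), mode="RGB").save(out_path, pnginfo=meta)
    sidecar = out_path.with_suffix(out_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "value_range_mg_per_g": [lo, hi],
                "map_min": float(vals.min()),
                "map_max": float(vals.max()),
                "n_valid_pixels": int(valid.sum()),
                "scale_constant": image.scale_constant,
                "model_ref": image.model_ref,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return out_path
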