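"""Plant/background segmentation from wavelength composites.

The canopy is separated from pot and soil using three named wavelengths
(947, 1,535, 1,946 nm in the SWIR; 560, 655, 750 nm in the VIS/NIR): a
normalized-difference score between a vegetation-bright and a
background-bright channel is thresholded with Otsu's method, then the
largest connected component is kept and small holes are filled. The
classifier behind the named wavelengths is deliberately parameter-light
and fully recorded in ``method_params`` so a run can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import EmptyMaskError, OutOfSpanError
from .io import Hypercube

__all__ = ["PlantMask", "composite_bands", "segment_plant", "COMPOSITE_WAVELENGTHS"]

#: the named segmentation wavelengths per sensor range (nm)
COMPOSITE_WAVELENGTHS = {
    "SWIR": (947.0, 1535.0, 1946.0),
    "VISNIR": (560.0, 655.0, 750.0),
}

# (vegetation-bright, background-bright) channel indices into the triple
_SCORE_CHANNELS = {"SWIR": (0, 2), "VISNIR": (2, 1)}


@dataclass
class PlantMask:
    """Boolean canopy mask plus the parameters that produced it."""

    mask: np.ndarray
    source_wavelengths: tuple[float, float, float]
    method_params: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def nearest_band(wavelengths_nm: np.ndarray, target: float) -> int:
    """Index of the band nearest *target*; ties break to the lower wavelength."""
    grid = np.asarray(wavelengths_nm, dtype=float)
    spacing = np.diff(grid).min() if grid.size > 1 else np.inf
    if target < grid[0] - spacing / 2 or target > grid[-1] + spacing / 2:
        raise OutOfSpanError(
            f"target {target:g} nm outside grid span "
            f"[{grid[0]:g}, {grid[-1]:g}] nm by more than half a band spacing"
        )
    dist = np.abs(grid - target)
    return int(np.flatnonzero(dist == dist.min())[0])  # grid increasing -> first is lower


def composite_bands(
    cube: Hypercube, targets: tuple[float, float, float] | None = None
) -> np.ndarray:
    """Three-channel image from the bands nearest the target wavelengths."""
    if targets is None:
        targets = COMPOSITE_WAVELENGTHS[cube.range_tag]
    idx = [nearest_band(cube.wavelengths_nm, t) for t in targets]
    return np.stack([cube.data[:, :, i] for i in idx], axis=-1)


def segment_plant(
    cube: Hypercube,
    targets: tuple[float, float, float] | None = None,
    threshold: float | None = None,
    min_pixels: int = 16,
    min_contrast: float = 0.05,
    min_score: float = 0.1,
    fill_holes_area: int = 32,
) -> PlantMask:
    """Segment the canopy from a calibrated cube.

    A normalized difference ``(veg - bg) / (veg + bg)`` between the
    vegetation-bright and background-bright composite channels is
    thresholded (Otsu by default, or the manual ``threshold`` override);
    the largest connected component is kept and holes below
    ``fill_holes_area`` pixels are filled. Deterministic given the cube.

    Raises :class:`EmptyMaskError` when the score image has no usable
    contrast (e.g. a pure-background scene) or cleanup empties the mask.
    """
    if not cube.calibrated:
        raise ValueError("segment_plant requires a calibrated cube")
    if targets is None:
        targets = COMPOSITE_WAVELENGTHS[cube.range_tag]
    comp = composite_bands(cube, targets)
    iv, ib = _SCORE_CHANNELS.get(cube.range_tag, (0, 2))
    veg, bg = comp[:, :, iv], comp[:, :, ib]
    score = (veg - bg) / (veg + bg + 1e-9)

    if threshold is None:
        if score.max() - score.min() < 1e-6:
            raise EmptyMaskError("score image is constant; nothing to segment")
        thr = float(threshold_otsu(score))
    else:
        thr = float(threshold)
    raw_mask = score > thr
    if not raw_mask.any() or raw_mask.all():
        raise EmptyMaskError("thresholding produced a trivial mask")
    contrast = float(score[raw_mask].mean() - score[~raw_mask].mean())
    fg_score = float(score[raw_mask].mean())
    if threshold is None and (contrast < min_contrast or fg_score < min_score):
        raise EmptyMaskError(
            f"foreground score {fg_score:.3f} / contrast {contrast:.3f} below "
            f"({min_score}, {min_contrast}); likely no plant in view"
        )

    labels = measure.label(raw_mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    mask = morphology.remove_small_holes(mask, max_size=fill_holes_area)
    if mask.sum() < min_pixels:
        raise EmptyMaskError(f"mask has {int(mask.sum())} px < min_pixels={min_pixels}")
    return PlantMask(
        mask=mask,
        source_wavelengths=tuple(targets),
        method_params={
            "threshold": thr,
            "otsu": threshold is None,
            "score_channels": (iv, ib),
            "min_pixels": min_pixels,
            "min_contrast": min_contrast,
            "min_score": min_score,
            "fill_holes_area": fill_holes_area,
            "contrast": contrast,
        },
    )
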