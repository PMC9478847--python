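"""Synthetic hyperspectral plant scenes with known phenolic ground truth.

Emulates line-scan acquisitions of rosette plants (an Arabidopsis-like
canopy of overlapping leaf disks) on a soil/pot background, in either the
VIS/NIR (400-1,000 nm) or SWIR (900-2,500 nm) sensor range.

The optical model for a plant pixel is

    latent = a * (baseline - c * signature) + b
    raw    = dark + latent * (white - dark) + noise

where ``baseline`` is a smooth vegetation reflectance, ``signature`` a
non-negative phenolic absorption profile scaled by the concentration
``c`` (mg/g dry weight), ``a ~ N(1, scatter_gain_sd)`` and
``b ~ N(0, scatter_offset_sd)`` are the per-pixel multiplicative/additive
scatter that MSC and SNV pretreatments are designed to remove, and
``noise`` is i.i.d. Gaussian sensor noise on the raw counts.

The phenolic signature is planted where C-H overtone absorption of
phenolic compounds is reported: second-overtone 1,110-1,130 nm and
first-overtone 1,645-1,670 nm in the SWIR, 450-475 and 535-565 nm in the
VIS/NIR. Water absorption shapes the vegetation baseline near 1,450 nm
(O-H stretch first overtone) and 1,940 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGridError
from .io import Hypercube, ReferenceFrames, validate_grid

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "Endmembers",
    "Cohort",
    "generate_basis_spectra",
    "rosette_mask",
    "generate_scene",
    "generate_cohort",
]

# absorption-window centres (nm) per sensor range; amplitudes are relative
_SIGNATURE_PEAKS = {
    "SWIR": ((1120.0, 6.0, 1.0), (1657.0, 8.0, 0.9)),
    "VISNIR": ((462.0, 7.0, 1.0), (550.0, 8.0, 0.9)),
}
#: absorption depth (reflectance units) per 1 mg/g of total phenolics
SIGNATURE_DEPTH_PER_MG = 0.09


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic plant scene.

    Defaults describe the desk-scale SWIR study condition: a 64x64-pixel
    scene on the 920-1,970 nm grid at 10 nm spacing (106 bands).
    """

    range_tag: str = "SWIR"
    image_height: int = 64
    image_width: int = 64
    n_bands: int = 106
    wavelength_lo: float = 920.0
    wavelength_hi: float = 1970.0
    plant_radius: float = 20.0
    concentration: float = 1.5
    scatter_gain_sd: float = 0.02
    scatter_offset_sd: float = 0.005
    noise_sd: float = 0.01
    seed: int = 0
    condition_label: str = ""
    n_leaves: int = 6

    def __post_init__(self) -> None:
        if self.n_bands < 8:
            raise InvalidGridError("n_bands must be >= 8")
        if self.wavelength_lo >= self.wavelength_hi:
            raise InvalidGridError("wavelength_lo must be < wavelength_hi")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(self.wavelength_lo, self.wavelength_hi, self.n_bands)


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    mask: np.ndarray
    concentration: float
    condition_label: str = ""


@dataclass
class Endmembers:
    """Endmember spectra on a common grid, reflectance in [0, 1]."""

    wavelengths_nm: np.ndarray
    vegetation: np.ndarray
    soil: np.ndarray
    pot: np.ndarray
    signature: np.ndarray  # unit absorption profile, scaled by mg/g at use
    white_level: np.ndarray
    dark_level: np.ndarray


def _smooth_perturbation(grid: np.ndarray, rng: np.random.Generator, amp: float) -> np.ndarray:
    """Seeded low-order cosine wiggle, amplitude ``amp``."""
    span = grid[-1] - grid[0]
    x = (grid - grid[0]) / span
    out = np.zeros_like(grid)
    for k in range(1, 4):
        out += rng.normal(0.0, amp / k) * np.cos(np.pi * k * x + rng.uniform(0, 2 * np.pi))
    return out


def _gauss(grid: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - centre) / sigma) ** 2)


def generate_basis_spectra(
    wavelengths_nm: np.ndarray, seed: int, range_tag: str = "SWIR"
) -> Endmembers:
    """Build the endmember set for one scene.

    The phenolic signature is a sum of Gaussians whose maxima sit inside
    the C-H overtone windows of the given sensor range; it is compactly
    supported in practice (negligible outside roughly +-4 sigma).
    """
    grid = validate_grid(wavelengths_nm, range_tag)
    rng = np.random.default_rng(seed)

    if range_tag == "SWIR":
        veg = 0.52 - 0.00005 * (grid - grid[0])
        veg = veg - 0.22 * _gauss(grid, 1450.0, 45.0) - 0.30 * _gauss(grid, 1940.0, 55.0)
        soil = 0.22 + 0.00008 * (grid - grid[0])
    else:
        # green bump, chlorophyll red dip, red-edge rise to NIR plateau
        veg = (
            0.08
            + 0.10 * _gauss(grid, 550.0, 35.0)
            - 0.04 * _gauss(grid, 670.0, 25.0)
            + 0.48 / (1.0 + np.exp(-(grid - 715.0) / 16.0))
        )
        soil = 0.18 + 0.00025 * (grid - grid[0])
    veg = np.clip(veg + _smooth_perturbation(grid, rng, 0.008), 0.01, 0.99)
    soil = np.clip(soil + _smooth_perturbation(grid, rng, 0.006), 0.01, 0.99)
    pot = np.clip(0.14 + _smooth_perturbation(grid, rng, 0.004), 0.01, 0.99)

    sig = np.zeros_like(grid)
    for centre, sigma, rel in _SIGNATURE_PEAKS[range_tag]:
        # jitter centres a little, but keep maxima inside their window
        sig += rel * _gauss(grid, centre + rng.uniform(-3.0, 3.0), sigma)
    sig *= SIGNATURE_DEPTH_PER_MG

    white = np.clip(0.92 + 0.00002 * (grid - grid.mean()) + _smooth_perturbation(grid, rng, 0.003), 0.5, 1.0)
    dark = np.clip(0.06 + _smooth_perturbation(grid, rng, 0.002), 0.01, 0.2)
    return Endmembers(grid, veg, soil, pot, sig, white, dark)


def rosette_mask(
    height: int, width: int, plant_radius: float, n_leaves: int = 6
) -> np.ndarray:
    """Plant footprint: a central disk plus ``n_leaves`` overlapping leaf
    disks at equal angles — pixels satisfy at least one disk inequality."""
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.6 * plant_radius) ** 2
    for k in range(n_leaves):
        ang = 2.0 * np.pi * k / n_leaves
        ly = cy + 0.72 * plant_radius * np.sin(ang)
        lx = cx + 0.72 * plant_radius * np.cos(ang)
        mask |= (yy - ly) ** 2 + (xx - lx) ** 2 <= (0.55 * plant_radius) ** 2
    return mask


def generate_scene(
    spec: SceneSpec,
) -> tuple[Hypercube, np.ndarray, np.ndarray, SceneTruth]:
    """Render one raw scene: ``(raw cube, white frame, dark frame, truth)``.

    The returned frames have shape ``(1, W, B)`` (full-width single-line
    references). With all noise terms zero, applying the white/dark
    correction to the outputs reproduces the latent reflectance exactly.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.wavelengths_nm
    em = generate_basis_spectra(grid, seed=spec.seed, range_tag=spec.range_tag)
    h, w, b = spec.image_height, spec.image_width, spec.n_bands

    mask = rosette_mask(h, w, spec.plant_radius, spec.n_leaves)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_pot = 0.42 * min(h, w)
    rad = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    pot_ring = (~mask) & (rad >= r_pot) & (rad < r_pot + 3.0)

    base = np.where(
        mask[:, :, None], em.vegetation, np.where(pot_ring[:, :, None], em.pot, em.soil)
    ).astype(float)
    base[mask] = base[mask] - spec.concentration * em.signature

    gain = rng.normal(1.0, spec.scatter_gain_sd, size=(h, w, 1))
    offset = rng.normal(0.0, spec.scatter_offset_sd, size=(h, w, 1))
    latent = gain * base + offset

    neg = latent[mask] < 0
    if neg.any():
        frac = neg.mean()
        if frac > 0.01:
            warnings.warn(
                f"concentration {spec.concentration:g} mg/g drives latent "
                f"reflectance < 0 on {100 * frac:.1f}% of plant pixels; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
        latent = np.clip(latent, 0.0, None)

    white_frame = np.broadcast_to(em.white_level, (1, w, b)).copy()
    dark_frame = np.broadcast_to(em.dark_level, (1, w, b)).copy()
    raw = em.dark_level + latent * (em.white_level - em.dark_level)
    if spec.noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.noise_sd, size=raw.shape)
    cube = Hypercube(raw, grid, spec.range_tag, calibrated=False)
    truth = SceneTruth(mask=mask, concentration=spec.concentration,
                       condition_label=spec.condition_label)
    return cube, white_frame, dark_frame, truth


@dataclass
class Cohort:
    """A generated experiment: one spec per plant plus reference tables.

    ``reference_table`` mirrors a group-level HPLC readout (one total per
    growing condition); per-plant truth is kept separately in
    ``plant_truth`` for recovery tests. Scenes are realised lazily with
    :meth:`scene` to keep memory flat.
    """

    specs: list[SceneSpec]
    plant_ids: list[str]
    conditions: list[str]
    true_concentrations: np.ndarray
    reference_table: "pd.DataFrame" = None  # type: ignore[name-defined]
    plant_truth: "pd.DataFrame" = None  # type: ignore[name-defined]

    def __len__(self) -> int:
        return len(self.specs)

    def scene(self, i: int):
        return generate_scene(self.specs[i])


def generate_cohort(
    n_conditions: int = 8,
    plants_per_condition: int = 15,
    condition_means: "np.ndarray | list[float] | None" = None,
    plant_sd: float = 0.05,
    seed: int = 0,
    condition_labels: list[str] | None = None,
    **scene_kwargs,
) -> Cohort:
    """Generate a cohort of plants grouped into growing conditions.

    Per-plant true totals are drawn ``N(condition mean, plant_sd)``
    (truncated at zero); the reference table records the condition mean,
    mirroring pooled group-level HPLC quantification. Defaults reproduce
    the study layout: 8 conditions x 15 plants = 120 scenes with
    condition means taken from the packaged compound table's totals
    (~0.98-2.19 mg/g).
    """
    import pandas as pd

    from .dataset import load_compound_table, total_phenolics

    if n_conditions < 1 or plants_per_condition < 1:
        raise ValueError("counts must be >= 1")
    if condition_means is None:
        totals = total_phenolics(load_compound_table())
        labels = list(totals.index[:n_conditions])
        means = totals.to_numpy()[:n_conditions]
        if n_conditions > len(totals):
            raise ValueError(
                f"default condition means provide only {len(totals)} conditions"
            )
    else:
        means = np.asarray(condition_means, dtype=float)
        labels = condition_labels or [f"condition-{i + 1}" for i in range(n_conditions)]
    if len(means) != n_conditions:
        raise ValueError("len(condition_means) must equal n_conditions")
    if np.any(means < 0):
        raise ValueError("condition means must be >= 0")
    if len(labels) != n_conditions:
        raise ValueError("len(condition_labels) must equal n_conditions")

    rng = np.random.default_rng(seed)
    specs: list[SceneSpec] = []
    plant_ids: list[str] = []
    conditions: list[str] = []
    concs: list[float] = []
    for ci, (label, mean) in enumerate(zip(labels, means)):
        for pi in range(plants_per_condition):
            c = max(0.0, float(rng.normal(mean, plant_sd))) if plant_sd > 0 else float(mean)
            scene_seed = int(rng.integers(0, 2**31 - 1))
            specs.append(
                SceneSpec(
                    concentration=c,
                    seed=scene_seed,
                    condition_label=label,
                    **scene_kwargs,
                )
            )
            plant_ids.append(f"plant-{ci + 1:02d}-{pi + 1:02d}")
            conditions.append(label)
            concs.append(c)

    reference = pd.DataFrame(
        {"condition": labels, "total_phenolics_mg_per_g": means}
    )
    truth = pd.DataFrame(
        {"plant_id": plant_ids, "condition": conditions, "true_concentration": concs}
    )
    return Cohort(
        specs=specs,
        plant_ids=plant_ids,
        conditions=conditions,
        true_concentrations=np.asarray(concs),
        reference_table=reference,
        plant_truth=truth,
    )
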