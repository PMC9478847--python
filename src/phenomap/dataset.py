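"""From masked cubes to the modelling table.

Each segmented plant is divided into ``k`` spatially coherent random
regions (seeded k-means on pixel coordinates) and the mean spectrum of
each region becomes one modelling row, accommodating physical variation
within a plant. Rows carry the plant id, region id, growing-condition
label and the group-level reference total phenolic content (mg/g dry
weight), and are split 70:30 into calibration and validation sets.

Total phenolics are computed from a compound-by-condition concentration
table (HPLC-style, ``ND`` marking a compound not detected, treated as
zero in the sum). A reference table for eight light x drought growing
conditions ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InvalidTableError, PartitionError, SplitError
from .io import Hypercube
from .segmentation import PlantMask

__all__ = [
    "SpectraTable",
    "load_compound_table",
    "total_phenolics",
    "partition_regions",
    "extract_mean_spectra",
    "assign_reference",
    "split_calibration_validation",
]


@dataclass
class SpectraTable:
    """An ``(n, B)`` spectrum matrix with per-row metadata.

    Invariants: one shared wavelength grid, no duplicated
    ``(plant_id, region_id)`` pair, non-negative reference values.
    """

    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    plant_id: np.ndarray
    region_id: np.ndarray
    condition: np.ndarray
    y: np.ndarray | None = None
    split_tag: np.ndarray | None = None  # "cal" | "val" | "unassigned"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        n = self.spectra.shape[0]
        self.plant_id = np.asarray(self.plant_id)
        self.region_id = np.asarray(self.region_id)
        self.condition = np.asarray(self.condition)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != self.wavelengths_nm.size:
            raise ValueError("spectra must be (n, B) matching the wavelength grid")
        for name, arr in (("plant_id", self.plant_id), ("region_id", self.region_id),
                          ("condition", self.condition)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per row")
        if self.split_tag is None:
            self.split_tag = np.full(n, "unassigned", dtype=object)
        keys = list(zip(self.plant_id.tolist(), self.region_id.tolist()))
        if len(set(keys)) != n:
            raise ValueError("duplicated (plant_id, region_id) pair")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if np.any(self.y < 0):
                raise ValueError("reference totals must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.spectra.shape[0]

    def subset(self, rows: np.ndarray) -> "SpectraTable":
        rows = np.asarray(rows)
        return SpectraTable(
            spectra=self.spectra[rows],
            wavelengths_nm=self.wavelengths_nm,
            plant_id=self.plant_id[rows],
            region_id=self.region_id[rows],
            condition=self.condition[rows],
            y=None if self.y is None else self.y[rows],
            split_tag=None if self.split_tag is None else self.split_tag[rows],
        )

    def partition(self, tag: str) -> "SpectraTable":
        return self.subset(np.flatnonzero(self.split_tag == tag))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra, columns=[f"{w:.3f}" for w in self.wavelengths_nm])
        meta = pd.DataFrame(
            {
                "plant_id": self.plant_id,
                "region_id": self.region_id,
                "condition": self.condition,
                "split_tag": self.split_tag,
            }
        )
        if self.y is not None:
            meta["y"] = self.y
        return pd.concat([meta, df], axis=1)

    @staticmethod
    def concat(tables: list["SpectraTable"]) -> "SpectraTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        grid = tables[0].wavelengths_nm
        for t in tables[1:]:
            if not np.allclose(t.wavelengths_nm, grid):
                raise ValueError("tables are on different wavelength grids")
        return SpectraTable(
            spectra=np.vstack([t.spectra for t in tables]),
            wavelengths_nm=grid,
            plant_id=np.concatenate([t.plant_id for t in tables]),
            region_id=np.concatenate([t.region_id for t in tables]),
            condition=np.concatenate([t.condition for t in tables]),
            y=None if tables[0].y is None else np.concatenate([t.y for t in tables]),
            split_tag=np.concatenate([t.split_tag for t in tables]),
        )


# ---------------------------------------------------------------------------
# Compound reference table and totals


def load_compound_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a compound x condition concentration table (mg/g DW).

    ``ND`` entries (compound not detected) become NaN. Without *path*,
    loads the packaged eight-condition reference table.
    """
    if path is None:
        src = resources.files("phenomap").joinpath("data/phenolic_compounds.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    return df.apply(pd.to_numeric, errors="coerce") if df.dtypes.eq(object).any() else df


def total_phenolics(table: pd.DataFrame) -> pd.Series:
    """Per-condition totals: sum over compounds with ND (NaN) as zero."""
    values = table.apply(pd.to_numeric, errors="coerce")
    if (values.fillna(0) < 0).any().any():
        raise InvalidTableError("negative compound concentration")
    return values.fillna(0.0).sum(axis=0)


# ---------------------------------------------------------------------------
# Regions, extraction, reference assignment, split


def partition_regions(
    mask: PlantMask | np.ndarray,
    k: int = 10,
    seed: int = 0,
    method: str = "kmeans",
) -> np.ndarray:
    """Assign every mask pixel one region label in ``1..k``.

    ``method='kmeans'`` (default) clusters pixel coordinates, yielding
    spatially coherent patches; ``method='random'`` scatters pixels into
    k near-equal groups. Background pixels get label 0.
    """
    m = mask.mask if isinstance(mask, PlantMask) else np.asarray(mask, dtype=bool)
    coords = np.argwhere(m)
    n = coords.shape[0]
    if n == 0:
        raise PartitionError("mask is empty")
    if k < 1:
        raise PartitionError("k must be >= 1")
    if n < k:
        raise PartitionError(f"mask has {n} pixels, fewer than k={k} regions")
    labels = np.zeros(m.shape, dtype=int)
    if k == 1:
        labels[m] = 1
        return labels
    if method == "kmeans":
        km = KMeans(n_clusters=k, random_state=seed, n_init=4)
        assign = km.fit_predict(coords.astype(float))
    elif method == "random":
        rng = np.random.default_rng(seed)
        assign = rng.permutation(np.arange(n) % k)
    else:
        raise ValueError(f"unknown partition method {method!r}")
    labels[m] = assign + 1
    return labels


def extract_mean_spectra(
    cube: Hypercube,
    labelling: np.ndarray,
    plant_id: str,
    condition: str = "",
) -> SpectraTable:
    """One row per region: the arithmetic mean spectrum over its pixels."""
    if not cube.calibrated:
        raise ValueError("extract_mean_spectra requires a calibrated cube")
    ids = np.unique(labelling)
    ids = ids[ids > 0]
    rows, regions = [], []
    for rid in ids:
        sel = labelling == rid
        if not sel.any():  # pragma: no cover - unique() precludes this
            continue
        rows.append(cube.data[sel].mean(axis=0))
        regions.append(int(rid))
    if not rows:
        raise PartitionError("labelling contains no regions")
    n = len(rows)
    return SpectraTable(
        spectra=np.vstack(rows),
        wavelengths_nm=cube.wavelengths_nm,
        plant_id=np.array([plant_id] * n),
        region_id=np.array(regions),
        condition=np.array([condition] * n),
    )


def assign_reference(table: SpectraTable, totals: "pd.Series | dict") -> SpectraTable:
    """Set each row's y to its condition's group-level total (mg/g DW)."""
    totals = pd.Series(totals)
    missing = set(table.condition.tolist()) - set(totals.index)
    if missing:
        raise KeyError(f"conditions without a reference total: {sorted(missing)}")
    y = totals.reindex(table.condition).to_numpy(dtype=float)
    return replace(table, y=y)


def split_calibration_validation(
    table: SpectraTable,
    ratio: float = 0.7,
    seed: int = 0,
    level: str = "spectrum",
) -> SpectraTable:
    """Tag rows ``cal``/``val`` at the given ratio.

    ``level='spectrum'`` samples rows independently (calibration size is
    ``round(n * ratio)``); ``level='plant'`` keeps all regions of a plant
    on the same side, avoiding plant-identity leakage across partitions.
    """
    if not 0 < ratio < 1:
        raise SplitError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = table.n_rows
    tags = np.full(n, "val", dtype=object)
    if level == "spectrum":
        n_cal = int(round(n * ratio))
        order = rng.permutation(n)
        tags[order[:n_cal]] = "cal"
    elif level == "plant":
        plants = np.unique(table.plant_id)
        n_cal = int(round(len(plants) * ratio))
        chosen = set(rng.permutation(plants)[:n_cal].tolist())
        tags = np.where(np.isin(table.plant_id, list(chosen)), "cal", "val").astype(object)
    else:
        raise ValueError(f"unknown split level {level!r}")
    if (tags == "cal").sum() == 0 or (tags == "val").sum() == 0:
        raise SplitError("split left one partition empty")
    return replace(table, split_tag=tags)
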