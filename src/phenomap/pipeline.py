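"""End-to-end orchestration: simulate -> calibrate -> segment -> extract
-> preprocess -> fit -> select bands -> refit -> map.

A :class:`RunConfig` captures every knob of a run; :func:`run_pipeline`
executes the stages and returns a manifest holding a metrics table of
the same shape as the study's comparison tables — one row per
pretreatment, each with a full-waveband and a reduced-waveband metric
set — plus artifact hashes so identical config + seed can be verified to
reproduce identical results.

No stage reads validation rows while anything is being fitted or frozen:
the MSC reference, the latent-variable count, the band scores and the
regression itself all see calibration rows only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dataset as ds
from .bands import DCTBandSelector, reduce_dataset
from .errors import ConfigError, PipelineStageError
from .io import calibrate_reflectance, ReferenceFrames, trim_wavelengths
from .plsr import PLSRegressionNIPALS, evaluate, select_n_components
from .preprocess import PREPROCESS_METHODS, PreprocessSpec, make_preprocessor
from .segmentation import segment_plant
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "build_spectra_table", "serialize_model"]

TRIM_WINDOWS = {"SWIR": (920.0, 1970.0), "VISNIR": (400.0, 990.0)}


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic run."""

    range_tag: str = "SWIR"
    trim_lo: float | None = None  # default: the range's standard window
    trim_hi: float | None = None
    n_conditions: int = 8
    plants_per_condition: int = 15
    plant_sd: float = 0.05
    image_size: int = 64
    n_bands: int = 106
    wavelength_lo: float = 920.0
    wavelength_hi: float = 1970.0
    noise_sd: float = 0.01
    scatter_gain_sd: float = 0.02
    scatter_offset_sd: float = 0.005
    k_regions: int = 10
    partition_method: str = "kmeans"
    split_ratio: float = 0.7
    split_level: str = "spectrum"
    preprocess_methods: tuple[str, ...] = PREPROCESS_METHODS
    sg_window: int = 11
    n_lv: "int | str" = "cv"  # fixed count, or "cv" for one-SE-rule selection
    max_lv: int = 12
    cv_folds: int = 5
    hf_cut: float = 0.5
    min_prominence_frac: float = 0.05
    min_separation: int = 1
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> "RunConfig":
        if self.range_tag not in TRIM_WINDOWS:
            raise ConfigError(f"unknown range_tag {self.range_tag!r}")
        for m in self.preprocess_methods:
            if m not in PREPROCESS_METHODS:
                raise ConfigError(
                    f"unknown preprocessing {m!r}; choose from {PREPROCESS_METHODS}"
                )
        if not 0 < self.split_ratio < 1:
            raise ConfigError("split_ratio must be in (0, 1)")
        if self.split_level not in ("spectrum", "plant"):
            raise ConfigError("split_level must be 'spectrum' or 'plant'")
        if isinstance(self.n_lv, str) and self.n_lv != "cv":
            raise ConfigError("n_lv must be an integer or 'cv'")
        if isinstance(self.n_lv, int) and self.n_lv < 1:
            raise ConfigError("n_lv must be >= 1")
        return self

    @property
    def trim_window(self) -> tuple[float, float]:
        lo, hi = TRIM_WINDOWS[self.range_tag]
        return (self.trim_lo or lo, self.trim_hi or hi)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "preprocess_methods" in d:
            d = {**d, "preprocess_methods": tuple(d["preprocess_methods"])}
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _stage(name: str):
    """Decorator-free stage guard: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def build_spectra_table(config: RunConfig, seed: int | None = None):
    """Stages simulate..extract: cohort -> calibrated, trimmed, segmented,
    region-averaged spectra table with reference values and split tags.

    Returns ``(table, cohort)``.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cohort_seed = int(rng.integers(0, 2**31 - 1))
    region_seed = int(rng.integers(0, 2**31 - 1))
    split_seed = int(rng.integers(0, 2**31 - 1))

    with _stage("simulate"):
        cohort = generate_cohort(
            n_conditions=config.n_conditions,
            plants_per_condition=config.plants_per_condition,
            plant_sd=config.plant_sd,
            seed=cohort_seed,
            range_tag=config.range_tag,
            image_height=config.image_size,
            image_width=config.image_size,
            n_bands=config.n_bands,
            wavelength_lo=config.wavelength_lo,
            wavelength_hi=config.wavelength_hi,
            noise_sd=config.noise_sd,
            scatter_gain_sd=config.scatter_gain_sd,
            scatter_offset_sd=config.scatter_offset_sd,
        )

    tables = []
    lo, hi = config.trim_window
    for i in range(len(cohort)):
        raw, white, dark, truth = cohort.scene(i)
        with _stage("calibrate"):
            cube = calibrate_reflectance(raw, ReferenceFrames(white, dark))
            cube = trim_wavelengths(cube, lo, hi)
        with _stage("segment"):
            mask = segment_plant(cube)
        with _stage("extract"):
            labels = ds.partition_regions(
                mask, k=config.k_regions, seed=region_seed + i, method=config.partition_method
            )
            tables.append(
                ds.extract_mean_spectra(
                    cube, labels, plant_id=cohort.plant_ids[i], condition=cohort.conditions[i]
                )
            )
    table = ds.SpectraTable.concat(tables)
    with _stage("reference"):
        totals = cohort.reference_table.set_index("condition")["total_phenolics_mg_per_g"]
        table = ds.assign_reference(table, totals)
    with _stage("split"):
        table = ds.split_calibration_validation(
            table, ratio=config.split_ratio, seed=split_seed, level=config.split_level
        )
    return table, cohort


def _fit_and_score(X_cal, y_cal, X_val, y_val, config: RunConfig, lv_seed: int) -> dict:
    if config.n_lv == "cv":
        n_lv = select_n_components(
            X_cal, y_cal, k_folds=config.cv_folds, max_lv=min(config.max_lv, X_cal.shape[1]),
            seed=lv_seed,
        )
    else:
        n_lv = min(int(config.n_lv), X_cal.shape[1])
    model = PLSRegressionNIPALS(n_components=n_lv).fit(X_cal, y_cal)
    mc = evaluate(y_cal, model.predict(X_cal), n_lv, "cal")
    mv = evaluate(y_val, model.predict(X_val), n_lv, "val")
    return {"model": model, "n_lv": n_lv, "metrics": mc.merge(mv).to_dict()}


def serialize_model(model: PLSRegressionNIPALS, spec: PreprocessSpec,
                    wavelengths_nm, n_lv: int, metrics: dict,
                    msc_reference=None) -> dict:
    """JSON-ready model record: grid, beta, intercept, pretreatment, metrics."""
    return {
        "wavelengths_nm": np.asarray(wavelengths_nm, dtype=float).tolist(),
        "beta": model.coef_.tolist(),
        "intercept": model.intercept_,
        "x_mean": model.x_mean_.tolist(),
        "preprocess": asdict(spec),
        "msc_reference": None if msc_reference is None else np.asarray(msc_reference).tolist(),
        "n_lv": n_lv,
        "metrics": metrics,
    }


def _sha256(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the run manifest.

    The manifest echoes the config, then for every pretreatment carries a
    ``full`` and a ``reduced`` metric set (R2c, SEC, R2v, SEP, RMSE,
    bias), the latent-variable counts, the band selection, and hashes of
    every serialized artifact.
    """
    config.validate()
    table, cohort = build_spectra_table(config)
    rng = np.random.default_rng(config.seed + 1)
    lv_seed = int(rng.integers(0, 2**31 - 1))

    cal, val = table.partition("cal"), table.partition("val")
    cal_order_hash = _sha256(list(zip(cal.plant_id.tolist(), cal.region_id.tolist())))

    methods = {}
    artifacts = {}
    for method in config.preprocess_methods:
        with _stage(f"fit[{method}]"):
            spec = PreprocessSpec(method=method, sg_window=config.sg_window)
            pre = make_preprocessor(spec)
            pre.fit(cal.spectra)  # MSC reference frozen on calibration rows only
            Xc, Xv = pre.transform(cal.spectra), pre.transform(val.spectra)
            full = _fit_and_score(Xc, cal.y, Xv, val.y, config, lv_seed)

        with _stage(f"select-bands[{method}]"):
            selector = DCTBandSelector(
                hf_cut=config.hf_cut,
                min_prominence_frac=config.min_prominence_frac,
                min_separation=config.min_separation,
            ).fit(Xc, wavelengths_nm=table.wavelengths_nm)
            sel = selector.selection_
            if sel.selected_indices.size:
                Xc_r, Xv_r = selector.transform(Xc), selector.transform(Xv)
                reduced = _fit_and_score(Xc_r, cal.y, Xv_r, val.y, config, lv_seed)
            else:  # flat score curve; fall back to the full set
                reduced = full
        msc_ref = getattr(pre, "reference_", None)
        methods[method] = {
            "full": {"n_lv": full["n_lv"], **full["metrics"]},
            "reduced": {
                "n_lv": reduced["n_lv"],
                "n_bands": int(sel.selected_indices.size) or table.wavelengths_nm.size,
                "selected_wavelengths_nm": table.wavelengths_nm[
                    sel.selected_indices
                ].tolist(),
                **reduced["metrics"],
            },
        }
        artifacts[f"model_full_{method}"] = serialize_model(
            full["model"], spec, table.wavelengths_nm, full["n_lv"], full["metrics"],
            msc_reference=msc_ref,
        )
        artifacts[f"selection_{method}"] = {
            **sel.to_dict(),
            "row_order_sha256": cal_order_hash,
        }

    manifest = {
        "config": {**asdict(config), "preprocess_methods": list(config.preprocess_methods)},
        "trim_window_nm": list(config.trim_window),
        "n_rows": table.n_rows,
        "n_cal": cal.n_rows,
        "n_val": val.n_rows,
        "n_plants": len(cohort),
        "methods": methods,
        "artifact_hashes": {k: _sha256(v) for k, v in sorted(artifacts.items())},
    }
    manifest["manifest_sha256"] = _sha256(manifest)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for name, art in artifacts.items():
            (out / f"{name}.json").write_text(json.dumps(art, indent=2))
        cohort.reference_table.to_csv(out / "reference_table.csv", index=False)
    return manifest
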