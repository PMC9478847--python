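import numpy as np
import pytest

import phenomap as pm
from phenomap.pipeline import RunConfig, build_spectra_table


@pytest.fixture(scope="session")
def default_run():
    """One full-size synthetic run (8 conditions x 15 plants, SWIR 64x64x106):
    the spectra table with reference values and split tags, plus the cohort."""
    table, cohort = build_spectra_table(RunConfig(seed=11))
    return table, cohort


@pytest.fixture(scope="session")
def sg2_model(default_run):
    """An sg2-pretreated PLSR calibration fitted on the default run."""
    table, _ = default_run
    cal, val = table.partition("cal"), table.partition("val")
    pre = pm.make_preprocessor("sg2").fit(cal.spectra)
    model = pm.PLSRegressionNIPALS(n_components=4).fit(pre.transform(cal.spectra), cal.y)
    mv = pm.evaluate(val.y, model.predict(pre.transform(val.spectra)), 4, "val")
    return pre, model, mv


@pytest.fixture()
def scene():
    """A small default SWIR scene: (raw cube, white, dark, truth)."""
    return pm.generate_scene(pm.SceneSpec(seed=7))


@pytest.fixture()
def calibrated_cube(scene):
    raw, white, dark, truth = scene
    cube = pm.calibrate_reflectance(raw, pm.ReferenceFrames(white, dark))
    return cube, truth


def make_noiseless_scene(**overrides) -> pm.SceneSpec:
    kw = dict(noise_sd=0.0, scatter_gain_sd=0.0, scatter_offset_sd=0.0, seed=5)
    kw.update(overrides)
    return pm.SceneSpec(**kw)
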