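"""Waveband reduction by DCT energy scoring.

For every waveband the across-sample value vector (calibration rows in a
fixed dataset order) is transformed with an orthonormal DCT-II. The DC
coefficient — carrying the band's mean level, enough on its own to
reconstruct the flat part of the signal — is discarded, as is the
highest-frequency tail of the AC coefficients (edge-like detail). The
band's score is the largest absolute retained AC coefficient, i.e. the
strongest coherent across-sample variation at that band. Peaks of the
score-versus-band curve are then picked as the reduced waveband set.

The across-sample transform axis, the AC retention cut and the peak
criterion are configuration (recorded with every selection), not
universal constants; an alternative per-spectrum transform axis is
available behind ``axis='spectrum'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dct as _scipy_dct
from scipy.signal import find_peaks

from .dataset import SpectraTable
from .errors import InsufficientRowsError, SelectionError

__all__ = [
    "BandSelection",
    "DCTBandSelector",
    "dct2",
    "band_scores",
    "select_bands",
    "reduce_dataset",
]


def dct2(vector: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II of a 1-D vector; coefficient 0 is ``mean * sqrt(n)``."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("dct2 expects a non-empty 1-D vector")
    return _scipy_dct(v, type=2, norm="ortho")


@dataclass
class BandSelection:
    """Per-band DCT energy scores and the peak-picked band subset."""

    scores: np.ndarray
    selected_indices: np.ndarray
    wavelengths_nm: np.ndarray | None = None
    dc_excluded: bool = True
    hf_cut: float = 0.5
    peak_params: dict = field(default_factory=dict)

    def selected_wavelengths(self) -> np.ndarray:
        if self.wavelengths_nm is None:
            raise ValueError("selection carries no wavelength grid")
        return self.wavelengths_nm[self.selected_indices]

    def to_dict(self) -> dict:
        return {
            "scores": self.scores.tolist(),
            "selected_indices": self.selected_indices.tolist(),
            "wavelengths_nm": None
            if self.wavelengths_nm is None
            else self.wavelengths_nm.tolist(),
            "dc_excluded": self.dc_excluded,
            "hf_cut": self.hf_cut,
            "peak_params": self.peak_params,
        }


def band_scores(X_cal: np.ndarray, hf_cut: float = 0.5, axis: str = "sample") -> np.ndarray:
    """Score each band by its highest-energy retained AC coefficient.

    ``axis='sample'`` (default): for band j, transform the across-sample
    vector X[:, j]; rows must be in a fixed dataset order, which the
    caller is responsible for serializing alongside the scores.
    ``axis='spectrum'``: transform each row across bands and score band j
    by the mean |coefficient j| over rows (comparison variant).
    """
    X = np.asarray(X_cal, dtype=float)
    if X.ndim != 2:
        raise ValueError("X_cal must be 2-D (rows, bands)")
    if not 0.0 <= hf_cut < 1.0:
        raise ValueError("hf_cut must be in [0, 1)")
    n, p = X.shape
    if axis == "spectrum":
        C = np.abs(_scipy_dct(X, type=2, norm="ortho", axis=1))
        return C.mean(axis=0)
    if axis != "sample":
        raise ValueError(f"unknown axis {axis!r}")
    if n < 4:
        raise InsufficientRowsError("need >= 4 calibration rows for band scoring")
    n_ac = n - 1
    n_keep = n_ac - int(np.floor(n_ac * hf_cut))
    if n_keep < 1:
        raise InsufficientRowsError(
            f"hf_cut={hf_cut} leaves no retained AC coefficient for n={n}"
        )
    C = _scipy_dct(X, type=2, norm="ortho", axis=0)
    retained = np.abs(C[1 : 1 + n_keep, :])  # drop DC, drop high-frequency tail
    return retained.max(axis=0)


def select_bands(
    scores: np.ndarray,
    min_prominence_frac: float = 0.05,
    min_separation: int = 1,
    include_endpoints: bool = True,
) -> np.ndarray:
    """Indices of score-curve local maxima (peak-picked wavebands).

    Prominence threshold is ``min_prominence_frac`` of the score range;
    plateau maxima take the left-most index; endpoints are eligible via
    edge padding when ``include_endpoints``.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    rng = float(s.max() - s.min())
    if rng <= 0:
        return np.array([], dtype=int)
    prom = min_prominence_frac * rng
    if include_endpoints:
        padded = np.concatenate(([s.min() - rng], s, [s.min() - rng]))
        _, props = find_peaks(
            padded,
            prominence=prom,
            distance=max(1, min_separation),
            plateau_size=(1, None),
        )
        idx = props["left_edges"] - 1
    else:
        _, props = find_peaks(
            s, prominence=prom, distance=max(1, min_separation), plateau_size=(1, None)
        )
        idx = props["left_edges"]
    return np.unique(idx)


def reduce_dataset(table: SpectraTable, selection: BandSelection | np.ndarray) -> SpectraTable:
    """Retain exactly the selected bands of a spectra table, in order."""
    idx = (
        selection.selected_indices
        if isinstance(selection, BandSelection)
        else np.asarray(selection, dtype=int)
    )
    if idx.size == 0:
        raise SelectionError("band selection is empty")
    if idx.min() < 0 or idx.max() >= table.spectra.shape[1]:
        raise SelectionError("selected index outside the table's band range")
    idx = np.unique(idx)
    return replace(
        table, spectra=table.spectra[:, idx], wavelengths_nm=table.wavelengths_nm[idx]
    )


class DCTBandSelector:
    """Scikit-learn-style transformer: fit scores on calibration rows,
    transform reduces any matrix to the selected bands.

    Parameters mirror :func:`band_scores` and :func:`select_bands`;
    fitted attributes: ``scores_``, ``selected_indices_``, ``selection_``.
    """

    def __init__(
        self,
        hf_cut: float = 0.5,
        min_prominence_frac: float = 0.05,
        min_separation: int = 1,
        axis: str = "sample",
    ):
        self.hf_cut = hf_cut
        self.min_prominence_frac = min_prominence_frac
        self.min_separation = min_separation
        self.axis = axis

    def get_params(self, deep: bool = True) -> dict:
        return {
            "hf_cut": self.hf_cut,
            "min_prominence_frac": self.min_prominence_frac,
            "min_separation": self.min_separation,
            "axis": self.axis,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, wavelengths_nm: np.ndarray | None = None):
        self.scores_ = band_scores(X, hf_cut=self.hf_cut, axis=self.axis)
        self.selected_indices_ = select_bands(
            self.scores_,
            min_prominence_frac=self.min_prominence_frac,
            min_separation=self.min_separation,
        )
        self.selection_ = BandSelection(
            scores=self.scores_,
            selected_indices=self.selected_indices_,
            wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm),
            hf_cut=self.hf_cut,
            peak_params={
                "min_prominence_frac": self.min_prominence_frac,
                "min_separation": self.min_separation,
                "axis": self.axis,
            },
        )
        return self

    def transform(self, X):
        if self.selected_indices_.size == 0:
            raise SelectionError("band selection is empty")
        return np.asarray(X, dtype=float)[:, self.selected_indices_]
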