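"""Row-wise spectral pretreatments as scikit-learn transformers.

The eight pretreatments compared in the calibration study are exposed
under one factory, :func:`make_preprocessor`:

``raw``
    identity.
``mean_norm`` / ``max_norm`` / ``range_norm``
    per-spectrum division by its mean / maximum, or min-max scaling to
    [0, 1]; compensates path-length and intensity inconsistencies.
``snv``
    standard normal variate: per-spectrum centering and scaling to unit
    sample standard deviation (n-1 divisor); removes multiplicative and
    additive scatter without a reference.
``msc``
    multiplicative scatter correction: each spectrum is regressed on a
    reference spectrum, ``x ~ a + b*ref``, and corrected to
    ``(x - a)/b``. The reference is frozen as the mean of the rows seen
    at fit time (the calibration set) — validation rows are always
    corrected against that frozen reference, never their own batch mean.
``sg1`` / ``sg2``
    Savitzky-Golay first/second derivative (local least-squares
    polynomial differentiator), in units of reflectance per band index;
    corrects baseline offset/slope and resolves overlapping peaks.

All transforms are row-local except MSC's fitted reference. Every
transformer is stateless at transform time, so the calibration-frozen
pipeline applied to identical rows in either partition yields identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateSpectrumError

__all__ = [
    "PreprocessSpec",
    "IdentityScaler",
    "RowNormalizer",
    "SNVScaler",
    "MSCorrector",
    "SavitzkyGolayDerivative",
    "make_preprocessor",
    "normalize",
    "snv",
    "msc",
    "sg_derivative",
    "PREPROCESS_METHODS",
]

PREPROCESS_METHODS = (
    "raw",
    "mean_norm",
    "max_norm",
    "range_norm",
    "msc",
    "snv",
    "sg1",
    "sg2",
)


@dataclass(frozen=True)
class PreprocessSpec:
    """Serializable description of a pretreatment choice."""

    method: str = "raw"
    sg_window: int = 11
    sg_polyorder: int | None = None  # default: 2 for sg1, 3 for sg2
    msc_reference: str = "calibration-mean"  # or "supplied"

    def __post_init__(self) -> None:
        if self.method not in PREPROCESS_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {PREPROCESS_METHODS}"
            )
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ValueError("sg_window must be odd and >= 3")
        poly = self.resolved_polyorder
        if poly >= self.sg_window:
            raise ValueError("sg_window must exceed sg_polyorder")

    @property
    def resolved_polyorder(self) -> int:
        if self.sg_polyorder is not None:
            return self.sg_polyorder
        return 3 if self.method == "sg2" else 2


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a spectrum or an (n, B) matrix")
    return X


class IdentityScaler(TransformerMixin, BaseEstimator):
    """The ``raw`` pretreatment: pass-through."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        return _as_matrix(X).copy()


class RowNormalizer(TransformerMixin, BaseEstimator):
    """Per-spectrum normalization by mean, max, or range.

    mean: ``x / mean(x)``; max: ``x / max(x)``;
    range: ``(x - min(x)) / (max(x) - min(x))`` (into [0, 1]).
    """

    def __init__(self, method: str = "range"):
        self.method = method

    def fit(self, X, y=None):
        if self.method not in ("mean", "max", "range"):
            raise ValueError(f"unknown normalization {self.method!r}")
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if self.method == "mean":
            denom = X.mean(axis=1, keepdims=True)
            if np.any(np.abs(denom) < 1e-12):
                raise DegenerateSpectrumError("zero-mean spectrum in mean normalization")
            return X / denom
        if self.method == "max":
            denom = X.max(axis=1, keepdims=True)
            if np.any(np.abs(denom) < 1e-12):
                raise DegenerateSpectrumError("zero-max spectrum in max normalization")
            return X / denom
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        if np.any(hi - lo < 1e-12):
            raise DegenerateSpectrumError("constant spectrum in range normalization")
        return (X - lo) / (hi - lo)


class SNVScaler(TransformerMixin, BaseEstimator):
    """Standard normal variate: ``(x - mean(x)) / sd(x)`` per spectrum."""

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd < 1e-12):
            raise DegenerateSpectrumError("constant spectrum in SNV")
        return (X - mu) / sd


class MSCorrector(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a frozen reference.

    Parameters
    ----------
    reference : ndarray or None
        A supplied reference spectrum; if None (default) the mean of the
        rows passed to :meth:`fit` is frozen as the reference.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.n_features_in_ = X.shape[1]
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise ValueError("reference length does not match band count")
            self.reference_ = ref.copy()
        else:
            self.reference_ = X.mean(axis=0)
        if np.std(self.reference_) < 1e-12:
            raise DegenerateSpectrumError("MSC reference spectrum is constant")
        return self

    def transform(self, X):
        X = _as_matrix(X)
        ref = self.reference_
        refc = ref - ref.mean()
        denom = float(refc @ refc)
        # least-squares fit x ~ a + b*ref, row-wise
        b = (X - X.mean(axis=1, keepdims=True)) @ refc / denom
        if np.any(np.abs(b) < 1e-9):
            raise DegenerateSpectrumError("degenerate MSC fit (slope ~ 0)")
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay derivative along the spectral axis.

    Derivatives are per band index (``delta=1``); for uniform grids this
    differs from a per-nm derivative only by a constant factor, to which
    a subsequent bilinear calibration is equivariant. Edges are handled
    by polynomial-fit extension (``mode='interp'``).
    """

    def __init__(self, order: int = 1, window: int = 11, polyorder: int | None = None):
        self.order = order
        self.window = window
        self.polyorder = polyorder

    def _resolved_polyorder(self) -> int:
        if self.polyorder is not None:
            return self.polyorder
        return 3 if self.order == 2 else 2

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        poly = self._resolved_polyorder()
        if poly >= self.window:
            raise ValueError("window must exceed polyorder")
        if poly < self.order:
            raise ValueError("polyorder must be >= derivative order")
        if X.shape[1] < self.window:
            raise ValueError(
                f"band count {X.shape[1]} smaller than window {self.window}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if X.shape[1] < self.window:
            raise ValueError(
                f"band count {X.shape[1]} smaller than window {self.window}"
            )
        return savgol_filter(
            X,
            window_length=self.window,
            polyorder=self._resolved_polyorder(),
            deriv=self.order,
            delta=1.0,
            axis=1,
            mode="interp",
        )


def make_preprocessor(spec: PreprocessSpec | str, msc_reference: np.ndarray | None = None):
    """Instantiate the transformer for a pretreatment spec or method name."""
    if isinstance(spec, str):
        spec = PreprocessSpec(method=spec)
    m = spec.method
    if m == "raw":
        return IdentityScaler()
    if m in ("mean_norm", "max_norm", "range_norm"):
        return RowNormalizer(method=m.removesuffix("_norm"))
    if m == "snv":
        return SNVScaler()
    if m == "msc":
        return MSCorrector(reference=msc_reference)
    order = 1 if m == "sg1" else 2
    return SavitzkyGolayDerivative(
        order=order, window=spec.sg_window, polyorder=spec.sg_polyorder
    )


# ---------------------------------------------------------------------------
# thin functional wrappers


def normalize(spectrum, method: str = "range") -> np.ndarray:
    """Normalize one spectrum (or matrix) by mean, max, or range."""
    out = RowNormalizer(method=method).fit(spectrum).transform(spectrum)
    return out[0] if np.asarray(spectrum).ndim == 1 else out


def snv(spectrum) -> np.ndarray:
    """Standard normal variate of one spectrum (or matrix)."""
    out = SNVScaler().fit(spectrum).transform(spectrum)
    return out[0] if np.asarray(spectrum).ndim == 1 else out


def msc(spectrum, reference: np.ndarray) -> np.ndarray:
    """MSC-correct one spectrum (or matrix) against *reference*."""
    corr = MSCorrector(reference=reference)
    ref2d = np.asarray(reference, dtype=float)[None, :]
    out = corr.fit(ref2d).transform(spectrum)
    return out[0] if np.asarray(spectrum).ndim == 1 else out


def sg_derivative(
    spectrum, order: int = 1, window: int = 11, polyorder: int | None = None
) -> np.ndarray:
    """Savitzky-Golay derivative of one spectrum (or matrix)."""
    tr = SavitzkyGolayDerivative(order=order, window=window, polyorder=polyorder)
    out = tr.fit(spectrum).transform(spectrum)
    return out[0] if np.asarray(spectrum).ndim == 1 else out
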