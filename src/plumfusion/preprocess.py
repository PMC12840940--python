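"""Reflectance calibration and scatter-correction preprocessing.

Transformers follow the scikit-learn fit/transform protocol and operate on
plain (n_samples, n_wavelengths) matrices, so they compose with
:class:`sklearn.pipeline.Pipeline`.  Thin functional wrappers accept
:class:`~plumfusion.spectra.SpectrumSet` objects and preserve grid, IDs and
sample order.

Five treatments are supported: SG (Savitzky-Golay smoothing), SNV (standard
normal variate), MSC (multiplicative scatter correction), and the chains
SG+SNV and SG+MSC, applied left to right.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

from .spectra import SpectrumSet, SpectralFormatError

__all__ = [
    "calibrate_reflectance",
    "SavitzkyGolaySmoother",
    "StandardNormalVariate",
    "MultiplicativeScatterCorrection",
    "make_chain",
    "savitzky_golay",
    "snv",
    "msc",
    "apply_chain",
]


class CalibrationError(ValueError):
    pass


class DegenerateSpectrumError(ValueError):
    pass


def calibrate_reflectance(
    sample: SpectrumSet, dark: np.ndarray, white: np.ndarray
) -> SpectrumSet:
    """Convert raw counts to relative reflectance R = (S - D) / (W - D).

    ``dark`` (fibre covered, light off) and ``white`` (standard white board)
    must share the sample grid, with ``white > dark`` at every wavelength.
    """
    dark = np.asarray(dark, float)
    white = np.asarray(white, float)
    if dark.shape != (sample.n_wavelengths,) or white.shape != (sample.n_wavelengths,):
        raise SpectralFormatError("dark/white references must share the sample wavelength grid")
    bad = np.nonzero(white <= dark)[0]
    if bad.size:
        raise CalibrationError(
            f"white reference does not exceed dark current at "
            f"{sample.wavelengths[bad[0]]:g} nm"
        )
    refl = (sample.intensities - dark) / (white - dark)
    return sample.with_intensities(refl)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a (n_samples, n_wavelengths) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("spectra contain non-finite values")
    return X


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """Moving least-squares polynomial smoothing along the wavelength axis.

    Stateless.  Edges are handled by evaluating the boundary window's fitted
    polynomial at the edge positions (``mode="interp"``), so the output grid
    equals the input grid.  Defaults (window 11 points, order 2) are a
    conventional Vis/NIR smoothing choice.
    """

    def __init__(self, window: int = 11, order: int = 2):
        self.window = window
        self.order = order

    def _validate(self, n_cols: int) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if not 0 <= self.order < self.window:
            raise ValueError("order must satisfy 0 <= order < window")
        if self.window > n_cols:
            raise ValueError("window exceeds number of wavelengths")

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self._validate(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        self._validate(X.shape[1])
        return savgol_filter(X, self.window, self.order, axis=1, mode="interp")


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Per-spectrum centering and scaling: (x - mean(x)) / sd(x), ddof=1.

    Removes per-sample multiplicative and additive scatter; every output row
    has mean 0 and unit sample standard deviation.  Stateless and
    idempotent.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if X.shape[1] < 2:
            raise ValueError("SNV requires at least 2 wavelengths")
        sd = X.std(axis=1, ddof=1)
        degenerate = np.nonzero(sd == 0)[0]
        if degenerate.size:
            raise DegenerateSpectrumError(
                f"zero-variance spectrum at row {degenerate[0]}"
            )
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """Per-spectrum affine regression against a reference, then inversion.

    Each row is modelled as ``x = a + b * ref``; the corrected row is
    ``(x - a) / b``.  With ``reference="mean"`` the reference is the mean
    spectrum of the *fitted* set, frozen at fit time and replayed on new
    data — test spectra never influence the correction.
    """

    def __init__(self, reference="mean", slope_tol: float = 1e-12):
        self.reference = reference
        self.slope_tol = slope_tol

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if isinstance(self.reference, str):
            if self.reference != "mean":
                raise ValueError("reference must be 'mean' or an explicit spectrum")
            self.reference_ = X.mean(axis=0)
        else:
            self.reference_ = np.asarray(self.reference, dtype=float)
            if self.reference_.shape != (X.shape[1],):
                raise ValueError("explicit reference must match the wavelength grid")
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise RuntimeError("MSC must be fitted before transform")
        X = _as_matrix(X)
        ref = self.reference_
        refc = ref - ref.mean()
        denom = refc @ refc
        if denom == 0:
            raise DegenerateSpectrumError("MSC reference spectrum is constant")
        b = (X - X.mean(axis=1, keepdims=True)) @ refc / denom
        small = np.nonzero(np.abs(b) < self.slope_tol)[0]
        if small.size:
            raise DegenerateSpectrumError(
                f"MSC slope below tolerance for row {small[0]}"
            )
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


_STEP_FACTORIES = {
    "SG": SavitzkyGolaySmoother,
    "SNV": StandardNormalVariate,
    "MSC": MultiplicativeScatterCorrection,
}


def make_chain(spec: str, sg_window: int = 11, sg_order: int = 2) -> Pipeline:
    """Build a preprocessing pipeline from a chain string like ``"SG+SNV"``.

    Steps are parsed case-insensitively and applied left to right; stateful
    steps (the MSC mean reference) are fitted on training data only when the
    pipeline is used inside a model workflow.
    """
    names = [tok.strip().upper() for tok in spec.split("+") if tok.strip()]
    if not names:
        raise ValueError("preprocessing chain must contain at least one step")
    steps = []
    for i, name in enumerate(names):
        if name not in _STEP_FACTORIES:
            raise ValueError(f"unknown preprocessing step {name!r} (step {i})")
        est = (
            SavitzkyGolaySmoother(sg_window, sg_order)
            if name == "SG"
            else _STEP_FACTORIES[name]()
        )
        steps.append((f"{i}_{name.lower()}", est))
    return Pipeline(steps)


# ------------------------------------------------------------- SpectrumSet wrappers


def savitzky_golay(spectra: SpectrumSet, window: int = 11, order: int = 2) -> SpectrumSet:
    out = SavitzkyGolaySmoother(window, order).fit_transform(spectra.intensities)
    return spectra.with_intensities(out)


def snv(spectra: SpectrumSet) -> SpectrumSet:
    return spectra.with_intensities(StandardNormalVariate().fit_transform(spectra.intensities))


def msc(spectra: SpectrumSet, reference="mean") -> SpectrumSet:
    est = MultiplicativeScatterCorrection(reference)
    return spectra.with_intensities(est.fit_transform(spectra.intensities))


def apply_chain(spectra: SpectrumSet, chain: str | Pipeline, **kwargs) -> SpectrumSet:
    pipe = make_chain(chain, **kwargs) if isinstance(chain, str) else chain
    return spectra.with_intensities(pipe.fit_transform(spectra.intensities))
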