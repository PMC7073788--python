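"""Preprocessing chain for raw LIBS spectra.

Order of operations, applied to every sample spectrum:

1. trim the wavelength axis to a closed band (default 380.01-860.04 nm,
   which on the default simulated axis retains 13,435 channels);
2. clip negative intensities to zero (detector noise artefacts);
3. wavelet denoising: db6 multilevel decomposition (level 3), soft
   thresholding of the detail coefficients with the universal threshold
   sigma * sqrt(2 ln N), sigma estimated per spectrum from the
   median absolute deviation of the finest-level details;
4. min-max normalisation x* = (x - min) / (max - min) to [0, 1], by
   default per spectrum.
"""

from __future__ import annotations

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectralDataset

__all__ = [
    "PreprocessConfig",
    "SpectralPreprocessor",
    "trim_range",
    "clip_negatives",
    "wavelet_denoise",
    "minmax_normalize",
    "preprocess_pipeline",
]


class PreprocessConfig:
    """Bag of preprocessing parameters (all have sensible defaults)."""

    def __init__(self, trim_lo: float = 380.01, trim_hi: float = 860.04,
                 wavelet_name: str = "db6", decomposition_level: int = 3,
                 normalization_scope: str = "per-spectrum"):
        if trim_lo >= trim_hi:
            raise ValueError("trim_lo must be < trim_hi")
        if decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if normalization_scope not in ("per-spectrum", "per-dataset"):
            raise ValueError("scope must be 'per-spectrum' or 'per-dataset'")
        if wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {wavelet_name!r}")
        self.trim_lo = trim_lo
        self.trim_hi = trim_hi
        self.wavelet_name = wavelet_name
        self.decomposition_level = decomposition_level
        self.normalization_scope = normalization_scope

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def trim_range(dataset: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep wavelengths with lo <= lambda <= hi (closed interval)."""
    mask = (dataset.wavelengths >= lo) & (dataset.wavelengths <= hi)
    if not mask.any():
        raise ValueError("trim produced empty axis")
    return dataset.replace(wavelengths=dataset.wavelengths[mask],
                           intensities=dataset.intensities[:, mask])


def clip_negatives(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def min_denoise_length(wavelet_name: str = "db6", level: int = 3) -> int:
    """Shortest spectrum for which `level` decompositions are meaningful
    (pywt's max_level rule: the data must outlast the filter at each level).
    """
    filt = pywt.Wavelet(wavelet_name).dec_len
    return (filt - 1) * 2**level + 1


def wavelet_denoise(x: np.ndarray, wavelet_name: str = "db6",
                    level: int = 3) -> np.ndarray:
    """Soft-threshold wavelet shrinkage along the last axis.

    Universal threshold sigma*sqrt(2 ln N) with sigma from the MAD of the
    finest detail coefficients (per spectrum), symmetric signal extension.
    Accepts a single spectrum or a (n_samples, n_variables) matrix.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    min_len = min_denoise_length(wavelet_name, level)
    if n < min_len:
        raise ValueError(
            f"spectrum of length {n} too short for level-{level} "
            f"{wavelet_name} denoising (minimum {min_len})")
    coeffs = pywt.wavedec(x, wavelet_name, level=level, mode="symmetric",
                          axis=-1)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest), axis=-1, keepdims=True) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    shrunk = [coeffs[0]]
    for d in coeffs[1:]:
        shrunk.append(np.sign(d) * np.maximum(np.abs(d) - thresh, 0.0))
    out = pywt.waverec(shrunk, wavelet_name, mode="symmetric", axis=-1)
    return out[..., :n]  # waverec may pad by one sample


def minmax_normalize(x: np.ndarray, scope: str = "per-spectrum") -> np.ndarray:
    """Affine rescale to [0, 1]: x* = (x - min) / (max - min).

    With per-spectrum scope each row uses its own extrema (and attains both
    bounds); per-dataset scope uses the global extrema of the matrix.
    """
    x = np.asarray(x, dtype=float)
    if scope == "per-spectrum" and x.ndim == 2:
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
    else:
        lo, hi = x.min(), x.max()
    if np.any(hi <= lo):
        raise ValueError("degenerate spectrum: max equals min")
    return (x - lo) / (hi - lo)


class SpectralPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer running the full trim/clip/denoise/normalise
    chain on a `SpectralDataset` (or a bare matrix, axis given at fit).

    sklearn-compatible so it can sit at the head of a Pipeline; `fit` only
    records the axis, every stage is deterministic.
    """

    def __init__(self, trim_lo: float = 380.01, trim_hi: float = 860.04,
                 wavelet_name: str = "db6", decomposition_level: int = 3,
                 normalization_scope: str = "per-spectrum"):
        self.trim_lo = trim_lo
        self.trim_hi = trim_hi
        self.wavelet_name = wavelet_name
        self.decomposition_level = decomposition_level
        self.normalization_scope = normalization_scope

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(self.trim_lo, self.trim_hi, self.wavelet_name,
                                self.decomposition_level,
                                self.normalization_scope)

    def fit(self, X, y=None):
        self._config()  # validates parameters
        axis = X.wavelengths if isinstance(X, SpectralDataset) else None
        self.input_axis_ = axis
        return self

    def transform(self, X) -> SpectralDataset | np.ndarray:
        cfg = self._config()
        if isinstance(X, SpectralDataset):
            return preprocess_pipeline(X, cfg)
        axis = getattr(self, "input_axis_", None)
        if axis is None:
            raise ValueError("matrix input needs a prior fit on a "
                             "SpectralDataset to know the axis")
        ds = SpectralDataset(wavelengths=axis, intensities=np.asarray(X),
                             labels=np.zeros(len(X), dtype=int))
        return preprocess_pipeline(ds, cfg).intensities


def preprocess_pipeline(dataset: SpectralDataset,
                        config: PreprocessConfig | None = None
                        ) -> SpectralDataset:
    """Apply trim -> clip -> denoise -> min-max normalise, in that order."""
    config = config or PreprocessConfig()
    out = trim_range(dataset, config.trim_lo, config.trim_hi)
    x = clip_negatives(out.intensities)
    x = wavelet_denoise(x, config.wavelet_name, config.decomposition_level)
    x = minmax_normalize(x, config.normalization_scope)
    meta = dict(out.meta)
    meta["preprocess"] = config.to_dict()
    return out.replace(intensities=x, meta=meta)
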