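"""Pixel-wise spectral preprocessing: wavelet smoothing and SNV.

Two chains are used downstream, [WT] and [WT, SNV].  Wavelet smoothing
("WT") is a multilevel discrete wavelet decomposition (Daubechies 8,
level 3, symmetric extension) whose detail coefficients are zeroed
before reconstruction — an approximation-only, seed-free smoother.
The standard normal variate ("SNV") transform centers each spectrum
and scales it to unit sample standard deviation, removing additive and
multiplicative scatter effects.

Crucial ordering contract: preprocessing is applied to each *pixel*
spectrum first, and region averaging happens afterwards — never the
other way around when a chain is set.

The two steps are also exposed as scikit-learn transformers
(:class:`WaveletSmoother`, :class:`SNVTransformer`) operating row-wise
on (n_spectra, n_bands) matrices, so they compose with sklearn
pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .hypercube import Hypercube
from .segmentation import SampleRegion

__all__ = [
    "PreprocessSpec",
    "wt_smooth",
    "snv",
    "apply_chain",
    "region_mean_spectrum",
    "WaveletSmoother",
    "SNVTransformer",
]

_WAVELET_ALIASES = {
    "daubechies 8": "db8",
    "daubechies8": "db8",
}


def _wavelet(name: str) -> pywt.Wavelet:
    return pywt.Wavelet(_WAVELET_ALIASES.get(name.strip().lower(), name))


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered preprocessing chain.

    ``chain`` is an ordered subset of {"wt", "snv"}; when both are
    present WT must precede SNV (smoothing the already-autoscaled
    spectrum is the one order the analysis never uses).
    """

    chain: tuple = ("wt",)
    wavelet_name: str = "db8"
    decomposition_level: int = 3

    def __post_init__(self) -> None:
        chain = tuple(s.lower() for s in self.chain)
        if any(s not in ("wt", "snv") for s in chain):
            raise ValueError("chain steps must be 'wt' or 'snv'")
        if len(set(chain)) != len(chain):
            raise ValueError("chain steps must be unique")
        if "wt" in chain and "snv" in chain and chain.index("wt") > chain.index("snv"):
            raise ValueError("WT must precede SNV in the chain")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        object.__setattr__(self, "chain", chain)

    @property
    def tag(self) -> str:
        """Short name used in file names and reports, e.g. 'wt-snv'."""
        return "-".join(self.chain) if self.chain else "raw"


def wt_smooth(spectra: np.ndarray, wavelet_name: str = "db8",
              level: int = 3, mode: str = "symmetric") -> np.ndarray:
    """Approximation-only wavelet reconstruction along the last axis.

    Decomposes to ``level``, zeroes all detail coefficients, and
    reconstructs; output has the input's length.  Linear in its input.
    Raises ``ValueError`` when the spectrum is too short for the
    requested level.
    """
    x = np.asarray(spectra, dtype=float)
    n = x.shape[-1]
    wav = _wavelet(wavelet_name)
    if pywt.dwt_max_level(n, wav.dec_len) < level:
        raise ValueError(
            f"spectrum of length {n} too short for {wav.name} at level {level}"
        )
    coeffs = pywt.wavedec(x, wav, mode=mode, level=level, axis=-1)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wav, mode=mode, axis=-1)
    return rec[..., :n]


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate along the last axis.

    Each spectrum is centered and divided by its sample standard
    deviation (n-1 denominator), yielding mean 0 and SD 1.  A constant
    spectrum (zero SD) is a degenerate input and raises ``ValueError``.
    """
    x = np.asarray(spectra, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 bands")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for constant spectra (sd = 0)")
    return (x - mean) / sd


def apply_chain(spectra: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Apply the chain, in order, to each row of ``spectra``."""
    out = np.asarray(spectra, dtype=float)
    for step in spec.chain:
        if step == "wt":
            out = wt_smooth(out, spec.wavelet_name, spec.decomposition_level)
        else:
            out = snv(out)
    return out


def region_mean_spectrum(cube: Hypercube, region: SampleRegion,
                         spec: PreprocessSpec) -> np.ndarray:
    """Preprocess every pixel spectrum of the region, then average.

    The pixel-then-average order is deliberate: for nonlinear steps
    (SNV) it differs from preprocessing the mean spectrum.
    """
    if region.area_px == 0:
        raise ValueError("empty region")
    rr, cc = region.coords[:, 0], region.coords[:, 1]
    if not cube.valid_mask[rr, cc].all():
        raise ValueError("region contains invalid (uncalibratable) pixels")
    pix = cube.data[rr, cc, :]
    return apply_chain(pix, spec).mean(axis=0)


class WaveletSmoother(TransformerMixin, BaseEstimator):
    """Row-wise wavelet approximation smoother (stateless transformer)."""

    def __init__(self, wavelet_name: str = "db8", level: int = 3,
                 mode: str = "symmetric"):
        self.wavelet_name = wavelet_name
        self.level = level
        self.mode = mode

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (n_spectra, n_bands) matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return wt_smooth(np.atleast_2d(np.asarray(X, float)),
                         self.wavelet_name, self.level, self.mode)


class SNVTransformer(TransformerMixin, BaseEstimator):
    """Row-wise standard normal variate (stateless transformer)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (n_spectra, n_bands) matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return snv(np.atleast_2d(np.asarray(X, float)))
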