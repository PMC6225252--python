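"""Hypercube data model, wavelength axis, and reflectance calibration.

A hypercube is the 3-D array produced by a line-scan imaging
spectrograph: two spatial axes (lines x samples, i.e. image rows and
columns) and one spectral axis.  Raw sensor counts are converted to
relative reflectance with dark-current and white-tile reference frames,

    R = (I_raw - I_dark) / (I_white - I_dark),

applied elementwise.  Pixels where the white and dark references nearly
coincide carry no radiometric information and are masked invalid rather
than propagated as infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default spectral coverage of the simulated instrument.
DEFAULT_WAVELENGTH_MIN_NM = 874.0
DEFAULT_WAVELENGTH_MAX_NM = 1734.0
DEFAULT_BAND_COUNT = 256

#: Minimum white-minus-dark signal (in count units) for a pixel to be
#: considered radiometrically valid.
CALIBRATION_EPS = 1e-6


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing vector of band-center wavelengths in nm."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("wavelength axis needs at least 2 bands")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)

    @classmethod
    def linear(
        cls,
        n_bands: int = DEFAULT_BAND_COUNT,
        low_nm: float = DEFAULT_WAVELENGTH_MIN_NM,
        high_nm: float = DEFAULT_WAVELENGTH_MAX_NM,
    ) -> "WavelengthAxis":
        """Linearly spaced axis between the instrument endpoints.

        Band indices are 0-based; the conventional "74th waveband"
        (1-based) of the 874-1734 nm / 256-band instrument is index 73
        here, at ~1120 nm on the linear axis.
        """
        return cls(np.linspace(float(low_nm), float(high_nm), int(n_bands)))

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def spacing_nm(self) -> float:
        return float(np.median(np.diff(self.wavelengths_nm)))

    def nearest_band(self, target_nm: float) -> int:
        return nearest_band(self, target_nm)

    def range_indices(self, low_nm: float, high_nm: float) -> np.ndarray:
        """Indices of bands with low_nm <= wavelength <= high_nm."""
        w = self.wavelengths_nm
        return np.flatnonzero((w >= low_nm) & (w <= high_nm))


def nearest_band(axis: WavelengthAxis, target_nm: float) -> int:
    """Index of the band closest to ``target_nm``; ties go to the lower index.

    Raises ``ValueError`` if the target lies outside the axis range by
    more than half a band spacing.
    """
    w = axis.wavelengths_nm
    half = 0.5 * axis.spacing_nm
    if target_nm < w[0] - half or target_nm > w[-1] + half:
        raise ValueError(
            f"target {target_nm} nm outside axis range "
            f"[{w[0]}, {w[-1]}] nm (+/- half spacing)"
        )
    # np.argmin returns the first minimum, i.e. the lower index on ties.
    return int(np.argmin(np.abs(w - target_nm)))


@dataclass
class Hypercube:
    """3-D spectral image: ``data[line, sample, band]``.

    ``kind`` records whether values are raw counts or relative
    reflectance; ``valid_mask`` marks pixels with usable calibration.
    """

    data: np.ndarray
    axis: WavelengthAxis
    kind: str = "reflectance"
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"band dimension {self.data.shape[2]} does not match axis "
                f"length {len(self.axis)}"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError("kind must be 'raw' or 'reflectance'")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.data.shape[:2]:
                raise ValueError("valid_mask shape must match spatial shape")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def band(self, index: int) -> np.ndarray:
        """2-D image plane of one band."""
        return self.data[:, :, index]

    def plane_at(self, target_nm: float) -> np.ndarray:
        """2-D image plane of the band nearest ``target_nm``."""
        return self.band(nearest_band(self.axis, target_nm))

    def pixel_spectra(self, mask: np.ndarray) -> np.ndarray:
        """(n_pixels, n_bands) matrix of spectra where ``mask`` is true."""
        return self.data[np.asarray(mask, bool)]


def _as_band_frame(frame: np.ndarray, shape: tuple) -> np.ndarray:
    """Broadcast a reference frame to the cube's (lines, samples, bands).

    Accepted shapes: full cube, a single scan line ``(1, samples,
    bands)`` / ``(samples, bands)`` broadcast along the scan direction,
    or a bare ``(bands,)`` spectrum.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 1:
        frame = frame[None, None, :]
    elif frame.ndim == 2:
        frame = frame[None, :, :]
    try:
        return np.broadcast_to(frame, shape)
    except ValueError as exc:
        raise ValueError(
            f"reference frame shape {frame.shape} not broadcastable to {shape}"
        ) from exc


def calibrate_reflectance(
    raw: "Hypercube | np.ndarray",
    dark: np.ndarray,
    white: np.ndarray,
    axis: WavelengthAxis | None = None,
    eps: float = CALIBRATION_EPS,
) -> Hypercube:
    """Convert raw counts to relative reflectance.

    Computes ``(raw - dark) / (white - dark)`` elementwise.  Dark and
    white frames may be full cubes, single-line references, or per-band
    vectors.  Pixels whose white-dark difference is <= ``eps`` at any
    band are marked invalid (masked) with reflectance 0 there, never
    infinite.  The result is invariant to rescaling all three inputs by
    a common positive factor.
    """
    if isinstance(raw, Hypercube):
        if axis is None:
            axis = raw.axis
        raw_data = raw.data
    else:
        raw_data = np.asarray(raw, dtype=float)
        if axis is None:
            raise ValueError("axis required when raw is a bare array")
    dark_b = _as_band_frame(dark, raw_data.shape)
    white_b = _as_band_frame(white, raw_data.shape)

    denom = white_b - dark_b
    bad = denom <= eps
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(bad, 0.0, (raw_data - dark_b) / np.where(bad, 1.0, denom))
    valid = ~np.any(bad, axis=2)
    return Hypercube(refl, axis, kind="reflectance", valid_mask=valid)


def trim_to_range(cube: Hypercube, low_nm: float, high_nm: float) -> Hypercube:
    """Keep exactly the bands with ``low_nm <= wavelength <= high_nm``.

    Endpoints are inclusive; an empty selection raises ``ValueError``.
    Applying the same trim twice is idempotent.
    """
    if not low_nm < high_nm:
        raise ValueError("low_nm must be < high_nm")
    idx = cube.axis.range_indices(low_nm, high_nm)
    if idx.size == 0:
        raise ValueError(
            f"no bands in [{low_nm}, {high_nm}] nm for this axis"
        )
    new_axis = WavelengthAxis(cube.axis.wavelengths_nm[idx])
    return Hypercube(
        cube.data[:, :, idx], new_axis, kind=cube.kind,
        valid_mask=cube.valid_mask.copy(),
    )
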