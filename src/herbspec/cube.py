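"""Image-side preprocessing of hyperspectral cubes.

Reflectance calibration against white/dark references, background
segmentation on a single near-infrared band, per-pixel wavelet
smoothing, mean-spectrum extraction per bulb, and truncation of the
spectral axis to the low-noise analysis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .axis import DEFAULT_WINDOW, SpectralAxis
from .exceptions import DegenerateReferenceError, HerbspecError, NoSampleError

DEFAULT_WAVELET = "db8"
DEFAULT_LEVEL = 3
DEFAULT_SEGMENT_BAND_NM = 1200.0
DEFAULT_MIN_AREA = 50


@dataclass
class HyperCube:
    """rows x cols x bands image stack with its spectral axis.

    ``kind`` is ``"raw"`` (digital numbers) or ``"reflectance"``.
    Reflectance values are nominally in [-0.1, 1.5]; nothing is clipped
    silently, but grossly out-of-range data trips a warning.
    """

    data: np.ndarray
    axis: SpectralAxis
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise HerbspecError("cube must be rows x cols x bands")
        if self.data.shape[2] != self.axis.count:
            raise HerbspecError(
                f"cube has {self.data.shape[2]} bands but axis has "
                f"{self.axis.count}"
            )
        if self.kind not in ("raw", "reflectance"):
            raise HerbspecError(f"unknown cube kind {self.kind!r}")
        if self.kind == "reflectance":
            lo, hi = self.data.min(), self.data.max()
            if lo < -0.1 or hi > 1.5:
                warnings.warn(
                    f"reflectance outside nominal [-0.1, 1.5]: "
                    f"[{lo:.3g}, {hi:.3g}]", stacklevel=2,
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Spectrum:
    """Single spectrum on a spectral axis."""

    values: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.axis.count,):
            raise HerbspecError("spectrum length must equal axis.count")


def calibrate(raw: HyperCube, white: np.ndarray, dark: np.ndarray) -> HyperCube:
    """White/dark reflectance calibration: (raw - dark)/(white - dark).

    Element-wise, no clipping.  Any band where white <= dark anywhere
    raises :class:`DegenerateReferenceError` naming the offending bands.
    """
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if white.shape != raw.data.shape or dark.shape != raw.data.shape:
        raise HerbspecError("reference frame shapes must match the cube")
    span = white - dark
    bad = np.flatnonzero((span <= 0).any(axis=(0, 1)))
    if bad.size:
        nm = ", ".join(f"{raw.axis.centers[b]:.1f}" for b in bad[:5])
        raise DegenerateReferenceError(
            f"white <= dark in {bad.size} band(s), e.g. at {nm} nm"
        )
    return HyperCube((raw.data - dark) / span, raw.axis, kind="reflectance")


def segment(
    cube: HyperCube,
    band_nm: float = DEFAULT_SEGMENT_BAND_NM,
    min_area: int = DEFAULT_MIN_AREA,
) -> np.ndarray:
    """Foreground mask from Otsu thresholding of one band image.

    The band nearest ``band_nm`` is thresholded (samples are brighter
    than the dark background), holes are filled, components below
    ``min_area`` pixels dropped, and the survivors relabelled 1..K in
    top-left (row-major first-pixel) order.
    """
    if cube.kind != "reflectance":
        raise HerbspecError("segment expects a reflectance cube")
    from skimage.filters import threshold_otsu

    band = cube.data[:, :, cube.axis.nearest(band_nm)]
    if np.ptp(band) == 0:
        raise NoSampleError("uniform band image: nothing to segment")
    binary = band > threshold_otsu(band)
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    out = np.zeros_like(labels, dtype=np.uint16)
    next_label = 1
    # np.unique on the flattened grid preserves row-major first-occurrence
    # order only via argsort; do it explicitly for top-left relabelling.
    flat = labels.ravel()
    seen: list[int] = []
    for lab in flat[flat > 0]:
        if lab not in seen:
            seen.append(int(lab))
        if len(seen) == n:
            break
    for lab in seen:
        comp = labels == lab
        if comp.sum() >= min_area:
            out[comp] = next_label
            next_label += 1
    if next_label == 1:
        raise NoSampleError("no foreground component above min_area")
    return out


def _universal_threshold(detail: np.ndarray, n: int) -> np.ndarray:
    """sigma_hat * sqrt(2 ln n) with sigma_hat = MAD(finest detail)/0.6745."""
    mad = np.median(np.abs(detail), axis=-1)
    sigma = mad / 0.6745
    return sigma * np.sqrt(2.0 * np.log(n))


def denoise_values(
    values: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
    threshold: float | None = None,
    mode: str = "symmetric",
) -> np.ndarray:
    """Wavelet smoothing of spectra along the last axis.

    Multi-level decomposition; detail coefficients are soft-thresholded
    (the approximation is untouched) and the signal reconstructed at its
    original length.  ``threshold=None`` uses the universal threshold
    per spectrum, estimated from the finest detail level; ``0`` makes
    the transform a pure round-trip.  Symmetric boundary extension is
    the default; reconstruction is exact to ~1e-12 either way.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n < 2 ** level:
        raise HerbspecError(
            f"spectrum of length {n} too short for level-{level} transform"
        )
    coeffs = pywt.wavedec(values, wavelet, mode=mode, level=level, axis=-1)
    if threshold is None:
        thr = _universal_threshold(coeffs[-1], n)[..., None]
    else:
        thr = np.asarray(float(threshold))
    smoothed = [coeffs[0]]
    for d in coeffs[1:]:
        smoothed.append(np.sign(d) * np.maximum(np.abs(d) - thr, 0.0))
    out = pywt.waverec(smoothed, wavelet, mode=mode, axis=-1)
    return out[..., :n]


def denoise(
    spectrum: Spectrum,
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
    threshold: float | None = None,
    mode: str = "symmetric",
) -> Spectrum:
    """Wavelet-smooth one spectrum (see :func:`denoise_values`)."""
    return Spectrum(
        denoise_values(spectrum.values, wavelet, level, threshold, mode),
        spectrum.axis,
    )


def mean_spectrum(
    cube: HyperCube,
    mask: np.ndarray,
    label: int,
    denoise_each_pixel: bool = True,
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
    threshold: float | None = None,
) -> Spectrum:
    """Average spectrum of one labelled sample region.

    Every in-mask pixel spectrum is wavelet-smoothed first (the noisy
    per-pixel spectra are the ones carrying sensor noise), then the
    arithmetic mean over pixels is taken.
    """
    mask = np.asarray(mask)
    if mask.shape != cube.data.shape[:2]:
        raise HerbspecError("mask shape must match cube spatial dims")
    in_mask = mask == label
    if not np.any(in_mask):
        raise HerbspecError(f"label {label} absent from mask")
    pixels = cube.data[in_mask]  # npix x bands
    if denoise_each_pixel:
        pixels = denoise_values(pixels, wavelet, level, threshold)
    return Spectrum(pixels.mean(axis=0), cube.axis)


def extract_spectra(
    cube: HyperCube, mask: np.ndarray, **kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Mean spectra for every label in the mask.

    Returns (labels, X) with X of shape n_labels x bands in label order.
    """
    labels = np.unique(np.asarray(mask))
    labels = labels[labels > 0]
    if labels.size == 0:
        raise NoSampleError("mask has no labelled samples")
    X = np.stack(
        [mean_spectrum(cube, mask, int(k), **kwargs).values for k in labels]
    )
    return labels, X


def truncate(
    obj: HyperCube | Spectrum,
    lo_nm: float = DEFAULT_WINDOW[0],
    hi_nm: float = DEFAULT_WINDOW[1],
):
    """Keep only bands whose centers lie in the closed [lo, hi] nm window."""
    idx = obj.axis.window_indices(lo_nm, hi_nm)
    new_axis = obj.axis.subset(idx)
    if isinstance(obj, Spectrum):
        return Spectrum(obj.values[idx], new_axis)
    return HyperCube(obj.data[:, :, idx], new_axis, obj.kind)
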