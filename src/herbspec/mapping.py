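"""Pixel-wise and per-bulb prediction maps.

A fitted regression model (trained on mean spectra at selected bands)
is applied to every in-mask pixel spectrum of a reflectance cube; pixel
predictions are aggregated to per-bulb means and rendered as
color-coded maps, alongside a pseudo-RGB composite built from three
single-band grayscale images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .axis import DEFAULT_WINDOW
from .cube import HyperCube, denoise_values
from .exceptions import HerbspecError

DEFAULT_PSEUDO_RGB_NM = (1000.0, 1200.0, 1400.0)


@dataclass
class PredictionMap:
    """Per-pixel predicted content over a labelled mask."""

    pixel_values: np.ndarray            # NaN outside the mask
    mask: np.ndarray
    sample_means: np.ndarray            # one mean per label, label order
    labels: np.ndarray
    bounds: tuple[float, float] | None = None
    model_ref: str = ""

    def __post_init__(self) -> None:
        defined = ~np.isnan(self.pixel_values)
        if not np.array_equal(defined, np.asarray(self.mask) > 0):
            raise HerbspecError(
                "pixel values must be defined exactly on mask > 0"
            )


def predict_pixels(
    cube: HyperCube,
    mask: np.ndarray,
    results,
    band_indices: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
    denoise_each_pixel: bool = True,
    model_ref: str = "",
) -> PredictionMap:
    """Apply a fitted model at selected bands to every in-mask pixel.

    Pixel spectra follow the training preprocessing: wavelet smoothing
    on the full axis, truncation to the analysis window, then the
    model's band subset.  ``band_indices`` index the truncated axis.
    """
    if cube.kind != "reflectance":
        raise HerbspecError("predict_pixels expects a reflectance cube")
    mask = np.asarray(mask)
    if mask.shape != cube.data.shape[:2]:
        raise HerbspecError("mask shape must match cube spatial dims")
    win_idx = cube.axis.window_indices(*window)
    band_indices = np.asarray(band_indices, dtype=int)
    if band_indices.size and band_indices.max() >= win_idx.size:
        raise HerbspecError("band index beyond the truncated axis")

    labels = np.unique(mask)
    labels = labels[labels > 0]
    pixel_values = np.full(mask.shape, np.nan)
    in_mask = mask > 0
    spectra = cube.data[in_mask]
    if denoise_each_pixel:
        spectra = denoise_values(spectra)
    preds = results.predict(spectra[:, win_idx][:, band_indices])
    pixel_values[in_mask] = preds
    means = np.array([
        float(np.nanmean(pixel_values[mask == k])) for k in labels
    ])
    return PredictionMap(
        pixel_values=pixel_values, mask=mask, sample_means=means,
        labels=labels, model_ref=model_ref,
    )


def sample_means(pmap: PredictionMap, mask: np.ndarray | None = None
                 ) -> np.ndarray:
    """Arithmetic mean of pixel predictions per label (per bulb)."""
    mask = pmap.mask if mask is None else np.asarray(mask)
    if mask.shape != pmap.pixel_values.shape:
        raise HerbspecError("mask shape mismatch")
    out = []
    for k in pmap.labels:
        sel = mask == k
        if not sel.any():
            raise HerbspecError(f"label {k} has no pixels")
        out.append(float(np.nanmean(pmap.pixel_values[sel])))
    return np.asarray(out)


def render(
    pmap: PredictionMap,
    colormap: str = "jet",
    bounds: tuple[float, float] | None = None,
    per_sample: bool = True,
) -> tuple[np.ndarray, dict]:
    """Color-code a prediction map; returns (uint8 RGB image, sidecar).

    With ``per_sample`` (the default) each bulb region is painted with
    its mean predicted content, which is the view used for sorting
    whole bulbs; ``per_sample=False`` paints raw pixel predictions.
    Values are min-max mapped onto the colormap between ``bounds``;
    out-of-range values are clamped and flagged in the sidecar.
    Background pixels are neutral gray.
    """
    import matplotlib

    if bounds is None:
        finite = pmap.pixel_values[~np.isnan(pmap.pixel_values)]
        bounds = (float(finite.min()), float(finite.max()))
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise HerbspecError(f"invalid bounds {bounds}")

    values = np.full(pmap.pixel_values.shape, np.nan)
    if per_sample:
        for k, m in zip(pmap.labels, pmap.sample_means):
            values[pmap.mask == k] = m
    else:
        values = pmap.pixel_values.copy()

    defined = ~np.isnan(values)
    clamped = int(np.sum((values[defined] < lo) | (values[defined] > hi)))
    norm = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    rgb = np.full(values.shape + (3,), 200, dtype=np.uint8)  # gray backdrop
    colored = (cmap(norm[defined])[:, :3] * 255).round().astype(np.uint8)
    rgb[defined] = colored
    sidecar = {
        "bounds": [lo, hi], "colormap": colormap,
        "per_sample": per_sample, "clamped_pixels": clamped,
        "model_ref": pmap.model_ref,
        "sample_means": [float(v) for v in pmap.sample_means],
    }
    return rgb, sidecar


def pseudo_rgb(
    cube: HyperCube,
    nm_triplet: tuple[float, float, float] = DEFAULT_PSEUDO_RGB_NM,
) -> np.ndarray:
    """False-color composite from three single-band grayscale images.

    Each channel is the band nearest the requested wavelength, linearly
    stretched to 0-255; a constant band maps to mid-gray (128).
    """
    channels = []
    for nm in nm_triplet:
        band = cube.data[:, :, cube.axis.nearest(nm)]
        span = np.ptp(band)
        if span == 0:
            ch = np.full(band.shape, 128, dtype=np.uint8)
        else:
            ch = ((band - band.min()) / span * 255).round().astype(np.uint8)
        channels.append(ch)
    return np.stack(channels, axis=-1)


def save_map(pmap: PredictionMap, basepath: str, colormap: str = "jet",
             bounds: tuple[float, float] | None = None) -> dict:
    """Write pixel map (float TIFF), per-bulb means (CSV), rendered PNG
    and sidecar JSON next to ``basepath``."""
    import tifffile
    from PIL import Image

    paths = {
        "pixels": f"{basepath}_pixels.tiff",
        "means": f"{basepath}_means.csv",
        "png": f"{basepath}.png",
        "sidecar": f"{basepath}.json",
    }
    tifffile.imwrite(paths["pixels"], pmap.pixel_values.astype(np.float32))
    with open(paths["means"], "w") as fh:
        fh.write("label,predicted_content\n")
        for k, m in zip(pmap.labels, pmap.sample_means):
            fh.write(f"{int(k)},{m!r}\n")
    rgb, sidecar = render(pmap, colormap=colormap, bounds=bounds)
    Image.fromarray(rgb).save(paths["png"])
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return paths
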