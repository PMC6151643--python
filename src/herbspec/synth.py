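"""Synthetic sulfur-fumigation study generator.

Emulates the full experiment on *Fritillaria thunbergii* bulbi: an
11-level sulfur-fumigation design with 15 replicate bulbs per level
(165 samples), per-sample ground-truth peimine/peiminine contents that
follow a two-plateau dose-response, and renderable near-infrared
hyperspectral scenes (raw digital numbers plus white/dark reference
frames) from which the whole downstream pipeline can be exercised.

The optical forward model is Beer-Lambert in reflectance:

    R(px, lambda) = B(lambda) * 10**(-sum_k c_k(px) * eps_k(lambda))

where ``B`` is a smooth instrument/matrix baseline in [0.3, 0.9],
``c_k`` the local analyte content (% w/w) and ``eps_k`` a fixed
absorptivity signature built from three Gaussian bands per analyte.
Raw digital numbers are then

    DN = dark + R * (white - dark) + sensor noise

so that the standard white/dark reflectance calibration inverts the
rendering exactly at zero noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .axis import SpectralAxis, make_axis
from .exceptions import HerbspecError, SceneGeometryError

# --------------------------------------------------------------------------
# study design and dose-response ground truth
# --------------------------------------------------------------------------

DEFAULT_SULFUR_LEVELS = tuple(range(0, 101, 10))  # g sulfur / kg sample
DEFAULT_REPLICATES = 15
ANALYTES = ("peimine", "peiminine")


@dataclass(frozen=True)
class StudyDesign:
    """Fumigation doses x replicate count defining the sample population."""

    sulfur_levels: Sequence[float] = DEFAULT_SULFUR_LEVELS
    replicates_per_level: int = DEFAULT_REPLICATES
    analytes: Sequence[str] = ANALYTES

    def __post_init__(self) -> None:
        doses = np.asarray(self.sulfur_levels, dtype=float)
        if doses.size == 0:
            raise HerbspecError("design has no sulfur levels")
        if np.any(doses < 0):
            raise HerbspecError("sulfur doses must be non-negative")
        if np.unique(doses).size != doses.size:
            raise HerbspecError("sulfur doses must be unique")
        if self.replicates_per_level < 1:
            raise HerbspecError("replicates_per_level must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.sulfur_levels) * self.replicates_per_level


@dataclass(frozen=True)
class DoseResponseParams:
    """Two-plateau piecewise-linear dose-response of an analyte content.

    Content (% w/w) holds at ``c_plateau_low_dose`` up to ``knee1`` g/kg,
    falls linearly to ``c_plateau_high_dose`` at ``knee2``, and stays
    there for higher doses.  ``between_sample_cv`` is the biological
    coefficient of variation across bulbs at a given dose;
    ``within_sample_cv`` the spatial variation within one bulb.
    """

    c_plateau_low_dose: float
    c_plateau_high_dose: float
    knee1: float = 50.0
    knee2: float = 70.0
    between_sample_cv: float = 0.10
    within_sample_cv: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.c_plateau_high_dose < self.c_plateau_low_dose):
            raise HerbspecError(
                "need 0 < c_plateau_high_dose < c_plateau_low_dose"
            )
        if not self.knee1 < self.knee2:
            raise HerbspecError("need knee1 < knee2")
        for cv in (self.between_sample_cv, self.within_sample_cv):
            if not (0 <= cv < 0.5):
                raise HerbspecError("CVs must lie in [0, 0.5)")


#: Default dose-response parameterisations per analyte (% w/w).
DEFAULT_DOSE_RESPONSE: Mapping[str, DoseResponseParams] = {
    "peimine": DoseResponseParams(0.18, 0.09),
    "peiminine": DoseResponseParams(0.095, 0.048),
}


def dose_response(dose, params: DoseResponseParams):
    """Mean analyte content (% w/w) at a sulfur dose (g/kg).

    Continuous, non-increasing, piecewise linear with plateaus below
    ``knee1`` and above ``knee2``.  Accepts scalars or arrays.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise HerbspecError("dose must be non-negative")
    out = np.interp(
        dose,
        [params.knee1, params.knee2],
        [params.c_plateau_low_dose, params.c_plateau_high_dose],
    )
    return float(out) if out.ndim == 0 else out


def simulate_study(
    design: StudyDesign = StudyDesign(),
    params: Mapping[str, DoseResponseParams] = DEFAULT_DOSE_RESPONSE,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the per-sample ground-truth content table.

    Returns a DataFrame with one row per (level, replicate):
    ``sample_id``, ``sulfur_dose`` and one content column per analyte.
    Contents are ``dose_response(dose) * (1 + eps)`` with
    ``eps ~ N(0, between_sample_cv)``, floored at 10% of the
    dose-response value so contents stay strictly positive.
    """
    for name in design.analytes:
        if name not in params:
            raise HerbspecError(f"missing dose-response params for {name!r}")
    rng = np.random.default_rng(seed)
    doses = np.repeat(
        np.asarray(design.sulfur_levels, dtype=float),
        design.replicates_per_level,
    )
    n = doses.size
    table = {
        "sample_id": [f"S{i + 1:03d}" for i in range(n)],
        "sulfur_dose": doses,
    }
    for name in design.analytes:
        p = params[name]
        base = dose_response(doses, p)
        noise = rng.normal(0.0, p.between_sample_cv, size=n)
        table[name] = np.maximum(base * (1.0 + noise), 0.1 * base)
    return pd.DataFrame(table)


# --------------------------------------------------------------------------
# optical forward model
# --------------------------------------------------------------------------

#: Gaussian absorptivity signatures per analyte: (center nm, FWHM nm,
#: amplitude per % w/w).  Centers sit at wavelengths each analyte's
#: successive-projections selection singles out on real bulbs; widths
#: are full-width-at-half-maximum of each absorption band.  Amplitudes
#: put the strongest band near 0.4 absorbance at typical contents, the
#: regime where reflectance is most sensitive to content.
SIGNATURES: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    "peimine": ((1416.0, 26.0, 1.6), (1517.0, 34.0, 2.4), (1558.0, 22.0, 1.9)),
    "peiminine": ((1305.0, 28.0, 1.7), (1348.0, 22.0, 2.2), (1379.0, 30.0, 1.5)),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Defaults of the sensor model (digital numbers).
WHITE_LEVEL = 3500.0
DARK_LEVEL = 120.0
#: Sensor noise default: 0.5% of the white-dark span.
DEFAULT_NOISE_SD = 0.005 * (WHITE_LEVEL - DARK_LEVEL)
BACKGROUND_REFLECTANCE = 0.02


def absorptivity(name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Evaluate an analyte's Gaussian-band absorptivity eps(lambda)."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    eps = np.zeros_like(lam)
    for center, fwhm, amp in SIGNATURES[name]:
        sigma = fwhm * _FWHM_TO_SIGMA
        eps += amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    return eps


def baseline(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth instrument/matrix reflectance baseline, inside [0.3, 0.9]."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    t = (lam - 870.0) / (1740.0 - 870.0)
    return 0.62 + 0.16 * np.sin(np.pi * t) - 0.08 * t


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse footprint of one bulb (pixel coordinates)."""

    cy: float
    cx: float
    ry: float
    rx: float


def default_geometry(
    n: int, shape: tuple[int, int], n_cols: int = 5
) -> list[Ellipse]:
    """Lay ``n`` non-overlapping ellipses on a grid inside ``shape``."""
    rows, cols = shape
    n_rows = -(-n // n_cols)
    cell_h, cell_w = rows / n_rows, cols / n_cols
    ry = 0.36 * cell_h
    rx = 0.38 * cell_w
    out = []
    for k in range(n):
        r, c = divmod(k, n_cols)
        out.append(
            Ellipse((r + 0.5) * cell_h, (c + 0.5) * cell_w, ry, rx)
        )
    return out


def rasterize(ellipses: Sequence[Ellipse], shape: tuple[int, int]) -> np.ndarray:
    """Label grid (0 background, k for sample k) from ellipse footprints.

    Raises :class:`SceneGeometryError` on overlap or out-of-frame shapes.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros(shape, dtype=np.uint16)
    for k, e in enumerate(ellipses, start=1):
        if (
            e.cy - e.ry < -0.5 or e.cy + e.ry > rows - 0.5
            or e.cx - e.rx < -0.5 or e.cx + e.rx > cols - 0.5
        ):
            raise SceneGeometryError(f"ellipse {k} extends outside the frame")
        inside = ((yy - e.cy) / e.ry) ** 2 + ((xx - e.cx) / e.rx) ** 2 <= 1.0
        if np.any(mask[inside] != 0):
            raise SceneGeometryError(f"ellipse {k} overlaps an earlier one")
        mask[inside] = k
    return mask


@dataclass
class SceneBundle:
    """One rendered scene: raw DN cube, references, truth and geometry."""

    raw: np.ndarray           # rows x cols x bands, digital numbers
    white: np.ndarray         # same shape
    dark: np.ndarray          # same shape
    reflectance: np.ndarray   # noise-free rendered reflectance
    truth_mask: np.ndarray    # uint16 labels, 0 = background
    truth: pd.DataFrame       # rows for the samples in this scene
    axis: SpectralAxis
    noise_sd: float
    seed: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.raw.shape


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-sd smooth spatial noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def render_scene(
    truth: pd.DataFrame,
    axis: SpectralAxis | None = None,
    geometry: Sequence[Ellipse] | None = None,
    shape: tuple[int, int] = (96, 128),
    within_sample_cv: float | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    analytes: Sequence[str] = ANALYTES,
) -> SceneBundle:
    """Render one scene holding the bulbs listed in ``truth``.

    ``truth`` needs columns ``sample_id`` plus one content column per
    analyte.  ``within_sample_cv`` defaults to the peimine
    dose-response default (5%).  The bundle is a pure function of its
    arguments and ``seed``.
    """
    if axis is None:
        axis = make_axis()
    if within_sample_cv is None:
        within_sample_cv = DEFAULT_DOSE_RESPONSE["peimine"].within_sample_cv
    n = len(truth)
    if n == 0:
        raise HerbspecError("truth table is empty")
    for name in analytes:
        for center, _, _ in SIGNATURES[name]:
            if not (axis.centers[0] <= center <= axis.centers[-1]):
                raise SceneGeometryError(
                    f"signature band {center} nm outside the spectral axis"
                )
    if geometry is None:
        geometry = default_geometry(n, shape)
    if len(geometry) != n:
        raise SceneGeometryError("one ellipse per truth row required")
    mask = rasterize(geometry, shape)

    rng = np.random.default_rng(seed)
    lam = axis.centers
    n_bands = axis.count
    rows, cols = shape

    # reference frames: flat across bands, smooth spatial non-uniformity
    white = WHITE_LEVEL * (1.0 + 0.02 * _smooth_field(rng, shape, 12.0))
    dark = DARK_LEVEL * (1.0 + 0.05 * _smooth_field(rng, shape, 12.0))
    white = np.broadcast_to(white[:, :, None], (rows, cols, n_bands)).copy()
    dark = np.broadcast_to(dark[:, :, None], (rows, cols, n_bands)).copy()

    eps = {name: absorptivity(name, lam) for name in analytes}
    base = baseline(lam)

    reflectance = np.full(
        (rows, cols, n_bands), BACKGROUND_REFLECTANCE, dtype=float
    )
    for k in range(1, n + 1):
        sample = truth.iloc[k - 1]
        in_mask = mask == k
        npix = int(in_mask.sum())
        absorbance = np.zeros((npix, n_bands))
        for name in analytes:
            content = float(sample[name])
            if within_sample_cv > 0:
                f = _smooth_field(rng, shape, 3.0)[in_mask]
                local = content * (1.0 + within_sample_cv * f)
                local = np.maximum(local, 0.1 * content)
            else:
                local = np.full(npix, content)
            absorbance += local[:, None] * eps[name][None, :]
        reflectance[in_mask] = base[None, :] * 10.0 ** (-absorbance)

    raw = dark + reflectance * (white - dark)
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)

    return SceneBundle(
        raw=raw, white=white, dark=dark, reflectance=reflectance,
        truth_mask=mask, truth=truth.reset_index(drop=True), axis=axis,
        noise_sd=noise_sd, seed=seed,
    )


def render_study(
    truth: pd.DataFrame,
    axis: SpectralAxis | None = None,
    samples_per_scene: int = 15,
    shape: tuple[int, int] = (96, 128),
    seed: int = 0,
    **kwargs,
) -> list[SceneBundle]:
    """Render the whole study as consecutive scenes of up to
    ``samples_per_scene`` bulbs each (default: one scene per dose level)."""
    scenes = []
    for j, start in enumerate(range(0, len(truth), samples_per_scene)):
        chunk = truth.iloc[start:start + samples_per_scene]
        scenes.append(
            render_scene(chunk, axis=axis, shape=shape,
                         seed=seed + 1000 + j, **kwargs)
        )
    return scenes


# --------------------------------------------------------------------------
# container I/O
# --------------------------------------------------------------------------

def save_bundle(bundle: SceneBundle, basepath: str) -> dict:
    """Write a scene as <basepath>.npz + _mask.tiff + _truth.csv.

    The .npz holds the named arrays (raw, white, dark, reflectance,
    centers) plus noise_sd and seed; the mask is 16-bit TIFF; the truth
    table CSV.  Returns the path mapping.
    """
    import tifffile

    paths = {
        "cube": f"{basepath}.npz",
        "mask": f"{basepath}_mask.tiff",
        "truth": f"{basepath}_truth.csv",
    }
    np.savez_compressed(
        paths["cube"],
        raw=bundle.raw, white=bundle.white, dark=bundle.dark,
        reflectance=bundle.reflectance, centers=bundle.axis.centers,
        noise_sd=np.float64(bundle.noise_sd), seed=np.int64(bundle.seed),
    )
    tifffile.imwrite(paths["mask"], bundle.truth_mask.astype(np.uint16))
    bundle.truth.to_csv(paths["truth"], index=False)
    return paths


def load_bundle(basepath: str) -> SceneBundle:
    """Inverse of :func:`save_bundle`."""
    import tifffile

    with np.load(f"{basepath}.npz") as z:
        raw, white, dark = z["raw"], z["white"], z["dark"]
        reflectance, centers = z["reflectance"], z["centers"]
        noise_sd, seed = float(z["noise_sd"]), int(z["seed"])
    return SceneBundle(
        raw=raw, white=white, dark=dark, reflectance=reflectance,
        truth_mask=tifffile.imread(f"{basepath}_mask.tiff"),
        truth=pd.read_csv(f"{basepath}_truth.csv"),
        axis=SpectralAxis(centers), noise_sd=noise_sd, seed=seed,
    )


def params_to_dict(params: Mapping[str, DoseResponseParams]) -> dict:
    return {k: dataclasses.asdict(v) for k, v in params.items()}


def params_from_dict(d: Mapping[str, Mapping]) -> dict[str, DoseResponseParams]:
    return {k: DoseResponseParams(**v) for k, v in d.items()}
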