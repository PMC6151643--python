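"""Spectral axis: band-center wavelengths and band <-> nm arithmetic.

The push-broom camera emulated here records 256 spectral bands.  The
instrument's nominal range is 874-1734 nm; band centers are uniformly
spaced and anchored so that band 30 sits at 975.0 nm, which places
exactly 200 bands inside the 975-1646 nm analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AxisError, AxisRangeError

#: Default camera geometry: 256 bands, 3.3719 nm pitch, band 30 = 975 nm.
DEFAULT_N_BANDS = 256
DEFAULT_ANCHOR_NM = 975.0
DEFAULT_ANCHOR_INDEX = 30
DEFAULT_SPACING_NM = 3.3719

#: Analysis window retained after discarding noisy head/tail bands (nm).
DEFAULT_WINDOW = (975.0, 1646.0)

_UNIFORMITY_TOL = 1e-9

#: Absolute tolerance (nm) for band-in-window comparisons.  Band-center
#: grids are specified to 4 decimals, so rounding can drift edge bands
#: by up to ~0.01 nm over 200 pitches; 0.02 nm is far below the band
#: pitch and keeps window membership stable.
WINDOW_EDGE_TOL_NM = 0.02


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing, uniformly spaced band-center wavelengths (nm)."""

    centers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 1:
            raise AxisError("axis needs at least 1 band center")
        diffs = np.diff(centers)
        if np.any(diffs <= 0):
            raise AxisError("band centers must be strictly increasing")
        if diffs.size and np.ptp(diffs) > _UNIFORMITY_TOL:
            raise AxisError(
                f"band spacing not uniform within {_UNIFORMITY_TOL} nm"
            )

    @property
    def count(self) -> int:
        return int(self.centers.size)

    @property
    def spacing(self) -> float:
        # a single-band axis (produced by degenerate truncation windows)
        # has no pitch; report 0 so nearest() only accepts exact hits
        if self.centers.size < 2:
            return 0.0
        return float(self.centers[1] - self.centers[0])

    def nearest(self, target_nm: float) -> int:
        """Index of the band center closest to ``target_nm``.

        Ties break toward the lower index.  Targets more than one band
        spacing outside the axis raise :class:`AxisRangeError`.
        """
        lo = self.centers[0] - self.spacing
        hi = self.centers[-1] + self.spacing
        if not (lo <= target_nm <= hi):
            raise AxisRangeError(
                f"{target_nm} nm outside axis range [{lo:.1f}, {hi:.1f}]"
            )
        return int(np.argmin(np.abs(self.centers - target_nm)))

    def window_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands whose centers lie in the closed [lo, hi] window.

        Edges are compared with a 0.02 nm tolerance (see
        ``WINDOW_EDGE_TOL_NM``).
        """
        if lo_nm > hi_nm:
            raise AxisError(f"empty window: lo {lo_nm} > hi {hi_nm}")
        idx = np.flatnonzero(
            (self.centers >= lo_nm - WINDOW_EDGE_TOL_NM)
            & (self.centers <= hi_nm + WINDOW_EDGE_TOL_NM)
        )
        if idx.size == 0:
            raise AxisError(
                f"window [{lo_nm}, {hi_nm}] nm contains no band centers"
            )
        return idx

    def subset(self, indices: np.ndarray) -> "SpectralAxis":
        return SpectralAxis(self.centers[np.asarray(indices)])

    def __len__(self) -> int:
        return self.count

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.centers.shape == other.centers.shape and bool(
            np.array_equal(self.centers, other.centers)
        )

    def __hash__(self) -> int:
        return hash((self.centers.size, float(self.centers[0]),
                     float(self.centers[-1])))


def make_axis(
    n_bands: int = DEFAULT_N_BANDS,
    anchor_nm: float = DEFAULT_ANCHOR_NM,
    anchor_index: int = DEFAULT_ANCHOR_INDEX,
    spacing_nm: float = DEFAULT_SPACING_NM,
) -> SpectralAxis:
    """Build a uniform axis with ``centers[anchor_index] == anchor_nm``."""
    if n_bands < 2:
        raise AxisError("n_bands must be >= 2")
    if spacing_nm <= 0:
        raise AxisError("spacing must be positive")
    if not (0 <= anchor_index < n_bands):
        raise AxisError(
            f"anchor_index {anchor_index} out of range for {n_bands} bands"
        )
    i = np.arange(n_bands, dtype=float)
    return SpectralAxis(anchor_nm + (i - anchor_index) * spacing_nm)
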