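"""Core in-memory containers for multi-band CARS worm images and derived records.

Intensity rasters are 12-bit counts stored in 16-bit arrays (values 0–4095).
Region labels live in a single 8-bit raster; labels are mutually exclusive
except that each oocyte nucleus is a sub-region of its oocyte (it carries its
own code, and the oocyte mask is cytoplasm ∪ nucleus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import numpy as np

#: counts ceiling of the 12-bit detector
DN_MAX = 4095

#: oocyte queue positions, most immature (−5) to next-to-ovulate (−1)
OOCYTE_POSITIONS = (-5, -4, -3, -2, -1)


class RegionLabel(IntEnum):
    """Codes used in the region-label raster (non-oocyte classes)."""

    BACKGROUND = 0
    INTESTINE = 1
    EMBRYO = 2
    BODY_WALL = 3
    HYPODERMIS = 4
    PSEUDOCOELOM = 5      # pseudocoelom area eligible for accumulation search
    BUFFER = 6            # surrounding-buffer reference ROI
    GFP_NEGATIVE = 7      # carrier-GFP-negative reference region


def oocyte_code(position: int) -> int:
    """Label code of the cytoplasm of the oocyte at ``position`` (−5…−1)."""
    if position not in OOCYTE_POSITIONS:
        raise ValueError(f"oocyte position must be in {OOCYTE_POSITIONS}, got {position}")
    return 10 + position + 5


def nucleus_code(position: int) -> int:
    """Label code of the nucleus of the oocyte at ``position`` (−5…−1)."""
    if position not in OOCYTE_POSITIONS:
        raise ValueError(f"oocyte position must be in {OOCYTE_POSITIONS}, got {position}")
    return 20 + position + 5


@dataclass
class BandFrame:
    """One 2-D intensity raster acquired at a stated Raman shift.

    Parameters
    ----------
    wavenumber : float
        Vibrational frequency probed, in cm⁻¹ (e.g. 2845 for the lipid CH₂
        stretch, 1665 for the protein amide-I band, 2200 for the non-resonant
        background).
    data : ndarray
        2-D array of detector counts in ``[0, DN_MAX]``.
    pixel_size : float
        Edge length of one pixel in μm.
    """

    wavenumber: float
    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("BandFrame.data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.data.size and (self.data.min() < 0 or self.data.max() > DN_MAX):
            raise ValueError(f"band counts must lie in [0, {DN_MAX}]")

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in μm²."""
        return self.pixel_size ** 2


@dataclass
class WormImageSet:
    """Co-registered band frames, optional GFP channel and region labels for one worm."""

    bands: Mapping[float, BandFrame]
    labels: np.ndarray
    pixel_size: float
    gfp: np.ndarray | None = None
    worm_id: str = "worm"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        shapes = {f.data.shape for f in self.bands.values()}
        shapes.add(self.labels.shape)
        if self.gfp is not None:
            self.gfp = np.asarray(self.gfp)
            shapes.add(self.gfp.shape)
        if len(shapes) != 1:
            raise ValueError("all rasters of a WormImageSet must share one shape")
        if not self.mask(RegionLabel.BUFFER).any():
            raise ValueError("buffer ROI must be nonempty")

    def band(self, wavenumber: float) -> BandFrame:
        """Return the frame at ``wavenumber``, tolerating float keys."""
        if wavenumber in self.bands:
            return self.bands[wavenumber]
        for wn, frame in self.bands.items():
            if abs(wn - wavenumber) < 0.5:
                return frame
        raise KeyError(f"no band at {wavenumber} cm^-1")

    def mask(self, code: int) -> np.ndarray:
        return self.labels == int(code)

    def oocyte_mask(self, position: int) -> np.ndarray:
        """Full oocyte mask (cytoplasm ∪ nucleus) at ``position``."""
        return (self.labels == oocyte_code(position)) | (self.labels == nucleus_code(position))

    def nucleus_mask(self, position: int) -> np.ndarray:
        return self.labels == nucleus_code(position)

    @property
    def buffer_mask(self) -> np.ndarray:
        return self.mask(RegionLabel.BUFFER)

    @property
    def eligible_mask(self) -> np.ndarray:
        """Pseudocoelom pixels eligible for accumulation segmentation."""
        return self.mask(RegionLabel.PSEUDOCOELOM)

    @property
    def gfp_negative_mask(self) -> np.ndarray:
        return self.mask(RegionLabel.GFP_NEGATIVE)


@dataclass
class AccumulationRecord:
    """One segmented yolk-lipoprotein accumulation component."""

    worm_id: str
    component_id: int
    area: float                 # μm²
    mean_intensity: float       # counts (NaN when no intensity raster given)
    mean_ratio: float           # dimensionless blob/buffer ratio
    centroid: tuple[float, float]  # (row, col) in μm


@dataclass
class OocyteMeasurement:
    """Per-oocyte staged quantities for one worm."""

    worm_id: str
    position: int               # −5 … −1
    integrated_cars: float      # Σ √(I − B), dimensionless
    integrated_gfp: float | None  # Σ (I − B)⁺ counts, None without a GFP channel
    length: float | None = None   # μm
    width: float | None = None    # μm
    volume: float | None = None   # μm³, cylinder model


@dataclass
class CarrierLipidFit:
    """OLS fit of Δ integrated CARS (lipid) on Δ integrated GFP (carrier)."""

    slope: float       # lipid units per GFP unit
    intercept: float   # lipid units; carrier-independent delivery contribution
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class ReproductionAssayRow:
    """One worm of an egg-laying / ovulation assay."""

    worm_id: str
    initial_retained: int
    eggs_laid: int
    final_retained: int
    elapsed: float              # hours
    gonad_arms: int = 2

    def __post_init__(self) -> None:
        if min(self.initial_retained, self.eggs_laid, self.final_retained) < 0:
            raise ValueError("assay counts must be nonnegative")
        if self.elapsed <= 0:
            raise ValueError("elapsed time must be positive")
        if self.gonad_arms < 1:
            raise ValueError("gonad_arms must be >= 1")


@dataclass
class AreaContributionCurve:
    """Binned size-frequency and area-contribution summary of pooled accumulations.

    ``contribution_per_worm[b] = freq_per_worm[b] × midpoint(b)``; its sum
    approximates the mean total accumulation area per worm (exact when every
    pooled area sits on a bin midpoint).
    """

    bin_edges: np.ndarray           # μm², uniform width, length n_bins + 1
    freq_per_worm: np.ndarray       # occurrences · worm⁻¹
    contribution_per_worm: np.ndarray  # μm² · worm⁻¹
    n_worms: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.freq_per_worm = np.asarray(self.freq_per_worm, dtype=float)
        self.contribution_per_worm = np.asarray(self.contribution_per_worm, dtype=float)
        if len(self.bin_edges) != len(self.freq_per_worm) + 1:
            raise ValueError("bin_edges must have one more entry than freq_per_worm")
        if (self.freq_per_worm < 0).any() or (self.contribution_per_worm < 0).any():
            raise ValueError("curve entries must be nonnegative")

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self) -> float:
        """Total of the contribution curve ≈ mean total accumulation area per worm (μm²)."""
        return float(self.contribution_per_worm.sum())

    def fraction_below(self, cutoff: float) -> float:
        """Fraction of the total area contribution from accumulations below ``cutoff`` μm².

        Bins entirely below the cutoff count fully; a straddled bin counts
        pro-rata by the overlapped width.
        """
        total = self.contribution_per_worm.sum()
        if total == 0:
            return 0.0
        lo, hi = self.bin_edges[:-1], self.bin_edges[1:]
        overlap = np.clip((np.minimum(hi, cutoff) - lo) / (hi - lo), 0.0, 1.0)
        return float((self.contribution_per_worm * overlap).sum() / total)
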