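"""Segmentation and size-distribution analysis of secreted yolk-lipoprotein accumulations.

The measurement chain: divide the lipid-band frame by the mean intensity of a
surrounding-buffer ROI (``ratio_image``), keep pixels whose ratio falls inside
the accumulation window (default 1.47–3.12) within the pseudocoelom-eligible
mask, label connected components, and discard components below the detection
limit (default 10 μm²).  Pooled component areas over a cohort are binned into
a per-worm frequency histogram whose product with the bin size gives the
area-contribution curve; its integral approximates the mean total
accumulation area per worm.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .types import AccumulationRecord, AreaContributionCurve, BandFrame, WormImageSet


@dataclass
class AnalysisParams:
    """Ratio-threshold segmentation parameters.

    ratio_low, ratio_high : dimensionless
        Accumulation/buffer intensity-ratio window (default 1.47–3.12).
    min_area : μm²
        Detection limit; smaller components are discarded (default 10).
    bin_width : μm²
        Histogram bin width for the size distribution (default 20).
    connectivity : int
        1 = 4-neighbour, 2 = 8-neighbour component adjacency (default 2, so
        diagonally touching polygon pixels remain one blob).
    """

    ratio_low: float = 1.47
    ratio_high: float = 3.12
    min_area: float = 10.0
    bin_width: float = 20.0
    connectivity: int = 2

    def __post_init__(self) -> None:
        if not (1.0 < self.ratio_low < self.ratio_high):
            raise ValueError("require 1 < ratio_low < ratio_high")
        if self.min_area <= 0 or self.bin_width <= 0:
            raise ValueError("min_area and bin_width must be positive")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 or 2")

    @classmethod
    def from_toml(cls, path) -> "AnalysisParams":
        with open(path, "rb") as fh:
            return cls(**tomllib.load(fh))


def ratio_image(frame: BandFrame, buffer_roi: np.ndarray) -> np.ndarray:
    """Per-pixel intensity divided by the mean intensity of the buffer ROI."""
    buffer_roi = np.asarray(buffer_roi, dtype=bool)
    if buffer_roi.shape != frame.data.shape:
        raise ValueError("buffer ROI and frame must share a shape")
    if not buffer_roi.any():
        raise ValueError("buffer ROI is empty")
    mean_buf = float(frame.data[buffer_roi].mean())
    if mean_buf <= 0:
        raise ValueError("buffer mean must be positive")
    return frame.data.astype(float) / mean_buf


def region_contrast(frame: BandFrame, region: np.ndarray, buffer_roi: np.ndarray) -> float:
    """Mean region intensity over mean buffer intensity (blob/buffer contrast)."""
    region = np.asarray(region, dtype=bool)
    buffer_roi = np.asarray(buffer_roi, dtype=bool)
    if not region.any() or not buffer_roi.any():
        raise ValueError("region and buffer ROI must be nonempty")
    mean_buf = float(frame.data[buffer_roi].mean())
    if mean_buf <= 0:
        raise ValueError("buffer mean must be positive")
    return float(frame.data[region].mean()) / mean_buf


def segment_accumulations(ratio: np.ndarray, eligible: np.ndarray,
                          params: AnalysisParams | None = None,
                          pixel_size: float = 1.0, *,
                          intensity: np.ndarray | None = None,
                          worm_id: str = "worm") -> list[AccumulationRecord]:
    """Threshold the ratio raster inside ``eligible`` and extract accumulation components.

    A pixel belongs to an accumulation when its ratio lies in
    ``[ratio_low, ratio_high]``; connected components (8-neighbour by default)
    smaller than ``min_area`` μm² are discarded.  Component areas are pixel
    counts × pixel_size², and ``mean_intensity`` is taken from ``intensity``
    (raw counts) when supplied, else NaN.
    """
    params = params or AnalysisParams()
    ratio = np.asarray(ratio, dtype=float)
    eligible = np.asarray(eligible, dtype=bool)
    if ratio.shape != eligible.shape:
        raise ValueError("ratio raster and eligible mask must share a shape")
    if intensity is not None and np.asarray(intensity).shape != ratio.shape:
        raise ValueError("intensity raster must share the ratio raster's shape")

    binary = (ratio >= params.ratio_low) & (ratio <= params.ratio_high) & eligible
    labeled = measure.label(binary, connectivity=params.connectivity)
    px_area = pixel_size ** 2
    records: list[AccumulationRecord] = []
    cid = 0
    for prop in measure.regionprops(labeled, intensity_image=ratio):
        area = prop.area * px_area
        if area < params.min_area:
            continue
        cid += 1
        coords = prop.coords
        mean_int = (float(np.asarray(intensity, dtype=float)[coords[:, 0], coords[:, 1]].mean())
                    if intensity is not None else math.nan)
        records.append(AccumulationRecord(
            worm_id=worm_id,
            component_id=cid,
            area=float(area),
            mean_intensity=mean_int,
            mean_ratio=float(prop.intensity_mean),
            centroid=(float(prop.centroid[0] * pixel_size),
                      float(prop.centroid[1] * pixel_size)),
        ))
    return records


def analyze_worm(image_set: WormImageSet, params: AnalysisParams | None = None,
                 band: float = 2845.0) -> list[AccumulationRecord]:
    """Full per-worm chain: ratio image at ``band`` → threshold → components."""
    frame = image_set.band(band)
    ratio = ratio_image(frame, image_set.buffer_mask)
    return segment_accumulations(
        ratio, image_set.eligible_mask, params, image_set.pixel_size,
        intensity=frame.data, worm_id=image_set.worm_id,
    )


def total_area(records: list[AccumulationRecord]) -> float:
    """Total accumulation area of one worm in μm² (0 for no accumulations)."""
    return float(sum(r.area for r in records))


def area_contribution(areas, n_worms: int,
                      params: AnalysisParams | None = None) -> AreaContributionCurve:
    """Build the per-worm size-frequency and area-contribution curve.

    ``freq_per_worm`` is the pooled histogram divided by ``n_worms``;
    ``contribution_per_worm`` multiplies each frequency by the bin midpoint.
    """
    params = params or AnalysisParams()
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    areas = np.asarray(list(areas), dtype=float)
    bw = params.bin_width
    top = areas.max() if areas.size else 0.0
    n_bins = max(1, int(math.ceil(top / bw)) + (1 if top % bw == 0 and top > 0 else 0))
    edges = np.arange(n_bins + 1) * bw
    counts, _ = np.histogram(areas, bins=edges)
    freq = counts / float(n_worms)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return AreaContributionCurve(
        bin_edges=edges,
        freq_per_worm=freq,
        contribution_per_worm=freq * mids,
        n_worms=int(n_worms),
    )


def normalized_spectrum(stack: list[BandFrame], region: np.ndarray) -> list[tuple[float, float]]:
    """Mean region intensity per frame normalized to the maximum across frames.

    Frames must be given at strictly increasing wavenumbers (e.g. a sweep over
    2800–3050 cm⁻¹); the returned values lie in (0, 1] with the peak at 1.
    """
    if len(stack) < 2:
        raise ValueError("need at least two frames for a spectrum")
    wns = [f.wavenumber for f in stack]
    if any(b <= a for a, b in zip(wns, wns[1:])):
        raise ValueError("wavenumbers must be strictly increasing")
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("spectrum region is empty")
    means = np.array([float(f.data[region].mean()) for f in stack])
    peak = means.max()
    if peak <= 0:
        raise ValueError("all-zero spectrum region")
    return list(zip(wns, (means / peak).tolist()))
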