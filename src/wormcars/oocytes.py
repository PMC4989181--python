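"""Per-oocyte integrated CARS/GFP signals, carrier–lipid regression and geometry.

The lipid content of one oocyte is the integrated CARS statistic
Σ√(I − B) over the oocyte pixels, where B is the mean intensity of the oocyte
nucleus (the non-lipid cellular background) and negative differences are
clamped to zero before the square root.  The carrier (GFP-tagged yolk
lipoprotein) content is the plain background-subtracted sum, fluorescence
being linear in fluorophore amount.  Δ signals are referenced to the −5
oocyte, whose carrier signal is essentially undetectable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    OOCYTE_POSITIONS,
    BandFrame,
    CarrierLipidFit,
    OocyteMeasurement,
    WormImageSet,
)


def integrated_cars(frame: BandFrame, oocyte: np.ndarray, nucleus: np.ndarray) -> float:
    """Integrated CARS lipid statistic of one oocyte: Σ √(max(I − B, 0)).

    B is the mean CARS intensity over the nucleus mask, which must be a
    nonempty subset of the oocyte mask.
    """
    oocyte = np.asarray(oocyte, dtype=bool)
    nucleus = np.asarray(nucleus, dtype=bool)
    if not oocyte.any() or not nucleus.any():
        raise ValueError("oocyte and nucleus masks must be nonempty")
    if (nucleus & ~oocyte).any():
        raise ValueError("nucleus mask must be contained in the oocyte mask")
    background = float(frame.data[nucleus].mean())
    diff = frame.data[oocyte].astype(float) - background
    return float(np.sqrt(np.clip(diff, 0.0, None)).sum())


def integrated_gfp(gfp: np.ndarray, oocyte: np.ndarray, gfp_negative: np.ndarray) -> float:
    """Integrated carrier fluorescence: Σ max(I − B, 0) over the oocyte.

    B is the mean fluorescence of the carrier-GFP-negative reference region;
    no square root — fluorescence is linear in carrier amount.
    """
    gfp = np.asarray(gfp, dtype=float)
    oocyte = np.asarray(oocyte, dtype=bool)
    gfp_negative = np.asarray(gfp_negative, dtype=bool)
    if not oocyte.any() or not gfp_negative.any():
        raise ValueError("oocyte and GFP-negative masks must be nonempty")
    background = float(gfp[gfp_negative].mean())
    return float(np.clip(gfp[oocyte] - background, 0.0, None).sum())


def axes_from_mask(mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Length and width (μm) of a mask as extents along its principal axes.

    The orientation comes from the mask's second moments; length and width are
    the pixel-footprint extents projected onto the major and minor axis.  For
    an elliptical mask this recovers the ellipse axes; the estimate is
    invariant under rotation of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if coords.size == 0:
        raise ValueError("mask is empty")
    centered = coords - coords.mean(axis=0)
    cov = np.cov(centered.T) if len(coords) > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    major = evecs[:, np.argmax(evals)]
    minor = evecs[:, np.argmin(evals)]
    proj_major = centered @ major
    proj_minor = centered @ minor
    length = (proj_major.max() - proj_major.min() + 1.0) * pixel_size
    width = (proj_minor.max() - proj_minor.min() + 1.0) * pixel_size
    return (max(length, width), min(length, width))


def oocyte_volume(length: float, width: float) -> float:
    """Cylinder-model oocyte volume: π × length × (width/2)² (μm³)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    return math.pi * length * (width / 2.0) ** 2


def measure_oocytes(image_set: WormImageSet, band: float = 2845.0) -> list[OocyteMeasurement]:
    """Quantify every oocyte present in a worm's label raster."""
    frame = image_set.band(band)
    out: list[OocyteMeasurement] = []
    for pos in OOCYTE_POSITIONS:
        oocyte = image_set.oocyte_mask(pos)
        if not oocyte.any():
            continue
        nucleus = image_set.nucleus_mask(pos)
        cars = integrated_cars(frame, oocyte, nucleus)
        gfp_val = None
        if image_set.gfp is not None and image_set.gfp_negative_mask.any():
            gfp_val = integrated_gfp(image_set.gfp, oocyte, image_set.gfp_negative_mask)
        length, width = axes_from_mask(oocyte, image_set.pixel_size)
        out.append(OocyteMeasurement(
            worm_id=image_set.worm_id, position=pos,
            integrated_cars=cars, integrated_gfp=gfp_val,
            length=length, width=width, volume=oocyte_volume(length, width),
        ))
    return out


def delta_signals(measurements: list[OocyteMeasurement]) -> dict[int, tuple[float, float | None]]:
    """Δ signals of one worm relative to its −5 oocyte.

    Returns position → (ΔCARS, ΔGFP); Δ(−5) ≡ (0, 0).  ΔGFP is None when the
    worm has no GFP channel.
    """
    by_pos = {m.position: m for m in measurements}
    if -5 not in by_pos:
        raise ValueError("worm lacks a -5 oocyte measurement")
    ref = by_pos[-5]
    out: dict[int, tuple[float, float | None]] = {}
    for pos, m in sorted(by_pos.items()):
        dc = m.integrated_cars - ref.integrated_cars
        dg = None
        if m.integrated_gfp is not None and ref.integrated_gfp is not None:
            dg = m.integrated_gfp - ref.integrated_gfp
        out[pos] = (0.0, 0.0 if dg is not None else None) if pos == -5 else (dc, dg)
    return out


def carrier_lipid_fit(delta_gfp, delta_cars) -> CarrierLipidFit:
    """OLS of mean ΔCARS (lipid) on mean ΔGFP (carrier) across oocyte positions."""
    x = np.asarray(delta_gfp, dtype=float)
    y = np.asarray(delta_cars, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matching (ΔGFP, ΔCARS) points")
    if np.allclose(x, x[0]):
        raise ValueError("ΔGFP has zero variance")
    res = stats.linregress(x, y)
    return CarrierLipidFit(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue ** 2))


def normalize_lipid(table: pd.DataFrame, reference: tuple[str, int] = ("N2", -1)) -> pd.DataFrame:
    """Normalize per-(strain, position) lipid means by one reference cell.

    ``table`` needs columns strain, position, mean and (optionally) sem; means
    and sems are divided by the reference mean (default: wild type, −1 oocyte).
    """
    strain, position = reference
    ref_rows = table[(table["strain"] == strain) & (table["position"] == position)]
    if ref_rows.empty:
        raise ValueError(f"reference cell ({strain}, {position}) missing from table")
    ref_mean = float(ref_rows["mean"].iloc[0])
    if ref_mean == 0:
        raise ValueError("reference mean is zero")
    out = table.copy()
    out["mean"] = out["mean"] / ref_mean
    if "sem" in out.columns:
        out["sem"] = out["sem"] / ref_mean
    return out
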