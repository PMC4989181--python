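"""Seeded synthetic worm-image and assay generator.

Renders 512 × 512 multi-band frames (protein 1665, non-resonant 2200 and
lipid 2845 cm⁻¹ plus an optional GFP channel) over a ~141 × 141 μm² field
with ground-truth region labels, so the whole segmentation/quantification
chain can be exercised without real microscopy data.

Scene model (no optics: no PSF, constant non-resonant offsets only):

* a uniform surrounding-buffer background at ``profile.buffer_level`` counts;
* polygonal pseudocoelomic yolk accumulations whose per-blob intensity is
  ``contrast × buffer_level`` with contrast drawn per blob from the strain's
  large/small accumulation statistics;
* circular hypodermal lipid droplets at the LD contrast;
* the oocyte queue (−5…−1) as vertical ellipses with nucleus sub-regions.
  The cytoplasm intensity of oocyte k is chosen so that the integrated CARS
  statistic Σ√(I − B) over the oocyte (B = nucleus mean) equals the profile's
  lipid content at k, i.e. the square-root sum is treated as the quantity
  linear in lipid amount;
* a GFP channel rendering the carrier amount
  max(0, lipid − carrier_offset)/carrier_slope the same way (linear sum);
* multiplicative Gaussian noise with the profile's CV, then quantization and
  clipping to the 12-bit range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import disk, ellipse, polygon

from .presets import OOCYTE_SCALE, StrainProfile, strain_preset
from .types import (
    DN_MAX,
    OOCYTE_POSITIONS,
    BandFrame,
    RegionLabel,
    ReproductionAssayRow,
    WormImageSet,
    nucleus_code,
    oocyte_code,
)

#: raster dimensions and calibration of the rendered field of view
SHAPE = (512, 512)
FIELD_UM = 141.0
PIXEL_SIZE = FIELD_UM / SHAPE[0]          # ≈ 0.2754 μm per pixel edge
PIXEL_AREA = PIXEL_SIZE ** 2              # ≈ 0.0758 μm²

#: nucleus (non-resonant cellular background) counts = factor × buffer_level
NUCLEUS_FACTOR = 1.2
#: GFP channel baseline counts
GFP_BASE = 20.0

#: large/small accumulation class boundary used by the generator only (μm²);
#: the analysis side reports continuous sizes.
LARGE_SMALL_BOUNDARY = 30.0

_BANDS = (1665.0, 2200.0, 2845.0)


@dataclass
class RenderTruth:
    """Ground truth accompanying one rendered worm."""

    blobs: pd.DataFrame           # blob_id, area_um2, px_area, contrast, contrast_realized
    blob_labels: np.ndarray       # int raster, 0 = none, i = blob i
    droplets: pd.DataFrame        # droplet_id, px_area, contrast
    droplet_labels: np.ndarray
    oocytes: pd.DataFrame         # position, lipid (planted, integrated-CARS units),
                                  # lipid_realized (after quantization), carrier,
                                  # length_um, width_um


@dataclass
class RenderResult:
    image_set: WormImageSet
    truth: RenderTruth
    profile: StrainProfile
    seed: int


@dataclass
class BlobField:
    """A single-band frame holding isolated planted blobs (for focused experiments)."""

    frame: BandFrame
    labels: np.ndarray            # int raster, i = blob i, 0 = none
    buffer_mask: np.ndarray
    eligible_mask: np.ndarray
    truth: pd.DataFrame           # blob_id, target_area_um2, px_area, area_um2, contrast


# ---------------------------------------------------------------------------
# geometry helpers


def _trim_to_count(rr: np.ndarray, cc: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``n`` pixels closest to the centroid (preserves convex-blob connectivity)."""
    if rr.size <= n:
        return rr, cc
    d2 = (rr - rr.mean()) ** 2 + (cc - cc.mean()) ** 2
    keep = np.argsort(d2, kind="stable")[:n]
    return rr[keep], cc[keep]


def _convex_polygon_pixels(rng: np.random.Generator, target_px: float,
                           center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a random convex polygon (5–8 vertices) of ``round(target_px)`` pixels.

    The polygon is drawn ~8% oversized and trimmed back to the exact pixel
    count so planted areas are not smeared by rasterization jitter.
    """
    target_n = max(1, int(round(target_px)))
    for _ in range(20):
        pts = rng.normal(size=(12, 2))
        pts *= 0.6 + 0.4 * rng.random((12, 1))
        try:
            hull = ConvexHull(pts)
        except QhullError:      # pragma: no cover - degenerate sample
            continue
        verts = pts[hull.vertices]
        if not (5 <= len(verts) <= 8):
            continue
        scale = np.sqrt(1.08 * target_px / hull.volume)   # 2-D: volume == area
        verts = verts * scale + np.asarray(center)
        rr, cc = polygon(verts[:, 0], verts[:, 1], shape=SHAPE)
        if rr.size >= target_n:
            return _trim_to_count(rr, cc, target_n)
    # fallback: small disk (only for degenerate tiny targets)
    rr, cc = disk(center, max(1.2, np.sqrt(1.3 * target_px / np.pi)), shape=SHAPE)
    return _trim_to_count(rr, cc, target_n)


def _place_blobs(rng: np.random.Generator, region: np.ndarray,
                 areas_px: np.ndarray, margin: int = 2) -> list[tuple[np.ndarray, np.ndarray]]:
    """Place non-overlapping polygons inside ``region``; skipped blobs yield empty arrays."""
    occupied = np.zeros(SHAPE, dtype=bool)
    rows, cols = np.nonzero(region)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for a_px in areas_px:
        placed = False
        for _ in range(60):
            i = rng.integers(rows.size)
            center = (float(rows[i]), float(cols[i]))
            rr, cc = _convex_polygon_pixels(rng, a_px, center)
            if not region[rr, cc].all():
                continue
            # margin check on the dilated footprint
            ok = True
            for dr in range(-margin, margin + 1):
                r2 = np.clip(rr + dr, 0, SHAPE[0] - 1)
                for dc in range(-margin, margin + 1):
                    c2 = np.clip(cc + dc, 0, SHAPE[1] - 1)
                    if occupied[r2, c2].any():
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                occupied[rr, cc] = True
                out.append((rr, cc))
                placed = True
                break
        if not placed:
            out.append((np.empty(0, dtype=int), np.empty(0, dtype=int)))
    return out


def _finish_channel(canvas: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Apply multiplicative noise, quantize and clip to the 12-bit range."""
    img = canvas
    if cv > 0:
        img = img * (1.0 + cv * rng.standard_normal(canvas.shape))
    return np.clip(np.rint(img), 0, DN_MAX).astype(np.uint16)


def _check_saturation(profile: StrainProfile) -> None:
    worst = max(
        profile.acc_contrast_large[0] + 3 * profile.acc_contrast_large[1],
        profile.acc_contrast_small[0] + 3 * profile.acc_contrast_small[1],
        profile.ld_contrast[0] + 3 * profile.ld_contrast[1],
    )
    if worst * profile.buffer_level > DN_MAX:
        raise ValueError(
            f"profile {profile.strain_name!r}: contrast × buffer_level "
            f"({worst:.2f} × {profile.buffer_level:.0f}) would saturate the 12-bit range"
        )


def _sample_contrast(rng: np.random.Generator, mean_sd: tuple[float, float],
                     buffer_level: float) -> float:
    mean, sd = mean_sd
    c = rng.normal(mean, sd) if sd > 0 else mean
    return float(np.clip(c, 1.02, DN_MAX / buffer_level))


# ---------------------------------------------------------------------------
# full worm rendering


def render_worm(profile: StrainProfile | str, seed: int, *,
                texture_amp: float = 0.0, worm_id: str | None = None) -> RenderResult:
    """Render one worm as a :class:`WormImageSet` with ground truth.

    Deterministic for a fixed ``(profile, seed, texture_amp)``.  With
    ``texture_amp > 0`` a smooth multiplicative texture, shared between the
    protein and lipid bands, is painted inside each accumulation; it models
    the internal structure responsible for the per-pixel band co-localization
    and is off by default so noiseless renders stay piecewise-uniform.
    """
    if isinstance(profile, str):
        profile = strain_preset(profile)
    _check_saturation(profile)
    rng = np.random.default_rng(seed)
    buf = profile.buffer_level
    nuc_level = round(NUCLEUS_FACTOR * buf)

    labels = np.zeros(SHAPE, dtype=np.uint8)
    base = {wn: np.full(SHAPE, buf, dtype=float) for wn in _BANDS}
    gfp = np.full(SHAPE, GFP_BASE, dtype=float)

    def paint(mask_idx, mult_by_band):
        for wn, m in mult_by_band.items():
            base[wn][mask_idx] = buf * m

    # static anatomy -------------------------------------------------------
    body = np.zeros(SHAPE, dtype=bool)
    body[:6, :] = body[-6:, :] = True
    body[:, :6] = body[:, -6:] = True
    labels[body] = RegionLabel.BODY_WALL
    paint(body, {1665.0: 1.25, 2200.0: 1.1, 2845.0: 1.3})

    hypo = np.zeros(SHAPE, dtype=bool)
    hypo[8:48, 8:504] = True
    labels[hypo] = RegionLabel.HYPODERMIS
    paint(hypo, {1665.0: 1.1, 2200.0: 1.05, 2845.0: 1.15})

    intest = np.zeros(SHAPE, dtype=bool)
    intest[320:372, 20:300] = True
    labels[intest] = RegionLabel.INTESTINE
    paint(intest, {1665.0: 2.0, 2200.0: 1.2, 2845.0: 2.2})

    emb_rr, emb_cc = ellipse(346, 350, 24, 28, shape=SHAPE)
    labels[emb_rr, emb_cc] = RegionLabel.EMBRYO
    for wn, m in {1665.0: 1.7, 2200.0: 1.15, 2845.0: 1.8}.items():
        base[wn][emb_rr, emb_cc] = buf * m

    pseudo = np.zeros(SHAPE, dtype=bool)
    pseudo[390:502, 10:502] = True
    labels[pseudo] = RegionLabel.PSEUDOCOELOM

    labels[60:110, 420:500] = RegionLabel.BUFFER
    labels[130:180, 420:500] = RegionLabel.GFP_NEGATIVE

    # pseudocoelomic accumulations ----------------------------------------
    n_blobs = int(rng.poisson(profile.acc_count_mean))
    areas_um2 = np.clip(
        rng.lognormal(profile.acc_size_logmean, profile.acc_size_logsd, size=n_blobs),
        5.0, 300.0,
    )
    placements = _place_blobs(rng, pseudo, areas_um2 / PIXEL_AREA)
    blob_labels = np.zeros(SHAPE, dtype=np.int32)
    blob_rows = []
    bid = 0
    for target_area, (rr, cc) in zip(areas_um2, placements):
        if rr.size == 0:
            continue
        bid += 1
        which = (profile.acc_contrast_large if target_area >= LARGE_SMALL_BOUNDARY
                 else profile.acc_contrast_small)
        c = _sample_contrast(rng, which, buf)
        blob_labels[rr, cc] = bid
        value = c * buf
        base[2845.0][rr, cc] = value
        base[1665.0][rr, cc] = buf * (1.0 + 0.8 * (c - 1.0))
        base[2200.0][rr, cc] = buf * 1.05
        if texture_amp > 0:
            tex = 1.0 + texture_amp * rng.standard_normal(rr.size)
            base[2845.0][rr, cc] *= tex
            base[1665.0][rr, cc] *= tex
        blob_rows.append({
            "blob_id": bid,
            "px_area": int(rr.size),
            "area_um2": rr.size * PIXEL_AREA,
            "target_area_um2": float(target_area),
            "contrast": c,
            "contrast_realized": round(value) / buf,
        })

    # hypodermal lipid droplets -------------------------------------------
    n_ld = int(rng.poisson(profile.ld_count_mean))
    droplet_labels = np.zeros(SHAPE, dtype=np.int32)
    ld_rows = []
    hypo_free = hypo.copy()
    did = 0
    for _ in range(n_ld):
        r_px = rng.uniform(2.0, 5.0)
        for _ in range(40):
            r0 = rng.uniform(10 + r_px, 46 - r_px)
            c0 = rng.uniform(10 + r_px, 502 - r_px)
            rr, cc = disk((r0, c0), r_px, shape=SHAPE)
            if hypo_free[rr, cc].all():
                did += 1
                c = _sample_contrast(rng, profile.ld_contrast, buf)
                droplet_labels[rr, cc] = did
                base[2845.0][rr, cc] = c * buf
                base[1665.0][rr, cc] = buf * (1.0 + 0.3 * (c - 1.0))
                base[2200.0][rr, cc] = buf * 1.1
                hypo_free[rr, cc] = False
                ld_rows.append({"droplet_id": did, "px_area": int(rr.size), "contrast": c})
                break

    # oocyte queue ---------------------------------------------------------
    L1 = max(10.0, rng.normal(*profile.oocyte_length_dist))
    W1 = max(5.0, rng.normal(*profile.oocyte_width_dist))
    oo_rows = []
    x_cursor = 40.0
    gap = 8.0
    for pos in OOCYTE_POSITIONS:
        s = OOCYTE_SCALE[pos]
        length, width = s * L1, s * W1
        a = (length / 2.0) / PIXEL_SIZE       # semi-axis along rows
        b = (width / 2.0) / PIXEL_SIZE
        cy, cx = 200.0, x_cursor + b
        x_cursor += 2 * b + gap
        rr, cc = ellipse(cy, cx, a, b, shape=SHAPE)
        labels[rr, cc] = oocyte_code(pos)
        nr, nc = disk((cy, cx), max(2.0, 0.25 * b), shape=SHAPE)
        labels[nr, nc] = nucleus_code(pos)

        cyt = labels == oocyte_code(pos)
        n_cyt = int(cyt.sum())
        lipid = profile.oocyte_lipid_profile[pos] * profile.lipid_unit
        s_px = lipid / n_cyt                               # per-pixel √counts
        cyt_value = nuc_level + s_px ** 2
        if cyt_value > DN_MAX:
            raise ValueError("oocyte lipid rendering would saturate the 12-bit range")
        base[2845.0][cyt] = cyt_value
        base[2845.0][nr, nc] = nuc_level
        base[1665.0][cyt] = nuc_level + 0.4 * s_px ** 2
        base[1665.0][nr, nc] = nuc_level
        base[2200.0][cyt] = nuc_level
        base[2200.0][nr, nc] = nuc_level

        carrier = max(0.0, (lipid - profile.carrier_offset * profile.lipid_unit)
                      / profile.carrier_slope)
        gfp[cyt] = GFP_BASE + carrier / n_cyt
        # realized content after quantization of the noiseless cytoplasm value
        lipid_realized = n_cyt * np.sqrt(max(0.0, round(cyt_value) - nuc_level))
        oo_rows.append({
            "position": pos, "lipid": lipid, "lipid_realized": lipid_realized,
            "carrier": carrier, "length_um": length, "width_um": width,
            "n_cytoplasm_px": n_cyt,
        })

    # noise / quantization -------------------------------------------------
    cv = profile.noise_cv
    frames = {
        wn: BandFrame(wn, _finish_channel(base[wn], cv, rng), PIXEL_SIZE)
        for wn in _BANDS
    }
    gfp_img = _finish_channel(gfp, cv, rng)

    wid = worm_id if worm_id is not None else f"{profile.strain_name}:{seed}"
    image_set = WormImageSet(bands=frames, labels=labels, pixel_size=PIXEL_SIZE,
                             gfp=gfp_img, worm_id=wid)
    truth = RenderTruth(
        blobs=pd.DataFrame(blob_rows),
        blob_labels=blob_labels,
        droplets=pd.DataFrame(ld_rows),
        droplet_labels=droplet_labels,
        oocytes=pd.DataFrame(oo_rows),
    )
    return RenderResult(image_set=image_set, truth=truth, profile=profile, seed=seed)


# ---------------------------------------------------------------------------
# focused blob fields (detection-limit and contrast-recovery experiments)


def render_blob_field(profile: StrainProfile | str, *, kind: str = "large",
                      areas_um2=None, n_blobs: int | None = None,
                      contrast_sd: float | None = None,
                      noise_cv: float | None = None, seed: int = 0) -> BlobField:
    """Render a frame of isolated blobs at one contrast class on a buffer background.

    Parameters
    ----------
    kind : {"large", "small", "ld"}
        Which preset contrast statistics to use.
    areas_um2 : sequence of float, optional
        Planted blob areas; defaults to sampling ``n_blobs`` from the preset
        size distribution (or small droplet sizes for ``kind="ld"``).
    contrast_sd : float, optional
        Override the preset contrast SD (0 pins every blob at the mean).
    noise_cv : float, optional
        Override the preset multiplicative-noise CV.
    """
    if isinstance(profile, str):
        profile = strain_preset(profile)
    _check_saturation(profile)
    rng = np.random.default_rng(seed)
    buf = profile.buffer_level
    cv = profile.noise_cv if noise_cv is None else noise_cv

    mean_sd = {"large": profile.acc_contrast_large,
               "small": profile.acc_contrast_small,
               "ld": profile.ld_contrast}[kind]
    if contrast_sd is not None:
        mean_sd = (mean_sd[0], contrast_sd)

    if areas_um2 is None:
        n = 12 if n_blobs is None else int(n_blobs)
        if kind == "ld":
            areas_um2 = np.pi * rng.uniform(0.6, 1.4, size=n) ** 2   # μm radius
        else:
            areas_um2 = np.clip(
                rng.lognormal(profile.acc_size_logmean, profile.acc_size_logsd, size=n),
                5.0, 300.0)
    areas_um2 = np.asarray(areas_um2, dtype=float)

    canvas = np.full(SHAPE, buf, dtype=float)
    buffer_mask = np.zeros(SHAPE, dtype=bool)
    buffer_mask[8:58, 8:88] = True
    region = np.ones(SHAPE, dtype=bool)
    region[:8, :] = region[-8:, :] = region[:, :8] = region[:, -8:] = False
    region[:68, :98] = False          # keep clear of the buffer ROI

    placements = _place_blobs(rng, region, areas_um2 / PIXEL_AREA, margin=3)
    labels = np.zeros(SHAPE, dtype=np.int32)
    rows = []
    for i, (target, (rr, cc)) in enumerate(zip(areas_um2, placements), start=1):
        if rr.size == 0:
            warnings.warn(f"blob {i} (target {target:.1f} um^2) could not be placed")
            continue
        c = _sample_contrast(rng, mean_sd, buf)
        labels[rr, cc] = i
        canvas[rr, cc] = c * buf
        rows.append({"blob_id": i, "target_area_um2": float(target),
                     "px_area": int(rr.size), "area_um2": rr.size * PIXEL_AREA,
                     "contrast": c})

    frame = BandFrame(2845.0, _finish_channel(canvas, cv, rng), PIXEL_SIZE)
    return BlobField(frame=frame, labels=labels, buffer_mask=buffer_mask,
                     eligible_mask=region, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# reproduction assay simulation


def simulate_reproduction(profile: StrainProfile | str, n_worms: int,
                          elapsed: float = 6.0, seed: int = 0,
                          gonad_arms: int = 2) -> list[ReproductionAssayRow]:
    """Simulate one ovulation assay cohort.

    Each worm ovulates ``Poisson(rate × arms × elapsed)`` new oocytes over the
    assay window; a fraction of the newly ovulated eggs is laid on the plate
    and the rest is retained, so laid + (final − initial) recovers the new
    ovulations exactly.
    """
    if isinstance(profile, str):
        profile = strain_preset(profile)
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if elapsed <= 0:
        raise ValueError("elapsed must be positive")
    rng = np.random.default_rng(seed)
    rate = profile.ovulation_rate_true
    rows = []
    for i in range(n_worms):
        initial = int(rng.poisson(12.0))
        new = int(rng.poisson(rate * gonad_arms * elapsed))
        laid = int(rng.binomial(new, 0.85)) if new else 0
        rows.append(ReproductionAssayRow(
            worm_id=f"{profile.strain_name}:{i}",
            initial_retained=initial,
            eggs_laid=laid,
            final_retained=initial + new - laid,
            elapsed=float(elapsed),
            gonad_arms=gonad_arms,
        ))
    return rows


def simulate_egg_numbers(profile: StrainProfile | str, n_worms: int,
                         seed: int = 0) -> np.ndarray:
    """Simulate lifetime egg numbers (Poisson around the strain mean)."""
    if isinstance(profile, str):
        profile = strain_preset(profile)
    rng = np.random.default_rng(seed)
    return rng.poisson(profile.egg_number_mean, size=n_worms)
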