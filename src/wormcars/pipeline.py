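"""Closed-loop recovery experiments: render synthetic worms, then measure them.

Each experiment plants a known quantity through the generator and recovers it
through the same analysis chain a microscopist would run on real frames
(ratio image → threshold → components, or mask → integrated signal).  They
back both the acceptance checks and the worked examples in the README.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import accumulation as acq
from . import oocytes as ooq
from . import reproduction as rep
from . import stats as st
from .accumulation import AnalysisParams
from .presets import strain_preset
from .synthetic import (
    render_blob_field,
    render_worm,
    simulate_egg_numbers,
    simulate_reproduction,
)
from .types import OOCYTE_POSITIONS


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# detection limit


def detection_limit(seed: int = 0, *, n_seeds: int = 20,
                    areas_um2=None, detect_frac: float = 0.95,
                    noise_cv: float = 0.05,
                    params: AnalysisParams | None = None) -> float:
    """Smallest planted area (μm²) detected in ≥ ``detect_frac`` of instances.

    Frames carry one blob per area on the grid (default 2–40 μm² in 0.5 μm²
    steps) at the small-accumulation mean contrast with multiplicative pixel
    noise; a blob counts as detected when an accepted component overlaps it.
    The reported limit is the smallest grid area from which detection stays
    above the criterion for every larger grid area.
    """
    params = params or AnalysisParams()
    if areas_um2 is None:
        areas_um2 = np.arange(2.0, 40.0 + 1e-9, 0.5)
    areas_um2 = np.asarray(areas_um2, dtype=float)
    hits = np.zeros(areas_um2.size, dtype=int)
    trials = np.zeros(areas_um2.size, dtype=int)
    for s in _subseeds(seed, n_seeds):
        field = render_blob_field("N2", kind="small", areas_um2=areas_um2,
                                  contrast_sd=0.0, noise_cv=noise_cv, seed=int(s))
        ratio = acq.ratio_image(field.frame, field.buffer_mask)
        records = acq.segment_accumulations(ratio, field.eligible_mask, params,
                                            field.frame.pixel_size)
        # map accepted components back to planted blobs via pixel overlap
        binary = (ratio >= params.ratio_low) & (ratio <= params.ratio_high) & field.eligible_mask
        from skimage import measure
        labeled = measure.label(binary, connectivity=params.connectivity)
        px_area = field.frame.pixel_area
        accepted = {prop.label for prop in measure.regionprops(labeled)
                    if prop.area * px_area >= params.min_area}
        for _, row in field.truth.iterrows():
            blob_mask = field.labels == row["blob_id"]
            idx = int(np.argmin(np.abs(areas_um2 - row["target_area_um2"])))
            trials[idx] += 1
            overlapping = set(np.unique(labeled[blob_mask])) - {0}
            if overlapping & accepted:
                hits[idx] += 1
    rate = np.where(trials > 0, hits / np.maximum(trials, 1), 0.0)
    ok = rate >= detect_frac
    # smallest area from which detection never drops below the criterion
    limit = areas_um2[-1]
    for i in range(areas_um2.size - 1, -1, -1):
        if not ok[i]:
            break
        limit = areas_um2[i]
    return float(limit)


# ---------------------------------------------------------------------------
# contrast recovery


def contrast_recovery(kind: str, n_blobs: int = 30, seed: int = 0,
                      strain: str = "N2", noise_cv: float = 0.05) -> tuple[float, float]:
    """Mean and SEM of measured blob/buffer ratios for one contrast class.

    ``kind`` is "large", "small" (pseudocoelomic accumulations) or "ld"
    (hypodermal lipid droplets); per-blob contrasts are drawn from the strain
    preset and recovered with :func:`wormcars.accumulation.region_contrast`.
    """
    field = render_blob_field(strain, kind=kind, n_blobs=n_blobs,
                              noise_cv=noise_cv, seed=seed)
    measured = []
    for _, row in field.truth.iterrows():
        mask = field.labels == row["blob_id"]
        measured.append(acq.region_contrast(field.frame, mask, field.buffer_mask))
    measured = np.asarray(measured)
    return float(measured.mean()), float(st.sem(measured))


# ---------------------------------------------------------------------------
# oocyte cohort experiments


def oocyte_cohort(strain: str, n_worms: int, seed: int = 0) -> pd.DataFrame:
    """Render ``n_worms`` worms of one strain and measure every oocyte.

    Returns one row per (worm, position) with the integrated CARS/GFP signals
    and the cylinder-model geometry.
    """
    rows = []
    for s in _subseeds(seed, n_worms):
        result = render_worm(strain, int(s))
        for m in ooq.measure_oocytes(result.image_set):
            rows.append({
                "worm_id": m.worm_id, "strain": strain, "position": m.position,
                "integrated_cars": m.integrated_cars,
                "integrated_gfp": m.integrated_gfp,
                "length_um": m.length, "width_um": m.width, "volume_um3": m.volume,
            })
    return pd.DataFrame(rows)


def lipid_increase_pct(cohort: pd.DataFrame, from_pos: int = -2, to_pos: int = -1) -> float:
    """Percent increase in mean integrated lipid between two queue positions."""
    means = cohort.groupby("position")["integrated_cars"].mean()
    return float(100.0 * (means[to_pos] - means[from_pos]) / means[from_pos])


def mean_volume(cohort: pd.DataFrame, position: int = -1) -> float:
    """Mean cylinder-model volume (μm³) at one queue position."""
    return float(cohort.loc[cohort["position"] == position, "volume_um3"].mean())


def lipid_deficit_pct(cohort_ref: pd.DataFrame, cohort_mut: pd.DataFrame,
                      positions=(-2, -1)) -> float:
    """Percent deficit of a mutant's mean −1/−2 lipid relative to a reference strain."""
    sel_ref = cohort_ref[cohort_ref["position"].isin(positions)]["integrated_cars"].mean()
    sel_mut = cohort_mut[cohort_mut["position"].isin(positions)]["integrated_cars"].mean()
    return float(100.0 * (1.0 - sel_mut / sel_ref))


def carrier_lipid_experiment(n_worms: int = 17, seed: int = 0, strain: str = "N2"):
    """Per-position mean Δ signals across a cohort and their OLS carrier–lipid fit."""
    dcars = {p: [] for p in OOCYTE_POSITIONS if p != -5}
    dgfp = {p: [] for p in OOCYTE_POSITIONS if p != -5}
    for s in _subseeds(seed, n_worms):
        result = render_worm(strain, int(s))
        deltas = ooq.delta_signals(ooq.measure_oocytes(result.image_set))
        for pos, (dc, dg) in deltas.items():
            if pos == -5:
                continue
            dcars[pos].append(dc)
            dgfp[pos].append(dg)
    positions = sorted(dcars)
    x = [float(np.mean(dgfp[p])) for p in positions]
    y = [float(np.mean(dcars[p])) for p in positions]
    return ooq.carrier_lipid_fit(x, y)


# ---------------------------------------------------------------------------
# reproduction


def ovulation_experiment(strain: str, n_worms: int = 200, elapsed: float = 6.0,
                         seed: int = 0) -> float:
    """Mean per-arm ovulation rate recovered from a simulated assay cohort."""
    rows = simulate_reproduction(strain, n_worms, elapsed=elapsed, seed=seed)
    return rep.mean_ovulation_rate(rows)


# ---------------------------------------------------------------------------
# strain survey (metric table for the cross-metric correlations)


def strain_survey(strains, n_worms: int = 6, seed: int = 0) -> pd.DataFrame:
    """Per-strain metric summary across the full pipeline.

    For each strain: total accumulation area (segmentation over rendered
    worms), −1/−2 oocyte lipid content and −1 volume (oocyte quantification),
    ovulation rate (simulated assay), −2→−1 lipid delivery rate, and egg
    number.  One row per (strain, metric) with mean, sem and n.
    """
    seeds = _subseeds(seed, len(strains) * 3).reshape(len(strains), 3)
    rows = []
    for (strain, (s_img, s_rep, s_egg)) in zip(strains, seeds):
        cohort = oocyte_cohort(strain, n_worms, seed=int(s_img))
        totals = []
        for s in _subseeds(int(s_img) + 1, n_worms):
            result = render_worm(strain, int(s))
            totals.append(acq.total_area(acq.analyze_worm(result.image_set)))
        assay = simulate_reproduction(strain, max(20, n_worms), seed=int(s_rep))
        ovul = rep.mean_ovulation_rate(assay)
        eggs = simulate_egg_numbers(strain, max(10, n_worms), seed=int(s_egg))
        lipid = cohort[cohort["position"].isin((-2, -1))]["integrated_cars"]
        vol = cohort[cohort["position"] == -1]["volume_um3"]
        means = cohort.groupby("position")["integrated_cars"].mean()
        delivery = float((means[-1] - means[-2]) * ovul)
        per_worm_lipid = (cohort[cohort["position"].isin((-2, -1))]
                          .groupby("worm_id")["integrated_cars"].mean())
        metric_values = {
            "total_accumulation_area": totals,
            "lipid_content": per_worm_lipid.tolist(),
            "oocyte_size": vol.tolist(),
            "ovulation_rate": [rep.ovulation_rate(r) for r in assay],
            "egg_number": eggs.tolist(),
        }
        for metric, values in metric_values.items():
            rows.append({"strain": strain, "metric": metric,
                         "mean": float(np.mean(values)), "sem": st.sem(values),
                         "n": len(values)})
        rows.append({"strain": strain, "metric": "delivery_rate",
                     "mean": delivery, "sem": float("nan"), "n": n_worms})
        _ = lipid  # pooled per-oocyte values retained for future summaries
    return pd.DataFrame(rows)
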