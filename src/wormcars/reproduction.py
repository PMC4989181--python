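"""Ovulation rate, egg number and per-transition lipid-delivery rates.

The ovulation rate of one assayed worm is
(eggs laid + final retained − initially retained) / (elapsed hours × gonad arms),
in oocytes · arm⁻¹ · h⁻¹.  The inverse of the ovulation rate is the mean
residence time at one queue position, so the lipid delivery rate across the
−n → −(n−1) transition is the lipid-content increment times the ovulation
rate.  Rates telescope: Σ rate × (1/ovulation) over the queue equals
C(−1) − C(−5) exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import ReproductionAssayRow


def ovulation_rate(row: ReproductionAssayRow) -> float:
    """Per-arm hourly ovulation rate of one assayed worm.

    A negative value diagnoses inconsistent assay counts (more oocytes at the
    start than accounted for at the end); it is returned with a warning rather
    than clamped.
    """
    rate = (row.eggs_laid + row.final_retained - row.initial_retained) / (
        row.elapsed * row.gonad_arms)
    if rate < 0:
        warnings.warn(
            f"worm {row.worm_id}: negative ovulation rate {rate:.3f} "
            "(inconsistent assay counts)", stacklevel=2)
    return float(rate)


def mean_ovulation_rate(rows: list[ReproductionAssayRow]) -> float:
    """Cohort mean of per-worm ovulation rates."""
    if not rows:
        raise ValueError("empty assay cohort")
    return float(np.mean([ovulation_rate(r) for r in rows]))


def egg_number(laid_counts) -> int:
    """Lifetime egg number: total laid eggs, hatched plus non-hatched."""
    total = 0
    for hatched, non_hatched in laid_counts:
        if hatched < 0 or non_hatched < 0:
            raise ValueError("egg counts must be nonnegative")
        total += hatched + non_hatched
    return int(total)


def delivery_rates(lipid_by_position: dict[int, float], ovulation: float) -> pd.DataFrame:
    """Per-transition lipid delivery rates from a position-lipid profile.

    rate(−n → −(n−1)) = (C(−(n−1)) − C(−n)) × ovulation rate, in lipid units
    per hour per gonad arm.  Positions must be consecutive.
    """
    if ovulation < 0:
        raise ValueError("ovulation rate must be >= 0")
    positions = sorted(lipid_by_position)
    if len(positions) < 2:
        raise ValueError("need lipid contents at >= 2 consecutive positions")
    if any(b - a != 1 for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be consecutive")
    rows = []
    for a, b in zip(positions, positions[1:]):
        rows.append({
            "from_position": a,
            "to_position": b,
            "rate": (lipid_by_position[b] - lipid_by_position[a]) * ovulation,
        })
    return pd.DataFrame(rows)


def normalize_delivery_rates(table: pd.DataFrame, reference: pd.DataFrame, *,
                             per_transition: bool = True) -> pd.DataFrame:
    """Add a ``normalized_rate`` column relative to a reference strain's rates.

    With ``per_transition=True`` (default) each transition is divided by the
    reference strain's same transition; otherwise every rate is divided by the
    reference −2 → −1 rate.
    """
    out = table.copy()
    if per_transition:
        ref = reference.set_index(["from_position", "to_position"])["rate"]
        idx = pd.MultiIndex.from_frame(out[["from_position", "to_position"]])
        denom = ref.reindex(idx).to_numpy()
        if np.isnan(denom).any():
            raise ValueError("reference table lacks a matching transition")
    else:
        ref_rows = reference[(reference["from_position"] == -2)
                             & (reference["to_position"] == -1)]
        if ref_rows.empty:
            raise ValueError("reference table lacks the -2 -> -1 transition")
        denom = float(ref_rows["rate"].iloc[0])
    out["normalized_rate"] = out["rate"] / denom
    return out
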