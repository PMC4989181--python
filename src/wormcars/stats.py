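"""Cohort summary statistics, group comparisons and cross-metric correlations.

Group means are compared with Welch's two-sided unequal-variance t test (the
robust default across strains with different spreads); Pearson's
product-moment coefficient serves both the strain-level metric correlations
and the per-pixel band co-localization.  No multiple-testing correction is
applied by default; a Bonferroni helper is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import BandFrame

#: metrics expected in strain-level summary tables
METRICS = ("delivery_rate", "ovulation_rate", "lipid_content",
           "oocyte_size", "total_accumulation_area", "egg_number")


def sem(values) -> float:
    """Standard error of the mean: sample SD / √n (needs n ≥ 2)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("SEM needs at least two values")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient r ∈ [−1, 1]."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching samples of length >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)


def band_colocalization(frame_a: BandFrame, frame_b: BandFrame, mask) -> float:
    """Per-pixel Pearson correlation of two band intensities within a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("colocalization mask is empty")
    return pearson(frame_a.data[mask].ravel(), frame_b.data[mask].ravel())


def group_compare(a, b) -> float:
    """Two-sided Welch (unequal-variance) p-value for a difference in means."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.size == b.size and np.array_equal(a, b):
        return 1.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star coding."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def bonferroni(pvalues) -> np.ndarray:
    """Bonferroni-adjusted p-values (optional; no correction is the default)."""
    p = np.asarray(list(pvalues), dtype=float)
    return np.minimum(p * p.size, 1.0)


def correlation_report(summaries: pd.DataFrame, exclude=()) -> pd.DataFrame:
    """Correlate each strain-level metric against egg number.

    ``summaries`` holds one row per (strain, metric) with a ``mean`` column.
    Strains named in ``exclude`` are dropped before computing r (leave-one-out
    re-analysis).  Returns one row per metric with r, n and the scatter data.
    """
    df = summaries[~summaries["strain"].isin(set(exclude))]
    wide = df.pivot(index="strain", columns="metric", values="mean")
    if "egg_number" not in wide.columns:
        raise ValueError("summaries must include an egg_number metric")
    eggs = wide["egg_number"]
    rows = []
    for metric in wide.columns:
        if metric == "egg_number":
            continue
        pair = wide[[metric]].assign(egg_number=eggs).dropna()
        if len(pair) < 3:
            raise ValueError(f"metric {metric!r}: need >= 3 strains, have {len(pair)}")
        rows.append({
            "metric": metric,
            "r": pearson(pair[metric], pair["egg_number"]),
            "n_strains": len(pair),
            "strains": ",".join(pair.index),
        })
    return pd.DataFrame(rows)


def plot_correlations(summaries: pd.DataFrame, path, exclude=()) -> None:
    """Write metric-vs-egg-number scatter panels with r annotations to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = correlation_report(summaries, exclude=exclude)
    df = summaries[~summaries["strain"].isin(set(exclude))]
    wide = df.pivot(index="strain", columns="metric", values="mean")
    metrics = report["metric"].tolist()
    fig, axes = plt.subplots(1, len(metrics), figsize=(3.2 * len(metrics), 3.2))
    axes = np.atleast_1d(axes)
    for ax, metric in zip(axes, metrics):
        pair = wide[[metric, "egg_number"]].dropna()
        ax.scatter(pair[metric], pair["egg_number"], s=30)
        r = float(report.loc[report["metric"] == metric, "r"].iloc[0])
        ax.set_xlabel(metric)
        ax.set_ylabel("egg number")
        ax.set_title(f"r = {r:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
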