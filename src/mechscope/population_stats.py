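"""Population statistics: Gaussian-fitted histograms and group comparison.

The Gaussian "fit" is the maximum-likelihood fit on the raw per-cell values
(mu = sample mean, sigma = sample SD), which makes the result independent of
the histogram binning; the histogram overlay curve is a rendering of that
fit scaled by n * bin width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["PopulationSummary", "ComparisonReport", "summarize", "compare_groups", "overlay_curve"]


@dataclass(frozen=True)
class PopulationSummary:
    label: str
    n: int
    mean: float
    sd: float
    mu: float
    sigma: float
    bin_edges: tuple
    counts: tuple
    degenerate: bool = False  # all values equal -> sigma 0

    @property
    def values_range(self) -> tuple[float, float]:
        return (self.bin_edges[0], self.bin_edges[-1])


@dataclass(frozen=True)
class ComparisonReport:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    difference: float  # mean_b - mean_a
    ordering: str  # e.g. "typeB > typeA", or "no ordering"
    p_value: float  # rank-based (Mann-Whitney U), descriptive only


def summarize(values, label: str = "", bins: int = 10) -> PopulationSummary:
    """Summarize per-cell aggregates with an MLE Gaussian fit and histogram."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values to summarize, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    mu = mean  # Gaussian MLE
    sigma = float(np.std(arr, ddof=0))
    degenerate = sigma == 0.0
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:  # all equal: a single degenerate bin around the value
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(arr, bins=bins, range=(lo, hi))
    return PopulationSummary(
        label=label,
        n=int(arr.size),
        mean=mean,
        sd=sd,
        mu=mu,
        sigma=sigma,
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        degenerate=degenerate,
    )


def overlay_curve(summary: PopulationSummary, n_points: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian overlay scaled to histogram counts (n * bin width * pdf)."""
    edges = np.asarray(summary.bin_edges)
    x = np.linspace(edges[0], edges[-1], n_points)
    binwidth = float(edges[1] - edges[0])
    if summary.degenerate or summary.sigma == 0:
        y = np.zeros_like(x)
    else:
        y = summary.n * binwidth * sstats.norm.pdf(x, summary.mu, summary.sigma)
    return x, y


def compare_groups(a: PopulationSummary, b: PopulationSummary, values_a=None, values_b=None) -> ComparisonReport:
    """Descriptive comparison of two populations.

    Reports the difference of means and the direction of ordering, plus a
    rank-based (Mann-Whitney U) descriptive p-value when the raw values are
    supplied.  No decision threshold is applied: the ordering claim is
    whichever mean is larger, "no ordering" on an exact tie.
    """
    diff = b.mean - a.mean
    if diff > 0:
        ordering = f"{b.label} > {a.label}"
    elif diff < 0:
        ordering = f"{a.label} > {b.label}"
    else:
        ordering = "no ordering"
    p = float("nan")
    if values_a is not None and values_b is not None:
        va = np.asarray(list(values_a), dtype=float)
        vb = np.asarray(list(values_b), dtype=float)
        if va.size and vb.size and not (np.all(va == va[0]) and np.all(vb == vb[0]) and va[0] == vb[0]):
            p = float(sstats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
    return ComparisonReport(
        label_a=a.label,
        label_b=b.label,
        mean_a=a.mean,
        mean_b=b.mean,
        difference=float(diff),
        ordering=ordering,
        p_value=p,
    )
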