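"""Descriptive statistics of a WQI vector and class-share summaries.

The block of statistics mirrors the spreadsheet "Descriptive Statistics"
toolpak output (mean, standard error, median, standard deviation, sample
variance, range, min, max, sum, 95% confidence half-width) plus a set of
percentiles computed by linear interpolation with inclusive endpoints —
the spreadsheet convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sps

from .wqi_core import CLASS_LABELS, WQIResult, classify_wqi

__all__ = ["SummaryStats", "describe", "class_shares", "format_summary"]

QUANTILE_LEVELS = (10, 25, 50, 75, 90, 95)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    se: float
    median: float
    sd: float
    variance: float
    range: float
    min: float
    max: float
    sum: float
    ci95_halfwidth: float
    quantiles: Mapping[int, float]

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "mean": self.mean,
            "standard_error": self.se,
            "median": self.median,
            "standard_deviation": self.sd,
            "sample_variance": self.variance,
            "range": self.range,
            "minimum": self.min,
            "maximum": self.max,
            "sum": self.sum,
            "confidence_level_95": self.ci95_halfwidth,
        }
        d["quantiles"] = {f"{q}%": v for q, v in self.quantiles.items()}
        return d


def describe(values: Iterable[float]) -> SummaryStats:
    """Descriptive statistics of a WQI vector (n >= 2, values >= 0).

    Sample variance uses the n-1 denominator; the 95% confidence half-width
    is ``t_{0.975, n-1} * sd / sqrt(n)``; percentiles interpolate linearly
    between order statistics.
    """
    x = np.asarray(list(values), dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"describe needs at least 2 values, got {x.size}")
    if np.isnan(x).any():
        raise ValueError("describe: input contains NaN")
    if (x < 0).any():
        raise ValueError("describe: WQI values must be >= 0")
    n = int(x.size)
    sd = float(np.std(x, ddof=1))
    se = sd / np.sqrt(n)
    quantiles = {
        q: float(v)
        for q, v in zip(QUANTILE_LEVELS, np.percentile(x, QUANTILE_LEVELS, method="linear"))
    }
    return SummaryStats(
        n=n,
        mean=float(np.mean(x)),
        se=se,
        median=float(np.median(x)),
        sd=sd,
        variance=sd**2,
        range=float(x.max() - x.min()),
        min=float(x.min()),
        max=float(x.max()),
        sum=float(x.sum()),
        ci95_halfwidth=float(sps.t.ppf(0.975, n - 1) * se),
        quantiles=quantiles,
    )


def class_shares(results: Iterable[WQIResult | float | str]) -> dict[str, float]:
    """Share of each quality class; every label present, shares sum to 1.

    Accepts WQIResult objects, raw WQI numbers, or class labels.
    """
    counts = {label: 0 for label in CLASS_LABELS}
    total = 0
    for item in results:
        if isinstance(item, WQIResult):
            label = item.class_label
        elif isinstance(item, str):
            if item not in counts:
                raise ValueError(f"unknown class label {item!r}")
            label = item
        else:
            label = classify_wqi(float(item))
        counts[label] += 1
        total += 1
    if total == 0:
        raise ValueError("class_shares: empty input")
    return {label: c / total for label, c in counts.items()}


def format_summary(stats: SummaryStats, shares: Mapping[str, float] | None = None) -> str:
    """Render the descriptive-statistics block as aligned text."""
    rows = [
        ("Mean", stats.mean),
        ("Standard Error", stats.se),
        ("Median", stats.median),
        ("Standard Deviation", stats.sd),
        ("Sample Variance", stats.variance),
        ("Range", stats.range),
        ("Minimum", stats.min),
        ("Maximum", stats.max),
        ("Sum", stats.sum),
        ("Confidence Level (95.0%)", stats.ci95_halfwidth),
    ]
    width = max(len(k) for k, _ in rows)
    lines = [f"n = {stats.n}"]
    lines += [f"{k:<{width}}  {v:.2f}" for k, v in rows]
    lines.append("")
    lines.append("Quantile%   WQI")
    lines += [f"{q:>8}    {v:.3f}" for q, v in stats.quantiles.items()]
    if shares is not None:
        lines.append("")
        lines.append("Class shares")
        w = max(len(k) for k in shares)
        lines += [f"{k:<{w}}  {v:6.1%}" for k, v in shares.items()]
    return "\n".join(lines)
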