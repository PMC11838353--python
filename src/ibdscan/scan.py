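"""Hypothesis testing along the grid, region calling, and diagnostics.

The per-position test rejects the neutral null where the standardized IBD
rate strictly exceeds the multiple-testing quantile z_star (values equal
to the threshold go to the null).  Significant results are reported as
contiguous stretches of rejected grid points at least ``min_span_cm``
long, with the peak rate, its position, and an upper-tail normal p value
(flagged "underflow" when it is not representable in double precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .standardize import ZTrack

__all__ = [
    "SignificantRegion",
    "test_positions",
    "call_regions",
    "max_min_statistic",
    "count_significant_windows",
    "regions_to_frame",
    "plot_scan",
]

UNDERFLOW = "underflow"


@dataclass(frozen=True)
class SignificantRegion:
    """A contiguous stretch of grid points rejecting the null."""

    chrom: str
    span_cm: float            # genetic distance between first and last point
    start_bp: float
    end_bp: float
    peak_bp: float            # position of the maximum rate in the stretch
    peak_rate: float
    peak_z: float
    p_value: float | str      # 1 - Phi(peak_z), or "underflow"


def test_positions(ztrack: ZTrack, z_star: float) -> np.ndarray:
    """Per-position reject calls: True where z > z_star (strict)."""
    return ztrack.z > z_star


def call_regions(
    ztrack: ZTrack,
    calls: np.ndarray,
    min_span_cm: float = 0.5,
) -> list[SignificantRegion]:
    """Collect maximal runs of rejections into reported regions.

    A run of r consecutive rejected points spans ``(r-1)*Delta`` cM; only
    runs with span >= ``min_span_cm`` are reported.  No gap-merging: a
    single sub-threshold point splits a region.  The p value at the peak
    is the upper normal tail at the peak's z; exact zero in double
    precision is reported as the marker string "underflow".
    """
    calls = np.asarray(calls, dtype=bool)
    if calls.shape != ztrack.z.shape:
        raise ValueError("calls do not match the track's grid")
    delta = ztrack.grid.delta_cm
    regions: list[SignificantRegion] = []
    for chrom, (a, b) in ztrack.grid.offsets.items():
        c = calls[a:b]
        if not c.any():
            continue
        # run boundaries from the diff of the padded indicator
        edges = np.flatnonzero(np.diff(np.concatenate(([0], c.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            span = (stop - start - 1) * delta
            if span < min_span_cm:
                continue
            seg = slice(a + start, a + stop)
            peak = int(np.argmax(ztrack.rates[seg])) + a + start
            peak_z = float(ztrack.z[peak])
            p = float(norm.sf(peak_z))
            regions.append(
                SignificantRegion(
                    chrom=chrom,
                    span_cm=float(span),
                    start_bp=float(ztrack.grid.bp[a + start]),
                    end_bp=float(ztrack.grid.bp[a + stop - 1]),
                    peak_bp=float(ztrack.grid.bp[peak]),
                    peak_rate=float(ztrack.rates[peak]),
                    peak_z=peak_z,
                    p_value=p if p > 0.0 else UNDERFLOW,
                )
            )
    return regions


def max_min_statistic(ztrack: ZTrack, window: int = 3) -> float:
    """Genome-wide max of per-position windowed minima.

    ``window=1`` is the plain maximum of the standardized track.
    ``window=3`` replaces each value with min(z_{m-1}, z_m, z_{m+1})
    before taking the maximum, which suppresses isolated one-point
    spikes; chromosome-edge points use only in-chromosome neighbors.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return float(np.max(ztrack.z))
    half = window // 2
    best = -math.inf
    for _chrom, (a, b) in ztrack.grid.offsets.items():
        z = ztrack.z[a:b]
        n = z.size
        mins = np.empty(n)
        for i in range(n):
            lo = max(0, i - half)
            hi = min(n, i + half + 1)
            mins[i] = z[lo:hi].min()
        best = max(best, float(mins.max()))
    return best


def count_significant_windows(
    calls: np.ndarray,
    grid,
    window_cm: float,
) -> int:
    """Number of non-overlapping windows containing >= 1 rejection.

    Each chromosome is partitioned into consecutive windows of
    ``window_cm``, anchored at its first grid point.
    """
    if window_cm < grid.delta_cm:
        raise ValueError("window_cm must be at least the grid spacing")
    calls = np.asarray(calls, dtype=bool)
    total = 0
    for _chrom, (a, b) in grid.offsets.items():
        c = calls[a:b]
        if not c.any():
            continue
        rel_cm = grid.cm[a:b] - grid.cm[a]
        win_idx = np.floor(rel_cm / window_cm + 1e-9).astype(int)
        total += len(np.unique(win_idx[c]))
    return total


def regions_to_frame(regions: list[SignificantRegion],
                     dataset: str = "") -> pd.DataFrame:
    """Region report mirroring the published scan tables.

    Columns: dataset, chrom, max rate, region size (cM), peak position
    (Mb), span (Mb), p value (or "underflow").
    """
    rows = []
    for r in regions:
        rows.append(
            {
                "dataset": dataset,
                "chrom": r.chrom,
                "max_rate": r.peak_rate,
                "region_size_cm": r.span_cm,
                "peak_mb": r.peak_bp / 1e6,
                "span_mb": f"{r.start_bp / 1e6:.2f}-{r.end_bp / 1e6:.2f}",
                "p_value": r.p_value,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "dataset", "chrom", "max_rate", "region_size_cm",
            "peak_mb", "span_mb", "p_value",
        ],
    )
    return frame.sort_values("max_rate", ascending=False, ignore_index=True) \
        if len(frame) else frame


def plot_scan(ztrack: ZTrack, thresholds: dict[str, float] | None = None,
              ax=None, rate_scale: float = 1.0):
    """Rate-vs-position scan plot with threshold lines.

    ``thresholds`` maps a label to a rate-scale threshold (e.g. the median,
    the heuristic median + 4 SD, and the analytical and simulation
    thresholds converted back to rates).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(12, 3.5))
    offset = 0.0
    ticks, labels = [], []
    for chrom, (a, b) in ztrack.grid.offsets.items():
        x = ztrack.grid.cm[a:b] - ztrack.grid.cm[a] + offset
        ax.plot(x, ztrack.rates[a:b] * rate_scale, lw=0.5, color="0.3")
        ticks.append(offset + (x[-1] - x[0]) / 2)
        labels.append(str(chrom))
        offset = x[-1] + 1.0
    if thresholds:
        for (label, value), color in zip(
            thresholds.items(), ("tab:blue", "tab:orange", "tab:green", "tab:red")
        ):
            ax.axhline(value * rate_scale, color=color, lw=1.0, label=label)
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("IBD rate")
    return ax
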