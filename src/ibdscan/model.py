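"""Model/results interface to the IBD-rate selection scan.

:class:`IBDScan` bundles a rate track with the scan geometry; ``fit()``
runs robust standardization, OU decay estimation, threshold computation,
and region calling, returning an :class:`IBDScanResults` with the
estimates, the thresholds under every requested correction, and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .maps import GeneticMap, build_grid
from .scan import (
    SignificantRegion,
    call_regions,
    max_min_statistic,
    plot_scan,
    regions_to_frame,
    test_positions,
)
from .segments import RateTrack, SampleInfo, compute_ibd_rates, read_ibd_segments
from .standardize import ThetaFit, ZTrack, estimate_theta, robust_standardize
from .thresholds import (
    HEURISTIC_Z,
    ThresholdResult,
    analytical_quantile,
    bonferroni_quantile,
    heuristic_significance_level,
    simulation_quantile,
)

__all__ = ["IBDScan", "IBDScanResults"]

#: Below this decay rate the analytical approximation is noticeably
#: conservative and the Monte Carlo threshold is preferred.
SIMULATION_RECOMMENDED_THETA = 20.0


class IBDScan:
    """Selection-scan model for an IBD rate track.

    Parameters
    ----------
    track : RateTrack
        IBD rates on a uniform-Delta grid (see
        :func:`ibdscan.segments.compute_ibd_rates`).

    Use :meth:`from_files` to go straight from a segment file and a
    recombination map.
    """

    def __init__(self, track: RateTrack):
        self.track = track

    @classmethod
    def from_files(
        cls,
        segment_path,
        gmap: GeneticMap,
        info: SampleInfo,
        min_cm: float = 2.0,
        delta_cm: float = 0.02,
        trim_cm: float | None = None,
    ) -> "IBDScan":
        """Build the model from a seg file and a genetic map.

        ``trim_cm`` defaults to the segment length threshold ``min_cm``,
        keeping focal positions at least one detectable segment length
        from each chromosome end.
        """
        if trim_cm is None:
            trim_cm = min_cm
        grid = build_grid(gmap, delta_cm=delta_cm, trim_cm=trim_cm)
        segments = read_ibd_segments(segment_path, min_cm=min_cm)
        track = compute_ibd_rates(segments, grid, gmap, info, min_cm=min_cm)
        return cls(track)

    def fit(
        self,
        alpha_fw: float = 0.05,
        methods: tuple[str, ...] = ("analytical", "simulation", "bonferroni"),
        min_region_cm: float = 0.5,
        max_lag_cm: float = 4.0,
        J: int = 2000,
        seed: int = 0,
        primary_method: str = "analytical",
    ) -> "IBDScanResults":
        """Standardize, estimate theta, compute thresholds, call regions."""
        ztrack = robust_standardize(self.track)
        theta_fit = estimate_theta(ztrack, max_lag_cm=max_lag_cm)
        theta = theta_fit.theta_hat
        grid = self.track.grid
        thresholds: dict[str, ThresholdResult] = {}
        for method in methods:
            if method == "analytical":
                thresholds[method] = analytical_quantile(
                    alpha_fw, theta, grid.L_morgans, grid.C, grid.delta_morgans
                )
            elif method == "simulation":
                thresholds[method] = simulation_quantile(
                    alpha_fw, theta, grid.L_morgans, grid.delta_morgans,
                    J=J, seed=seed,
                )
            elif method == "bonferroni":
                thresholds[method] = bonferroni_quantile(alpha_fw, grid.M)
            else:
                raise ValueError(f"unknown threshold method {method!r}")
        if primary_method not in thresholds:
            raise ValueError(
                f"primary_method {primary_method!r} not among computed methods"
            )
        calls = test_positions(ztrack, thresholds[primary_method].z_star)
        regions = call_regions(ztrack, calls, min_span_cm=min_region_cm)
        return IBDScanResults(
            model=self,
            ztrack=ztrack,
            theta_fit=theta_fit,
            thresholds=thresholds,
            primary_method=primary_method,
            calls=calls,
            regions=regions,
            alpha_fw=alpha_fw,
            min_region_cm=min_region_cm,
        )


@dataclass
class IBDScanResults:
    """Fitted scan: standardized track, theta, thresholds, regions."""

    model: IBDScan
    ztrack: ZTrack
    theta_fit: ThetaFit
    thresholds: dict[str, ThresholdResult]
    primary_method: str
    calls: np.ndarray
    regions: list[SignificantRegion] = field(default_factory=list)
    alpha_fw: float = 0.05
    min_region_cm: float = 0.5

    @property
    def theta(self) -> float:
        return self.theta_fit.theta_hat

    def threshold_rate(self, method: str) -> float:
        """A method's quantile converted back to the IBD rate scale."""
        m = self.ztrack.moments
        return m.mu_hat + self.thresholds[method].z_star * m.sigma_hat

    @property
    def heuristic_rate(self) -> float:
        """The legacy median + 4 SD rule on the rate scale."""
        return float(np.median(self.ztrack.rates)) + HEURISTIC_Z * float(
            np.std(self.ztrack.rates, ddof=1)
        )

    def max_min(self, window: int = 3) -> float:
        return max_min_statistic(self.ztrack, window=window)

    def regions_frame(self, dataset: str = "") -> pd.DataFrame:
        return regions_to_frame(self.regions, dataset=dataset)

    def summary(self) -> str:
        grid = self.ztrack.grid
        mom = self.ztrack.moments
        lines = [
            "IBD rate selection scan",
            "=" * 60,
            f"Grid: M={grid.M} tests on C={grid.C} chromosomes, "
            f"Delta={grid.delta_cm} cM, L={grid.L_morgans:.3f} Morgans",
            f"Robust moments: mean={mom.mu_hat:.4g}  SD={mom.sigma_hat:.4g}  "
            f"outliers excluded={mom.n_excluded}",
            f"OU decay: theta_hat={self.theta:.2f} per Morgan "
            f"({self.theta_fit.n_lags_used} lags)",
            "",
            f"Thresholds at family-wise alpha={self.alpha_fw}:",
        ]
        for method, thr in self.thresholds.items():
            tag = " *" if method == self.primary_method else ""
            lines.append(
                f"  {method:<11s} z*={thr.z_star:.4f}  "
                f"alpha*={thr.alpha_star:.3e}{tag}"
            )
        lines.append(
            f"  heuristic   z*={HEURISTIC_Z:.4f}  "
            f"alpha*={heuristic_significance_level():.3e}"
        )
        if self.theta <= SIMULATION_RECOMMENDED_THETA:
            lines.append(
                f"  note: theta_hat <= {SIMULATION_RECOMMENDED_THETA:g}; the "
                "simulation-based threshold is recommended over the analytical one"
            )
        lines.append("")
        lines.append(
            f"Significant regions (>= {self.min_region_cm} cM contiguous, "
            f"{self.primary_method} threshold): {len(self.regions)}"
        )
        for r in self.regions:
            p = r.p_value if isinstance(r.p_value, str) else f"{r.p_value:.3e}"
            lines.append(
                f"  chr{r.chrom}  rate={r.peak_rate:.3e}  "
                f"size={r.span_cm:.2f} cM  peak={r.peak_bp / 1e6:.2f} Mb  p={p}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        thr = {"median": float(np.median(self.ztrack.rates)),
               "heuristic": self.heuristic_rate}
        for method in self.thresholds:
            if method != "bonferroni":
                thr[method] = self.threshold_rate(method)
        return plot_scan(self.ztrack, thresholds=thr, ax=ax)
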