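"""Synthetic null data and family-wise error rate calibration experiments.

Two generators live here.  ``simulate_ou_genome`` draws standardized
tracks directly from the Ornstein-Uhlenbeck null — one independent chain
per chromosome — and is the ground truth against which the threshold
methods' FWER is measured.  ``synthetic_segment_file`` writes a toy
8-column segment file (uniform midpoints, shifted-exponential lengths,
random haplotype pairs) so the full scan pipeline can be exercised end to
end without any external data; it tests plumbing, not population
genetics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .maps import GeneticMap, ScanGrid, build_grid, uniform_map
from .segments import SampleInfo, pair_count
from .standardize import RobustMoments, ZTrack
from .thresholds import (
    ThresholdResult,
    analytical_quantile,
    bonferroni_quantile,
    simulate_ou_chain,
    simulation_quantile,
)

__all__ = [
    "FWERExperiment",
    "FWERReport",
    "simulate_ou_genome",
    "run_fwer_experiment",
    "synthetic_segment_file",
]


def simulate_ou_genome(
    theta: float,
    chrom_lengths_cm: list[float],
    delta_cm: float,
    rng: np.random.Generator,
    grid: ScanGrid | None = None,
    stationary_variance: bool = True,
) -> ZTrack:
    """Draw a standardized null track from the OU model.

    Each chromosome is an independent chain restarted at N(0, 1) with the
    AR(1) transitions of the discretely sampled OU process.  The default
    uses the exactly stationary conditional variance ``1 - exp(-2*theta*Delta)``
    so every marginal is N(0, 1) and the lag-k covariance is exactly
    ``exp(-theta*k*Delta)`` — i.e. a true OU null.  The result is packaged
    as a ZTrack (rates equal to z; identity moments) so downstream testing
    and region calling apply unchanged.  ``grid`` may be supplied to skip
    rebuilding the same geometry across replicates.
    """
    if grid is None:
        gmap = uniform_map(chrom_lengths_cm)
        grid = build_grid(gmap, delta_cm=delta_cm, trim_cm=0.0)
    z = np.empty(grid.M)
    delta_m = delta_cm / 100.0
    for _chrom, (a, b) in grid.offsets.items():
        z[a:b] = simulate_ou_chain(
            theta, delta_m, b - a, rng, stationary_variance=stationary_variance
        )
    moments = RobustMoments(
        initial_threshold=math.inf, mu_hat=0.0, sigma_hat=1.0, n_excluded=0
    )
    return ZTrack(
        grid=grid,
        z=z,
        rates=z.copy(),
        outlier_mask=np.zeros(grid.M, dtype=bool),
        moments=moments,
    )


@dataclass
class FWERExperiment:
    """Configuration of a null-model FWER calibration run."""

    n_replicates: int = 500
    theta: float = 50.0
    chrom_lengths_cm: list[float] = field(default_factory=lambda: [100.0] * 10)
    delta_cm: float = 0.02
    alpha_fw: float = 0.05
    methods: tuple[str, ...] = ("analytical", "simulation", "bonferroni")
    seed: int = 0
    J: int = 2000                  # simulation-threshold replicates
    reestimate_theta: bool = False  # re-fit theta per simulated genome

    def __post_init__(self):
        if self.n_replicates < 100:
            raise ValueError("need at least 100 replicates")
        if any(l <= 0 for l in self.chrom_lengths_cm):
            raise ValueError("chromosome lengths must be positive")
        if not 0 < self.alpha_fw < 0.5:
            raise ValueError("alpha_fw must be in (0, 0.5)")


@dataclass
class FWERReport:
    """Empirical FWER per threshold method."""

    config: FWERExperiment
    thresholds: dict[str, ThresholdResult]
    n_rejecting: dict[str, int]

    @property
    def fwer(self) -> dict[str, float]:
        n = self.config.n_replicates
        return {m: k / n for m, k in self.n_rejecting.items()}

    @property
    def standard_error(self) -> dict[str, float]:
        n = self.config.n_replicates
        return {
            m: math.sqrt(p * (1 - p) / n) for m, p in self.fwer.items()
        }

    def to_json(self, path) -> None:
        payload = {
            "theta": self.config.theta,
            "alpha_fw": self.config.alpha_fw,
            "n_replicates": self.config.n_replicates,
            "delta_cm": self.config.delta_cm,
            "chrom_lengths_cm": list(self.config.chrom_lengths_cm),
            "seed": self.config.seed,
            "methods": {
                m: {
                    "z_star": self.thresholds[m].z_star,
                    "alpha_star": self.thresholds[m].alpha_star,
                    "n_rejecting": self.n_rejecting[m],
                    "fwer": self.fwer[m],
                    "binomial_se": self.standard_error[m],
                }
                for m in self.n_rejecting
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _compute_thresholds(cfg: FWERExperiment,
                        rng: np.random.Generator) -> dict[str, ThresholdResult]:
    L = sum(cfg.chrom_lengths_cm) / 100.0
    C = len(cfg.chrom_lengths_cm)
    delta_m = cfg.delta_cm / 100.0
    M = sum(
        int(math.floor(l / cfg.delta_cm + 1e-9)) + 1 for l in cfg.chrom_lengths_cm
    )
    out: dict[str, ThresholdResult] = {}
    for method in cfg.methods:
        if method == "analytical":
            out[method] = analytical_quantile(cfg.alpha_fw, cfg.theta, L, C, delta_m)
        elif method == "simulation":
            # same transition variance as the null genomes being tested
            out[method] = simulation_quantile(
                cfg.alpha_fw, cfg.theta, L, delta_m, J=cfg.J, rng=rng,
                stationary_variance=True,
            )
        elif method == "bonferroni":
            out[method] = bonferroni_quantile(cfg.alpha_fw, M)
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    return out


def run_fwer_experiment(cfg: FWERExperiment) -> FWERReport:
    """Measure the empirical FWER of each threshold method on OU nulls.

    Thresholds are computed once from the true theta (default) or, with
    ``reestimate_theta``, re-derived per replicate from a theta fitted to
    that replicate's autocovariances.  A replicate counts as rejecting
    under a method iff any grid point's z strictly exceeds the method's
    z_star.
    """
    from .standardize import estimate_theta

    rng = np.random.default_rng(cfg.seed)
    thresholds = _compute_thresholds(cfg, rng)
    n_rejecting = {m: 0 for m in cfg.methods}
    grid = build_grid(uniform_map(cfg.chrom_lengths_cm), delta_cm=cfg.delta_cm,
                      trim_cm=0.0)
    for _rep in range(cfg.n_replicates):
        track = simulate_ou_genome(
            cfg.theta, cfg.chrom_lengths_cm, cfg.delta_cm, rng, grid=grid
        )
        if cfg.reestimate_theta:
            theta_hat = estimate_theta(track).theta_hat
            rep_cfg = FWERExperiment(
                n_replicates=cfg.n_replicates,
                theta=theta_hat,
                chrom_lengths_cm=cfg.chrom_lengths_cm,
                delta_cm=cfg.delta_cm,
                alpha_fw=cfg.alpha_fw,
                methods=cfg.methods,
                J=cfg.J,
            )
            rep_thresholds = _compute_thresholds(rep_cfg, rng)
        else:
            rep_thresholds = thresholds
        zmax = track.z.max()
        for m, thr in rep_thresholds.items():
            if zmax > thr.z_star:
                n_rejecting[m] += 1
    return FWERReport(config=cfg, thresholds=thresholds, n_rejecting=n_rejecting)


def synthetic_segment_file(
    path,
    n_samples: int,
    ploidy: str,
    chrom_lengths_cm: list[float],
    gmap: GeneticMap | None = None,
    mean_rate: float = 1e-3,
    length_scale_cm: float = 3.0,
    min_len_cm: float = 2.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Write a toy 8-column segment file with a target mean IBD rate.

    Segment midpoints are uniform on the genome, lengths are
    ``min_len_cm`` plus an exponential with mean
    ``length_scale_cm - min_len_cm``, and each segment's two haplotypes
    are drawn uniformly without replacement (never the same individual
    for diploids).  The number of segments is chosen so the expected
    coverage at a focal point is ``mean_rate * f(n)``.

    Returns the number of segments written.
    """
    if rng is None:
        rng = np.random.default_rng()
    if length_scale_cm <= min_len_cm:
        raise ValueError("length_scale_cm must exceed the detection threshold")
    info = SampleInfo(n=n_samples, ploidy=ploidy)
    f_n = pair_count(info)
    if gmap is None:
        gmap = uniform_map(chrom_lengths_cm)
    total_cm = sum(chrom_lengths_cm)
    # E[#segments covering a point] ~= n_seg * E[length] / total_cm
    n_seg = int(round(mean_rate * f_n * total_cm / length_scale_cm))
    if n_seg < 1:
        raise ValueError(
            "requested mean_rate implies fewer than one segment; "
            "increase mean_rate or the sample size"
        )
    chrom_names = gmap.chromosomes
    probs = np.array(chrom_lengths_cm) / total_cm
    n_hap = 2 * n_samples if ploidy == "diploid" else n_samples
    written = 0
    with open(path, "w") as fh:
        for _ in range(n_seg):
            ci = rng.choice(len(chrom_names), p=probs)
            chrom = chrom_names[ci]
            length = min_len_cm + rng.exponential(length_scale_cm - min_len_cm)
            mid = rng.uniform(0, chrom_lengths_cm[ci])
            lo_cm = max(0.0, mid - length / 2)
            hi_cm = min(chrom_lengths_cm[ci], mid + length / 2)
            start_bp = gmap.interpolate(chrom, lo_cm, "cm_to_bp")
            end_bp = gmap.interpolate(chrom, hi_cm, "cm_to_bp")
            while True:
                ha, hb = rng.integers(0, n_hap, size=2)
                if ploidy == "diploid":
                    if ha // 2 != hb // 2:
                        break
                elif ha != hb:
                    break
            if ploidy == "diploid":
                s1, h1 = f"s{ha // 2}", 1 + ha % 2
                s2, h2 = f"s{hb // 2}", 1 + hb % 2
            else:
                s1, h1, s2, h2 = f"s{ha}", 1, f"s{hb}", 1
            fh.write(
                f"{s1}\t{h1}\t{s2}\t{h2}\t{chrom}\t{start_bp:.0f}\t"
                f"{end_bp:.0f}\t{hi_cm - lo_cm:.4f}\n"
            )
            written += 1
    return written
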