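"""Robust standardization of the rate track and estimation of the
Ornstein-Uhlenbeck decay parameter.

Strong selection produces rate outliers (the LCT region can sit tens of
standard deviations above the genome-wide mean), so moments for
standardization are computed with a two-pass outlier rule: an initial
threshold of median + 4 SD over all rates, then a revised mean and SD over
the rates at or below that threshold.  All points are standardized with
the revised moments; points above the threshold are only flagged.

Under neutrality the standardized track is modeled as a stationary OU
process whose autocorrelation at genetic distance d Morgans is
exp(-theta * d).  theta is estimated by regressing log autocovariances at
lags k*Delta (up to 4 cM) on the lag, through the origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segments import RateTrack
from .maps import ScanGrid

__all__ = [
    "RobustMoments",
    "ZTrack",
    "ThetaFit",
    "DegenerateTrackError",
    "ThetaEstimationError",
    "robust_standardize",
    "autocovariance_curve",
    "fit_theta",
    "estimate_theta",
]


class DegenerateTrackError(ValueError):
    """All usable rates identical — no variance to standardize against."""


class ThetaEstimationError(ValueError):
    """Not enough usable autocovariance estimates to fit theta."""


@dataclass(frozen=True)
class RobustMoments:
    """Two-pass outlier-robust mean and SD of a rate track."""

    initial_threshold: float    # median + 4*SD over all rates
    mu_hat: float               # revised mean, outliers excluded
    sigma_hat: float            # revised SD, outliers excluded
    n_excluded: int


@dataclass
class ZTrack:
    """Standardized IBD rates on the scan grid."""

    grid: ScanGrid
    z: np.ndarray
    rates: np.ndarray
    outlier_mask: np.ndarray    # True where rate > initial_threshold
    moments: RobustMoments

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chrom_ids,
                "cm": self.grid.cm,
                "bp": self.grid.bp,
                "rate": self.rates,
                "z": self.z,
                "outlier": self.outlier_mask.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ThetaFit:
    """Fitted exponential decay parameter with its supporting lags."""

    theta_hat: float            # per Morgan
    lags: np.ndarray            # genetic distances k*Delta, in Morgans
    covariances: np.ndarray     # autocovariance estimates at those lags
    n_lags_used: int            # positive estimates entering the log fit

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "theta_hat": self.theta_hat,
                    "lags_morgans": self.lags.tolist(),
                    "covariances": self.covariances.tolist(),
                    "n_lags_used": self.n_lags_used,
                },
                fh,
                indent=2,
            )


def robust_standardize(track: RateTrack) -> ZTrack:
    """Standardize a rate track with the two-pass outlier rule.

    Pass 1: initial threshold = median(rates) + 4 * SD(rates), SD with
    denominator M-1 over all rates.  Pass 2: mean and SD over rates at or
    below the threshold.  Every point is standardized with the revised
    moments.
    """
    rates = np.asarray(track.rates, dtype=float)
    if rates.size < 2:
        raise DegenerateTrackError("need at least 2 grid points")
    sd_all = float(np.std(rates, ddof=1))
    if sd_all == 0.0:
        raise DegenerateTrackError("all IBD rates identical")
    threshold = float(np.median(rates)) + 4.0 * sd_all
    keep = rates <= threshold
    mu = float(np.mean(rates[keep]))
    sigma = float(np.std(rates[keep], ddof=1))
    if sigma == 0.0:
        raise DegenerateTrackError("non-outlier IBD rates are all identical")
    moments = RobustMoments(
        initial_threshold=threshold,
        mu_hat=mu,
        sigma_hat=sigma,
        n_excluded=int(np.sum(~keep)),
    )
    return ZTrack(
        grid=track.grid,
        z=(rates - mu) / sigma,
        rates=rates,
        outlier_mask=~keep,
        moments=moments,
    )


def autocovariance_curve(
    ztrack: ZTrack,
    max_lag_cm: float = 4.0,
    center: bool = True,
    min_points: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate autocovariances of the standardized track at lags k*Delta.

    For k = 1 ... floor(max_lag_cm / Delta), the estimate pools all
    within-chromosome pairs (m, m+k) where neither point is an outlier:

        c_k = mean over pairs of (z_m - zbar) * (z_{m+k} - zbar)

    with zbar the mean of included z values (``center=False`` uses zbar=0,
    appropriate if the track is taken as already mean-zero) and denominator
    equal to the pair count.  Pairs never span chromosome boundaries.

    Returns ``(lags, covariances)`` with lags in Morgans.
    """
    if ztrack.grid.M < min_points and ztrack.grid.C < 2:
        raise ThetaEstimationError(
            f"track too short for autocovariance estimation "
            f"(M={ztrack.grid.M} < {min_points} on a single chromosome)"
        )
    delta_cm = ztrack.grid.delta_cm
    kmax = int(np.floor(max_lag_cm / delta_cm + 1e-9))
    if kmax < 1:
        raise ThetaEstimationError("max_lag_cm smaller than the grid spacing")
    include = ~ztrack.outlier_mask
    zbar = float(np.mean(ztrack.z[include])) if center else 0.0
    zc = ztrack.z - zbar
    sums = np.zeros(kmax)
    counts = np.zeros(kmax, dtype=np.int64)
    for chrom, (a, b) in ztrack.grid.offsets.items():
        z = zc[a:b]
        ok = include[a:b]
        n = b - a
        all_ok = bool(ok.all())
        for k in range(1, min(kmax, n - 1) + 1):
            if all_ok:
                counts[k - 1] += n - k
                sums[k - 1] += float(np.dot(z[:-k], z[k:]))
            else:
                pair_ok = ok[:-k] & ok[k:]
                counts[k - 1] += int(pair_ok.sum())
                sums[k - 1] += float(np.dot(z[:-k][pair_ok], z[k:][pair_ok]))
    if counts[0] == 0:
        raise ThetaEstimationError("no valid pairs at lag 1")
    valid = counts > 0
    lags = (np.arange(1, kmax + 1)[valid] * delta_cm) / 100.0
    covs = sums[valid] / counts[valid]
    return lags, covs


def fit_theta(lags: np.ndarray, covariances: np.ndarray) -> ThetaFit:
    """Fit the exponential decay rate by no-intercept log-linear regression.

    Drops non-positive covariance estimates, then solves the ordinary
    least-squares problem log c_k ~ -theta * lag through the origin:

        theta_hat = -sum(lag * log c_k) / sum(lag**2)

    ``theta_hat`` is per Morgan (lags are in Morgans).
    """
    lags = np.asarray(lags, dtype=float)
    covs = np.asarray(covariances, dtype=float)
    pos = covs > 0
    if int(pos.sum()) < 3:
        raise ThetaEstimationError(
            f"only {int(pos.sum())} positive autocovariance estimates; "
            "need at least 3 to fit the decay parameter"
        )
    x = lags[pos]
    y = np.log(covs[pos])
    theta = -float(np.dot(x, y) / np.dot(x, x))
    if theta <= 0:
        raise ThetaEstimationError(
            "fitted decay parameter is non-positive; autocovariances do not decay"
        )
    return ThetaFit(
        theta_hat=theta,
        lags=lags,
        covariances=covs,
        n_lags_used=int(pos.sum()),
    )


def estimate_theta(ztrack: ZTrack, max_lag_cm: float = 4.0,
                   center: bool = True) -> ThetaFit:
    """Convenience wrapper: autocovariance curve then log-linear fit."""
    lags, covs = autocovariance_curve(ztrack, max_lag_cm=max_lag_cm, center=center)
    return fit_theta(lags, covs)
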