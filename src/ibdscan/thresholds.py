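"""Genome-wide significance thresholds for the OU-modeled scan statistic.

Three multiple-testing corrections at family-wise level alpha:

* **analytical** — the Siegmund–Yakir boundary-crossing approximation for
  the maximum of a discretely sampled Ornstein–Uhlenbeck process,

      P(max_m Z_m >= z) ~= 1 - exp(-[ C*(1-Phi(z))
                                      + theta*L*z*phi(z)*nu(z*sqrt(2*theta*Delta)) ]),

  root-solved for z.  C is the number of chromosomes, L the genome length
  in Morgans, theta the OU decay rate per Morgan, Delta the test spacing
  in Morgans, and nu the discretization correction (nu(0)=1 recovers the
  continuous process).

* **simulation** — Monte Carlo: simulate the stationary Gaussian AR(1)
  chain implied by the OU model over one chromosome of the total genome
  length, take the maximum of each replicate, and return the empirical
  (1-alpha) quantile of the maxima.

* **bonferroni** — alpha / M over the M grid tests.

The genome-wide significance level is alpha_star = 1 - Phi(z_star); the
per-position test rejects where the standardized rate exceeds z_star.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.stats import norm

__all__ = [
    "ThresholdResult",
    "nu",
    "analytical_quantile",
    "simulate_ou_chain",
    "simulation_quantile",
    "bonferroni_quantile",
    "HEURISTIC_Z",
    "heuristic_significance_level",
]

#: The field's pre-existing heuristic: four standard deviations above the
#: genome-wide median, a fixed z = 4 cutoff regardless of scan geometry.
HEURISTIC_Z = 4.0


def heuristic_significance_level() -> float:
    """Per-test tail probability 1 - Phi(4) of the heuristic threshold."""
    return float(norm.sf(HEURISTIC_Z))


@dataclass(frozen=True)
class ThresholdResult:
    """A multiple-testing quantile with the inputs that produced it."""

    method: str                 # "analytical" | "simulation" | "bonferroni"
    alpha_fw: float             # family-wise level
    z_star: float               # standard-normal quantile threshold
    alpha_star: float           # genome-wide significance level 1 - Phi(z_star)
    theta: float | None = None  # OU decay per Morgan (None for bonferroni)
    L_morgans: float | None = None
    C: int | None = None
    delta_morgans: float | None = None
    M: int | None = None
    J: int | None = None        # simulation replicates
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def nu(y) -> float | np.ndarray:
    """Discretization correction for maxima of a sampled OU process.

    Uses the rational approximation

        nu(y) = (2/y) * (Phi(y/2) - 1/2) / [ (y/2)*Phi(y/2) + phi(y/2) ]

    which is continuous at 0 with nu(0) = 1 (the continuous-process limit)
    and strictly decreasing in y.  For small y it is close to
    exp(-0.583*y).
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("nu is defined for non-negative arguments")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.ones_like(arr)
    pos = arr > 0
    half = arr[pos] / 2.0
    # (2/y)*(Phi(y/2) - 1/2) cancels catastrophically at small y; switch to
    # the Taylor expansion phi(0)*(1 - h^2/6 + h^4/40), h = y/2, below 0.1
    small = half < 0.05
    num = np.empty_like(half)
    num[small] = norm.pdf(0.0) * (
        1.0 - half[small] ** 2 / 6.0 + half[small] ** 4 / 40.0
    )
    num[~small] = (norm.cdf(half[~small]) - 0.5) / half[~small]
    den = half * norm.cdf(half) + norm.pdf(half)
    out[pos] = num / den
    return float(out[0]) if scalar else out


def _fwer_probability(z: float, theta: float, L: float, C: float,
                      delta: float) -> float:
    """The analytical approximation to P(max_m Z_m >= z)."""
    term = C * norm.sf(z) + theta * L * z * norm.pdf(z) * nu(
        z * math.sqrt(2.0 * theta * delta)
    )
    return 1.0 - math.exp(-term)


def analytical_quantile(
    alpha_fw: float,
    theta: float,
    L_morgans: float,
    C: int,
    delta_morgans: float,
) -> ThresholdResult:
    """Root-solve the analytical FWER approximation for z_star.

    Parameters are in Morgans (theta per Morgan, L and Delta in Morgans).
    The root is bracketed on z in [1, 10] and solved to machine tolerance;
    plugging z_star back into the approximation returns alpha_fw to
    better than 1e-10.
    """
    if not 0 < alpha_fw < 0.5:
        raise ValueError("alpha_fw must be in (0, 0.5)")
    if theta <= 0 or L_morgans <= 0 or C < 1 or delta_morgans <= 0:
        raise ValueError("theta, L, C, delta must all be positive")

    def f(z):
        return _fwer_probability(z, theta, L_morgans, C, delta_morgans) - alpha_fw

    lo, hi = 1.0, 10.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(
            f"no root in z bracket [1, 10] for alpha={alpha_fw}, theta={theta}, "
            f"L={L_morgans}, C={C}, delta={delta_morgans}"
        )
    z_star = float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))
    return ThresholdResult(
        method="analytical",
        alpha_fw=alpha_fw,
        z_star=z_star,
        alpha_star=float(norm.sf(z_star)),
        theta=theta,
        L_morgans=L_morgans,
        C=int(C),
        delta_morgans=delta_morgans,
        M=int(math.floor(L_morgans / delta_morgans)),
    )


def simulate_ou_chain(
    theta: float,
    delta_morgans: float,
    M: int,
    rng: np.random.Generator,
    n_chains: int = 1,
    stationary_variance: bool = False,
) -> np.ndarray:
    """Simulate the Gaussian AR(1) chain of the discretely sampled OU model.

    The first value is N(0, 1); each subsequent value is normal with mean
    ``z_{m-1} * exp(-theta*Delta)`` and variance ``2 - 2*exp(-theta*Delta)``.
    ``stationary_variance=True`` swaps in the exactly stationary conditional
    variance ``1 - exp(-2*theta*Delta)`` (the two differ at O((theta*Delta)^2)).

    Returns an array of shape ``(n_chains, M)`` (squeezed to ``(M,)`` when
    ``n_chains == 1``).  The recursion is evaluated as a linear filter over
    the innovation sequence, so long chains are vectorized.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if theta <= 0 or delta_morgans <= 0:
        raise ValueError("theta and delta must be positive")
    a = math.exp(-theta * delta_morgans)
    var = (1.0 - a * a) if stationary_variance else (2.0 - 2.0 * a)
    z0 = rng.standard_normal(n_chains)
    if M == 1:
        out = z0[:, None]
    else:
        innov = rng.standard_normal((n_chains, M - 1)) * math.sqrt(var)
        # z_m = a*z_{m-1} + e_m  <=>  IIR filter 1/(1 - a q^-1) with
        # initial condition carrying a*z0 into the first step
        zi = (a * z0)[:, None]
        rest, _ = lfilter([1.0], [1.0, -a], innov, axis=1, zi=zi)
        out = np.concatenate([z0[:, None], rest], axis=1)
    return out[0] if n_chains == 1 else out


def simulation_quantile(
    alpha_fw: float,
    theta: float,
    L_morgans: float,
    delta_morgans: float,
    J: int = 2000,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
    stationary_variance: bool = False,
) -> ThresholdResult:
    """Monte Carlo threshold: empirical (1-alpha) quantile of chain maxima.

    Simulates J chains of ``M = floor(L/Delta)`` steps — one chromosome of
    the total genome length, a deliberate simplification that avoids
    per-chromosome bookkeeping — and takes the order statistic of rank
    ``ceil((1-alpha)*J)`` of the J maxima.
    """
    if J < 100:
        raise ValueError("J must be >= 100")
    if alpha_fw * J < 5:
        raise ValueError(
            f"J={J} too small to resolve the (1-{alpha_fw}) quantile; "
            "need alpha_fw*J >= 5"
        )
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = None
    if rng is None:
        seed = 0 if seed is None else int(seed)
        rng = np.random.default_rng(seed)
    M = int(math.floor(L_morgans / delta_morgans))
    chains = simulate_ou_chain(
        theta, delta_morgans, M, rng, n_chains=J,
        stationary_variance=stationary_variance,
    )
    maxima = np.sort(chains.max(axis=1) if chains.ndim == 2 else chains)
    rank = math.ceil((1.0 - alpha_fw) * J)   # 1-based order statistic
    z_star = float(maxima[rank - 1])
    return ThresholdResult(
        method="simulation",
        alpha_fw=alpha_fw,
        z_star=z_star,
        alpha_star=float(norm.sf(z_star)),
        theta=theta,
        L_morgans=L_morgans,
        C=1,
        delta_morgans=delta_morgans,
        M=M,
        J=int(J),
        seed=seed,
    )


def bonferroni_quantile(alpha_fw: float, M: int) -> ThresholdResult:
    """Bonferroni correction over M tests: alpha_star = alpha / M."""
    if M < 1:
        raise ValueError("M must be >= 1")
    alpha_star = alpha_fw / M
    return ThresholdResult(
        method="bonferroni",
        alpha_fw=alpha_fw,
        z_star=float(norm.isf(alpha_star)),
        alpha_star=alpha_star,
        M=int(M),
    )
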