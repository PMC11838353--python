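import math

import numpy as np
import pytest
from scipy.stats import norm

from ibdscan.thresholds import (
    analytical_quantile,
    bonferroni_quantile,
    heuristic_significance_level,
    nu,
    simulate_ou_chain,
    simulation_quantile,
)

GEOM = dict(L_morgans=10.0, C=10, delta_morgans=0.0002)  # ten 100 cM chromosomes


class TestNu:
    def test_continuous_limit_is_one(self):
        assert nu(0.0) == 1.0

    def test_continuous_at_zero(self):
        assert nu(1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_strictly_decreasing(self):
        ys = np.linspace(0.1, 3.0, 30)
        vals = nu(ys)
        assert np.all(np.diff(vals) < 0)

    def test_small_y_exponential_approximation(self):
        """nu(y) ~ exp(-0.583 y) for moderate y."""
        assert nu(0.5) == pytest.approx(math.exp(-0.583 * 0.5), rel=0.03)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            nu(-0.1)


class TestAnalyticalQuantile:
    def test_reproduces_constant_size_quantile(self):
        """theta=58.84 on the ten-chromosome geometry gives z* near 4.36."""
        r = analytical_quantile(0.05, 58.84, **GEOM)
        assert r.z_star == pytest.approx(4.36, rel=0.01)

    @pytest.mark.parametrize(
        "theta,level",
        [(74.75, 5.41e-6), (56.78, 6.82e-6), (58.84, 6.56e-6), (44.97, 8.38e-6)],
    )
    def test_reproduces_published_significance_levels(self, theta, level):
        r = analytical_quantile(0.05, theta, **GEOM)
        assert r.alpha_star == pytest.approx(level, rel=0.03)

    def test_theta_to_zero_limit_is_per_chromosome_sidak(self):
        """As theta -> 0 only the chromosome-count term survives."""
        r = analytical_quantile(0.05, 1e-9, **GEOM)
        # solves 1 - exp(-C*(1-Phi(z))) = alpha
        expected = norm.isf(-math.log(1 - 0.05) / GEOM["C"])
        assert r.z_star == pytest.approx(expected, rel=1e-6)

    def test_round_trip_residual(self):
        from ibdscan.thresholds import _fwer_probability

        r = analytical_quantile(0.05, 50.0, **GEOM)
        back = _fwer_probability(r.z_star, 50.0, GEOM["L_morgans"], GEOM["C"],
                                 GEOM["delta_morgans"])
        assert abs(back - 0.05) < 1e-10

    def test_monotone_in_theta_length_and_alpha(self):
        z = lambda **kw: analytical_quantile(**{**dict(alpha_fw=0.05, theta=50.0,
                                                       **GEOM), **kw}).z_star
        assert z(theta=80.0) > z(theta=50.0) > z(theta=20.0)
        assert z(L_morgans=20.0) > z(L_morgans=10.0) > z(L_morgans=5.0)
        assert z(alpha_fw=0.01) > z(alpha_fw=0.05) > z(alpha_fw=0.10)

    def test_coarser_spacing_lowers_the_quantile(self):
        """Fewer effective tests at wider spacing (nu decreasing)."""
        z_fine = analytical_quantile(0.05, 50.0, 10.0, 10, 0.0002).z_star
        z_coarse = analytical_quantile(0.05, 50.0, 10.0, 10, 0.001).z_star
        assert z_coarse < z_fine

    def test_alpha_domain_checked(self):
        with pytest.raises(ValueError):
            analytical_quantile(0.7, 50.0, **GEOM)

    def test_alpha_star_consistent_with_z_star(self):
        r = analytical_quantile(0.05, 50.0, **GEOM)
        assert r.alpha_star == norm.sf(r.z_star)
        assert r.alpha_star < r.alpha_fw


class TestBonferroni:
    @pytest.mark.parametrize("alpha,expected", [(0.01, 2.08e-7), (0.05, 1.04e-6),
                                                (0.10, 2.08e-6)])
    def test_published_levels_at_48010_tests(self, alpha, expected):
        r = bonferroni_quantile(alpha, 48010)
        assert r.alpha_star == pytest.approx(expected, rel=0.005)

    def test_single_test(self):
        r = bonferroni_quantile(0.05, 1)
        assert r.alpha_star == 0.05

    def test_ordering_against_analytical_and_single_test(self):
        an = analytical_quantile(0.05, 50.0, **GEOM)
        bon = bonferroni_quantile(0.05, 50000)
        assert bon.z_star >= an.z_star >= norm.isf(0.05)


class TestSimulateOUChain:
    def test_single_step_is_standard_normal(self, rng):
        draws = simulate_ou_chain(50.0, 0.0002, 1, rng, n_chains=100_000)
        assert np.mean(draws) == pytest.approx(0.0, abs=0.02)
        assert np.var(draws) == pytest.approx(1.0, rel=0.02)

    def test_large_theta_delta_decorrelates(self, rng):
        chain = simulate_ou_chain(50_000.0, 0.0002, 100_000, rng)
        r = np.corrcoef(chain[:-1], chain[1:])[0, 1]
        assert abs(r) < 0.02

    def test_lag_one_correlation_matches_ar1(self, rng):
        """Sample lag-1 correlation approaches exp(-theta*Delta)."""
        chain = simulate_ou_chain(50.0, 0.0002, 1_000_000, rng)
        r = np.corrcoef(chain[:-1], chain[1:])[0, 1]
        assert r == pytest.approx(math.exp(-0.01), abs=0.01)

    def test_stationary_variance_option_keeps_unit_marginals(self, rng):
        chain = simulate_ou_chain(50.0, 0.001, 200_000, rng,
                                  stationary_variance=True)
        assert np.var(chain) == pytest.approx(1.0, rel=0.02)


class TestSimulationQuantile:
    def test_single_point_genome_recovers_normal_quantile(self):
        # L/delta = 1: maxima are iid N(0,1)
        r = simulation_quantile(0.05, 50.0, 0.0002, 0.0002, J=20_000, seed=4)
        assert r.z_star == pytest.approx(norm.isf(0.05), abs=0.05)

    def test_independence_limit_matches_max_of_iid_normals(self):
        # huge theta*Delta decouples the chain into iid N(0,1) draws
        # (stationary transition variance, so marginals stay unit)
        M = 10
        r = simulation_quantile(0.05, 1e6, 10 * 0.001, 0.001, J=20_000, seed=8,
                                stationary_variance=True)
        expected = norm.ppf((1 - 0.05) ** (1 / M))
        assert r.z_star == pytest.approx(expected, abs=0.06)

    def test_agrees_with_analytical_method(self):
        sim = simulation_quantile(0.05, 50.0, 10.0, 0.0002, J=4000, seed=12)
        an = analytical_quantile(0.05, 50.0, **GEOM)
        assert sim.z_star == pytest.approx(an.z_star, abs=0.05)

    def test_fixed_seed_bit_reproducible(self):
        a = simulation_quantile(0.05, 50.0, 1.0, 0.0002, J=500, seed=3)
        b = simulation_quantile(0.05, 50.0, 1.0, 0.0002, J=500, seed=3)
        assert a.z_star == b.z_star

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulation_quantile(0.05, 50.0, 1.0, 0.0002, J=50)
        with pytest.raises(ValueError):
            simulation_quantile(0.001, 50.0, 1.0, 0.0002, J=200)


def test_heuristic_significance_level():
    """Four SDs above the mean corresponds to 1 - Phi(4) = 3.17e-5."""
    assert heuristic_significance_level() == pytest.approx(3.17e-5, rel=0.002)
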