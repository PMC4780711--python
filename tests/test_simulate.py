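import numpy as np
import pytest

from dsdesign.errors import ConfigError
from dsdesign.families import gbar, half_normal, hazard_rate
from dsdesign.simulate import (
    SimulationConfig,
    SimulationResult,
    crossing_range,
    draw_overdispersed_distances,
    draw_uniform_distances,
    empirical_penalty,
    optimal_strip_width,
    overdispersion_alpha,
    run_simulation,
    support_points,
    thin_by_detection,
)


class TestGenerators:
    def test_uniform_moments(self, rng):
        pop = draw_uniform_distances(1_000_000, 10.0, rng)
        se = 10.0 / np.sqrt(12.0) / 1000.0
        assert abs(pop.distances_all.mean() - 5.0) < 3 * se
        assert pop.phi is None

    def test_uniform_count_variance_binomial(self, rng):
        """Count of distances <= w behaves like bin(N, P)."""
        N, reps = 20_000, 500
        counts = np.array(
            [(draw_uniform_distances(N, 10.0, rng).distances_all <= 1.0).sum() for _ in range(reps)]
        )
        expected = N * 0.1 * 0.9
        assert 0.85 < counts.var() / expected < 1.15

    def test_uniform_determinism(self):
        a = draw_uniform_distances(100, 10.0, np.random.default_rng(5)).distances_all
        b = draw_uniform_distances(100, 10.0, np.random.default_rng(5)).distances_all
        assert np.array_equal(a, b)

    def test_alpha_arithmetic(self):
        assert overdispersion_alpha(1667, 2.0) == pytest.approx(1665.0)
        # round trip: c = (alpha + N)/(alpha + 1)
        for N, c in [(1667, 2.0), (833, 3.0), (10_000, 1.5)]:
            a = overdispersion_alpha(N, c)
            assert (a + N) / (a + 1) == pytest.approx(c, abs=1e-12)
        with pytest.raises(ConfigError):
            overdispersion_alpha(100, 1.0)
        with pytest.raises(ConfigError):
            overdispersion_alpha(100, 200.0)

    def test_support_points_avoid_boundaries(self):
        """Midpoint support: 100 of 1000 points lie below w=1 and none sits
        on a 0.01-width strip boundary."""
        pts = support_points(1000, 10.0)
        assert pts.size == 1000
        assert (pts < 1.0).sum() == 100
        inside = pts[pts <= 1.0]
        grid = np.round(np.arange(1, 101) * 0.01, 10)
        assert not np.isin(np.round(inside, 12), grid).any()

    def test_overdispersed_weights_normalized(self, rng):
        pop = draw_overdispersed_distances(1000, 10.0, 2.0, 1000, rng)
        assert pop.phi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pop.phi >= 0)
        assert np.all((pop.distances_all > 0) & (pop.distances_all < 10.0))

    @pytest.mark.parametrize("c", [2.0, 3.0])
    def test_overdispersed_count_moments(self, c, rng):
        """Counts in the covered strip are beta-binomial: mean NvP, variance
        c*N*v*P*(1 - vP)."""
        N, reps, v = 1667, 2000, 1.0
        counts = np.empty(reps)
        for r in range(reps):
            pop = draw_overdispersed_distances(N, 10.0, c, 1000, rng)
            counts[r] = (pop.distances_all <= 1.0).sum()
        mean_expect = N * v * 0.1
        var_expect = c * N * v * 0.1 * (1 - v * 0.1)
        assert abs(counts.mean() - mean_expect) < 3 * counts.std() / np.sqrt(reps)
        assert 0.9 * var_expect < counts.var() < 1.1 * var_expect


class TestThinning:
    def test_perfect_detection_keeps_covered(self, rng):
        from dsdesign.families import CustomFamily

        fam = CustomFamily(lambda d, th: np.ones_like(d), n_params=1, name="flat")
        pop = draw_uniform_distances(10_000, 10.0, rng)
        sample = thin_by_detection(pop, fam, [1.0], rng)
        assert sample.n == (pop.distances_all <= 1.0).sum()

    def test_vanishing_detection(self, hn, rng):
        pop = draw_uniform_distances(10_000, 10.0, rng)
        sample = thin_by_detection(pop, hn, [1e-6], rng)
        assert sample.n <= 2

    def test_expected_detections(self, hn, rng):
        """E[n] = N*P*gbar = 0.06 N under the study settings."""
        N, reps = 16_670, 100
        ns = np.empty(reps)
        for r in range(reps):
            pop = draw_uniform_distances(N, 10.0, rng)
            ns[r] = thin_by_detection(pop, hn, [0.502], rng).n
        assert abs(ns.mean() - 0.06 * N) < 3 * ns.std() / np.sqrt(reps)


def small_result(**kw):
    cfg = dict(
        family="half_normal",
        theta_true=(0.502,),
        E_n=60,
        c=1.0,
        reps=30,
        fit_families=(),
        master_seed=99,
    )
    cfg.update(kw)
    return run_simulation(SimulationConfig(**cfg))


class TestHarness:
    def test_seed_determinism(self):
        a, b = small_result(), small_result()
        assert np.array_equal(a.strip, b.strip)
        assert np.array_equal(a.known_theta, b.known_theta)
        assert a.summary().equals(b.summary())

    def test_different_seed_differs(self):
        assert not np.array_equal(small_result().strip, small_result(master_seed=100).strip)

    def test_abundance_rule(self):
        cfg = SimulationConfig(family="half_normal", theta_true=(0.502,), E_n=100)
        gb = gbar(half_normal(), [0.502])
        assert cfg.abundance() == round(100 / (0.1 * gb))

    def test_mse_decomposition(self):
        res = small_result()
        s = res.summary()
        assert np.allclose(s["mse"], s["var"] + s["bias"] ** 2, rtol=1e-10)
        assert np.allclose(s["rrmse_pct"], 100 * np.sqrt(s["mse"]) / res.N, rtol=1e-12)

    def test_single_replicate_record(self):
        res = small_result(reps=1)
        assert res.strip.shape == (1, 100)
        assert res.n_detections.shape == (1,)

    def test_fitted_harness_smoke(self):
        res = small_result(E_n=100, reps=8, fit_families=("half_normal",))
        assert "half_normal" in res.cds
        ok = res.converged["half_normal"]
        assert np.all(np.isfinite(res.cds["half_normal"][ok]))

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimulationConfig(family="half_normal", theta_true=(0.5,), E_n=100, c=0.5)
        with pytest.raises(ConfigError):
            SimulationConfig(family="half_normal", theta_true=(0.5,), E_n=100, P=0.2)

    def test_rrmse_curve_frame(self):
        res = small_result()
        curve = res.rrmse_curve()
        assert list(curve.columns) == ["w_prime", "c", "rrmse_pct"]
        assert len(curve) == 100


def synthetic_result(strip_mse_curve, cds_values, N=1000):
    """Assemble a SimulationResult with prescribed per-width strip deviations
    so argmin/crossing contracts can be checked exactly."""
    grid = np.round(np.arange(1, len(strip_mse_curve) + 1) * 0.01, 10)
    cfg = SimulationConfig(
        family="half_normal",
        theta_true=(0.502,),
        E_n=60,
        reps=2,
        strip_grid=grid,
        fit_families=("half_normal",),
    )
    # two replicates with deviations +/- sqrt(mse) give exactly that MSE
    dev = np.sqrt(np.asarray(strip_mse_curve))
    strip = np.vstack([N + dev, N - dev])
    cds = {"half_normal": np.asarray(cds_values, dtype=float)}
    conv = {"half_normal": np.ones(2, dtype=bool)}
    return SimulationResult(
        cfg, N, np.array([60, 60]), np.array([980.0, 1020.0]), cds, conv, strip
    )


class TestSummaries:
    def test_optimal_width_monotone_curve_takes_first(self):
        res = synthetic_result(np.arange(1.0, 101.0), [1000.0, 1000.0])
        assert optimal_strip_width(res) == pytest.approx(0.01)

    def test_optimal_width_tie_breaks_small(self):
        mse = np.full(100, 5.0)
        mse[30] = mse[60] = 1.0
        res = synthetic_result(mse, [1000.0, 1000.0])
        assert optimal_strip_width(res) == pytest.approx(0.31)

    def test_crossing_empty_when_strip_never_wins(self):
        res = synthetic_result(np.full(100, 100.0), [1001.0, 999.0])  # CDS MSE 1
        assert crossing_range(res) is None

    def test_crossing_endpoints(self):
        mse = np.full(100, 100.0)
        mse[14:71] = 1.0  # strip beats CDS for widths 0.15..0.71
        res = synthetic_result(mse, [1010.0, 990.0])  # CDS MSE 100 > 1
        lo, hi = crossing_range(res)
        assert (lo, hi) == (pytest.approx(0.15), pytest.approx(0.71))

    def test_empirical_penalty_identical_streams(self):
        res = synthetic_result(np.full(100, 1.0), [980.0, 1020.0])
        assert empirical_penalty(res) == pytest.approx(1.0)
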