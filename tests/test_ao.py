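"""Unit and property tests for the Aquila Optimizer core."""

import numpy as np
import pytest

from dermao import ao


# ---------------------------------------------------------------------------
# Lévy machinery

@pytest.mark.parametrize(
    "beta, expected",
    [
        (1.0, 1.0),            # Gamma(2) = Gamma(1) = 1, sin(pi/2) = 1, 2^0 = 1
        (2.0, 0.0),            # sin(pi) = 0
        (1.5, 0.6965745025576968),  # frozen from the gamma-function closed form
    ],
)
def test_levy_sigma_closed_form(beta, expected):
    assert ao.levy_sigma(beta) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("beta", [0.0, -1.0, 2.5])
def test_levy_sigma_domain(beta):
    with pytest.raises(ValueError):
        ao.levy_sigma(beta)


def test_levy_step_zero_scale_annihilates():
    rng = np.random.default_rng(0)
    assert np.array_equal(ao.levy_step(7, 1.5, 0.0, rng), np.zeros(7))


def test_levy_step_seed_determinism():
    a = ao.levy_step(10, 1.5, 0.01, np.random.default_rng(42))
    b = ao.levy_step(10, 1.5, 0.01, np.random.default_rng(42))
    assert np.array_equal(a, b)


def test_levy_step_heavy_tail():
    # Lévy-stable steps have far heavier tails than a Gaussian: the
    # empirical excess kurtosis over 1e5 draws must be large.
    from scipy.stats import kurtosis

    draws = ao.levy_step(100_000, 1.5, 0.01, np.random.default_rng(7))
    assert kurtosis(draws, fisher=True) > 10.0


# ---------------------------------------------------------------------------
# position-update strategies

def test_mean_position():
    assert np.array_equal(ao.mean_position(np.array([[1.0, 2.0]])), [1.0, 2.0])
    assert np.array_equal(
        ao.mean_position(np.array([[3.0, -1.0], [-3.0, 1.0]])), [0.0, 0.0]
    )
    assert np.array_equal(
        ao.mean_position(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])), [3.0, 4.0]
    )
    with pytest.raises(ValueError):
        ao.mean_position(np.empty((0, 3)))


def test_expanded_exploration_algebra(stub_rng_factory):
    xbest = np.array([2.0, 2.0])
    xm = np.array([4.0, 0.0])
    # rand pinned to 0: update is Xbest*(1 - t/T) + XM
    out = ao.expanded_exploration(None, xbest, xm, 50, 100, stub_rng_factory([0.0]))
    assert np.allclose(out, xbest * 0.5 + xm)
    # t = 0, rand pinned to 1: Xbest + XM - Xbest = XM
    out = ao.expanded_exploration(None, xbest, xm, 0, 100, stub_rng_factory([1.0]))
    assert np.allclose(out, xm)


def test_spiral_offsets_first_term():
    # frozen from scalar trigonometry: theta = 3pi/2 - 0.005, r = 1.00565
    x, y = ao.spiral_offsets(1, omega=0.005, r_base=1.0)
    assert x[0] == pytest.approx(-1.00564, abs=1e-4)
    assert y[0] == pytest.approx(-0.0050282, abs=1e-6)


def test_spiral_offsets_omega_zero_and_monotone_radius():
    x, y = ao.spiral_offsets(20, omega=0.0, r_base=2.0)
    r = 2.0 + 0.00565 * np.arange(1, 21)
    assert np.allclose(x, -r)          # sin(3pi/2) = -1
    assert np.allclose(y, 0.0, atol=1e-12)  # cos(3pi/2) = 0
    assert np.all(np.diff(np.hypot(x, y)) > 0)


def test_narrowed_exploration_reduces_to_xr(stub_rng_factory):
    # with zero Lévy scale and the trailing rand pinned to 0, the update
    # returns the stochastic companion position exactly
    config = ao.AOConfig(levy_scale=0.0)
    bounds = ao.Bounds.cube(4)
    xr = np.array([0.1, 0.2, 0.3, 0.4])
    out = ao.narrowed_exploration(
        np.full(4, 0.5), xr, bounds, config, stub_rng_factory([0.0], integer=1)
    )
    assert np.array_equal(out, xr)


def test_expanded_exploitation_algebra(stub_rng_factory):
    bounds = ao.Bounds(np.zeros(2), np.ones(2))
    # Xbest = XM and both rands 0 -> LB * delta
    out = ao.expanded_exploitation(
        np.ones(2), np.ones(2), bounds, 0.1, 0.1, stub_rng_factory([0.0, 0.0])
    )
    assert np.allclose(out, bounds.lower * 0.1)
    # hand-derived: (0.1,0) - 0.5 + (0.05,0.05) = (-0.35, -0.45)
    out = ao.expanded_exploitation(
        np.array([1.0, 0.0]), np.zeros(2), bounds, 0.1, 0.1,
        stub_rng_factory([0.5, 0.5]),
    )
    assert np.allclose(out, [-0.35, -0.45])


def test_g2_endpoints_and_linearity():
    T = 40
    assert ao.g2_slope(0, T) == 2.0
    assert ao.g2_slope(T, T) == 0.0
    ts = np.arange(T + 1)
    vals = np.array([ao.g2_slope(t, T) for t in ts])
    assert np.allclose(np.diff(vals), -2.0 / T)


def test_quality_function_balance():
    # QF(t) = t^((2 rand - 1)/(1-T)^2): exponent vanishes at rand = 0.5
    assert ao.quality_function(17, 100, 0.5) == pytest.approx(1.0)
    assert ao.quality_function(1, 100, 0.9) == pytest.approx(1.0)  # 1^x = 1
    assert ao.quality_function(50, 100, 1.0) == pytest.approx(
        50.0 ** (1.0 / 99.0**2)
    )


def test_narrowed_exploitation_reduction(stub_rng_factory):
    # all uniforms pinned to 0.5: G1 = 0 wipes both G1 terms, QF = 1,
    # and zero Lévy scale removes the flight term -> Xbest survives
    config = ao.AOConfig(levy_scale=0.0)
    xbest = np.array([0.3, 0.7])
    out = ao.narrowed_exploitation(
        np.array([0.9, 0.1]), xbest, 10, 40, config,
        stub_rng_factory([0.5, 0.5, 0.5]),
    )
    assert np.allclose(out, xbest)


@pytest.mark.parametrize(
    "t, T, u, expected",
    [
        (50, 100, 0.2, ao.EXPANDED_EXPLORATION),
        (50, 100, 0.8, ao.NARROWED_EXPLORATION),
        (90, 100, 0.2, ao.EXPANDED_EXPLOITATION),
        (90, 100, 0.8, ao.NARROWED_EXPLOITATION),
        (60, 90, 0.9, ao.NARROWED_EXPLORATION),  # t = 2T/3 exactly: inclusive
        (61, 90, 0.9, ao.NARROWED_EXPLOITATION),
    ],
)
def test_select_strategy_phase_rule(t, T, u, expected):
    assert ao.select_strategy(t, T, u) == expected


def test_phase_rule_property():
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=200)
    @given(T=st.integers(1, 1000), frac=st.floats(0.0, 1.0), u=st.floats(0.0, 1.0))
    def check(T, frac, u):
        t = int(round(frac * T))
        strategy = ao.select_strategy(t, T, u)
        exploring = strategy in (ao.EXPANDED_EXPLORATION, ao.NARROWED_EXPLORATION)
        assert exploring == (t <= 2 * T / 3)

    check()


def test_clip_to_bounds():
    bounds = ao.Bounds(np.zeros(3), np.ones(3))
    inside = np.array([0.1, 0.5, 0.9])
    assert np.array_equal(ao.clip_to_bounds(inside, bounds), inside)
    assert np.array_equal(
        ao.clip_to_bounds(np.array([-5.0, 0.5, 7.0]), bounds), [0.0, 0.5, 1.0]
    )


# ---------------------------------------------------------------------------
# the optimize loop

def _sphere(x):
    return float(np.sum(x**2))


def test_optimize_sphere_convergence():
    config = ao.AOConfig(pop_size=30, max_iter=500, seed=1)
    result = ao.optimize(_sphere, ao.Bounds.cube(5, -10.0, 10.0), config)
    assert result.best_fitness <= 1e-2


def test_optimize_bookkeeping_and_determinism():
    config = ao.AOConfig(pop_size=8, max_iter=30, seed=3)
    bounds = ao.Bounds.cube(4, -5.0, 5.0)
    a = ao.optimize(_sphere, bounds, config)
    b = ao.optimize(_sphere, bounds, config)
    assert np.all(np.diff(a.history) <= 0)
    assert a.evaluations == 8 * 31
    assert a.best_fitness == b.best_fitness
    assert np.array_equal(a.best_position, b.best_position)
    assert np.array_equal(a.history, b.history)
    assert a.strategy_trace == b.strategy_trace


def test_strategy_trace_respects_phases():
    T = 30
    config = ao.AOConfig(pop_size=6, max_iter=T, seed=5)
    result = ao.optimize(_sphere, ao.Bounds.cube(3, -2.0, 2.0), config)
    cutoff = 2.0 * T / 3.0
    for t, strategy in result.strategy_trace:
        if t <= cutoff:
            assert strategy in (ao.EXPANDED_EXPLORATION, ao.NARROWED_EXPLORATION)
        else:
            assert strategy in (ao.EXPANDED_EXPLOITATION, ao.NARROWED_EXPLOITATION)
    seen = {s for _, s in result.strategy_trace}
    assert len(seen) == 4


@pytest.mark.parametrize("seed", range(5))
def test_optimize_positions_within_bounds_any_seed(seed):
    bounds = ao.Bounds(np.array([-1.0, 0.0, 2.0]), np.array([1.0, 3.0, 4.0]))
    seen = []

    def probe(x):
        seen.append(x.copy())
        return _sphere(x)

    ao.optimize(probe, bounds, ao.AOConfig(pop_size=5, max_iter=20, seed=seed))
    stacked = np.stack(seen)
    assert np.all(stacked >= bounds.lower - 1e-12)
    assert np.all(stacked <= bounds.upper + 1e-12)


def test_optimize_rejects_non_finite_objective():
    calls = {"n": 0}

    def nasty(x):
        calls["n"] += 1
        return np.nan if calls["n"] % 3 == 0 else _sphere(x)

    config = ao.AOConfig(pop_size=4, max_iter=10, seed=0)
    with pytest.warns(UserWarning):
        result = ao.optimize(nasty, ao.Bounds.cube(2, -1.0, 1.0), config)
    assert np.isfinite(result.best_fitness)
    assert np.all(np.diff(result.history) <= 0)


def test_doubling_budget_helps_on_sphere():
    # stochastic monotonicity: more iterations should not hurt, checked
    # on the median over seeds
    bounds = ao.Bounds.cube(5, -10.0, 10.0)
    short, long = [], []
    for seed in range(10):
        short.append(
            ao.optimize(_sphere, bounds, ao.AOConfig(pop_size=15, max_iter=50, seed=seed)).best_fitness
        )
        long.append(
            ao.optimize(_sphere, bounds, ao.AOConfig(pop_size=15, max_iter=100, seed=seed)).best_fitness
        )
    assert np.median(long) <= np.median(short)


def test_config_validation():
    with pytest.raises(ValueError):
        ao.AOConfig(pop_size=1)
    with pytest.raises(ValueError):
        ao.AOConfig(alpha=0.5)
    with pytest.raises(ValueError):
        ao.AOConfig(levy_beta=3.0)
    with pytest.raises(ValueError):
        ao.Bounds(np.array([0.0, 1.0]), np.array([1.0, 0.5]))
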