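"""Unit and property tests for the five trajectory generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anomdiff import simulators as sim
from anomdiff.models import (
    EventTrajectory,
    Interpolation,
    InvalidParameterError,
    Model,
    ModelConstraintError,
    ModelSpec,
)
from anomdiff.simulators import (
    fractional_gaussian_noise,
    lift_dimension,
    random_directions,
    regularize,
    sample_powerlaw,
    simulate,
    simulate_attm,
    simulate_ctrw,
    simulate_lw,
    simulate_sbm,
)


# ---------------------------------------------------------------------------
# power-law sampler


class TestSamplePowerlaw:
    def test_empty(self, rng):
        assert sample_powerlaw(2.0, 0, rng).size == 0

    def test_inverse_cdf_algebra(self, stub_rng_factory):
        # u = 0.75, tail exponent 2: t = (1 - u)^(-1) = 4
        out = sample_powerlaw(2.0, 1, stub_rng_factory(uniform=[0.75]))
        assert out[0] == pytest.approx(4.0)

    def test_pareto_survival(self, rng):
        draws = sample_powerlaw(1.5, 10**5, rng)
        assert np.all(draws >= 1.0)
        # closed-form survival P(T > 100) = 100^(1 - 1.5) = 0.1
        assert np.mean(draws > 100.0) == pytest.approx(0.1, abs=0.01)

    def test_nonnormalizable_exponent_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            sample_powerlaw(1.0, 5, rng)

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(1.1, 6.0), st.integers(1, 50))
    def test_draws_at_least_one(self, exponent, n):
        draws = sample_powerlaw(exponent, n, np.random.default_rng(0))
        assert draws.shape == (n,)
        assert np.all(draws >= 1.0)


# ---------------------------------------------------------------------------
# CTRW


class TestCtrw:
    def test_manual_recursion(self, monkeypatch, stub_rng_factory):
        # stubbed waits {2, 3} and jumps {+1.0, -0.5}: events (2, 5) at (1.0, 0.5)
        monkeypatch.setattr(
            sim, "sample_powerlaw", lambda e, n, r: np.array([2.0, 3.0])
        )
        stub = stub_rng_factory(normal=[1.0, -0.5])
        traj = simulate_ctrw(ModelSpec.create("CTRW", 0.5), horizon=4, rng=stub)
        np.testing.assert_allclose(traj.times, [2.0, 5.0])
        np.testing.assert_allclose(traj.positions[0], [1.0, 0.5])
        assert traj.interpolation is Interpolation.HOLD

    def test_alpha_one_fixed_unit_waits(self, rng):
        traj = simulate_ctrw(ModelSpec.create("CTRW", 1.0), horizon=5, rng=rng)
        np.testing.assert_allclose(traj.times, [1, 2, 3, 4, 5])

    def test_superdiffusive_alpha_rejected(self):
        with pytest.raises(ModelConstraintError):
            ModelSpec.create("CTRW", 1.5)

    def test_positions_piecewise_constant(self, rng):
        spec = ModelSpec.create("CTRW", 0.5)
        event = simulate_ctrw(spec, horizon=99, rng=rng)
        reg = regularize(event, horizon=99)
        attained = np.concatenate([[0.0], event.positions[0]])
        assert np.all(np.isin(reg.positions[0], attained))


# ---------------------------------------------------------------------------
# FBM / fractional Gaussian noise

FGN_COV = lambda h, k: 0.5 * (
    abs(k + 1) ** (2 * h) - 2 * abs(k) ** (2 * h) + abs(k - 1) ** (2 * h)
)


class TestFbm:
    def test_brownian_limit_uncorrelated(self, rng):
        fgn = fractional_gaussian_noise(0.5, 1000, rng, size=100)
        lag1 = np.mean(fgn[:, :-1] * fgn[:, 1:])
        assert lag1 == pytest.approx(0.0, abs=0.02)

    def test_lag1_autocovariance_h075(self, rng):
        # closed form gamma(1) = (2^1.5 - 2)/2 for unit-variance fGn
        fgn = fractional_gaussian_noise(0.75, 1000, rng, size=100)
        lag1 = np.mean(fgn[:, :-1] * fgn[:, 1:])
        assert lag1 == pytest.approx((2**1.5 - 2) / 2, abs=0.02)

    @pytest.mark.parametrize("hurst", [0.25, 0.5, 0.75])
    def test_autocovariance_closed_form(self, hurst, rng):
        fgn = fractional_gaussian_noise(hurst, 2000, rng, size=60)
        for k in range(6):
            emp = np.mean(fgn[:, : fgn.shape[1] - k] * fgn[:, k:])
            assert emp == pytest.approx(FGN_COV(hurst, k), abs=0.03)

    def test_hosking_matches_closed_form(self, rng):
        fgn = sim._fgn_hosking(0.75, 8, rng, size=20000)
        cov = fgn.T @ fgn / fgn.shape[0]
        expected = np.array([[FGN_COV(0.75, i - j) for j in range(8)] for i in range(8)])
        np.testing.assert_allclose(cov, expected, atol=0.05)

    def test_cross_dimension_independence(self, rng):
        traj = simulate("FBM", 1.5, 2000, dim=3, rng=rng)
        inc = np.diff(traj.positions, axis=1)
        corr = np.corrcoef(inc)
        off_diag = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.1)

    def test_ballistic_alpha_rejected(self):
        with pytest.raises(ModelConstraintError):
            ModelSpec.create("FBM", 2.0)


# ---------------------------------------------------------------------------
# LW


class TestLw:
    def test_manual_recursion(self, monkeypatch, stub_rng_factory):
        # v=2, flights {1, 2}, signs {+, -}: events (1, 3) at (2, -2)
        monkeypatch.setattr(
            sim, "sample_powerlaw", lambda e, n, r: np.array([1.0, 2.0])
        )
        stub = stub_rng_factory(integers=[0, 1])
        spec = ModelSpec.create("LW", 1.5, speed=2.0)
        traj = simulate_lw(spec, horizon=3, rng=stub)
        np.testing.assert_allclose(traj.times, [1.0, 3.0])
        np.testing.assert_allclose(traj.positions[0], [2.0, -2.0])
        reg = regularize(traj, horizon=3)
        np.testing.assert_allclose(reg.positions[0], [0.0, 2.0, 0.0, -2.0])

    def test_constant_speed_within_flights(self, rng):
        spec = ModelSpec.create("LW", 1.2, speed=3.0)
        event = simulate_lw(spec, horizon=200, rng=rng)
        reg = regularize(event, horizon=200)
        # grid steps [i, i+1] strictly inside one flight move exactly v
        bounds = np.concatenate([[0.0], event.times])
        inc = np.abs(np.diff(reg.positions[0]))
        for i, d in enumerate(inc):
            j = np.searchsorted(bounds, i, side="right")
            if j < bounds.size and i + 1 <= bounds[j]:  # same flight
                assert d == pytest.approx(3.0, rel=1e-9)

    def test_subdiffusive_alpha_rejected(self):
        with pytest.raises(ModelConstraintError):
            ModelSpec.create("LW", 0.5)

    def test_speed_drawn_in_range(self, rng):
        spec = ModelSpec.create("LW", 2.0)
        assert spec.sigma == pytest.approx(0.5)
        for _ in range(20):
            traj = simulate_lw(spec, horizon=10, rng=rng)
            speeds = np.abs(np.diff(traj.positions[0], prepend=0.0)) / np.diff(
                traj.times, prepend=0.0
            )
            assert np.all((speeds > 0) & (speeds <= 10))


# ---------------------------------------------------------------------------
# ATTM


class TestAttm:
    def test_accepted_sigma_range(self, rng):
        # for alpha = 0.5 the rejection rule reduces to sigma in (0, 1)
        for _ in range(200):
            sigma, gamma = sim._attm_parameters(0.5, rng)
            assert 0 < sigma < 1
            assert sigma < gamma < sigma + 1

    def test_segment_duration_power_of_diffusivity(self, monkeypatch):
        # sigma=0.5, gamma=1, first uniform u=0.5 -> D_1 = u^2 = 0.25,
        # t_1 = D_1^-1 = 4; with all-ones Gaussian draws each increment
        # equals its s.d. sqrt(2 D dt), exposing the segment boundary.
        monkeypatch.setattr(sim, "_attm_parameters", lambda a, r: (0.5, 1.0))

        class Stub:
            draws = iter([0.5] + [0.81] * 20)

            def random(self, size=None):
                return next(self.draws)

            def standard_normal(self, size=None):
                return np.ones(size)

        traj = simulate_attm(ModelSpec.create("ATTM", 0.5), horizon=10, rng=Stub())
        inc = np.diff(traj.positions[0])
        assert traj.length == 11
        np.testing.assert_allclose(inc[:4], np.sqrt(2 * 0.25))
        # later segments use D = 0.81^2: duration 0.6561^-1 rounds to 2 steps
        np.testing.assert_allclose(inc[4:], np.sqrt(2 * 0.81**2))

    def test_brownian_segment_variance(self, rng):
        # alpha=1 degenerates to BM with one random D: var(dx) = 2 D dt
        seed = 7
        d = np.random.default_rng(seed).random()
        traj = simulate_attm(
            ModelSpec.create("ATTM", 1.0), horizon=20000, rng=np.random.default_rng(seed)
        )
        inc = np.diff(traj.positions[0])
        assert np.var(inc) == pytest.approx(2 * d, rel=0.05)

    def test_superdiffusive_alpha_rejected(self):
        with pytest.raises(ModelConstraintError):
            ModelSpec.create("ATTM", 1.2)


# ---------------------------------------------------------------------------
# SBM


class TestSbm:
    def test_increment_variance_ratio(self, rng):
        # var(dx_2)/var(dx_1) = 2^alpha - 1
        inc = sim._sbm_increments(0.5, 3, 1.0, rng, size=10**5)
        ratio = np.var(inc[:, 1]) / np.var(inc[:, 0])
        assert ratio == pytest.approx(2**0.5 - 1, abs=0.02)

    def test_alpha_one_iid_increments(self, rng):
        traj = simulate_sbm(ModelSpec.create("SBM", 1.0), 5000, rng=rng)
        inc = np.diff(traj.positions[0])
        # constant diffusivity: halves of the path have equal increment variance
        v1, v2 = np.var(inc[:2500]), np.var(inc[2500:])
        assert v1 == pytest.approx(v2, rel=0.15)

    def test_exact_grid_variance(self, rng):
        # var(x(t)) = 2 K t^alpha exactly on the sampling grid
        inc = sim._sbm_increments(1.5, 6, 1.0, rng, size=200000)
        var = np.var(np.cumsum(inc, axis=1), axis=0)
        t = np.arange(1, 6)
        np.testing.assert_allclose(var, 2 * t**1.5, rtol=0.03)


# ---------------------------------------------------------------------------
# regularize / lift_dimension


class TestRegularize:
    def test_hold(self):
        traj = EventTrajectory([2.0, 5.0], [[1.0, 0.5]], Interpolation.HOLD)
        reg = regularize(traj, horizon=4)
        np.testing.assert_allclose(reg.positions[0], [0, 0, 1.0, 1.0, 1.0])

    def test_linear(self):
        traj = EventTrajectory([1.0, 3.0], [[2.0, -2.0]], Interpolation.LINEAR)
        reg = regularize(traj, horizon=3)
        np.testing.assert_allclose(reg.positions[0], [0, 2.0, 0.0, -2.0])

    def test_origin_before_first_event(self):
        traj = EventTrajectory([10.0], [[1.0]], Interpolation.HOLD)
        reg = regularize(traj, horizon=5)
        np.testing.assert_allclose(reg.positions[0], np.zeros(6))

    def test_uncovered_horizon_rejected(self):
        traj = EventTrajectory([2.0], [[1.0]], Interpolation.HOLD)
        with pytest.raises(InvalidParameterError):
            regularize(traj, horizon=5)


class TestLiftDimension:
    def test_dim1_passthrough(self, rng):
        lengths = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            lift_dimension(Model.LW, 1, lengths, rng), lengths[None, :]
        )

    def test_lw_2d_flight_norm(self, rng):
        spec = ModelSpec.create("LW", 1.5, speed=4.0)
        traj = simulate_lw(spec, horizon=50, rng=rng, dim=2)
        steps = np.diff(traj.positions, axis=1, prepend=np.zeros((2, 1)))
        norms = np.linalg.norm(steps, axis=0)
        flights = np.diff(traj.times, prepend=0.0)
        np.testing.assert_allclose(norms, 4.0 * flights, rtol=1e-9)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_direction_uniformity(self, dim, rng):
        dirs = random_directions(dim, 10**4, rng)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=0), 1.0, rtol=1e-9)
        resultant = np.linalg.norm(dirs.mean(axis=1))
        assert resultant < 3 / np.sqrt(10**4)

    def test_bad_dim_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            lift_dimension(Model.LW, 4, np.ones(3), rng)


# ---------------------------------------------------------------------------
# dispatcher


class TestSimulate:
    @pytest.mark.parametrize(
        "model,alpha",
        [("ATTM", 0.6), ("CTRW", 0.5), ("FBM", 1.2), ("LW", 1.5), ("SBM", 0.8)],
    )
    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_length_contract(self, model, alpha, dim):
        traj = simulate(model, alpha, 64, dim=dim, rng=3)
        assert traj.positions.shape == (dim, 64)
        assert np.all(np.isfinite(traj.positions))
        np.testing.assert_allclose(traj.positions[:, 0], 0.0)

    def test_seed_determinism(self):
        a = simulate("FBM", 0.8, 100, dim=2, rng=7)
        b = simulate("FBM", 0.8, 100, dim=2, rng=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_incompatible_pair_rejected(self):
        with pytest.raises(ModelConstraintError, match="subdiffusive"):
            simulate("CTRW", 1.5, 100)

    def test_bad_dim_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate("SBM", 1.0, 100, dim=4)
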