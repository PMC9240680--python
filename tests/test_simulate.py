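from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm

from dentdist.environment import GrowthParams, SiteEnvironment, growth_coefficient
from dentdist.simulate import (
    CFLError,
    DispersalParams,
    PopulationState,
    RunConfig,
    SheddingModel,
    SimGrid,
    Simulator,
    ToothAccumulator,
    accumulate_teeth,
    adult_dispersal_rate,
    adult_return_rate,
    default_config,
    expected_migrations_per_year,
    juvenile_dispersal_rate,
    run_simulation,
    total_variation,
)

DISP = DispersalParams()


class TestJuvenileDispersalKernel:
    def test_logistic_midpoint(self):
        assert juvenile_dispersal_rate(DISP.m_j, DISP) == pytest.approx(DISP.k_j_max / 2)

    def test_one_window_above_threshold(self):
        expected = DISP.k_j_max / (1 + np.exp(-1))
        assert juvenile_dispersal_rate(DISP.m_j + DISP.xi_j, DISP) == pytest.approx(expected)

    def test_sharp_window_approaches_step(self):
        d = replace(DISP, xi_j=1.0)
        assert juvenile_dispersal_rate(d.m_j - 10 * d.xi_j, d) < 1e-4 * d.k_j_max
        m = np.linspace(1e3, 1.6e5, 200)
        rates = juvenile_dispersal_rate(m, DISP)
        assert np.all(np.diff(rates) >= 0)
        # open interval (0, k_j_max) up to float saturation of the logistic
        assert np.all((rates > 0) & (rates <= DISP.k_j_max))


class TestAdultDispersalKernel:
    def test_peak_location_and_periodicity(self):
        t = np.linspace(0, 365, 2000, endpoint=False)
        rates = adult_dispersal_rate(t, DISP)
        assert abs(t[np.argmax(rates)] - DISP.t_peak) < 0.5
        assert np.allclose(adult_dispersal_rate(t, DISP),
                           adult_dispersal_rate(t + 365, DISP), atol=1e-12)

    def test_annual_integral_matches_closed_form(self):
        """Quadrature of the pulse equals k_a_max * xi_a * sqrt(2*pi)."""
        for xi_a in (3.0, 20.0, 90.0):
            d = replace(DISP, xi_a=xi_a)
            t = np.linspace(0, 365, 200_001)
            integral = np.trapezoid(adult_dispersal_rate(t, d), t)
            assert integral == pytest.approx(expected_migrations_per_year(d), rel=1e-3)

    def test_return_pulse_delayed_by_residence(self):
        t = np.linspace(0, 365, 5000, endpoint=False)
        peak = t[np.argmax(adult_return_rate(t, DISP))]
        assert peak == pytest.approx((DISP.t_peak + DISP.residence) % 365, abs=0.5)


def _toy_two_bin_config():
    growth = GrowthParams()
    edges = (growth.m0 / 2, 3.2e4, 1.05 * growth.M)
    cfg = RunConfig(
        site_juvenile=SiteEnvironment(15.0, 15.0, label="juvenile"),
        site_adult=SiteEnvironment(15.0, 15.0, label="adult"),
        grid=SimGrid(edges, dt=0.002, n_years=2, burn_in_years=1),
    )
    cfg = replace(cfg, demography=replace(cfg.demography, r=0.0))
    return cfg.with_dispersal(k_a_max=0.0)


class TestStepOperator:
    def test_pure_mortality_decay(self, default_cfg):
        """With r = 0 and dispersal off, N(t) = N0 exp(-mu t) to high accuracy."""
        cfg = replace(default_cfg, demography=replace(default_cfg.demography, r=0.0))
        cfg = cfg.with_dispersal(k_j_max=0.0, k_a_max=0.0)
        sim = Simulator(cfg)
        A0 = np.zeros((2, cfg.grid.n_bins))
        A0[0, sim.m0_bin] = 600.0
        A0[1, -4] = 400.0
        state = PopulationState(A0, 0.0)
        days = 3650
        for _ in range(days):
            state = sim.step(state)
        exact = 1000.0 * np.exp(-cfg.demography.mu * days)
        assert state.total() == pytest.approx(exact, rel=1e-8)

    def test_two_bin_toy_matches_matrix_exponential(self):
        """Sequential operator splitting converges to the linear-system flow."""
        cfg = _toy_two_bin_config()
        sim = Simulator(cfg)
        a = growth_coefficient(15.0, cfg.growth)
        g_rate = a * sim.growth_base / cfg.grid.dt  # per-day advection rates
        kj = juvenile_dispersal_rate(sim.centers, cfg.dispersal)
        mu = cfg.demography.mu
        # state ordering [j0, j1, a0, a1]
        K = np.zeros((4, 4))
        K[0, 0] -= g_rate[0]; K[1, 0] += g_rate[0]
        K[2, 2] -= g_rate[0]; K[3, 2] += g_rate[0]
        K[0, 0] -= kj[0]; K[2, 0] += kj[0]
        K[1, 1] -= kj[1]; K[3, 1] += kj[1]
        K -= mu * np.eye(4)
        x0 = np.array([100.0, 40.0, 10.0, 50.0])
        t_end = 2.0
        n_steps = int(round(t_end / cfg.grid.dt))
        state = PopulationState(x0.reshape(2, 2).copy(), 0.0)
        for _ in range(n_steps):
            state = sim.step(state)
        exact = expm(K * t_end) @ x0
        assert np.allclose(state.abundance.ravel(), exact, rtol=1e-6)

    def test_supercritical_juvenile_site_grows(self, default_cfg):
        """With no dispersal and r > mu, the nursery population rises yearly."""
        cfg = default_cfg.with_dispersal(k_j_max=0.0, k_a_max=0.0)
        sim = Simulator(cfg)
        A0 = np.zeros((2, cfg.grid.n_bins))
        A0[0, -4] = 100.0  # mature females resident at the nursery
        state = PopulationState(A0, 0.0)
        totals = []
        for year in range(6):
            for _ in range(365):
                state = sim.step(state)
            totals.append(state.total(0))
        assert np.all(np.diff([100.0] + totals) > 0)

    def test_cfl_violation_raises_named_error(self, default_cfg):
        cfg = replace(default_cfg, grid=replace(default_cfg.grid, dt=60.0))
        sim = Simulator(cfg)
        state = PopulationState(np.ones((2, cfg.grid.n_bins)), 0.0)
        with pytest.raises(CFLError, match="growth advection"):
            sim.step(state)
        with pytest.raises(CFLError, match="juvenile dispersal"):
            Simulator(replace(default_cfg,
                              grid=replace(default_cfg.grid, dt=300.0)))

    def test_negative_state_rejected(self):
        with pytest.raises(Exception):
            PopulationState(-np.ones((2, 5)), 0.0)


class TestRunSimulation:
    def test_deterministic_reruns(self, fast_config):
        r1 = run_simulation(fast_config)
        r2 = run_simulation(fast_config)
        assert np.array_equal(r1.accumulator.counts, r2.accumulator.counts)
        assert r1.config_hash == r2.config_hash

    def test_abundances_stay_finite_nonnegative(self, fast_result):
        assert np.all(np.isfinite(fast_result.final_state.abundance))
        assert np.all(fast_result.final_state.abundance >= 0)
        assert np.all(fast_result.accumulator.counts >= 0)

    def test_step_size_convergence(self, fast_config):
        """Halving dt perturbs normalized tooth distributions by < 1% TV."""
        fine = replace(fast_config, grid=replace(fast_config.grid, dt=0.5))
        a1 = run_simulation(fast_config).accumulator
        a2 = run_simulation(fine).accumulator
        for s in (0, 1):
            assert total_variation(a1.counts[s], a2.counts[s]) < 0.01


class TestToothAccumulation:
    def test_rate_scaling_and_seasonality(self):
        state = PopulationState(np.arange(1.0, 11.0).reshape(2, 5), time=40.0)
        edges = np.linspace(8, 20, 6)
        acc1 = ToothAccumulator(edges, np.zeros((2, 5)))
        acc2 = ToothAccumulator(edges, np.zeros((2, 5)))
        accumulate_teeth(state, 1.0, SheddingModel(base_rate=0.01), acc1)
        accumulate_teeth(state, 1.0, SheddingModel(base_rate=0.02), acc2)
        assert np.allclose(acc2.counts, 2.0 * acc1.counts, rtol=1e-12)
        # empty population accumulates nothing
        empty = PopulationState(np.zeros((2, 5)), 0.0)
        acc3 = ToothAccumulator(edges, np.zeros((2, 5)))
        accumulate_teeth(empty, 1.0, SheddingModel(), acc3)
        assert acc3.counts.sum() == 0.0

    def test_seasonal_rate_modulation(self):
        shed = SheddingModel(base_rate=0.01, seasonal_amplitude=0.3,
                             seasonal_peak_day=100.0)
        assert shed.rate(100.0) == pytest.approx(0.013)
        assert shed.rate(100.0 + 365 / 2) == pytest.approx(0.007)
        assert SheddingModel(base_rate=0.01).rate(77.0) == 0.01


class TestConfigValidation:
    def test_grid_must_bracket_growth_range(self):
        g = GrowthParams()
        with pytest.raises(ValueError):
            RunConfig(grid=SimGrid(tuple(np.geomspace(2 * g.m0, g.M / 2, 31))))

    def test_maturation_mass_inside_growth_range(self):
        with pytest.raises(ValueError):
            default_config().with_dispersal(m_j=1e3)

    def test_hash_stable_and_sensitive(self, default_cfg):
        assert default_cfg.config_hash() == default_config().config_hash()
        assert default_cfg.with_dispersal(xi_j=123.0).config_hash() != \
            default_cfg.config_hash()

    def test_dt_and_windows_validated(self):
        with pytest.raises(ValueError):
            SimGrid((1.0, 2.0, 3.0), dt=-1.0)
        with pytest.raises(ValueError):
            DispersalParams(xi_a=0.0)
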