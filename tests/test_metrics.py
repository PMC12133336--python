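"""Accounting metrics: CS forms, closed-form oracles, baseline differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carbontime as ct
from carbontime.core import GridError


def cs_closed_form(C0, k, T):
    """One-pool no-input oracle: CS = C0[(1 - e^{-kT})/k - T]."""
    return C0 * ((1 - np.exp(-k * T)) / k - T)


def analytic_decay_traj(C0, k, T, step):
    grid = np.linspace(0.0, T, int(round(T / step)) + 1)
    return ct.StockTrajectory(grid=grid, stocks=C0 * np.exp(-k * grid))


class TestIntegrateSeries:
    @pytest.mark.parametrize("grid, values, expected", [
        ([0, 1, 2], [1, 1, 1], 2.0),
        ([0, 10], [0, 10], 50.0),
        ([0, 1, 3], [2, 4, 4], 11.0),
    ])
    def test_piecewise_linear_exactness(self, grid, values, expected):
        assert ct.integrate_series(grid, values) == pytest.approx(expected)

    def test_exponential_area_converges(self):
        grid = np.arange(0, 60.0 + 1e-9, 0.01)
        value = ct.integrate_series(grid, 6 * np.exp(-0.01 * grid))
        assert value == pytest.approx(6 * (1 - np.exp(-0.6)) / 0.01, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(GridError):
            ct.integrate_series([0.0], [1.0])


class TestStockChange:
    def test_matches_table_values(self, estanzuela_trajs):
        d = {k: ct.stock_change_time(v, 60.0).value
             for k, v in estanzuela_trajs.items()}
        assert d["S1"] == pytest.approx(-2.71, abs=5e-3)
        assert d["S2"] == pytest.approx(-1.56, abs=5e-3)
        assert d["S3"] == 0.0

    def test_zero_at_reference_time(self, estanzuela_trajs):
        assert ct.stock_change_time(estanzuela_trajs["S1"], 0.0).value == 0.0


class TestCarbonSequestration:
    @pytest.mark.parametrize("C0, k, T", [
        (6.0, 0.01, 60.0), (1.0, 0.1, 10.0), (10.0, 0.005, 100.0),
        (3.0, 0.05, 30.0),
    ])
    def test_matches_closed_form_oracle(self, C0, k, T):
        traj = analytic_decay_traj(C0, k, T, step=0.01)
        cs = ct.carbon_sequestration(traj, T)
        assert cs.value == pytest.approx(cs_closed_form(C0, k, T), rel=1e-6)
        assert cs.units == "kg C m-2 yr"

    def test_constant_stock_gives_exact_zero(self):
        traj = ct.StockTrajectory(grid=np.linspace(0, 60, 61),
                                  stocks=np.full(61, 6.0))
        assert ct.carbon_sequestration(traj, 60.0).value == 0.0

    def test_quadrature_error_is_second_order(self):
        exact = cs_closed_form(6.0, 0.01, 60.0)
        errs = [abs(ct.carbon_sequestration(
            analytic_decay_traj(6.0, 0.01, 60.0, step=h), 60.0).value - exact)
            for h in (0.4, 0.2, 0.1)]
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        assert all(3.5 < r < 4.5 for r in ratios), (errs, ratios)

    def test_horizon_beyond_span_rejected(self, estanzuela_trajs):
        with pytest.raises(GridError, match="exceeds"):
            ct.carbon_sequestration(estanzuela_trajs["S1"], 120.0)

    def test_coarse_grid_warns_in_provenance(self):
        traj = ct.StockTrajectory(grid=[0.0, 30.0, 60.0],
                                  stocks=[6.0, 4.5, 3.3])
        cs = ct.carbon_sequestration(traj, 60.0)
        assert "warning" in cs.provenance

    def test_monotone_loss_in_horizon(self, estanzuela_trajs):
        # pure-loss system: CS strictly decreases as the horizon grows
        traj = estanzuela_trajs["S1"]
        values = [ct.carbon_sequestration(traj, T).value
                  for T in (10, 20, 30, 40, 50, 60)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestFluxFormEquivalence:
    def test_fixture_forms_agree(self, estanzuela_models, estanzuela_trajs):
        for name in ("S1", "S2", "S3"):
            traj = estanzuela_trajs[name]
            fluxes = ct.release_flux(estanzuela_models[name], traj)
            a = ct.cs_from_fluxes(fluxes, 60.0).value
            b = ct.carbon_sequestration(traj, 60.0).value
            assert abs(a - b) <= 1e-6 * max(abs(a), abs(b), 1.0)

    def test_constant_net_flux_gives_half_cT_squared(self):
        grid = np.linspace(0, 10, 101)
        fluxes = ct.FluxSeries(grid=grid, uptake=np.full(101, 0.3),
                               release=np.full(101, 0.1))
        assert ct.cs_from_fluxes(fluxes, 10.0).value == pytest.approx(
            0.2 * 100 / 2, rel=1e-12)

    def test_zero_net_flux_gives_zero(self):
        grid = np.linspace(0, 10, 101)
        fluxes = ct.FluxSeries(grid=grid, uptake=np.zeros(101),
                               release=np.zeros(101))
        assert ct.cs_from_fluxes(fluxes, 10.0).value == 0.0


class TestNewInputsCS:
    def test_zero_inputs_give_zero_with_note(self, one_pool_decay):
        res = ct.cs_new_inputs(one_pool_decay, 60.0)
        assert res.value == 0.0
        assert "note" in res.provenance

    def test_empty_system_equals_total_cs(self):
        m = ct.CompartmentalModel(B=[[-0.02]], u=[1.0], x0=[0.0])
        traj = ct.simulate(m, 50.0, step=0.01)
        total = ct.carbon_sequestration(traj, 50.0).value
        new = ct.cs_new_inputs(m, 50.0).value
        assert new == pytest.approx(total, rel=1e-8)

    def test_superposition_against_legacy_run(self):
        m = ct.CompartmentalModel(B=[[-0.02]], u=[1.0], x0=[5.0])
        full = ct.carbon_sequestration(ct.simulate(m, 50.0, step=0.01), 50.0)
        legacy = ct.carbon_sequestration(
            ct.simulate(m.with_(u=[0.0]), 50.0, step=0.01), 50.0)
        new = ct.cs_new_inputs(m, 50.0)
        assert full.value - legacy.value == pytest.approx(new.value, rel=1e-6)


class TestBaselineMetrics:
    def test_avoided_stock_losses(self, estanzuela_trajs):
        s1, s2, s3 = (estanzuela_trajs[k] for k in ("S1", "S2", "S3"))
        assert ct.delta_baseline_stock(s2, s1, 60.0).value == pytest.approx(
            1.15, abs=5e-3)
        assert ct.delta_baseline_stock(s3, s1, 60.0).value == pytest.approx(
            2.71, abs=5e-3)
        assert ct.delta_baseline_stock(s1, s1, 60.0).value == 0.0

    def test_avoided_sequestration_losses(self, estanzuela_trajs):
        s1, s2, s3 = (estanzuela_trajs[k] for k in ("S1", "S2", "S3"))
        assert ct.delta_baseline_cs(s2, s1, 60.0).value == pytest.approx(
            40.31, abs=5e-3)
        assert ct.delta_baseline_cs(s3, s1, 60.0).value == pytest.approx(
            89.29, abs=5e-3)

    def test_antisymmetry_under_swap(self, estanzuela_trajs):
        s1, s2 = estanzuela_trajs["S1"], estanzuela_trajs["S2"]
        fwd = ct.delta_baseline_cs(s2, s1, 60.0).value
        rev = ct.delta_baseline_cs(s1, s2, 60.0).value
        assert fwd == pytest.approx(-rev, rel=1e-12)

    def test_equal_initial_stock_identity(self, estanzuela_trajs):
        # shared C(0) implies dbCS = integral of dbC(t) dt
        s1, s2 = estanzuela_trajs["S1"], estanzuela_trajs["S2"]
        dcs = ct.delta_baseline_cs(s2, s1, 60.0).value
        integral = ct.integrate_series(s1.grid, s2.total - s1.total)
        assert dcs == pytest.approx(integral, rel=1e-6)

    def test_relative_percentages(self, estanzuela_trajs):
        s1, s2, s3 = (estanzuela_trajs[k] for k in ("S1", "S2", "S3"))
        rs2, rcs2 = ct.relative_metrics(s2, s1, 60.0)
        rs3, rcs3 = ct.relative_metrics(s3, s1, 60.0)
        assert round(rs2.value) == 35 and round(rcs2.value) == 45
        assert round(rs3.value) == 82 and round(rcs3.value) == 100
        rs_self, rcs_self = ct.relative_metrics(s1, s1, 60.0)
        assert rs_self.value == 0.0 and rcs_self.value == 0.0

    def test_zero_denominator_raises(self):
        grid = np.linspace(0, 10, 11)
        flat0 = ct.StockTrajectory(grid=grid, stocks=np.zeros(11), name="nil")
        proj = ct.StockTrajectory(grid=grid, stocks=np.ones(11))
        with pytest.raises(ZeroDivisionError, match="nil"):
            ct.relative_metrics(proj, flat0, 10.0)

    def test_span_mismatch_rejected(self, estanzuela_trajs):
        short = ct.StockTrajectory(grid=[0.0, 10.0], stocks=[6.0, 5.0])
        with pytest.raises(GridError, match="span"):
            ct.delta_baseline_cs(estanzuela_trajs["S1"], short, 60.0)


class TestConstantBaselineEquivalence:
    def test_proportional_area_equals_proportional_stock(self):
        # two constant stocks 1.0 and 0.75 over 30 time units
        grid = np.linspace(0, 30, 301)
        hi = ct.StockTrajectory(grid=grid, stocks=np.full(301, 1.0))
        lo = ct.StockTrajectory(grid=grid, stocks=np.full(301, 0.75))
        area_hi = ct.integrate_series(grid, hi.total)
        area_lo = ct.integrate_series(grid, lo.total)
        assert (area_hi, area_lo) == (30.0, 22.5)
        prop_area = 100 * (area_hi - area_lo) / area_lo
        prop_stock = 100 * (hi.total_at(30) - lo.total_at(30)) / lo.total_at(30)
        assert prop_area == pytest.approx(prop_stock, rel=1e-12)
        assert round(prop_area) == 33


class TestSuperpositionSweep:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_total_cs_splits_into_legacy_and_new(self, seed):
        m = ct.random_model(seed)
        T, step = 20.0, 0.02
        full = ct.carbon_sequestration(ct.simulate(m, T, step=step), T).value
        legacy = ct.carbon_sequestration(
            ct.simulate(m.with_(u=np.zeros(m.n_pools)), T, step=step), T).value
        new = ct.cs_new_inputs(m, T, step=step).value
        scale = max(abs(full), np.max(m.x0) * T, 1.0)
        assert abs(full - (legacy + new)) / scale < 1e-6
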