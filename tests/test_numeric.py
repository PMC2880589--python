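import math

import numpy as np
import pytest

import gcmature as g
from gcmature import numeric
from gcmature.analytic import AnalyticSolution, total_population
from gcmature.core import derive_rates
from gcmature.spectrum import MutationSpectrum

KA18_OFFSET = 1.0  # Ka_in/Ka* = 0.18 at kT = 0.59


def single_class(delta):
    return MutationSpectrum(bin_width=0.5, offsets=(delta,), weights=(1.0,))


class TestStep:
    def test_pure_growth_single_bin(self):
        # no mutations: one eligible bin just multiplies by e^{B dt}
        params = g.ModelParams(p_mutated_daughter=0.0, b=0.7, N0=1000, X_star_offset_in=1.0)
        rates = derive_rates(params)
        state = numeric.initial_state(params)
        dt = 0.01 / (0.7 * 0.5)
        out = numeric.step(state, params, rates, single_class(-0.5), dt)
        idx = np.argmin(np.abs(state.x_offsets - 1.0))
        assert out.counts[idx] == pytest.approx(1000 * math.exp(-0.7 * dt), rel=1e-12)
        assert out.counts.sum() == pytest.approx(out.counts[idx])

    def test_first_order_mutation_influx(self):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e6, X_star_offset_in=1.0)
        rates = derive_rates(params)
        state = numeric.initial_state(params)
        dt = 0.01 / (0.7 * 0.5)
        out = numeric.step(state, params, rates, single_class(-0.5), dt)
        src = np.argmin(np.abs(state.x_offsets - 1.0))
        dest = src - 1
        assert out.counts[dest] == pytest.approx(1e6 * rates.m_aff * dt, rel=5e-2)

    def test_subunity_bins_are_frozen(self):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
        rates = derive_rates(params)
        state = numeric.initial_state(params)
        state.counts[:] = 0.0
        state.counts[2] = 0.5  # strong-affinity bin below one cell
        out = numeric.step(state, params, rates, single_class(-0.5), 0.02)
        assert out.counts[2] == 0.5
        assert out.counts.sum() == 0.5

    def test_mutation_operator_conserves_cells_without_growth(self):
        # b = 0 and no lethal class: pure mutation shuffling must conserve
        # the total to machine precision
        params = g.ModelParams(
            p_mutated_daughter=0.5, b=0.0, N0=1e5, X_star_offset_in=0.0,
            f_silent=0.8, f_lethal=0.0, f_affinity=0.2,
        )
        rates = derive_rates(params)
        state = numeric.initial_state(params)
        total0 = state.counts.sum()
        for _ in range(50):
            state = numeric.step(state, params, rates, single_class(-0.5), dt=0.02)
        assert state.counts.sum() + state.edge_loss_low == pytest.approx(total0, rel=1e-13)

    def test_nan_state_rejected(self):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7)
        state = numeric.initial_state(params)
        state.counts[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            numeric.step(state, params, dt=0.02)

    def test_nonpositive_dt_rejected(self):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7)
        state = numeric.initial_state(params)
        with pytest.raises(ValueError, match="dt"):
            numeric.step(state, params, dt=0.0)


class TestAnalyticOracle:
    def test_cutoff_free_integrator_matches_closed_form(self, default_spec, anchor_params):
        # the central consistency check: without the sub-unity cutoff the
        # grid integrator must reproduce the exact solution through the
        # population-decline phase
        params = anchor_params.with_(t_max=5.0)
        sol = AnalyticSolution(params, default_spec)
        traj = numeric.run(
            params, default_spec, "horizon_only", cutoff=False, dt=0.001 / (0.7 * 0.5)
        )
        for t in (1.0, 2.0, 3.0, 4.0, 5.0):
            i = np.argmin(np.abs(traj.times - t))
            exact = total_population(traj.times[i], sol)
            assert traj.n_tot[i] == pytest.approx(exact, rel=5e-3)

    def test_step_size_convergence(self, default_spec, anchor_params):
        params = anchor_params.with_(t_max=5.0)
        coarse = numeric.run(params, default_spec, "horizon_only")
        fine = numeric.run(params, default_spec, "horizon_only", dt=0.005 / (0.7 * 0.5))
        assert abs(coarse.n_tot[-1] - fine.n_tot[-1]) / fine.n_tot[-1] < 2e-3

    def test_edge_loss_negligible_on_default_grid(self, default_spec, anchor_params):
        traj = numeric.run(anchor_params.with_(t_max=5.0), default_spec, "horizon_only")
        assert traj.edge_loss < 1e-3 * anchor_params.N0


class TestRun:
    def test_bottleneck_shape_shrink_then_grow(self, default_spec):
        # large population one kcal/mol weaker than neutral: total count
        # decreases, passes a minimum, and recovers
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e6, X_star_offset_in=1.0)
        traj = numeric.run(params, default_spec, "recovery_unbounded")
        assert traj.status == "recovered"
        imin = np.argmin(traj.n_tot)
        assert 0 < imin < len(traj.n_tot) - 1
        assert traj.bottleneck_depth < 0.05 * params.N0
        assert traj.n_tot[-1] >= params.N0

    def test_extinction_below_critical_size(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=300, X_star_offset_in=1.0)
        traj = numeric.run(params, default_spec, "recovery_unbounded")
        assert traj.status == "extinct"
        assert numeric.improvement(traj) == 0.0

    def test_supercritical_start_recovers_immediately(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e4, X_star_offset_in=-1.0)
        traj = numeric.run(params, default_spec, "recovery_unbounded")
        assert traj.status == "recovered"
        assert traj.bottleneck_time == 0.0
        assert np.all(np.diff(traj.n_tot) >= 0)

    def test_fixed_window_caps_at_14_days(self, default_spec, anchor_params):
        traj = numeric.run(anchor_params, default_spec, "fixed_window_14d")
        assert traj.t_end <= 14.0 + 1e-9
        assert traj.status in ("recovered", "timed_out")

    def test_mode_a_bounded_by_mode_b(self, default_spec):
        # truncating at 14 days can only reduce the improvement for cells
        # that recover in both conventions
        for ka in (0.437, 0.658):
            params = g.ModelParams(
                p_mutated_daughter=0.5, b=0.7, N0=1e5,
                X_star_offset_in=-0.59 * math.log(ka),
            )
            a = numeric.run(params, default_spec, "fixed_window_14d")
            b = numeric.run(params, default_spec, "recovery_unbounded")
            if a.status == b.status == "recovered":
                assert numeric.improvement(a) <= numeric.improvement(b) + 1e-9

    def test_strong_fraction_non_decreasing_after_first_strong_cell(self, default_spec):
        params = g.ModelParams(
            p_mutated_daughter=0.5, b=0.7, N0=3000, X_star_offset_in=-0.59 * math.log(0.5)
        )
        traj = numeric.run(params, default_spec, "recovery_unbounded")
        f = traj.strong_fraction
        i0 = int(np.argmax(f > 0))
        assert np.all(np.diff(f[i0:]) >= -1e-9)

    def test_initial_offset_outside_grid_rejected(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, X_star_offset_in=20.0)
        with pytest.raises(ValueError, match="outside grid"):
            numeric.run(params, default_spec, "horizon_only")

    def test_unknown_mode_rejected(self, default_spec, anchor_params):
        with pytest.raises(ValueError, match="termination"):
            numeric.run(anchor_params, default_spec, "whenever")


class TestImprovement:
    def test_zero_duration_run_is_unity(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, t_max=0.0)
        traj = numeric.run(params, default_spec, "horizon_only")
        assert numeric.improvement(traj) == 1.0

    def test_extinct_run_is_zero(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=100, X_star_offset_in=1.5)
        traj = numeric.run(params, default_spec, "recovery_unbounded")
        assert traj.status == "extinct"
        assert numeric.improvement(traj) == 0.0
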