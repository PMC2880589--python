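import math

import numpy as np
import pytest

import gcmature as g
from gcmature.analytic import (
    AnalyticSolution,
    gaussian_profile,
    j_max,
    peak_mutation_count,
    subpopulation_j,
    total_population,
)
from gcmature.spectrum import MutationSpectrum


def single_class(delta, h=0.5):
    lo = min(delta, 0.0) if delta < 0 else 0.0
    offs = [delta]
    return MutationSpectrum(bin_width=h, offsets=tuple(offs), weights=(1.0,))


@pytest.fixture
def sol(default_spec):
    params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
    return AnalyticSolution(params, default_spec)


class TestTotalPopulation:
    def test_initial_value(self, sol):
        assert total_population(0.0, sol) == pytest.approx(sol.N0)

    def test_no_mutation_limit_is_pure_exponential(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.0, b=0.7, N0=1e4, X_star_offset_in=1.0)
        s = AnalyticSolution(params, default_spec)
        for t in (0.5, 2.0, 4.0):
            assert total_population(t, s) == pytest.approx(1e4 * math.exp(-0.7 * t), rel=1e-12)

    def test_negative_time_rejected(self, sol):
        with pytest.raises(ValueError):
            total_population(-1.0, sol)

    def test_zero_selection_collapses_mutation_factors(self, default_spec):
        # with b = 0 every growth gain g_i vanishes, mutations become plain
        # Poisson bookkeeping, and their factors multiply to exactly 1
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.0, N0=1e5, X_star_offset_in=1.0)
        s = AnalyticSolution(params, default_spec)
        for t in (0.0, 1.0, 3.0, 10.0):
            assert total_population(t, s) == pytest.approx(1e5, rel=1e-14)

    def test_continuity_in_b_at_zero(self, default_spec):
        params0 = g.ModelParams(p_mutated_daughter=0.5, b=0.0, N0=1e5, X_star_offset_in=1.0)
        params_eps = g.ModelParams(p_mutated_daughter=0.5, b=1e-9, N0=1e5, X_star_offset_in=1.0)
        n0 = total_population(3.0, AnalyticSolution(params0, default_spec))
        n_eps = total_population(3.0, AnalyticSolution(params_eps, default_spec))
        assert n_eps == pytest.approx(n0, rel=1e-6)

    def test_multi_class_factorization(self, default_spec):
        # the total factorizes: growth term times one mutation factor per
        # spectrum class
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
        full = AnalyticSolution(params, default_spec)
        t = 3.0
        base = 1e5 * math.exp(-0.7 * t)
        product = base
        for delta, w in zip(default_spec.offsets, default_spec.weights):
            one = AnalyticSolution(
                params, MutationSpectrum(bin_width=0.5, offsets=(delta,), weights=(1.0,))
            )
            m_aff_scale = w  # class rate is m_aff * w
            m = full.rates.m_aff * w
            ggain = -0.7 * delta
            product *= math.exp(m * ((math.expm1(ggain * t)) / ggain - t))
        assert total_population(t, full) == pytest.approx(product, rel=1e-10)


class TestSubpopulations:
    def test_poisson_normalization_sums_to_total(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
        spec = single_class(-0.5)
        s = AnalyticSolution(params, spec)
        t = 4.0
        lam = s.rates.m_aff * math.expm1(0.35 * t) / 0.35
        total = sum(subpopulation_j(t, 0, j, s) for j in range(j_max(lam)))
        assert total == pytest.approx(total_population(t, s), rel=1e-10)

    def test_zero_gain_limit_is_plain_poisson(self, default_spec):
        # b -> 0: N_j = N0 Poisson(m t)(j), neutral mutation accumulation
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.0, N0=1e5, X_star_offset_in=1.0)
        s = AnalyticSolution(params, single_class(-0.5))
        t, m = 2.0, params.f_affinity * 4 * math.log(2)
        for j in range(6):
            expected = 1e5 * math.exp(-m * t) * (m * t) ** j / math.factorial(j)
            assert subpopulation_j(t, 0, j, s) == pytest.approx(expected, rel=1e-12)

    def test_short_time_power_law(self):
        # for b h t << 1 the j-mutant subpopulation scales as t^j
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
        s = AnalyticSolution(params, single_class(-0.5))
        ts = np.array([0.002, 0.004, 0.008]) / (0.7 * 0.5)
        for j in (1, 2, 3):
            vals = np.array([subpopulation_j(t, 0, j, s) for t in ts])
            slopes = np.diff(np.log(vals)) / np.diff(np.log(ts))
            assert np.allclose(slopes, j, rtol=0.02)

    def test_negative_count_rejected(self, sol):
        with pytest.raises(ValueError):
            subpopulation_j(1.0, 0, -1, sol)


class TestPeakMutationCount:
    def test_zero_at_short_time(self, sol):
        assert peak_mutation_count(1e-9, 0, sol) == 0

    def test_poisson_mode_is_floor_of_mean(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
        s = AnalyticSolution(params, single_class(-0.5))
        # find t where lambda = 3.7 and check the mode
        m = s.rates.m_aff
        target = 3.7
        t = math.log1p(target * 0.35 / m) / 0.35
        assert peak_mutation_count(t, 0, s) == 3

    def test_deleterious_class_rejected(self, sol):
        # class index of a positive-offset (deleterious) bin
        i_del = list(sol.spectrum.offsets).index(0.5)
        with pytest.raises(ValueError, match="beneficial"):
            peak_mutation_count(1.0, i_del, sol)

    def test_monotone_non_decreasing_in_time(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
        s = AnalyticSolution(params, single_class(-1.0))
        peaks = [peak_mutation_count(t, 0, s) for t in np.linspace(0.01, 12, 60)]
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))


class TestGaussianProfile:
    @pytest.fixture
    def gsol(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.0, b=0.7, N0=1e4, X_star_offset_in=1.0)
        return AnalyticSolution(params, default_spec, sigma=0.6)

    def test_initial_profile_is_the_gaussian(self, gsol):
        x = np.linspace(-2, 4, 200)
        expected = 1e4 * np.exp(-0.5 * ((x - 1.0) / 0.6) ** 2) / (0.6 * math.sqrt(2 * math.pi))
        assert np.allclose(gaussian_profile(x, 0.0, gsol), expected, rtol=1e-12)

    def test_mean_drifts_at_b_sigma_squared(self, gsol):
        # completing the square: mean(t) = X_in - b sigma^2 t at fixed width
        x = np.linspace(-10, 10, 4001)
        for t in (1.0, 3.0):
            prof = gaussian_profile(x, t, gsol)
            mean = np.trapezoid(x * prof, x) / np.trapezoid(prof, x)
            assert mean == pytest.approx(1.0 - 0.7 * 0.36 * t, abs=1e-6)

    def test_integral_matches_total_population(self, gsol):
        x = np.linspace(-15, 12, 8001)
        for t in (0.5, 2.0):
            integral = np.trapezoid(gaussian_profile(x, t, gsol), x)
            assert integral == pytest.approx(total_population(t, gsol), rel=1e-7)

    def test_requires_gaussian_ic_and_no_mutation(self, default_spec):
        params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e4, X_star_offset_in=1.0)
        with pytest.raises(ValueError, match="Gaussian"):
            gaussian_profile(0.0, 1.0, AnalyticSolution(params, default_spec))
        with pytest.raises(ValueError, match="mutation-free"):
            gaussian_profile(0.0, 1.0, AnalyticSolution(params, default_spec, sigma=0.5))
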