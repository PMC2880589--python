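"""Closed-form solution of the linear-selection mutation equation.

In the regime where the net growth rate depends linearly on the binding
free-energy offset, ``B(X) = -b (X - X*)``, the mean-field equation for the
population density admits an exact solution.  For a point (delta) initial
condition of ``N0`` cells at offset ``X_in`` the total population factorizes
over mutation classes:

    N_tot(t) = N0 exp(B(X_in) t) * prod_i exp{ m_i [ (e^{g_i t} - 1)/g_i - t ] }

with one factor per spectrum bin, where ``m_i = m_aff w_i`` is the rate of
mutations of effect ``delta_i`` and ``g_i = -b delta_i`` the growth-rate gain
they confer.  Beneficial classes (``g_i > 0``) contribute super-exponential
growth; deleterious classes reduce the population by at most ``e^{-m_i t}``.
The per-class subpopulation with exactly ``j`` mutations is Poisson with the
time-dependent mean ``lambda_i(t) = m_i (e^{g_i t} - 1)/g_i``, which replaces
the plain ``m_i t`` of neutral (``b = 0``) Poisson accumulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import DerivedRates, ModelParams, derive_rates
from .spectrum import MutationSpectrum

__all__ = [
    "AnalyticSolution",
    "total_population",
    "subpopulation_j",
    "peak_mutation_count",
    "gaussian_profile",
]


@dataclass(frozen=True)
class AnalyticSolution:
    """Parameters + spectrum + initial condition for the closed form.

    ``sigma is None`` selects a delta initial condition (``N0`` cells at
    offset ``X_in``); otherwise the initial profile is Gaussian with mean
    ``X_in`` and width ``sigma``.  The linear growth law is assumed valid
    over the occupied range (no saturation cap).
    """

    params: ModelParams
    spectrum: MutationSpectrum
    X_in: float | None = None
    sigma: float | None = None
    N0: float | None = None

    def __post_init__(self) -> None:
        if self.X_in is None:
            object.__setattr__(self, "X_in", self.params.X_star_offset_in)
        if self.N0 is None:
            object.__setattr__(self, "N0", self.params.N0)
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"Gaussian width sigma must be positive, got {self.sigma}")

    @property
    def rates(self) -> DerivedRates:
        return derive_rates(self.params)


def _growth_integral(g: float, t) -> np.ndarray:
    """(e^{g t} - 1)/g, with the analytic g -> 0 limit t + g t^2/2."""
    t = np.asarray(t, dtype=float)
    if abs(g) < 1e-12 or np.all(np.abs(g * t) < 1e-6):
        return t * (1.0 + 0.5 * g * t)
    return np.expm1(g * t) / g


def _class_rates(sol: AnalyticSolution) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mutation rates m_i and growth gains g_i."""
    m_aff = sol.rates.m_aff
    w = np.asarray(sol.spectrum.weights)
    delta = np.asarray(sol.spectrum.offsets)
    return m_aff * w, -sol.params.b * delta


def _base_log_growth(sol: AnalyticSolution, t: np.ndarray) -> np.ndarray:
    """log of the mutation-free total: delta IC grows as e^{B(X_in) t};
    a Gaussian IC gains the extra e^{b^2 sigma^2 t^2 / 2} from its
    drifting mean."""
    b = sol.params.b
    out = -b * sol.X_in * t
    if sol.sigma is not None:
        out = out + 0.5 * (b * sol.sigma) ** 2 * t**2
    return out


def total_population(t, sol: AnalyticSolution) -> np.ndarray:
    """Expected total cell count at time ``t`` (days, scalar or array).

    Warns when the dominant beneficial subpopulation drifts below the
    saturation offset ``-D``, where the uncapped linear growth law (and
    hence this closed form) overestimates growth.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    m_i, g_i = _class_rates(sol)
    log_n = _base_log_growth(sol, t_arr).astype(float)
    for m, g in zip(m_i, g_i):
        if m == 0:
            continue
        log_n = log_n + m * (_growth_integral(g, t_arr) - t_arr)
    _warn_if_capped(sol, t_arr, m_i, g_i)
    return (sol.N0 * np.exp(log_n))[()]


def _warn_if_capped(sol, t_arr, m_i, g_i) -> None:
    D = sol.rates.D
    t_end = float(np.max(t_arr)) if np.size(t_arr) else 0.0
    for m, g, delta in zip(m_i, g_i, sol.spectrum.offsets):
        if g <= 0 or m == 0:
            continue
        lam = m * _growth_integral(g, t_end)
        x_peak = sol.X_in + math.floor(lam) * delta
        if x_peak < -D:
            warnings.warn(
                "dominant subpopulation crossed the saturation offset -D; "
                "linear-growth closed form is an overestimate there",
                RuntimeWarning,
                stacklevel=3,
            )
            return


def subpopulation_j(t, class_index: int, j: int, sol: AnalyticSolution) -> np.ndarray:
    """Expected count of cells carrying exactly ``j`` mutations of one class.

    ``N_j(t) = N0 e^{B(X_in) t} e^{-m_i t} lambda_i(t)^j / j!`` — Poisson in
    ``j`` with mean ``lambda_i(t) = m_i (e^{g_i t} - 1)/g_i``.  In the
    ``g_i -> 0`` limit this reduces to plain Poisson accumulation with mean
    ``m_i t``.  The subpopulation sits at offset ``X_in + j delta_i``.
    """
    if j < 0 or int(j) != j:
        raise ValueError(f"mutation count j must be a non-negative integer, got {j}")
    t_arr = np.asarray(t, dtype=float)
    m_i, g_i = _class_rates(sol)
    m, g = m_i[class_index], g_i[class_index]
    lam = m * _growth_integral(g, t_arr)
    log_base = _base_log_growth(sol, t_arr) - m * t_arr
    with np.errstate(divide="ignore"):
        log_pois = np.where(lam > 0, j * np.log(np.maximum(lam, 1e-300)), 0.0 if j == 0 else -np.inf)
    return (sol.N0 * np.exp(log_base + log_pois - math.lgamma(j + 1)))[()]


def j_max(lam: float) -> int:
    """Truncation index for Poisson tails: ceil(lam + 10 sqrt(lam) + 20)."""
    return int(math.ceil(lam + 10.0 * math.sqrt(max(lam, 0.0)) + 20.0))


def peak_mutation_count(t: float, class_index: int, sol: AnalyticSolution) -> int:
    """Mutation count of the largest subpopulation of a beneficial class.

    The per-class counts are Poisson(lambda_i(t)), so the mode is
    ``floor(lambda_i(t))``; at long times ``lambda_i`` grows like
    ``e^{g_i t}`` and the peak advances exponentially fast.
    """
    m_i, g_i = _class_rates(sol)
    if g_i[class_index] <= 0:
        raise ValueError("peak defined for beneficial classes only")
    lam = m_i[class_index] * _growth_integral(g_i[class_index], float(t))
    return int(math.floor(lam))


def gaussian_profile(X_offset, t: float, sol: AnalyticSolution) -> np.ndarray:
    """Mutation-free population density for a Gaussian initial profile.

    The exact linear-selection solution is the product of the initial
    Gaussian and the accumulated growth factor,

        N(X, t) = N0 Gaussian(X; X_in, sigma) e^{-b (X - X*) t},

    which by completing the square is again Gaussian with mean drifting as
    ``X_in - b sigma^2 t`` at constant width ``sigma``.  Requires
    ``m_aff = 0`` (mutation effects on the total are exercised through
    :func:`total_population`).
    """
    if sol.sigma is None:
        raise ValueError("gaussian_profile requires a Gaussian initial condition")
    if sol.rates.m_aff != 0:
        raise ValueError("gaussian_profile is the mutation-free profile; set p_mutated_daughter=0")
    if t < 0:
        raise ValueError("time must be non-negative")
    x = np.asarray(X_offset, dtype=float)
    gauss = np.exp(-0.5 * ((x - sol.X_in) / sol.sigma) ** 2) / (sol.sigma * math.sqrt(2 * math.pi))
    return (sol.N0 * gauss * np.exp(-sol.params.b * x * t))[()]
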