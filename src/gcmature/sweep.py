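"""Parameter-space sweeps: affinity-improvement landscapes over mutation
load and initial binding level, survival masks, optimum location, and the
pooled-vs-isolated migration comparison.

The mutation-load axis is the fraction ``p`` of mutated daughter cells;
the binding axis is the germline association-constant ratio
``Ka_in/Ka* = exp(-(X_in - X*)/kT)``.  The pooled-spleen limit (fast
B-cell migration between germinal centers) uses N0 = 1e5 cells and a
14-day/recovery termination; a single isolated center uses N0 = 3000 and
terminates only on recovery of the initial size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import numeric
from .core import ModelParams
from .spectrum import MutationSpectrum, default_spectrum

__all__ = [
    "SweepResult",
    "default_p_grid",
    "default_ka_grid",
    "sweep_grid",
    "find_optimum",
    "migration_comparison",
]

log = logging.getLogger(__name__)

POOLED_N0 = 1e5
ISOLATED_N0 = 3000.0


def default_p_grid() -> np.ndarray:
    """Mutated-daughter fractions 0.1 .. 0.9 in steps of 0.1."""
    return np.round(np.arange(1, 10) * 0.1, 10)


def default_ka_grid(n: int = 12) -> np.ndarray:
    """Log-spaced germline binding ratios Ka_in/Ka* in [0.01, 1]."""
    return np.geomspace(0.01, 1.0, n)


@dataclass
class SweepResult:
    """Improvement / survival landscape over (p, Ka_in/Ka*) at fixed b."""

    p_grid: np.ndarray
    ka_in_grid: np.ndarray
    b: float
    N0: float
    mode: str
    improvement: np.ndarray  # shape (len(p), len(ka))
    survival: np.ndarray
    status: np.ndarray  # object array of status strings
    t_end: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.p_grid):
            for j, ka in enumerate(self.ka_in_grid):
                rows.append(
                    dict(
                        p=p,
                        ka_in_ratio=ka,
                        b=self.b,
                        improvement=self.improvement[i, j],
                        survival=self.survival[i, j],
                        status=self.status[i, j],
                        t_end_days=self.t_end[i, j],
                    )
                )
        return pd.DataFrame(rows)


def sweep_grid(
    p_grid=None,
    ka_in_grid=None,
    b: float = 0.7,
    N0: float = POOLED_N0,
    mode: str = "fixed_window_14d",
    spectrum: MutationSpectrum | None = None,
    *,
    base_params: ModelParams | None = None,
    survival_fn=None,
) -> SweepResult:
    """Run the deterministic integrator over a (p, Ka_in/Ka*) grid.

    ``survival_fn(params, spectrum) -> probability`` plugs in the
    stochastic survival estimate per cell; by default survival is the
    deterministic 0/1 indicator of recovery.  Per-cell failures are
    recorded as status ``"error"`` rather than aborting the sweep.
    """
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    ka_in_grid = default_ka_grid() if ka_in_grid is None else np.asarray(ka_in_grid, dtype=float)
    if p_grid.size == 0 or ka_in_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    base = base_params or ModelParams()
    if spectrum is None:
        spectrum = default_spectrum(base.kT)

    shape = (p_grid.size, ka_in_grid.size)
    imp = np.zeros(shape)
    surv = np.zeros(shape)
    status = np.full(shape, "", dtype=object)
    t_end = np.full(shape, np.nan)

    for i, p in enumerate(p_grid):
        for j, ka in enumerate(ka_in_grid):
            x_in = -base.kT * math.log(ka)
            params = base.with_(p_mutated_daughter=float(p), b=b, N0=N0, X_star_offset_in=x_in)
            try:
                traj = numeric.run(params, spectrum, mode)
            except Exception as exc:  # recorded, not fatal
                log.warning("sweep cell p=%.2f ka=%.3g failed: %s", p, ka, exc)
                status[i, j] = "error"
                continue
            imp[i, j] = numeric.improvement(traj)
            status[i, j] = traj.status
            t_end[i, j] = traj.t_end
            if survival_fn is not None:
                surv[i, j] = survival_fn(params, spectrum)
            else:
                surv[i, j] = 1.0 if traj.status == "recovered" else 0.0
    return SweepResult(
        p_grid=p_grid, ka_in_grid=ka_in_grid, b=b, N0=N0, mode=mode,
        improvement=imp, survival=surv, status=status, t_end=t_end,
    )


def find_optimum(result: SweepResult) -> dict:
    """Locate the improvement maximum of a sweep.

    Ties are broken toward smaller recovery time, then smaller p.
    Raises if every grid cell went extinct (or errored).
    """
    ok = np.array(
        [[s not in ("extinct", "error") for s in row] for row in result.status], dtype=bool
    )
    if not ok.any():
        raise ValueError("no surviving parameter cell")
    best = None
    for i in range(result.p_grid.size):
        for j in range(result.ka_in_grid.size):
            if not ok[i, j]:
                continue
            key = (-result.improvement[i, j], result.t_end[i, j], result.p_grid[i])
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i, j = best
    return {
        "p": float(result.p_grid[i]),
        "ka_in_ratio": float(result.ka_in_grid[j]),
        "b": float(result.b),
        "improvement": float(result.improvement[i, j]),
        "t_end_days": float(result.t_end[i, j]),
    }


def migration_comparison(
    spectrum: MutationSpectrum | None = None,
    b: float = 0.7,
    *,
    base_params: ModelParams | None = None,
    pooled_N0: float = POOLED_N0,
    isolated_N0: float = ISOLATED_N0,
    p_grid=None,
    ka_in_grid=None,
    isolated_mode: str = "recovery_unbounded",
    pooled_mode: str = "fixed_window_14d",
) -> dict:
    """Fold-enhancement of affinity improvement from fast inter-GC migration.

    Ratio of the pooled-spleen optimum (large effective population, which
    can afford a weaker germline binding) to the isolated-GC optimum, each
    maximized over its own (p, Ka_in/Ka*) grid under its own termination
    convention.
    """
    pooled = sweep_grid(
        p_grid, ka_in_grid, b, pooled_N0, pooled_mode, spectrum, base_params=base_params
    )
    isolated = sweep_grid(
        p_grid, ka_in_grid, b, isolated_N0, isolated_mode, spectrum, base_params=base_params
    )
    opt_pooled = find_optimum(pooled)
    opt_isolated = find_optimum(isolated)
    return {
        "pooled": opt_pooled,
        "isolated": opt_isolated,
        "ratio": opt_pooled["improvement"] / opt_isolated["improvement"],
    }
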