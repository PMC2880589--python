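"""The "all-or-none" statistic: distribution of the strong-affinity
fraction across an ensemble of identically parameterized germinal centers.

Individual centers following the same development curve but starting at
random times are, at any observation moment, equivalent to a single center
observed at a uniformly random time.  The observed distribution of the
strong-affinity fraction F is therefore P(F) ~ dt(F)/dF, estimated here
robustly as time-spent-per-F-bin: because F dwells near its initial and
terminal plateaus and sweeps quickly through intermediate values, P(F)
piles up at the extremes — centers look either unmutated or fully matured,
rarely in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .numeric import Trajectory

__all__ = ["FractionDistribution", "f_trajectory", "p_of_f"]


@dataclass(frozen=True)
class FractionDistribution:
    """Probability mass of the strong-affinity fraction F per bin of [0, 1]."""

    edges: np.ndarray
    mass: np.ndarray
    t_end: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.mass) < 0):
            raise ValueError("bin masses must be non-negative")

    def decile_masses(self) -> np.ndarray:
        """Re-aggregate the masses onto 10 equal F-deciles."""
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        dec = np.clip((centers * 10).astype(int), 0, 9)
        out = np.zeros(10)
        np.add.at(out, dec, self.mass)
        return out


def f_trajectory(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Time series (t, F(t)) of the strong-affinity fraction.

    F is the population fraction at binding offsets at or below the
    neutral level (Ka >= Ka*).  Undefined for extinct runs.
    """
    if traj.status == "extinct":
        raise ValueError("strong-fraction series undefined for an extinct trajectory")
    return traj.times, traj.strong_fraction


def p_of_f(traj: Trajectory, n_bins: int = 20) -> FractionDistribution:
    """Distribution of F over an ensemble of randomly time-shifted centers.

    Mass in each F-bin is the fraction of the run time the trajectory
    spends with F in that bin — the discrete equivalent of dt(F)/dF that
    stays finite where F plateaus.  Invariant under uniform rescaling of
    the time axis.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    times, f = f_trajectory(traj)
    if times[-1] <= 0:
        raise ValueError("trajectory has zero duration")
    # each inter-sample interval contributes its duration at the segment's
    # midpoint F value
    dt = np.diff(times)
    f_mid = 0.5 * (f[:-1] + f[1:])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mass, _ = np.histogram(np.clip(f_mid, 0.0, 1.0), bins=edges, weights=dt)
    mass = mass / dt.sum()
    return FractionDistribution(edges=edges, mass=mass, t_end=float(times[-1]))
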