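"""Prescribing the fractal dimension: calibration and inversion.

Growing with the scaling interaction range lam(N) = N**eps produces
monofractal clusters whose dimension D(eps) decreases from the base
model's D0 (1.71 for DLA, 2 for BA) at eps -> 0 to the mean-field value
1 at eps -> 1.  Calibrating D(eps) on a grid and inverting it linearly
in D gives the exponent eps(D*) that grows aggregates with any
prescribed dimension D* in [1, D0].

The entropic/energetic split of a measured dimension is
f_s = (D - 1)/(D0 - 1) and f_E = 1 - f_s: f_s -> 1 in the purely
entropic (trajectory-limited) regime, f_E -> 1 in the purely energetic
(interaction-limited, mean-field) one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .analysis import ensemble_mean, fit_dimension
from .growth import LambdaSchedule, grow
from .walkers import Model

__all__ = [
    "D0_DLA",
    "D0_BA",
    "base_dimension",
    "Decomposition",
    "CalibrationCurve",
    "decompose",
    "calibrate",
    "invert",
    "ExtrapolationWarning",
]

D0_DLA = 1.71
D0_BA = 2.0

DEFAULT_EPSILON_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


class ExtrapolationWarning(UserWarning):
    """The requested D falls outside the calibrated range; the nearest
    endpoint's epsilon was returned."""


def base_dimension(model) -> float:
    return D0_BA if Model(model) is Model.BA else D0_DLA


@dataclass(frozen=True)
class Decomposition:
    """Entropic (f_s) and energetic (f_E) fractions; f_s + f_E == 1."""

    f_s: float
    f_E: float


@dataclass
class CalibrationCurve:
    """Monotone table of (epsilon, D) for one base model.

    ``epsilon`` is strictly increasing; ``d`` is empirically
    nonincreasing (within sampling noise) from ~D0 towards 1.
    ``metadata`` records how the table was produced (ensemble, N_max,
    seeds, fit window) so tuned runs are auditable.
    """

    model: Model
    epsilon: np.ndarray
    d: np.ndarray
    d_stderr: np.ndarray
    d0: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=np.float64)
        self.d = np.asarray(self.d, dtype=np.float64)
        self.d_stderr = np.asarray(self.d_stderr, dtype=np.float64)
        if self.epsilon.size < 1:
            raise ValueError("calibration curve is empty")
        if np.any(np.diff(self.epsilon) <= 0):
            raise ValueError("epsilon grid must be strictly increasing")


def decompose(d: float, d0: float) -> Decomposition:
    """Split a dimension D in [1, D0] into entropic/energetic fractions."""
    if d0 <= 1.0:
        raise ValueError("D0 must exceed 1")
    if not 1.0 - 1e-9 <= d <= d0 + 1e-9:
        raise ValueError(f"D = {d:g} outside [1, D0 = {d0:g}]")
    f_s = (min(max(d, 1.0), d0) - 1.0) / (d0 - 1.0)
    return Decomposition(f_s=f_s, f_E=1.0 - f_s)


def calibrate(model, epsilon_grid=DEFAULT_EPSILON_GRID, ensemble: int = 8,
              n_max: int = 5000, seed: int = 0, record_every: int = 10,
              fit_range=None) -> CalibrationCurve:
    """Measure D(epsilon) on a grid of scaling exponents.

    For each epsilon, ``ensemble`` clusters are grown to ``n_max`` with
    lam(N) = N**epsilon (cluster seeds ``seed + j*ensemble + i`` for
    grid point j), their traces ensemble-averaged, and D fitted on the
    last decade of N (or ``fit_range``).  The standard error comes from
    per-cluster fits.  Adjacent non-monotone points raise a warning but
    do not fail: they indicate sampling noise, not an invalid curve.
    """
    model = Model(model)
    eps_grid = np.asarray(sorted(epsilon_grid), dtype=np.float64)
    if eps_grid.size < 1 or eps_grid[0] <= 0 or eps_grid[-1] > 1:
        raise ValueError("epsilon grid must lie in (0, 1]")
    if ensemble < 2:
        raise ValueError("ensemble must be >= 2")
    d_vals = np.empty(eps_grid.size)
    d_err = np.empty(eps_grid.size)
    for j, eps in enumerate(eps_grid):
        sched = LambdaSchedule(lambda0=1.0, epsilon=float(eps))
        traces = []
        per_cluster = []
        for i in range(ensemble):
            _, tr = grow(model, sched, n_max, record_every=record_every,
                         seed=seed + j * ensemble + i)
            traces.append(tr)
            per_cluster.append(fit_dimension(tr, fit_range).d)
        d_vals[j] = fit_dimension(ensemble_mean(traces), fit_range).d
        d_err[j] = float(np.std(per_cluster, ddof=1) / np.sqrt(ensemble))
    if np.any(np.diff(d_vals) > 0):
        warnings.warn(
            "calibration curve is not monotone between adjacent grid points "
            "(sampling noise); consider a larger ensemble",
            stacklevel=2,
        )
    return CalibrationCurve(
        model=model, epsilon=eps_grid, d=d_vals, d_stderr=d_err,
        d0=base_dimension(model),
        metadata={
            "ensemble": ensemble,
            "n_max": n_max,
            "base_seed": seed,
            "record_every": record_every,
            "fit_range": list(fit_range) if fit_range is not None
                         else [n_max / 10.0, float(n_max)],
        },
    )


def invert(curve: CalibrationCurve, d_target: float) -> float:
    """Exponent epsilon that grows clusters with dimension ``d_target``.

    Linear interpolation between the two calibrated points bracketing
    ``d_target`` in D (the curve is treated as a monotone D -> epsilon
    map).  A target outside the sampled D range clamps to the nearest
    endpoint and emits :class:`ExtrapolationWarning`.
    """
    if curve.epsilon.size < 2:
        raise ValueError("need at least 2 calibration points to invert")
    if not 1.0 - 1e-9 <= d_target <= curve.d0 + 1e-9:
        raise ValueError(
            f"D target {d_target:g} outside [1, D0 = {curve.d0:g}]"
        )
    # sort by D ascending (epsilon descending for a decreasing curve)
    order = np.argsort(curve.d)
    d_sorted = curve.d[order]
    e_sorted = curve.epsilon[order]
    if d_target <= d_sorted[0]:
        if d_target < d_sorted[0]:
            warnings.warn(
                f"D target {d_target:g} below calibrated range "
                f"[{d_sorted[0]:g}, {d_sorted[-1]:g}]; clamping",
                ExtrapolationWarning, stacklevel=2,
            )
        return float(e_sorted[0])
    if d_target >= d_sorted[-1]:
        if d_target > d_sorted[-1]:
            warnings.warn(
                f"D target {d_target:g} above calibrated range "
                f"[{d_sorted[0]:g}, {d_sorted[-1]:g}]; clamping",
                ExtrapolationWarning, stacklevel=2,
            )
        return float(e_sorted[-1])
    return float(np.interp(d_target, d_sorted, e_sorted))
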