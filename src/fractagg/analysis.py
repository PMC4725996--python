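"""Fractal-dimension estimation from radius-of-gyration traces.

The fractal dimension D is defined through Rg = k * N**beta with
beta = 1/D.  For monofractal growth a single log-log fit suffices; for
multiscaling clusters (constant interaction range) the local dimension
D(N) = 1 / (d log Rg / d log N) is estimated by 2/3-point numerical
derivatives on the sampled (log N, log Rg) grid, smoothed by a running
average.  Traces are ensemble-averaged before differentiating or
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import GyrationTrace

__all__ = [
    "DimensionCurve",
    "FitResult",
    "radius_of_gyration",
    "log_derivative",
    "running_average",
    "ensemble_mean",
    "fit_dimension",
]

#: default smoothing window (recorded points) for local-D curves
DEFAULT_WINDOW = 51


@dataclass
class DimensionCurve:
    """Local fractal dimension D sampled against cluster size N."""

    n: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.n.shape != self.d.shape:
            raise ValueError("N and D must have the same length")


@dataclass(frozen=True)
class FitResult:
    """Power-law fit Rg = k * N**(1/D) over ``fit_range`` (inclusive)."""

    d: float
    k: float
    fit_range: tuple[float, float]
    residual: float  # rms of log Rg residuals
    n_points: int


def radius_of_gyration(positions) -> float:
    """Root-mean-square distance of the particles from their centroid."""
    arr = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    if arr.shape[0] < 1:
        raise ValueError("need at least one position")
    centred = arr - arr.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred ** 2, axis=1))))


def log_derivative(trace: GyrationTrace) -> DimensionCurve:
    """Local dimension from numerical log-log derivatives.

    With x = log N and f = log Rg: one-sided two-point differences at
    the ends, the centred three-point formula in between (valid on any
    strictly increasing N grid), then D = 1/beta pointwise.
    """
    n = np.asarray(trace.n, dtype=np.float64)
    rg = np.asarray(trace.rg, dtype=np.float64)
    if n.size < 3:
        raise ValueError("need at least 3 records to differentiate")
    if np.any(np.diff(n) <= 0):
        raise ValueError("degenerate spacing: N must be strictly increasing")
    if np.any(rg <= 0):
        raise ValueError("Rg must be positive to take logarithms")
    x = np.log(n)
    f = np.log(rg)
    beta = np.empty_like(f)
    beta[0] = (f[1] - f[0]) / (x[1] - x[0])
    beta[-1] = (f[-1] - f[-2]) / (x[-1] - x[-2])
    beta[1:-1] = (f[2:] - f[:-2]) / (x[2:] - x[:-2])
    with np.errstate(divide="ignore"):
        d = 1.0 / beta
    return DimensionCurve(n=trace.n.copy(), d=d)


def running_average(curve: DimensionCurve, window: int = DEFAULT_WINDOW) -> DimensionCurve:
    """Centred moving mean over ``window`` records (odd); the ends use
    the truncated window, so output length equals input length."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    d = curve.d
    csum = np.concatenate([[0.0], np.cumsum(d)])
    idx = np.arange(d.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, d.size - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return DimensionCurve(n=curve.n.copy(), d=smoothed)


def ensemble_mean(traces) -> GyrationTrace:
    """Pointwise mean Rg over traces sharing an identical N grid."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    n0 = traces[0].n
    for t in traces[1:]:
        if t.n.shape != n0.shape or np.any(t.n != n0):
            raise ValueError("traces do not share an identical N grid")
    rg = np.mean([t.rg for t in traces], axis=0)
    return GyrationTrace(n=n0.copy(), rg=rg,
                         record_every=traces[0].record_every)


def fit_dimension(trace: GyrationTrace, fit_range=None) -> FitResult:
    """Least-squares fit of log Rg vs log N over ``fit_range``.

    ``fit_range`` is an inclusive (N_lo, N_hi) window; by default the
    last decade [N_max/10, N_max], where monofractal traces have a
    stable slope.  Returns D = 1/slope and k = exp(intercept).
    """
    n = np.asarray(trace.n, dtype=np.float64)
    rg = np.asarray(trace.rg, dtype=np.float64)
    if fit_range is None:
        fit_range = (n[-1] / 10.0, n[-1])
    lo, hi = fit_range
    if not lo < hi:
        raise ValueError("fit_range must satisfy N_lo < N_hi")
    mask = (n >= lo) & (n <= hi) & (rg > 0)
    if mask.sum() < 5:
        raise ValueError(
            f"insufficient points in fit range [{lo:g}, {hi:g}]: {int(mask.sum())} < 5"
        )
    x = np.log(n[mask])
    f = np.log(rg[mask])
    slope, intercept = np.polyfit(x, f, 1)
    resid = f - (slope * x + intercept)
    return FitResult(
        d=float(1.0 / slope),
        k=float(np.exp(intercept)),
        fit_range=(float(lo), float(hi)),
        residual=float(np.sqrt(np.mean(resid ** 2))),
        n_points=int(mask.sum()),
    )
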