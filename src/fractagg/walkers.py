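"""Mobile particles: launch geometry, launching, stepping, killing.

Walkers are launched uniformly from a circle enclosing the cluster and
discarded ("killed") past twice the launch radius.  Ballistic walkers
(BA) travel along a single straight ray; diffusive walkers (DLA) take
unit steps in fresh uniform directions, with the mean free path
enlarged far from the cluster so that the accelerated hop can never
overshoot the interaction boundary.

All distances are in particle diameters.  Functions here are the
reference, per-walker formulation; :func:`fractagg.growth.grow` runs the
same logic in compiled form.  Both consume the legacy NumPy Mersenne
Twister (``np.random.RandomState``) with a fixed draw order, so the two
paths are interchangeable draw-for-draw.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .geometry import Segment

__all__ = [
    "Model",
    "Status",
    "WalkerState",
    "LaunchGeometry",
    "launch_geometry",
    "launch",
    "next_segment_diffusive",
    "enforce_kill",
]

#: launch-circle offsets delta, in particle diameters
BA_DELTA = 1000.0
DLA_DELTA = 100.0


class Model(str, enum.Enum):
    BA = "BA"
    DLA = "DLA"


class Status(str, enum.Enum):
    ALIVE = "alive"
    ATTACHED = "attached"
    KILLED = "killed"


@dataclass(frozen=True)
class WalkerState:
    position: tuple[float, float]
    direction: tuple[float, float]
    status: Status = Status.ALIVE


@dataclass(frozen=True)
class LaunchGeometry:
    """Launch circle L, killing circle L_k = 2L, and the cluster state
    (r_max, lam) they were derived from."""

    L: float
    L_k: float
    delta: float
    model: Model
    r_max: float
    lam: float


def launch_geometry(model, r_max: float, lam: float) -> LaunchGeometry:
    """Launch/killing radii for the current cluster extent.

    BA walkers start from L = r_max + 1000 (the large offset avoids
    screening artefacts of the straight trajectories); DLA walkers from
    L = r_max + lam + 100, which always clears the interaction boundary.
    Both use a killing radius of 2L.
    """
    model = Model(model)
    if r_max < 0:
        raise ValueError("r_max must be nonnegative")
    if lam <= 0:
        raise ValueError("lam must be positive")
    delta = BA_DELTA if model is Model.BA else DLA_DELTA
    L = r_max + delta if model is Model.BA else r_max + lam + delta
    return LaunchGeometry(L=L, L_k=2.0 * L, delta=delta, model=model,
                          r_max=r_max, lam=lam)


def _unit(angle: float) -> tuple[float, float]:
    return (np.cos(angle), np.sin(angle))


def launch(geom: LaunchGeometry, rng) -> WalkerState:
    """Launch a walker uniformly from the circle of radius L.

    BA: the direction is re-drawn until the ray's closest approach to
    the origin is at most r_max + lam; rays that cannot touch the disk
    enclosing the interaction boundary would be killed unperturbed, so
    rejecting them at launch leaves the attachment statistics unchanged.
    DLA: the stored direction is a placeholder ((1, 0)); diffusive steps
    re-draw it anyway.
    """
    theta = 2.0 * np.pi * rng.random_sample()
    pos = (geom.L * np.cos(theta), geom.L * np.sin(theta))
    if geom.model is Model.DLA:
        return WalkerState(position=pos, direction=(1.0, 0.0))
    b_max = geom.r_max + geom.lam
    while True:
        phi = 2.0 * np.pi * rng.random_sample()
        ux, uy = _unit(phi)
        s0 = -(pos[0] * ux + pos[1] * uy)
        b = abs(pos[0] * uy - pos[1] * ux)
        if s0 > 0.0 and b <= b_max:
            return WalkerState(position=pos, direction=(ux, uy))


def next_segment_diffusive(state: WalkerState, cluster_positions, lam: float,
                           geom: LaunchGeometry, rng) -> Segment:
    """Next diffusive step as a directed segment.

    The step has unit length within lam + 2 of the nearest aggregated
    particle; farther out it is enlarged to d_nn - lam - 1, which stops
    at least one diameter short of the interaction boundary in every
    direction, and is capped at L_k - |p| so an accelerated hop cannot
    leap past the killing circle (a unit floor keeps the walker able to
    cross it and be culled).
    """
    if state.status is not Status.ALIVE:
        raise ValueError("cannot advance a walker that is not alive")
    arr = np.atleast_2d(np.asarray(cluster_positions, dtype=np.float64))
    px, py = state.position
    d_nn = float(np.min(np.hypot(arr[:, 0] - px, arr[:, 1] - py)))
    phi = 2.0 * np.pi * rng.random_sample()
    if d_nn <= lam + 2.0:
        ell = 1.0
    else:
        ell = d_nn - lam - 1.0
        cap = geom.L_k - np.hypot(px, py)
        ell = max(1.0, min(ell, cap))
    return Segment(origin=state.position, direction=_unit(phi), length=ell)


def enforce_kill(state: WalkerState, geom: LaunchGeometry) -> WalkerState:
    """Mark the walker killed iff it sits strictly beyond L_k."""
    if state.status is not Status.ALIVE:
        raise ValueError("enforce_kill expects a live walker")
    if np.hypot(*state.position) > geom.L_k:
        return replace(state, status=Status.KILLED)
    return state
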