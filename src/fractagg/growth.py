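"""Cluster growth: the launch -> walk -> attach loop.

One walker is in flight at a time (strict particle-cluster
aggregation).  Growth starts from a seed particle at the origin.  Each
incoming particle is captured at the exact first crossing of its
trajectory with the interaction boundary of radius ``lam`` (evaluated
from the schedule ``lam(N) = lam0 * N**eps`` on the pre-attachment
count N) and then aggregates in contact with the crossed particle: it
is placed one diameter away from it, along the direction to the
capture point.  With lam = 1 capture and contact coincide and this is
plain off-lattice DLA or BA; with lam > 1 the interaction range decides
*where* growth happens while the aggregate itself remains a connected
cluster of touching particles (this is what makes the cluster extent
stay far below lam in the interaction-limited regime, with D -> 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .geometry import Segment
from .walkers import Model

__all__ = [
    "LambdaSchedule",
    "Cluster",
    "GyrationTrace",
    "lambda_at",
    "grow",
    "candidate_neighbors",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Interaction range schedule lam(N) = lam0 * N**epsilon.

    epsilon = 0 gives the constant-range regime (multiscaling clusters
    for lam0 > 1); epsilon in (0, 1] balances the range against the
    cluster size and yields a single fractal dimension D(epsilon).
    """

    lambda0: float = 1.0
    epsilon: float = 0.0

    def __post_init__(self):
        if self.lambda0 < 1.0:
            raise ValueError("lambda0 must be >= 1 (particle diameters)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


def lambda_at(schedule: LambdaSchedule, n: int) -> float:
    """Interaction range in force while the cluster holds n particles."""
    if n < 1:
        raise ValueError("cluster count must be >= 1")
    return schedule.lambda0 * n ** schedule.epsilon


@dataclass
class Cluster:
    """Aggregate with attachment topology.

    positions[0] is the seed at the origin; particle i >= 1 sits in
    contact (one diameter) with particle parent[i], whose interaction
    boundary its walker crossed.  lam_at_attach[i] records the
    interaction range in force at its aggregation (lam_at_attach[0] = 0
    by convention).
    """

    positions: np.ndarray
    parent: np.ndarray
    lam_at_attach: np.ndarray
    model: Model
    schedule: LambdaSchedule
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def r_max(self) -> float:
        return float(np.max(np.hypot(self.positions[:, 0], self.positions[:, 1])))


@dataclass
class GyrationTrace:
    """Radius-of-gyration samples (N, Rg) taken during growth."""

    n: np.ndarray
    rg: np.ndarray
    record_every: int = 1

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.int64)
        self.rg = np.asarray(self.rg, dtype=np.float64)
        if self.n.shape != self.rg.shape:
            raise ValueError("N and Rg must have the same length")
        if self.n.size > 1 and not np.all(np.diff(self.n) > 0):
            raise ValueError("N must be strictly increasing")


def grow(model, schedule: LambdaSchedule, n_target: int, record_every: int = 10,
         seed: int = 0, use_grid: bool = True) -> tuple[Cluster, GyrationTrace]:
    """Grow one cluster to ``n_target`` particles.

    ``use_grid`` selects the uniform-grid spatial index (the default)
    or a brute-force neighbour scan; the two produce bit-identical
    clusters for the same seed.  Rg is recorded at every multiple of
    ``record_every`` (and at ``n_target``).
    """
    model = Model(model)
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    code = _engine.BA if model is Model.BA else _engine.DLA
    xs, ys, parent, lam_attach, rec_n, rec_rg, status = _engine.grow_cluster(
        code, schedule.lambda0, schedule.epsilon, n_target, record_every,
        seed, use_grid,
    )
    if status != 0:
        raise RuntimeError(
            f"walker budget exhausted while growing particle {int(np.sum(parent >= 0)) + 1}"
        )
    cluster = Cluster(
        positions=np.column_stack([xs, ys]),
        parent=parent,
        lam_at_attach=lam_attach,
        model=model,
        schedule=schedule,
        seed=seed,
    )
    trace = GyrationTrace(n=rec_n, rg=rec_rg, record_every=record_every)
    return cluster, trace


def candidate_neighbors(cluster_positions, seg: Segment, lam: float) -> np.ndarray:
    """Indices of particles that could be crossed by ``seg``.

    Superset-exact contract: contains every particle whose perpendicular
    distance to the segment line is below ``lam`` with projection within
    [-lam, length + lam]; may contain a bounded padding band beyond
    that.  Implemented with the same uniform grid as the growth loop.
    """
    arr = np.atleast_2d(np.asarray(cluster_positions, dtype=np.float64))
    n = arr.shape[0]
    if n == 0:
        raise ValueError("cluster must be nonempty")
    xs = np.ascontiguousarray(arr[:, 0])
    ys = np.ascontiguousarray(arr[:, 1])
    cs = max(2.0, 1.25 * lam)
    r_max = float(np.max(np.hypot(xs, ys)))
    R = 1.5 * (r_max + lam) + 2.0 * cs
    ncx = int(np.ceil(2.0 * R / cs)) + 1
    head = np.full(ncx * ncx, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    _engine.grid_build(xs, ys, n, head, nxt, ncx, cs, R)
    ox, oy = seg.origin
    ux, uy = seg.direction
    length = seg.length if np.isfinite(seg.length) else _engine._INF_LEN
    ex, ey = ox + min(length, 4.0 * R) * ux, oy + min(length, 4.0 * R) * uy
    buf = np.empty(n, np.int64)
    # inflate by lam*sqrt(2): the projection band's corners (d = lam,
    # s = length + lam) stick out diagonally from the segment's box
    m = _engine.grid_candidates(ox, oy, ex, ey, 1.5 * lam,
                                head, nxt, ncx, cs, R, buf)
    return buf[:m].copy()
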