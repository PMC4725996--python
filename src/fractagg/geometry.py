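"""Continuous first-crossing geometry of the attachment rule.

A growing aggregate defines an *interaction boundary*: the outer edge of
the union of disks of radius ``lam`` centred on every aggregated
particle.  A mobile particle attaches at the first point where its
trajectory segment crosses this boundary.  For a segment with origin
``o``, unit direction ``u`` and a disk centre ``c``, the entry parameter
is

    t = s - sqrt(lam**2 - d**2),   s = (c - o) . u,   d = |(c - o) x u|

whenever the perpendicular distance ``d`` is strictly below ``lam``; the
attachment event is the candidate with the smallest ``t`` within the
segment.  Tangency (``d == lam``) counts as a miss, and near-ties in
``t`` (within 1e-12) resolve to the lowest particle index so results do
not depend on candidate ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine

__all__ = [
    "Segment",
    "AggregationEvent",
    "perpendicular_distance",
    "first_crossing",
    "inside_boundary",
]

#: slack used when validating that a segment origin is outside the boundary
ORIGIN_TOL = 1e-9


@dataclass(frozen=True)
class Segment:
    """Directed trajectory segment; ``length`` may be ``inf`` for a ray."""

    origin: tuple[float, float]
    direction: tuple[float, float]
    length: float = np.inf

    def __post_init__(self):
        ox, oy = self.origin
        ux, uy = self.direction
        if not (np.isfinite(ox) and np.isfinite(oy)):
            raise ValueError("segment origin must be finite")
        if abs(np.hypot(ux, uy) - 1.0) > 1e-12:
            raise ValueError("segment direction must be a unit vector")
        if not self.length > 0:
            raise ValueError("segment length must be positive")


@dataclass(frozen=True)
class AggregationEvent:
    """First crossing of the interaction boundary by a trajectory segment.

    ``landing`` sits at distance exactly ``lam`` from the particle at
    ``attach_index`` and at least ``lam`` from every other particle;
    ``entry_parameter`` is the distance travelled along the segment.
    """

    landing: tuple[float, float]
    attach_index: int
    entry_parameter: float


def _as_centers(centers) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("centers must be an (n, 2) array of positions")
    return arr


def perpendicular_distance(center, seg: Segment) -> tuple[float, float]:
    """Distance from ``center`` to the infinite line through ``seg`` and
    the scalar projection of ``center - origin`` on the direction."""
    cx, cy = center
    ox, oy = seg.origin
    ux, uy = seg.direction
    d, s = _engine.perp_and_proj(cx, cy, ox, oy, ux, uy)
    return float(d), float(s)


def first_crossing(seg: Segment, centers, lam: float) -> AggregationEvent | None:
    """First crossing of ``seg`` with the union of radius-``lam`` disks.

    Returns ``None`` when the segment never enters any disk.  Raises
    ``ValueError`` if the origin already lies inside the boundary
    (distance to some centre below ``lam - 1e-9``): first-crossing is
    only defined for walkers approaching from outside.
    """
    if not lam > 0:
        raise ValueError("lam must be positive")
    arr = _as_centers(centers)
    ox, oy = seg.origin
    dmin = _engine.nearest_all(ox, oy, arr[:, 0], arr[:, 1], arr.shape[0])
    if dmin < lam - ORIGIN_TOL:
        raise ValueError(
            f"segment origin is inside the interaction boundary "
            f"(nearest centre at {dmin:.6g} < lam = {lam:.6g})"
        )
    ux, uy = seg.direction
    length = seg.length if np.isfinite(seg.length) else _engine._INF_LEN
    t, i = _engine.first_crossing_all(
        ox, oy, ux, uy, length, arr[:, 0], arr[:, 1], arr.shape[0], lam
    )
    if i < 0:
        return None
    return AggregationEvent(
        landing=(ox + t * ux, oy + t * uy),
        attach_index=int(i),
        entry_parameter=float(t),
    )


def inside_boundary(p, centers, lam: float) -> bool:
    """True iff ``p`` lies strictly inside some radius-``lam`` disk."""
    if not lam > 0:
        raise ValueError("lam must be positive")
    arr = _as_centers(centers)
    return bool(
        _engine.nearest_all(p[0], p[1], arr[:, 0], arr[:, 1], arr.shape[0]) < lam
    )
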