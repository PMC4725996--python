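"""Deterministic fixtures for kernel validation.

The central piece is :func:`marching_first_crossing`, a brute-force
oracle for the first-crossing geometry: it marches along the segment in
steps of 1e-4 and reports the first sub-step at which the walker enters
a disk, then bisects the bracketing interval.  It shares no code with
the analytic kernel, so agreement between the two is meaningful.

:func:`make_fixtures` emits small plain-text fixture files: scripted
segments with oracle-computed expected events, exact power-law gyration
traces, and a random cluster for spatial-index cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import Segment

__all__ = ["marching_first_crossing", "FixtureScript", "make_fixtures",
           "power_law_trace"]

MARCH_STEP = 1e-4


def marching_first_crossing(seg: Segment, centers, lam: float,
                            step: float = MARCH_STEP, t_max: float = 1e4):
    """Oracle: first entry of the segment into any radius-lam disk.

    Returns (t, index) or None.  ``t`` is located by marching in
    ``step`` increments and bisecting the first inside bracket, accurate
    to ~1e-12 in t; the attaching particle is the closest centre at the
    crossing point.  Finite march horizon ``t_max`` stands in for
    infinite rays.
    """
    arr = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    ox, oy = seg.origin
    ux, uy = seg.direction
    horizon = min(seg.length, t_max)

    def min_dist(t):
        px, py = ox + t * ux, oy + t * uy
        return np.min(np.hypot(arr[:, 0] - px, arr[:, 1] - py))

    # march in chunks (vectorised over sample points, still a plain scan)
    chunk = 200_000
    n_steps = int(np.floor(horizon / step)) + 1
    hit_bracket = None
    for start in range(1, n_steps + 2, chunk):
        ts = np.minimum(np.arange(start, min(start + chunk, n_steps + 2),
                                  dtype=np.float64) * step, horizon)
        pts = np.empty((ts.size, 2))
        pts[:, 0] = ox + ts * ux
        pts[:, 1] = oy + ts * uy
        d2 = np.min(
            (pts[:, 0, None] - arr[None, :, 0]) ** 2
            + (pts[:, 1, None] - arr[None, :, 1]) ** 2,
            axis=1,
        )
        inside = d2 < lam * lam
        if inside.any():
            k = int(np.argmax(inside))
            hi = ts[k]
            lo = ts[k - 1] if k > 0 else max(0.0, hi - step)
            hit_bracket = (lo, hi)
            break
        if ts[-1] >= horizon:
            break
    if hit_bracket is None:
        return None
    lo, hi = hit_bracket
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < lam:
            hi = mid
        else:
            lo = mid
    t_hit = 0.5 * (lo + hi)
    px, py = ox + t_hit * ux, oy + t_hit * uy
    idx = int(np.argmin(np.hypot(arr[:, 0] - px, arr[:, 1] - py)))
    return t_hit, idx


@dataclass
class FixtureScript:
    """Scripted segments against a fixed set of centres, with the
    oracle's expected events stored alongside."""

    centers: list
    lam: float
    segments: list
    expected: list  # per segment: {"t":..., "landing":[x,y], "index":...} or None


def _segment_scripts():
    """Head-on, shielded, oblique, tangent and miss cases."""
    return [
        # (centers, lam, origin, direction, length, label)
        ([(0.0, 0.0)], 1.0, (5.0, 0.0), (-1.0, 0.0), 100.0, "head-on"),
        ([(0.0, 0.0), (3.0, 0.0)], 1.0, (10.0, 0.0), (-1.0, 0.0), 100.0,
         "shielded"),
        ([(0.0, 0.0)], 2.0, (5.0, 1.0), (-1.0, 0.0), 100.0, "oblique"),
        ([(0.0, 0.0)], 1.0, (5.0, 2.0), (-1.0, 0.0), 100.0, "miss"),
        ([(0.0, 0.0)], 1.0, (5.0, 1.0), (-1.0, 0.0), 100.0, "tangent"),
        ([(0.0, 0.0), (0.5, 0.8)], 1.2, (6.0, -0.3),
         (-0.9486832980505138, 0.31622776601683794), 100.0, "two-disk"),
    ]


def power_law_trace(d: float, k: float = 1.0, n_values=None):
    """Exact trace Rg = k * N**(1/d) (lazy import keeps this cheap)."""
    from .growth import GyrationTrace
    if n_values is None:
        n_values = np.arange(10, 2001, 10)
    n_values = np.asarray(n_values, dtype=np.int64)
    return GyrationTrace(n=n_values, rg=k * n_values ** (1.0 / d),
                         record_every=int(n_values[0]))


def make_fixtures(seed: int, outdir) -> FixtureScript:
    """Write fixture files under ``outdir`` and return the segment script.

    Emits segments.json (scripted crossings + oracle expectations),
    trace_D<d>.tsv for d in {1, 1.31, 1.51, 1.71, 2}, and
    random_cluster.csv (50 uniform points, synthetic, for
    spatial-index-vs-brute-force comparisons).
    """
    from .io import write_trace_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scripts = _segment_scripts()
    records = []
    all_segments = []
    for centers, lam, origin, direction, length, label in scripts:
        seg = Segment(origin=origin, direction=direction, length=length)
        all_segments.append(seg)
        hit = marching_first_crossing(seg, centers, lam)
        if hit is None:
            expected = None
        else:
            t, idx = hit
            expected = {
                "t": t,
                "landing": [origin[0] + t * direction[0],
                            origin[1] + t * direction[1]],
                "index": idx,
            }
        records.append({
            "label": label, "centers": centers, "lam": lam,
            "origin": list(origin), "direction": list(direction),
            "length": length, "expected": expected,
        })
    (outdir / "segments.json").write_text(
        json.dumps(records, indent=2) + "\n")

    for d in (1.0, 1.31, 1.51, 1.71, 2.0):
        write_trace_tsv(power_law_trace(d),
                        outdir / f"trace_D{d:g}.tsv")

    rng = np.random.RandomState(seed)
    pts = rng.uniform(-20.0, 20.0, size=(50, 2))
    pts[0] = (0.0, 0.0)
    lines = ["index,x,y,parent,lambda_at_attach"]
    for i, (x, y) in enumerate(pts):
        lines.append(f"{i},{x:.9g},{y:.9g},{-1 if i == 0 else 0},1")
    (outdir / "random_cluster.csv").write_text("\n".join(lines) + "\n")

    return FixtureScript(
        centers=[s[0] for s in scripts],
        lam=1.0,
        segments=all_segments,
        expected=[r["expected"] for r in records],
    )
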