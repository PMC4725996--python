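"""Compiled growth kernels.

Everything in this module is numba-njit code shared by the public API
(:mod:`fractagg.geometry`, :mod:`fractagg.growth`).  The same scalar
primitives back both the one-off geometric queries and the hot
launch/walk/attach loop, so there is a single code path to validate.

Random numbers: each cluster is grown from ``np.random.seed(seed)``
inside njit code, whose Mersenne-Twister stream is bit-identical to
``numpy.random.RandomState(seed)``.  The draw order is part of the
reproducibility contract:

* BA launch: position angle, then direction angles until the ray is
  accepted (aims at the disk of radius ``r_max + lam``).
* DLA launch: position angle only.
* DLA step: one direction angle per step.
"""

import numpy as np
from numba import njit

TAU = 2.0 * np.pi
_TIE_TOL = 1e-12
_INF_LEN = 1e300

BA = 0
DLA = 1

# walker-budget per aggregated particle; defensive, never binding
MAX_STEPS = 10_000_000


@njit(cache=True, inline="always")
def perp_and_proj(cx, cy, ox, oy, ux, uy):
    """Perpendicular distance of (cx,cy) to the line through (ox,oy)
    with unit direction (ux,uy), and the signed projection along it."""
    rx = cx - ox
    ry = cy - oy
    s = rx * ux + ry * uy
    d = abs(rx * uy - ry * ux)
    return d, s


@njit(cache=True)
def first_crossing_subset(ox, oy, ux, uy, length, xs, ys, lam, idxs):
    """First crossing of the segment with the union of radius-lam disks
    centred on xs[idxs], ys[idxs].

    Returns (t, index); index == -1 means no crossing.  ``idxs`` must be
    ascending so that near-ties in t (within 1e-12) resolve to the lowest
    particle index independently of how candidates were gathered.
    """
    best_t = np.inf
    best_i = -1
    lam2 = lam * lam
    for k in range(idxs.shape[0]):
        i = idxs[k]
        d, s = perp_and_proj(xs[i], ys[i], ox, oy, ux, uy)
        if d < lam:
            t = s - np.sqrt(lam2 - d * d)
            if 0.0 <= t <= length and t < best_t - _TIE_TOL:
                best_t = t
                best_i = i
    return best_t, best_i


@njit(cache=True)
def first_crossing_all(ox, oy, ux, uy, length, xs, ys, n, lam):
    """As first_crossing_subset but scanning particles 0..n-1."""
    best_t = np.inf
    best_i = -1
    lam2 = lam * lam
    for i in range(n):
        d, s = perp_and_proj(xs[i], ys[i], ox, oy, ux, uy)
        if d < lam:
            t = s - np.sqrt(lam2 - d * d)
            if 0.0 <= t <= length and t < best_t - _TIE_TOL:
                best_t = t
                best_i = i
    return best_t, best_i


@njit(cache=True)
def nearest_all(px, py, xs, ys, n):
    best = np.inf
    for i in range(n):
        dx = xs[i] - px
        dy = ys[i] - py
        d2 = dx * dx + dy * dy
        if d2 < best:
            best = d2
    return np.sqrt(best)


# ---------------------------------------------------------------------------
# Uniform-grid spatial index.  The grid covers [-R, R]^2 with square cells
# of side cs >= max(2, 1.25*lam); it is rebuilt lazily whenever lam outgrows
# the cell size or the cluster approaches the bounding box.
# ---------------------------------------------------------------------------


@njit(cache=True)
def grid_insert(i, xs, ys, head, nxt, ncx, cs, R):
    ix = int(np.floor((xs[i] + R) / cs))
    iy = int(np.floor((ys[i] + R) / cs))
    c = iy * ncx + ix
    nxt[i] = head[c]
    head[c] = i


@njit(cache=True)
def grid_build(xs, ys, n, head, nxt, ncx, cs, R):
    head[:] = -1
    for i in range(n):
        grid_insert(i, xs, ys, head, nxt, ncx, cs, R)


@njit(cache=True)
def grid_nearest(px, py, xs, ys, head, nxt, ncx, cs, R):
    """Exact nearest-particle distance via expanding-ring search."""
    ix = int(np.floor((px + R) / cs))
    iy = int(np.floor((py + R) / cs))
    best = np.inf
    kmax = max(max(ix, ncx - 1 - ix), max(iy, ncx - 1 - iy))
    if kmax < 0:
        kmax = 0
    k = 0
    while True:
        for cy in range(iy - k, iy + k + 1):
            if cy < 0 or cy >= ncx:
                continue
            if cy == iy - k or cy == iy + k:
                step = 1
            else:
                step = 2 * k if k > 0 else 1
            cx = ix - k
            while cx <= ix + k:
                if 0 <= cx < ncx:
                    j = head[cy * ncx + cx]
                    while j != -1:
                        dx = xs[j] - px
                        dy = ys[j] - py
                        d2 = dx * dx + dy * dy
                        if d2 < best:
                            best = d2
                        j = nxt[j]
                cx += step
        # a particle in ring k+1 or beyond is at least k*cs away
        if best <= (k * cs) * (k * cs):
            break
        if k > kmax:
            break
        k += 1
    return np.sqrt(best)


@njit(cache=True)
def grid_candidates(ox, oy, ex, ey, lam, head, nxt, ncx, cs, R, buf):
    """Indices of particles in cells overlapping the segment's bounding
    box inflated by lam (a superset of every disk the segment can cross),
    sorted ascending into buf.  Returns the count."""
    x0 = min(ox, ex) - lam
    x1 = max(ox, ex) + lam
    y0 = min(oy, ey) - lam
    y1 = max(oy, ey) + lam
    ix0 = max(0, int(np.floor((x0 + R) / cs)))
    ix1 = min(ncx - 1, int(np.floor((x1 + R) / cs)))
    iy0 = max(0, int(np.floor((y0 + R) / cs)))
    iy1 = min(ncx - 1, int(np.floor((y1 + R) / cs)))
    m = 0
    for cy in range(iy0, iy1 + 1):
        for cx in range(ix0, ix1 + 1):
            j = head[cy * ncx + cx]
            while j != -1:
                buf[m] = j
                m += 1
                j = nxt[j]
    # insertion sort: candidate lists are tiny
    for a in range(1, m):
        v = buf[a]
        b = a - 1
        while b >= 0 and buf[b] > v:
            buf[b + 1] = buf[b]
            b -= 1
        buf[b + 1] = v
    return m


# ---------------------------------------------------------------------------
# Attachment of a single particle
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _contact_point(cx, cy, qx, qy):
    """Place the new particle in contact (one diameter) with the
    particle at (cx, cy), along the direction towards the capture
    point (qx, qy)."""
    dx = qx - cx
    dy = qy - cy
    r = np.hypot(dx, dy)
    return cx + dx / r, cy + dy / r


@njit(cache=True)
def _nearest_index(px, py, xs, ys, n):
    best = np.inf
    bi = 0
    for i in range(n):
        dx = xs[i] - px
        dy = ys[i] - py
        d2 = dx * dx + dy * dy
        if d2 < best:
            best = d2
            bi = i
    return np.sqrt(best), bi


@njit(cache=True)
def _ba_attach(xs, ys, n, lam, r_max):
    """Launch ballistic rays until one crosses the interaction boundary.

    Rays are launched from the circle L = r_max + 1000 with uniform
    position and direction; directions whose closest approach to the
    origin exceeds r_max + lam (certain miss) are re-drawn.  A launch
    point already inside the boundary (possible only when lam exceeds
    the launch offset) is already within the attraction range and
    attaches immediately to the nearest particle.
    """
    L = r_max + 1000.0
    b_max = r_max + lam
    tries = 0
    while True:
        tries += 1
        if tries > MAX_STEPS:
            return np.nan, np.nan, -2
        th = TAU * np.random.random()
        px = L * np.cos(th)
        py = L * np.sin(th)
        if b_max >= L:
            d0, i0 = _nearest_index(px, py, xs, ys, n)
            if d0 < lam:
                gx, gy = _contact_point(xs[i0], ys[i0], px, py)
                return gx, gy, i0
        while True:
            tries += 1
            if tries > MAX_STEPS:
                return np.nan, np.nan, -2
            phi = TAU * np.random.random()
            ux = np.cos(phi)
            uy = np.sin(phi)
            s0 = -(px * ux + py * uy)
            b = abs(px * uy - py * ux)
            if s0 > 0.0 and b <= b_max:
                break
        t, i = first_crossing_all(px, py, ux, uy, _INF_LEN, xs, ys, n, lam)
        if i >= 0:
            gx, gy = _contact_point(xs[i], ys[i], px + t * ux, py + t * uy)
            return gx, gy, i


# walker-step strategies (bit-identical results, different cost profiles)
MODE_BRUTE = 0   # reference: full scan every step
MODE_GRID = 1    # uniform grid; best when lam is a few diameters
MODE_ACTIVE = 2  # cached active list; best when lam >> cluster spacing

#: grid mode is used while lam <= this, active-list mode above
GRID_LAM_MAX = 32.0

# active-list geometry: particles within lam + _ACT_MARGIN of the anchor
# are cached; the cache stays valid (for unit steps and nearest queries
# below lam + 2) while the walker is within _ACT_DRIFT of the anchor.
_ACT_MARGIN = 8.0
_ACT_DRIFT = 6.0


@njit(cache=True)
def _full_pass(px, py, xs, ys, n, lam, act):
    """Exact nearest distance plus the active list (ascending indices of
    particles within lam + _ACT_MARGIN of (px, py)) in a single scan."""
    best = np.inf
    thr = (lam + _ACT_MARGIN) * (lam + _ACT_MARGIN)
    m = 0
    for i in range(n):
        dx = xs[i] - px
        dy = ys[i] - py
        d2 = dx * dx + dy * dy
        if d2 < best:
            best = d2
        if d2 <= thr:
            act[m] = i
            m += 1
    return np.sqrt(best), m


@njit(cache=True)
def _subset_nearest(px, py, xs, ys, act, m):
    best = np.inf
    for k in range(m):
        i = act[k]
        dx = xs[i] - px
        dy = ys[i] - py
        d2 = dx * dx + dy * dy
        if d2 < best:
            best = d2
    return np.sqrt(best)


@njit(cache=True)
def _dla_attach(xs, ys, n, lam, r_max, mode, head, nxt, ncx, cs, R, buf, act):
    """Random-walk a diffusive particle until it first crosses the
    interaction boundary; killed walkers (|p| > 2L) are relaunched.

    Step length: 1 within lam + 2 of the cluster, else d_nn - lam - 1
    (which can never overshoot the boundary), capped at L_k - |p| so a
    single accelerated hop cannot leap past the killing circle.

    The three modes produce bit-identical walks: every step uses the
    exact nearest distance and an exact first-crossing screen; only the
    way neighbours are gathered differs.
    """
    L = r_max + lam + 100.0
    Lk = 2.0 * L
    near_band = r_max + lam + 2.0
    steps = 0
    while True:
        th = TAU * np.random.random()
        px = L * np.cos(th)
        py = L * np.sin(th)
        ax = px
        ay = py
        m_act = -1  # no valid active list yet
        while True:
            steps += 1
            if steps > MAX_STEPS:
                return np.nan, np.nan, -2
            rho = np.hypot(px, py)
            if rho > Lk:
                break  # killed -> relaunch
            if rho > near_band:
                dnn = rho - r_max  # conservative lower bound, exact enough
            elif mode == MODE_GRID:
                dnn = grid_nearest(px, py, xs, ys, head, nxt, ncx, cs, R)
            elif mode == MODE_ACTIVE:
                drift = np.hypot(px - ax, py - ay)
                if m_act < 0 or drift > _ACT_DRIFT:
                    dnn, m_act = _full_pass(px, py, xs, ys, n, lam, act)
                    ax = px
                    ay = py
                else:
                    dnn = _subset_nearest(px, py, xs, ys, act, m_act)
                    if dnn > lam + 2.0:
                        # excluded particles are farther still, but the
                        # exact value is needed for the step length
                        dnn, m_act = _full_pass(px, py, xs, ys, n, lam, act)
                        ax = px
                        ay = py
            else:
                dnn = nearest_all(px, py, xs, ys, n)
            phi = TAU * np.random.random()
            ux = np.cos(phi)
            uy = np.sin(phi)
            if dnn <= lam + 2.0:
                ell = 1.0
            else:
                ell = dnn - lam - 1.0
                cap = Lk - rho
                if ell > cap:
                    ell = cap
                if ell < 1.0:
                    ell = 1.0
                m_act = -1  # accelerated hop invalidates the cache
            if dnn - ell < lam:  # segment may reach the boundary: screen it
                if mode == MODE_GRID:
                    m = grid_candidates(px, py, px + ell * ux, py + ell * uy,
                                        lam, head, nxt, ncx, cs, R, buf)
                    t, i = first_crossing_subset(px, py, ux, uy, ell,
                                                 xs, ys, lam, buf[:m])
                elif mode == MODE_ACTIVE:
                    # screening only happens with ell = 1, where the
                    # active list covers every disk the segment can reach
                    t, i = first_crossing_subset(px, py, ux, uy, ell,
                                                 xs, ys, lam, act[:m_act])
                else:
                    t, i = first_crossing_all(px, py, ux, uy, ell,
                                              xs, ys, n, lam)
                if i >= 0:
                    gx, gy = _contact_point(xs[i], ys[i],
                                            px + t * ux, py + t * uy)
                    return gx, gy, i
            px += ell * ux
            py += ell * uy


# ---------------------------------------------------------------------------
# Full growth loop
# ---------------------------------------------------------------------------


@njit(cache=True)
def grow_cluster(model, lam0, eps, n_target, record_every, seed, use_grid):
    """Grow one cluster from a seed particle at the origin.

    Returns (xs, ys, parent, lam_attach, recN, recRg, status); status 0
    on success, -2 if the walker budget was exhausted (defensive).
    lambda is evaluated on the pre-attachment count N: particle number
    N+1 is captured at the first crossing of the boundary of radius
    lam0 * N**eps and placed in contact with the crossed particle.
    """
    np.random.seed(seed)
    xs = np.zeros(n_target)
    ys = np.zeros(n_target)
    parent = np.full(n_target, -1, np.int64)
    lam_attach = np.zeros(n_target)
    nrec_cap = n_target // record_every + 2
    recN = np.empty(nrec_cap, np.int64)
    recRg = np.empty(nrec_cap)
    nrec = 0
    sx = 0.0
    sy = 0.0
    sr2 = 0.0
    r_max = 0.0

    # spatial-index state (allocated lazily)
    cs = 0.0
    R = -1.0
    ncx = 0
    head = np.full(1, -1, np.int64)
    nxt = np.full(n_target, -1, np.int64)
    buf = np.empty(n_target, np.int64)
    act = np.empty(n_target, np.int64)

    n = 1
    while n < n_target:
        lam = lam0 * n ** eps
        if model == DLA:
            if not use_grid:
                mode = MODE_BRUTE
            elif lam <= GRID_LAM_MAX:
                mode = MODE_GRID
            else:
                mode = MODE_ACTIVE
            if mode == MODE_GRID and (lam > cs or r_max + lam > R - cs):
                cs = max(2.0, 1.25 * lam)
                R = 1.5 * (r_max + lam) + 2.0 * cs
                ncx = int(np.ceil(2.0 * R / cs)) + 1
                head = np.full(ncx * ncx, -1, np.int64)
                grid_build(xs, ys, n, head, nxt, ncx, cs, R)
            gx, gy, pi = _dla_attach(xs, ys, n, lam, r_max, mode,
                                     head, nxt, ncx, cs, R, buf, act)
        else:
            gx, gy, pi = _ba_attach(xs, ys, n, lam, r_max)
        if pi < 0:
            return xs, ys, parent, lam_attach, recN[:nrec], recRg[:nrec], -2
        xs[n] = gx
        ys[n] = gy
        parent[n] = pi
        lam_attach[n] = lam
        if use_grid and model == DLA and lam <= GRID_LAM_MAX:
            grid_insert(n, xs, ys, head, nxt, ncx, cs, R)
        r = np.hypot(gx, gy)
        if r > r_max:
            r_max = r
        sx += gx
        sy += gy
        sr2 += gx * gx + gy * gy
        n += 1
        if n % record_every == 0 or n == n_target:
            mx = sx / n
            my = sy / n
            rg2 = sr2 / n - (mx * mx + my * my)
            if rg2 < 0.0:
                rg2 = 0.0
            recN[nrec] = n
            recRg[nrec] = np.sqrt(rg2)
            nrec += 1
    return xs, ys, parent, lam_attach, recN[:nrec], recRg[:nrec], 0
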