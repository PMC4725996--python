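# Methods

## Model

Identical hard particles of diameter 1 aggregate one at a time onto a
seed fixed at the origin; all lengths below are in particle diameters.
Every aggregated particle carries an effective interaction range λ, so
the cluster presents an *interaction boundary*: the outer edge of the
union of radius-λ disks around its particles.

A mobile particle is **captured** at the first point where its
trajectory crosses this boundary.  For a trajectory segment with origin
o, unit direction u and a disk centre c, the entry parameter is

    t = s − √(λ² − d²),  s = (c − o)·u,  d = |(c − o)×u|,  (d < λ),

and the capture event is the smallest admissible t ∈ [0, ℓ] over all
disks.  Tangency (d = λ) counts as a miss and candidates with t < 0
(boundary behind the walker) are ignored; both are zero-measure
conventions.  Near-ties in t (within 10⁻¹²) resolve to the lowest
particle index so the result cannot depend on the order in which
candidates were gathered by a spatial index.

The captured particle then **aggregates in contact** with the particle
whose disk it crossed: it is placed one diameter from that particle,
along the direction from it to the capture point.  The interaction
range decides *where* growth happens; the aggregate itself remains a
connected cluster of touching particles.  For λ = 1 capture and contact
coincide and the dynamics is exactly standard off-lattice DLA/BA.  This
two-step reading is what produces the interaction-limited regime: at
constant λ = 1000 a 2·10³-particle cluster stays far smaller than λ,
its nearly circular envelope funnels growth to the outermost particles,
and the local dimension sits near the mean-field value 1 (typically
with three dominant arms).  Placing particles *at* the crossing point
instead would scale the whole cluster by λ and reproduce plain DLA at
any λ, with no mean-field stage — and a linear schedule λ(N) = N would
give R_g ~ N² (β = 2, "D" = ½), outside the physical band [1, D₀].

The new particle may in principle overlap a non-parent particle
(capture guarantees clearance λ from all particles, contact is enforced
only towards the parent); at λ = 1 no overlap is possible, and at
λ > 1 overlaps are rare and cosmetic — positions, not excluded volume,
drive the statistics of this model class.

### Walkers

* **BA**: straight rays launched uniformly (position and direction)
  from the circle L = r_max + 1000, where r_max is the farthest
  particle's distance from the seed.  The large offset avoids screening
  artefacts.  Directions whose closest approach to the origin exceeds
  r_max + λ (certain misses) are re-drawn at launch; this is
  distributionally identical to simulating and killing them.  When
  λ(N) > 1000 the launch circle can dip inside the interaction
  boundary; such a walker is born within the attraction range and
  attaches immediately to its nearest particle (re-launching would
  deadlock once the whole circle is covered).
* **DLA**: unit-step random walks (mean free path 1, fresh uniform
  direction each step) launched from L = r_max + λ + 100, which always
  clears the boundary.  Far from the cluster the step is enlarged to
  d_nn − λ − 1 (d_nn = distance to the nearest particle): by the
  triangle inequality such a hop can never reach the boundary in any
  direction, so the acceleration is exact, not approximate.  The hop is
  additionally capped at L_k − |p| so a single jump cannot leap past
  the killing circle; the cap floors at 1 so walkers can still cross it
  and be culled.
* **Killing**: walkers strictly beyond L_k = 2L are discarded and
  relaunched uniformly, the standard convention for killing-radius
  schemes.  Killed walkers never count toward N.

Every unit step that could reach the boundary (d_nn − ℓ < λ) is
screened by the exact first-crossing kernel before the move is
committed, so no walker ever tunnels through the boundary.

### Schedule

λ(N) = λ₀·N^ε is evaluated on the pre-attachment count N — the incoming
particle interacts with the cluster as it currently exists.  λ₀ = 1 and
ε ∈ [0, 1] throughout; ε = 0 gives the constant-range regime.

## Estimating the fractal dimension

R_g (root-mean-square distance from the centroid, updated in O(1)
during growth) is recorded every 10 aggregations.  Traces are averaged
over the ensemble *first*; derivatives and fits act on the mean trace,
with per-cluster fits kept only for standard errors.

* **Global D**: least-squares slope β of log R_g vs log N on a window;
  D = 1/β.  Default window: the last decade [N_max/10, N_max], where
  monofractal traces have a stable slope.
* **Local D(N)**: β_j from two-point differences at the ends and the
  centred three-point formula in between, on the (log N, log R_g) grid
  as sampled (any strictly increasing grid is accepted); D_j = 1/β_j.
  The pointwise derivative is noisy by construction, so curves are
  smoothed with a centred running mean over 51 recorded points
  (truncated at the ends) — wide enough to quiet derivative noise
  without masking the multiscaling crossover.

## Calibration and inversion

For each ε on a grid (default 0.05, 0.1, 0.2, …, 1.0) an ensemble is
grown at λ(N) = N^ε, the mean trace fitted on the last decade, and the
(ε, D) table stored with its provenance (ensemble, N_max, seeds, fit
window) so tuned runs are auditable.  D(ε) decreases from ≈ D₀ at
ε → 0 to ≈ 1 at ε → 1.  Inversion interpolates linearly *in D* between
the two bracketing calibration points (the curve is smooth enough that
a coarse grid suffices); targets outside the sampled range clamp to the
nearest endpoint with an explicit warning.  The entropic/energetic
split of any D in [1, D₀] is the affine map f_s = (D−1)/(D₀−1),
f_E = 1 − f_s, exact at both endpoints.

## Numerical choices

* One walker in flight at a time (strict particle–cluster aggregation).
* RNG: one Mersenne-Twister stream per cluster, seeded inside the
  compiled loop; the stream is bit-compatible with
  `numpy.random.RandomState`, which lets a pure-Python replica of the
  loop reproduce the compiled engine draw-for-draw (test suite).
  Cluster i of an ensemble uses base_seed + i; calibration point j uses
  base_seed + j·ensemble + i, and tuned verification runs shift the
  base by 2·10⁴ so they never reuse calibration streams.
* Neighbour gathering uses three interchangeable strategies that are
  *bit-identical* by construction (each step uses the exact nearest
  distance and exact crossing screen): a brute-force scan (reference),
  a uniform grid with cell size max(2, 1.25λ) rebuilt lazily as λ or
  r_max grow (λ ≤ 32), and a cached active list of particles within
  λ + 8 of an anchor, refreshed when the walker drifts more than 6
  diameters (λ > 32, where grid cells would each hold a large fraction
  of the cluster).  The margins guarantee the cache can never miss a
  disk reachable by a unit step.
* Defensive walker budget: 10⁷ steps per aggregated particle; never
  binding.
* Coordinates are written with 9 significant digits; writers are
  canonical so write → read → write is byte-stable, which is what the
  determinism hash checks compare.

## What the experiments show (and what they do not)

All quantities in the test suite and `scripts/acceptance.py` are
measured at desk scale: 8–16 clusters of 2·10³–2·10⁴ particles instead
of the 48–192 clusters of 10⁵–3·10⁵ behind the published figures.  At
this scale the direct-contact baselines recover D ≈ 1.71 (DLA) and
D ≈ 1.95–1.96 (BA; the compact limit 2 is approached slowly from below,
a known finite-size effect of ballistic growth), the λ = 1000 first
stage sits within 0.15 of the mean-field line, and calibrate → invert →
grow round-trips land within ±0.08 of prescribed dimensions 1.51 (BA)
and 1.31 (DLA).  Full-scale multiscaling traces spanning several decades
of N, and dimension estimates at the printed precision of the original
figures, are outside desk runtime and are not asserted.

The model itself idealises: monodisperse particles, irreversible
sticking at first capture, no restructuring, no drift or Lévy
statistics in the walkers, two dimensions only.  Agreement of the
scaled-down experiments therefore validates the implementation and the
qualitative regime structure, not the quantitative behaviour of any
specific experimental system.
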