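# Methods

## Model

The landscape is a site-percolation map on an L × L torus: every site
is habitat (fraction p) or non-habitat (fraction q = 1 − p), assigned
uniformly at random with the habitat count fixed exactly at round(pN),
N = L².  Two geometries are supported:

* **hex6** — the 6-neighbour triangular adjacency in axial coordinates
  on a rhombic torus: neighbours of (i, j) are (i±1, j), (i, j±1),
  (i+1, j−1), (i−1, j+1) mod L.  This is the standard lattice whose
  site-percolation threshold is exactly p_c = 1/2.  (The literature
  sometimes calls this arrangement a "hexagonal" or even "honeycomb"
  lattice because its cells are hexagons; the honeycomb *adjacency*
  proper has z = 3 and is not what is implemented — the z = 6 reading
  is the one consistent with the analytic loss probability p(1 − p)⁶
  and with p_c = 0.5.)
* **square4** — the square lattice with von Neumann adjacency (z = 4),
  p_c ≈ 0.592746 (numerical literature value).

Dynamics are density-conserving swaps: per step, one habitat site
chosen uniformly becomes non-habitat and one non-habitat site chosen
uniformly *from the pre-swap state* becomes habitat.  The uniform
measure over fixed-density configurations is stationary and reversible
under this kernel, so a uniform random start needs no burn-in (a test
checks that patch-count statistics do not drift between early and late
sweeps).  Reversibility also forces the removal/addition dual events to
occur at equal rates in steady state, which the suite checks.

A removal is classified against the pre-swap state; the addition of the
same swap is classified against the intermediate (post-removal) state,
the state it is actually applied to.  The alternative convention
(classifying both against the pre-swap state) differs only when the two
focal sites are adjacent, a vanishing fraction of events; some ordering
had to be fixed and this one keeps each classification consistent with
the landscape it mutates.

## Event classification

Removing a habitat site causes loss (no habitat neighbours), shrinkage
(remaining neighbours still connected) or splitting; adding one causes
formation, enlargement or coalescence.  Classification is local:

1. The habitat neighbours of the focal site are grouped by a lookup
   table indexed by the occupancy bitmask of the surrounding ring (the
   6 neighbours on hex6; the 8-site Moore ring on square4, where the
   diagonals act as connectors between the 4 von Neumann neighbours).
   Ring-connected groups are provably in the same fragment.  If a
   single group remains, the event is shrinkage/enlargement with no
   search at all.
2. Otherwise one breadth-first search per group runs in round-robin,
   restricted to habitat sites (excluding the removed site).  Searches
   that touch merge (union-find); a search that exhausts its component
   has found a fragment and sized it exactly.  The procedure stops as
   soon as at most one unexhausted search remains, so the cost is
   bounded by twice the size of the smaller fragments, not by the patch
   size.

**Size saturation.**  Long simulations record patch sizes saturated at
a cap c (default 16): any size above c is stored as c + 1, sizes ≤ c
are exact.  This is lossless for everything the analyses need.  Event
*type* probabilities never need sizes.  The effective habitat loss of a
removal (patch size s, fragments s_i with Σ s_i = s − 1) satisfies

    e(m) = s·[s ≥ m] − Σ s_i·[s_i ≥ m]
         = 0                     if s < m
         = 1 + Σ_{s_i < m} s_i   if s ≥ m,

so only fragments *smaller than m* must be exact; any m ≤ c is computed
exactly (the accumulator refuses m > c).  One-off classification
(`classify_removal`/`classify_addition`, the CLI `classify` command)
defaults to exact sizing.

**Verification.**  Three independent routes must agree: the fast local
classifier, a brute-force oracle that relabels the whole landscape
before and after a trial change (scipy connected-component labelling
plus torus merging, itself validated against a generic graph-components
library), and a numba kernel that mirrors the reference engine and must
reproduce its event stream bit for bit (both engines consume the same
SplitMix64 stream).

## Curves, thresholds, transitions

**Event curves.**  Probabilities are reported *conditioned on removal
events* (loss + shrinkage + splitting = 1 per grid point); the
addition-side dual counts are tallied and stored alongside.  The
conditional analytic baseline for loss is (1 − p)^z.  Standard errors
are binomial from counts and labelled approximate (events within a run
are weakly dependent).

**Percolation threshold.**  Each replicate landscape is labelled on the
cut-open grid (scipy), then the torus wrap edges are merged with a
union-find that carries unrolled displacement vectors; a wrap edge
whose displacement constraint closes with a nonzero winding vector
proves a cluster wraps the corresponding axis (the finite-size proxy
for the spanning/infinite cluster).  The scan statistic is the per-axis
mean wrapping probability (R₀ + R₁)/2, whose value at criticality is
≈ 0.52 in the large-L limit; interpolating its 0.5 crossing is
therefore nearly unbiased at L = 100, whereas the either-axis union
(critical value ≈ 0.69) would bias the crossing several thousandths
low.  The either-axis probability is still reported in the scan table.
Default protocol: L = 100, 200 replicates per point, p scanned in 0.01
steps (0.40–0.60 hex, 0.50–0.70 square); no crossing inside the scan
raises a diagnostic error rather than extrapolating.

**Transitions.**  On a curve covering q from ≤ 0.05 to ≥ 0.95:
q1 is the first downward linear-interpolated crossing of P(shrinkage)
through 0.99; q2 is the percolation threshold (wrapping estimate if
supplied, else the geometry's reference value); q3 is the vertex of a
parabola through the grid argmax of P(splitting) and its two
neighbours (exact for three points, works on non-uniform grids, clamped
to the bracketing interval); q4 is the first upward crossing of
P(loss) − max(P(shrinkage), P(splitting)) through 0.  Multiple
crossings take the first in increasing q with a logged warning.  These
are the simplest schemes consistent with the integer-percent precision
of the reference values; a refinement-invariance test on a smooth
synthetic curve bounds the grid-coarsening error at ~0.01–0.015.

## Parameters and problem sizes

| parameter | default | notes |
|---|---|---|
| L | 100 | N = 10⁴ sites; the scale of the full study |
| events per q | 10⁵ | desk scale; the full-scale study used 6·10⁶ (`PAPER_N_EVENTS`, `--paper-scale`) |
| q grids | per-geometry study grids | hex: 0.05–0.95 step 0.05 ∪ 0.45–0.55 step 0.01 ∪ {0.33, 0.37, 0.43}(as q); square: 0.05–0.95 step 0.05 ∪ 0.20–0.55 step 0.01 (as q) |
| m | 1–9 | minimum viable patch sizes evaluated in one pass |
| size cap | 16 | exact for all m ≤ 16 |
| threshold scan | 200 replicates/point | SE of the crossing ≈ 0.002 |

All randomness derives from a single user seed through numpy
`SeedSequence` spawning (landscape draw and swap stream separately per
grid point), so every run is reproducible bit for bit; derived integer
seeds are kept below 2³¹.

At desk scale the whole test suite runs in a few minutes on one CPU.
Curve-shape quantities (splitting peak, transition locations) carry a
Monte Carlo localisation uncertainty of roughly 1–2 percentage points
at 10⁵ events per point; the full-scale event count would shrink this
by about a factor of 8.

## What the generator does and does not emulate

The simulator *is* the model under study — an uncorrelated percolation
map with uniform random site turnover — so passing tests show that the
implementation reproduces the model's known analytics (loss baseline,
thresholds) and its reported phenomenology (splitting peak above the
threshold, transition locations, amplification behaviour).  They say
nothing about real landscapes: real habitat is spatially aggregated
(which delays splitting to higher q), non-habitat may be traversable
(functional connectivity), and real loss processes are spatially
correlated rather than uniform.  Random maps are best read as a
worst-case fragmentation scenario.

## Limitations

* Only the two torus geometries; no honeycomb (z = 3), Moore (z = 8),
  open-boundary or 3-D variants, and no aggregated/correlated maps.
* The wrapping threshold estimator does no finite-size-scaling
  extrapolation; at L = 100 the residual bias is well inside ±0.01.
* Classical percolation observables beyond wrapping (cluster-size
  distributions, correlation lengths) are out of scope.
* No population dynamics: the minimum-area rule is the only viability
  criterion, and effective loss is averaged over removal events only
  (living-area gains from additions are tallied but never mixed into
  A).
* When a splitting produces no viable fragment from a patch that was
  itself below m, the event contributes 0 to A but stays in the
  denominator — the averaging is over *all* removal events.
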