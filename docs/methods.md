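# Methods

This note documents the modeling conventions, algorithms, and numerical
choices behind the package, and what the synthetic test ecosystems do and
do not establish about real genome-scale models (GEMs).

## Ecosystem assembly

Member models are joined *diagonally*: every member keeps its own
metabolite rows and reaction columns, and interaction happens exclusively
through a pool compartment.

* Each exchange reaction of a member (single-metabolite boundary reaction
  in an external compartment) becomes a **transport reaction (TR)**
  between the member's external metabolite and the pooled copy of that
  metabolite.  TR bounds are set to ±`flux_cap` (default 1000
  mmol·gDW⁻¹·h⁻¹) at build time so metabolites transit freely; the cap
  keeps every LP bounded and is configurable.
* Each pooled metabolite gets exactly one **pool exchange reaction (ER)**
  to the environment.  Diets act only on ER (and, for a host model, on
  blood-side boundary reactions).
* Pool metabolite identity is the exchange metabolite id itself.  Two
  members share a metabolite exactly when their ids agree — namespace
  reconciliation (`apply_namespace`, two-column TSV maps) is deliberately
  the user's contract, because automated cross-nomenclature matching is
  error-prone and model-specific.
* Host models may declare *blood* compartments; their boundary reactions
  are never treated as exchanges (they connect the host to its
  bloodstream, not to the shared environment) but can be constrained
  through the diet's blood table.

Flux sign convention (BiGG): negative exchange/ER flux is uptake,
positive is secretion.

**Diet policy.** ER named in the diet get its bounds; unnamed ER default
to *unconstrained* (±cap).  The alternative `blocked` policy (uptake
forbidden, secretion allowed) is available but starves organisms of every
nutrient outside the diet table — including by-products they need to
dispose of or feed on — which is rarely the intended medium semantics.
Western-diet / protein-diet flux tables are not shipped: their numeric
bounds come from an external supplement, and inventing values under those
names would be misleading.  Any diet can be supplied as TSV
(`metabolite_id  lower  upper`) or YAML (with `name`, `default_policy`,
`lumen`, `blood` sections).

## Linear programming

All solves go through one wrapper around scipy's HiGHS interface with
feasibility and optimality tolerances of 1e−9 and no stochastic elements
(deterministic across runs by construction).  Member objectives can be
pinned exactly by appending equality rows `c_iᵀv = z` to the steady-state
system; infeasible or unbounded statuses are propagated, never clipped.

FVA solves two LPs per reaction under the given pins.  The parsimonious
solve minimizes Σ|v| via split auxiliary variables and is used as the
deterministic representative of under-determined flux spaces.

## Pareto front enumeration

* **k = 2 — NISE** (non-inferior set estimation).  Endpoints are found by
  lexicographic maximization (max f₁ then f₂, and vice versa); each chord
  is probed with its outward-normal weighted sum, recursing while the
  optimum improves on the chord by more than the tolerance.  Because a
  weighted LP may return a mid-face point, every weighted solve is
  refined to a vertex of its optimal face (fix the weighted value,
  maximize f₁).  Exact for LPs.
* **k ≥ 3 — Benson-style outer approximation** of the dominated region
  P = {y : y ≤ Cv, v feasible}.  P is intersected with a strict lower box
  (component-wise minima minus a margin) so the working polytope is
  always full-dimensional — this is what lets the same code handle
  degenerate fronts (a single ideal point, or a front of dimension
  < k−1) without qhull failures.  Outer-polytope vertices come from
  `scipy.spatial.HalfspaceIntersection` seeded at the Chebyshev center;
  each unattainable vertex is cut off by a supporting hyperplane whose
  normal is read from the duals of the attainability LP
  (max t s.t. Cv − t·1 ≥ y).  On termination the vertices clear of the
  lower box are exactly the Pareto extreme points.
* Duplicate vertices are merged when ‖p−q‖∞ < 1e−6·(1+‖p‖∞); the
  enumeration tolerance (default 1e−6) is a config knob.
* A weighted-sum grid fallback exists but is approximate (it can miss
  vertices interior to a sampled face's optimum set) and is never the
  default.

Degenerate alternate flux optima at a front vertex are irrelevant
downstream: scoring consumes objective-space geometry only, which is
unique.

## Interaction score and types

Axes are normalized by each member's optimum **alone under the same
diet**, computed by rebuilding a one-member ecosystem (the member keeps
the whole pool to itself).  A member with zero standalone growth makes
the score undefined and raises an error rather than dividing by zero.
The k unit vectors ("original growth" points) are appended to the
normalized front, each exactly once.

* k = 2: S = AUC_P − AUC_NI with AUC_NI = 1, the area of the unit square
  under the neutral front (0,1)–(1,1)–(1,0).  The AUC is trapezoidal over
  the curve ordered by the first coordinate; the curve may reverse
  direction only at its final segment (which happens when the front
  extends past x = 1 and the appended (1,0) point steps back), in which
  case that final trapezoid is subtracted.  An interior reversal is a
  hard error, not silently absorbed.
* k ≥ 3: S = HV_P − HV_NI, convex-hull volumes (qhull) of the augmented
  points plus the origin.  The non-interaction reference applies the same
  augmentation to a neutral ecosystem's front — a single all-ones point —
  giving HV_NI = hull{0, e₁…e_k, 1}.  This choice reproduces AUC_NI = 1
  at k = 2 and is stated prominently because it controls the absolute
  value (not the sign) of every k-dimensional score.  Scores of different
  k are **not** mutually comparable; removal analysis reports them only
  to rank members within one ecosystem.
* Interaction types (k = 2 only): flags E+ / B+ (some front point exceeds
  1 by more than the relative tolerance, default 1e−6, on the first /
  second axis) and E+B+ (E+ and B+ hold and a single point attains both
  members' front maxima simultaneously, within tolerance).  The sign of S
  within ±tol of zero counts as "+" so exact neutrality classifies as
  Neutralism.  The (sign, E+, B+, E+B+) tuple indexes a six-type table;
  combinations outside it (e.g., negative score with B+) return
  Unclassified rather than forcing a fit.

## Front sampling and correlation analyses

Samples are FBA solutions with **both objectives pinned** at points placed
along the front; n defaults to 100,000 for production use (tests and the
acceptance script use 10–1000, which is exact to the same degree on the
toys because the correlations there are rank-perfect).

Placement (default `boundary`): an arc-length-uniform sweep of the
attainable upper boundary — pin f₁ at each grid value, maximize f₂, then
pin both.  Between front vertices this boundary *is* the front polyline
(LP images are polyhedral), so proper trade-off fronts are sampled
exactly as drawn.  A single-vertex ("spike") front is extended with its
*rising approach arc* — from the minimum attainable value of one
objective up to the front — but **only when the other objective's
constrained optimum strictly increases along it**, i.e., only where the
members are positively coupled; both axis orientations are checked.  Flat
approaches carry no interaction information (the other member is
insensitive there), so a strictly neutral ecosystem samples as a constant
column and produces empty driver reports instead of spurious
substrate-uptake "drivers".  The literal `polyline` placement
(interpolation through the augmented front including the descending leg)
is retained for comparison; note that traversing a descending leg dilutes
rank correlations — on the reciprocal cross-feeding toy it caps the
by-product correlation near 0.9.

Per pinned point the flux representative is the parsimonious solution
(secondary objective `min_total_flux`); `none` accepts an arbitrary
optimal basis.  Numerically infeasible pins are nudged inward by 1e−9
once and otherwise dropped with a warning.

* **Drivers**: Spearman rank correlation (average ranks on ties) of each
  TR and host-blood flux against the ecosystem biomass (sum of pinned
  objectives); ρ ≥ +0.95 → secreted driver, ρ ≤ −0.95 → uptaken driver.
  Constant columns are skipped (undefined correlation), as is the whole
  analysis when the ecosystem biomass itself is constant (pure
  competition fronts).
* **Exchanged metabolites**: for pool metabolites carried by ≥ 2 members,
  member i's TR flux is correlated with the negated TR flux of member j;
  pairs with ρ > 0.5 where i secretes (mean flux > 0) and j takes up
  (mean flux < 0) are reported with direction.  The sign filter prevents
  anti-correlated co-uptake of a shared substrate (competition) from
  masquerading as cross-feeding.
* **Obligatory reactions**: objectives pinned at a chosen front point,
  FVA run, reactions whose interval excludes zero (min > 1e−6 or
  max < −1e−6) returned.

## Synthetic ecosystems (what they emulate, what they do not)

The generators build ≤ 8-reaction chain organisms (exchange → transport →
biomass) with integer-friendly stoichiometry so every oracle value is
exact arithmetic:

* *competition*: one pooled substrate, default bound 10 — front is the
  trade-off segment, S = −0.5 in closed form;
* *neutralism*: disjoint substrates, default bounds (5, 7) — front
  (5,7), S = 0;
* *crossfeed_oneway*: A obligatorily secretes 0.5 units of by-product per
  unit growth (coupled into the biomass reaction), B holds a small
  private substrate (bound 1) so its standalone growth is positive —
  FavorsBacteria;
* *crossfeed_mutual*: reciprocal coupling (0.5 each way) with both
  members' private substrates at bound 1 — alone maxima (1,1), coupled
  peak (2,2), S = +1, Mutualism.

A host-like generator adds a lumen/blood two-sided member with a
maintenance-style objective and blood sinks excluded from exchange
detection.  Community generation (3–11 members) places one motif pair
plus neutral bystanders and returns a machine-readable matrix of expected
pairwise signs.  Randomized parameterizations draw yields from
{0.5, 1, 2}, bounds from 3–12, and couplings from {0.25, 0.5, 1}, all
seed-fixed.

These toys validate the algebra and algorithms — assembly bookkeeping,
front enumeration, score geometry, correlation logic — under known ground
truth.  They do not emulate GEM-scale features: thousands of reactions,
redundant pathways with unequal yields, cofactor coupling, reversible
internal cycles, or realistic diet compositions.  Passing tests therefore
demonstrates correctness of the method, not predictive accuracy on any
particular organism pair; real-model scores inherit all the usual
caveats of constraint-based modeling (objective choice, bounds curation,
namespace quality).

## Problem sizes used in tests and the acceptance run

Front-enumeration cross-checks run 20 randomized bi-objective toys
against a 100-point ε-constraint sweep; ground-truth recovery runs 100
seeded parameterizations per motif; sampling analyses use 1000 front
samples; the Monte-Carlo hull oracle uses 10⁶ points; the removal
decomposition uses a 5-member community.  These sizes make every check
exact or rank-perfect on the toy constructions while keeping the whole
suite fast on a single CPU.

## Known limitations

* Interaction types are defined for two-member ecosystems only; higher
  dimensions get a score but no type.
* k-dimensional scores depend on the chosen non-interaction hypervolume
  convention (above) and must not be compared across different k.
* The member soft cap (warn above 11) reflects the combinatorial growth
  of outer-approximation vertices, not a hard limit.
* Dynamic (time-course) community modeling and abundance-weighted
  community objectives are out of scope by design: the framework is
  deliberately non-parametric in composition.
* Exact namespace mappings between model collections are user-supplied;
  the package validates injectivity but cannot judge biological
  correctness of a mapping.
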