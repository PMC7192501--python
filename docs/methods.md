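# Methods

## Model and canonical form

All computations run on one canonical form of a constraint-based metabolic
model: the steady-state polytope `P = {v : S v = 0, lb <= v <= ub}` with
`lb >= 0`.  Canonicalisation (a) splits every reversible reaction into a
forward copy and a `_reverse` copy with the negated stoichiometric column,
(b) caps infinite bounds at 1000 mmol gDW⁻¹ h⁻¹, and (c) removes blocked
reactions — columns whose maximum achievable flux is below 1e-9 — by one
flux-maximisation LP per reaction.  Blocked removal is repeated after medium
constraints are applied, because closing imports creates new blocked
reactions.  A reaction left with `lb = ub = 0` (e.g. the zero-width forward
copy of a purely backward reaction) is treated as blocked.

Minimal media are described by a carbon source with bounded import (default
20 mmol gDW⁻¹ h⁻¹), a set of freely imported compounds, a minimum flux
through the ATP-maintenance pseudo-reaction (default 3.15 mmol gDW⁻¹ h⁻¹),
and a biomass fraction `alpha_b` (default 0.95): the biomass lower bound is
set to `alpha_b` times the FBA optimum under that medium.  Import reactions
are recognised as columns whose entries are all positive (they create
internal metabolites from the environment in irreversible form); SBML
boundary-metabolite annotation takes precedence when present.

## The order decision

The extrema `z_min`, `z_max` of `v_i / v_j` over `P` restricted to
`v_j > 0` are obtained from the Charnes–Cooper LP (variables `w = v / v_j`,
`t = 1 / v_j`; constraints `S w = 0`, `w_j = 1`, `t lb <= w <= t ub`,
`t >= 0`).  The pair is *ordered* iff `z_min >= 1 - eps` and
`z_max > 1 + eps`, *equal* iff both extrema lie within `eps` of 1, and
*unordered* otherwise, with `eps = 1e-6` on ratio space (LP duality gaps on
genome-scale double-precision solves exceed 1e-9, so a tighter value would
misclassify).  Two points matter numerically:

* The bound constraints are scaled by the homogenisation variable `t`, so a
  finite bound cap does **not** bound the ratio program; `z_max` can be
  genuinely unbounded (LP status "unbounded"), which satisfies `z_max > 1`.
  The cap only keeps FBA and blocked-detection LPs bounded.
* If both ratio LPs are infeasible, `v_j` is identically zero.  This cannot
  happen after blocked removal; it is still caught and surfaced as a
  "ratio undefined" error, and such a pair is classified unordered.

The ratio decision is equivalent to the sign of `min (v_i - v_j)` over `P`
together with `max (v_i - v_j) > 0`: by convexity, a pair whose ratio is 1
whenever `v_j > 0` cannot simultaneously admit a point with `v_j = 0 < v_i`.
The test suite exploits this equivalence through two independent oracles
(difference-LPs, and vertex enumeration — a linear objective attains its
extrema at polytope vertices).

## Two-stage search

Deciding all pairs needs `n(n-1)` LP pairs, so candidates are prefiltered by
sampling: a seeded hit-and-run walk in the null space of `S` (so `S v = 0`
holds exactly at every iterate; chords are clipped at the flux bounds,
burn-in 100 steps, thinning 5).  A directed pair violated beyond 1e-6 in any
sampled row carries an explicit counterexample and is provably unordered; a
single violation suffices mathematically, so one is what we require.  The
default sample size of 1000 only trades prefilter sharpness against LP count
— the final pair set is exact and seed-independent, which the acceptance
suite asserts over multiple seeds.  A zero-volume polytope (e.g.
`alpha_b = 1` pinning the space) degenerates the walk; the single feasible
point is then returned under a warning.

Fully coupled candidates (constant ratio `alpha`) are resolved without LPs:
ordered if `alpha > 1`, equal if `alpha = 1`.  Pairs on which the primary
solver (HiGHS via scipy) fails are retried once on GLPK before being
reported "undetermined" — never silently dropped.

## Coupling classification

From the same ratio extrema (`R_min`, `R_max` of `v_i / v_j`): *full* iff
`R_min = R_max` (the constant is `alpha`), *partial* iff
`0 < R_min < R_max < inf`, *directional* iff exactly one side is bounded
(`R_min > 0` means `v_j > 0` forces `v_i > 0`, so `i` leads), *uncoupled*
otherwise.  Directional pairs are stored leader → follower, the orientation
in which an order relation, when present, also points.  By default coupling
uses the same homogenised constraints as ordering, so the overlap
conditionals `Pr(C|O)`, `Pr(O|D)`, … are internally consistent; a flag drops
strictly positive lower bounds to reproduce the pure flux-cone behaviour of
classical flux-coupling tools, since a configured biomass or maintenance
minimum otherwise pins `t` and tightens the ratio set.

## DAG, levels, essentiality

Always-equal groups (closed under union) become single nodes; edges are
deduplicated at group level and the unique transitive reduction for DAGs is
taken (re-reduction is a no-op, asserted).  A cycle can only arise from
tolerance defects and raises an error naming the offending nodes.  The level
of a node is the *longest shortest path* from any root that reaches it
(roots and isolated nodes at level 0; exports also carry 1-based labels,
since both conventions are common).  The first/middle/last partition used by
the regulatory analysis defaults to level 0 / level 1 / levels ≥ 2, and is
configurable.

Every ancestor of the biomass node is necessarily essential (zero flux
through it would propagate an upper bound of zero to biomass); the converse
fails in general.  Essentiality is a single-knockout FBA scan with threshold
1e-6 × the wild-type optimum; a configured biomass minimum is relaxed during
the scan so that essentiality means "cannot grow at all", not "cannot keep
the configured rate".  The ATP-maintenance reaction is excluded from the
ancestor subgraph by default: its fixed minimum flux orders it above biomass
by construction, not by network structure.

## Concordance statistics

Gene-level values are pooled onto reactions through the GPR rules (every
gene anywhere in the rule, counted once, all replicates); reaction-level
data (fluxes, k_cat, mean enzyme costs) attach directly.  For each covered
ordered pair, `delta_ij = mean(D_i) - mean(D_j)` (identical to the
normalised double sum over all value pairs); the agreement score is the
strictly positive fraction `f_>0`, so pairs whose reactions share one value
set (common for isozymes) do not inflate agreement.  The permutation null
redraws values at the profile's granularity — per gene for transcript and
protein data, per reaction for fluxes and k_cat — from the pool of all
available values, preserving multiset sizes, with replacement (a
without-replacement mode permutes the pool instead); `p = (r + 1)/(n + 1)`
with `r` the number of permuted `f_>0` values ≥ the observed one, so
`p ∈ [1/(n+1), 1]` by construction.  The cost-percentile subsets use linear
interpolation on the sorted employed-cost vector and require **both**
members of a pair to meet the threshold (the economic hypothesis concerns
the violation cost on either side); percentile 0 is the identity.  The
Mann–Whitney comparisons between level subsets are one-sided (earlier
levels more regulated), exact when both samples are ≤ 20 and tie-free,
normal-approximated with tie correction otherwise.

## Synthetic data

The fixture generator provides networks with known structure (chain, branch,
diamond, growth, a 9-reaction "paperlike" network, and a seeded random
layered-flow generator with a guaranteed import-to-export backbone).  The
synthetic-omics generator draws one steady-state flux vector as ground
truth, assigns single-gene GPRs where absent, and emits per-gene replicate
values equal to the true flux plus Gaussian noise.  It emulates the
magnitude structure that makes the concordance statistic meaningful — at
zero noise every strictly ordered pair is concordant; as noise dominates,
`f_>0` approaches 1/2 — but *not* the features of real expression data
(multiplicative noise, isozyme-specific regulation, condition effects,
detection limits), so passing tests demonstrate correctness of the
statistics, not biological performance.

## Problem sizes and verification

The test and acceptance workloads run on the named fixtures (≤ 9 reactions)
plus 25 random 8-metabolite × 12-reaction networks; at this size the main
path can be checked for *exact set equality* against both brute-force
oracles (all-pairs difference-LPs, and full vertex enumeration over active
bound sets), which is the package's core correctness gate.  Genome-scale
runs (e.g. iJO1366 with ~2600 reactions before preprocessing) use the same
code path through the CLI but are hours-long jobs dominated by the
`n(n-1)` LPs; the sampling prefilter and the coupling shortcut exist for
exactly that regime.

## Known limitations

* Vertex enumeration is exponential in the polytope corank and refuses
  inputs beyond ~500k candidate active sets; the difference-LP oracle covers
  larger models.
* The hit-and-run sampler is not a calibrated uniform sampler (burn-in and
  thinning are fixed); it is used only as a counterexample generator, where
  distributional accuracy is irrelevant.
* Coupling on models whose lower bounds are strictly positive mixes bound
  information into the cone classification unless the cone flag is used.
* The macrosystem mapping ships as an editable substring table covering the
  common *E. coli* subsystem names; unmapped subsystems report "other".
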