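# Methods

## Problem setting

`pessiknock` computes reaction-knockout strategies for overproducing a target
chemical in a stoichiometric metabolic model.  The organism is modeled at
steady state: fluxes `v` (mmol/gDW/hr) satisfy mass balance `S v = 0` over
the balanced metabolites, bounds `v_min <= v <= v_max`, a fixed substrate
uptake `v_glc = v_glc_uptake` (implemented as an equality pair on the uptake
reaction's bounds) and a viability threshold `v_biom >= v_biomass_min` on the
biomass pseudo-reaction.  A knockout design is a binary vector `z` over the
knockable reactions with `v_j_min z_j <= v_j <= v_j_max z_j` and at most `K`
zeros.

Strain design is a bi-level problem: the engineer picks `z` to maximize the
target flux `v_chem`, but the flux state is chosen by the cell, modeled as an
inner optimization.  Two inner (cell-response) models are supported:

* **biomass** — the mutant maximizes growth, `max v_biom`;
* **room** (minimal flux change, LP relaxation) — the mutant minimizes the
  number of significantly changed fluxes relative to a wild-type reference
  `w`: `min sum_j y_j` with relaxed indicators `y_j in [0, 1]` and
  `v_j - y_j (v_j_max - w_j) <= w_j`, `v_j - y_j (v_j_min - w_j) >= w_j`.
  The original mixed-integer variant with binary `y` and relative
  significance thresholds is deliberately out of scope; the constraints
  compare fluxes to `w_j` exactly.

### Optimistic vs pessimistic

When the inner problem has multiple optima, the classical formulations
(OptKnock-style for biomass, its minimal-change analogue) assume the *most
favorable* inner optimum — the cooperative assumption.  The pessimistic
formulations instead maximize the *worst case*: the guaranteed target flux
over every inner response the cell might adopt.  Response uncertainty is
widened by a tolerance `eps` — the epsilon-approximation band — containing
all responses whose inner objective is within a multiplicative factor of
optimal:

* biomass model: `v_biom >= (1 - eps) * phi*(z)` (and always `>= v_biomass_min`),
* room model: `sum_j y_j <= (1 + eps) * phi*(z)`,

where `phi*(z)` is the inner optimum for the design `z`.  `eps = 0` is the
fully pessimistic problem on the inner-optimal face; `eps = 1` makes the
biomass band collapse to the viability threshold alone (so the evaluation
reduces to flux variability of the target reaction).  When the room optimum
is `phi* = 0`, the band degenerates to `sum y <= 0` exactly; no additive
floor is introduced.

## Reduction to a single-level MILP

Both inner models are put in one canonical maximization form over variables
`x` (`x = v`, or `x = (v, y)`):

    max c_in' x   s.t.   A x = 0,   B x <= b0 + Bz z,

with the knockout vector entering only the right-hand side of the bound
rows.  The pessimistic program `max_z min_{x in band(z)} f' x` is collapsed
mechanically in two dualizations:

1. Replace `phi*(z)` in the band by the dual objective of the inner LP and
   let the adversary minimize over dual-feasible points as well.  By weak
   duality every dual-feasible point over-estimates `phi*`, and since a
   smaller band bound only shrinks the adversary's feasible set, the
   adversary drives it exactly to `phi*`.  This yields a single adversary LP
   over `(x, nu, lam)`.
2. Dualize the adversary LP (variables `gamma`, `beta`, `pi` and the band
   dual `t >= 0`), turning max–min into a joint maximization over `z` and
   the second-level duals.

A feasibility witness `x_hat` satisfying the inner primal constraints for
the chosen `z` is added: without it, designs whose inner problem is
infeasible would make the adversary dual unbounded and the MILP unsound.
The optimistic baselines use one dualization only (primal feasibility +
dual feasibility + primal objective = dual objective).

The bilinear products (`z * beta` in the objective, `z * t` in the band-dual
rows, `z * lam` in the optimistic strong-duality row) are linearized exactly
with the big-M construction: `xi <= M z`, `xi >= -M z`,
`xi <= x + M (1 - z)`, `xi >= x - M (1 - z)`.

## Numerical safeguards

These choices came out of observed failure modes of big-M bi-level MILPs and
are part of the method, not incidental tuning:

* **Dual cap and activity audit.**  LP duals have no a-priori bound, so
  dual-type factors are capped at `M_dual` (default `1e4`; flux-type factors
  use the largest bound magnitude in the model).  After each solve the
  largest product factor is audited: within 5 % of the cap invalidates the
  relaxation and `M_dual` is escalated tenfold (at most twice).  Because
  very large M combined with ill-conditioned instances can make
  branch-and-bound grind, escalated re-solves run under a 10 s wall-clock
  cap; if one fails, the last successful solve is kept and flagged in
  `solver_stats` (`bigM_audit_ok: false`).
* **Certification.**  The MILP selects the design; its reported objective is
  then re-computed exactly by the two-stage LP evaluator on that design.
  This removes big-M and MIP-tolerance round-off from the reported
  guaranteed flux (the raw MILP bound is kept as `milp_bound`).
* **Tight integrality tolerance.**  HiGHS' default `1e-6` integrality slack
  on a binary can leak `M * 1e-6` through a product into an embedded
  strong-duality equality — enough to corrupt the design choice.  MIP
  feasibility tolerance is therefore set to `1e-8` (primal/dual `1e-7`).
* **Wild-type reference conditioning.**  The room constraints carry
  coefficients `v_max - w_j` and `v_min - w_j`.  A reference flux that is
  within round-off of a bound produces nearly-zero coefficients whose inner
  duals explode as `1/(v_max - w)`; `w` is therefore snapped exactly onto
  any bound it approaches within `1e-8`.
* **Band slack.**  The two-stage evaluator adds an absolute `1e-7` to the
  epsilon band so stage 2 cannot be spuriously infeasible at `eps = 0`.

## Wild-type reference

The room model needs a unique, reproducible `w`.  "The" FBA optimum is
usually degenerate, so `w` is pinned down parsimoniously: stage 1 maximizes
biomass; stage 2 fixes biomass at that optimum (as an equality) and
minimizes total absolute flux.  Any solver-vertex-dependent choice would
make every downstream minimal-change result irreproducible.

## Worst-case evaluation and the enumeration oracle

Any *fixed* design is evaluated by a two-stage LP: stage 1 computes the
inner optimum `phi*`, stage 2 minimizes (pessimistic) and maximizes
(optimistic) the target flux inside the epsilon band.  This is also how
designs produced by the cooperative methods are stress-tested: their
guaranteed production typically collapses well below the promised value even
at small `eps`.

The enumeration oracle scores *every* design of size `<= K` this way and
returns the argmax (ties broken by size-then-lexicographic enumeration
order).  It is exponential in `K` but exact and independent of the MILP
machinery — the referee used throughout the test suite.

## Synthetic networks

The fixture generator emulates the features that make knockout design
non-trivial on real networks, at toy scale:

* a fixed substrate uptake (default 10 mmol/gDW/hr) and a biomass reaction
  with a viability threshold (default 1 mmol/gDW/hr);
* competing routes from substrate to biomass precursor, one of which
  co-produces the target metabolite;
* an *uncredited sink* draining the target metabolite — the source of
  inner-level non-uniqueness that separates cooperative from worst-case
  predictions;
* random internal conversions (coefficients 0.5–2, occasional reversibility
  with lower bound −100, bounds [0, 100] otherwise), capped at 8 knockable
  reactions so the enumeration oracle stays exhaustive.

Random fixtures are rejection-sampled until wild-type FBA is feasible with
maximum biomass above the threshold; generation is reproducible from the
seed.  What these networks do **not** emulate: genome-scale size (10^3
reactions), compartments, gene–protein–reaction coupling, cofactor/energy
stoichiometry, and realistic degeneracy structure.  Passing the test grid
demonstrates correctness of the formulations and reductions, not biological
validity of any particular knockout prediction; runs on curated models
(SBML L3/FBC input is supported, with role overrides for the
uptake/biomass/target designations) are needed for the latter.

## Problem sizes used by the test and acceptance runs

The property grid runs the toy7 network plus 20 seeded random fixtures
(9–11 reactions, up to 8 knockable), budgets `K in {1,2,3}` and tolerances
`eps in {0, 0.1, 0.5, 1}`, checking MILP-vs-oracle agreement at `1e-4`,
strong duality of the inner dual block at `1e-5` on 50 random
(fixture, design) pairs, the optimistic-upper-bound property, and eps/K
monotonicity.  These sizes keep the exhaustive oracle exact; the MILPs
themselves scale far beyond them.

## Known limitations

* Pessimistic values are certified per selected design; global optimality of
  the *selection* rests on the audited big-M MILP.  A flagged audit
  (`bigM_audit_ok: false`) means the dual cap was active and the design
  choice is best-effort for that instance.
* The room inner model is the LP relaxation; binary-indicator ROOM designs
  may differ.
* No gene-level knockouts, regulatory constraints, thermodynamic loop-law
  constraints, or flux sampling.
* Alternate optimal knockout sets are not enumerated by default; the solver
  returns one optimum deterministically.
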