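# Methods

## Model overview

`evogrid` simulates discrete-generation dynamics of polymorphic bacterial
populations on a lattice of flow-coupled *point environments* — uniformly
mixed 0D habitat blocks holding substrate pools and resident cells.  A species
is defined by the *structure* of its gene networks: the substrates it consumes
and secretes, the environmental substances that activate or inhibit its
growth, and its reproduction strategy.  Numeric parameters of those networks
(utilization efficiencies, inhibitor sensitivities, synthesis yields, maximum
growth coefficients) are heritable "genes"; a polymorphic population is stored
as explicit cohorts over full allelic combinations, and the per-gene allele
distributions of the generalized genome are marginal views over the cohorts.
Cohorts were chosen over independent per-gene marginals because fitness is
defined per allelic combination; shipped scenarios keep supports small (2
alleles per gene) so the combination space stays tiny.

Each generation has two stages:

1. **Local update** (independent per node, in any order): substrate
   consumption, utilization, reproduction, synthesis/secretion, optional
   mutation.  Per-cohort fitness is recorded as `(P_after - P_before) /
   P_before` over the reproduction stage.
2. **Spatial redistribution**: flow, then diffusion, then chemotaxis (the
   sub-order is configurable; this default is fixed and documented because
   nothing in the model pins it down).  An integer sub-stepping factor can run
   stage 2 several times per generation when spatial processes are faster than
   reproduction; the default is 1.

## Local dynamics

**Consumption.** A cohort of `n` cells demands `n * k_max * c_i` raw units of
each consumed substrate (`c_i` = resource units per new cell).  Each pool is
split among all demanding cohorts of all species proportionally to demand and
capped by availability; pools are decremented by exactly the allocated totals.
Demand-proportional sharing was preferred over an equal split, which would
depend on how cells happen to be partitioned into cohorts.  Demand
deliberately excludes the utilization efficiency: efficiency acts downstream,
converting the granted raw share into usable resource, so efficient alleles
extract more from the same share and remain under selection even when the
pool is scarce.  (If demand scaled with `1/e`, proportional sharing would
cancel the efficiency exactly and utilization-efficiency alleles would be
neutral.)

**Growth laws.** With `u_i` the usable resource per cell:

* non-compensatory (Liebig's law of the minimum):
  `k = min(k_max, min_i u_i / c_i)` — growth is set by the scarcest required
  resource, zero if any required substrate is absent;
* compensatory (Rubel's law of compensation):
  `k = min(k_max, sum_i w_i u_i / sum_i w_i c_i)` — abundant resources offset
  scarce ones through non-negative weights `w_i` (uniform by default).

These are minimal closed forms satisfying the two laws with a `k_max` cap;
they contain no per-substrate uptake saturation (see Limitations).

**Activation/inhibition.** Growth is multiplied by
`m = (1 + a * A) / (1 + s * I)` where `A`/`I` are summed activator/inhibitor
concentrations read from the pre-consumption snapshot, `a` is the activator
gain and `s` the (allele-carried) inhibitor sensitivity.  The form is bounded,
positive, equals 1 with no links, and is monotone in both loads.

**Reproduction and mortality.** Deterministic mode:
`n' = n * (1 + k*m - d)` floored at zero, with `d` a resource-independent
per-generation death rate (default 0).  Stochastic mode: Poisson births with
mean `n*k*m` and binomial deaths, on integer counts.  A configurable death
rate is needed for spatial source–sink structure: in a flow-through tube with
outflow-only mortality, interior nodes are perpetually refilled by advection
and populations can never become locally extinct.

**Synthesis.** Secretion is powered by utilization energy: pools grow by
`yield * newborn cells`, so a starving cohort secretes nothing.  Coupling
secretion to standing population size instead would make a closed trophic
cycle a positive-gain loop with unbounded growth.  Non-secreted products stay
in a species-internal pool consumed preferentially next generation.

**Mutation.** Each mutating cell (fraction = rate; binomial in stochastic
mode) picks one gene slot uniformly.  Finite-sites model: the new value is
drawn from the slot's current marginal distribution at the node, so the
support never grows.  Infinite-sites model: a fresh value is drawn as
`lo + X * (hi - lo)`, `X ~ Beta(a, b)` on the slot bounds (defaults a = b = 2,
a symmetric bell), adding a support point.  Cell counts are conserved exactly.

**Horizontal transfer and gene loss.** Transfer copies one gene slot from a
donor into `n` acceptor cells at one node, founding a new species whose
structure is the acceptor's extended with the slot (a utilization slot also
extends the diet).  The transferred allele value is the donor's modal allele
(configurable to a random draw from the donor's marginal; the modal choice is
a design decision — nothing in the model fixes it).  Gene loss removes a slot
and any consumed-substrate link only it served, refusing to strip the last
consumable substrate.  Both operations move cells proportionally across
cohorts (multivariate hypergeometric in stochastic mode) and conserve global
cell counts.  Species identity is purely structural: two populations are one
species iff their structures are equal up to the species label, regardless of
allele frequencies.

## Spatial operators

* **Through-flow** advects fraction `r` of *all* cells and substrates to the
  downstream neighbor along the first lattice axis each step; upstream-face
  nodes receive `r * inflow` of each inflow substrate and the downstream
  face's share leaves the system.  Inflow never carries cells.
* **Perpendicular flow** exchanges fraction `r` of every node's content with
  an external flow independently; no inter-node advection.
* **Diffusion** is the synchronous nearest-neighbor stencil
  `dS(x) = d * sum_nb (S(y) - S(x))` with no-flux boundaries; `d` is validated
  against the non-negativity bound `1/(2 * dimensionality)`.  Cells do not
  diffuse unless the `cell_diffusion` toggle is on (cell movement is otherwise
  flow and chemotaxis only).
* **Chemotaxis** is greedy: from a synchronous snapshot each cohort scores
  every neighbor as total consumable substrate minus sensitivity-weighted
  inhibitor load and moves fraction `c` to the best neighbor if it strictly
  improves on the current node (tolerance 1e-12; ties break toward the lowest
  flat node index).  A probabilistic (softmax) rule was rejected so the
  deterministic mode stays bit-reproducible.

All stage-2 operators conserve substrate totals and cell counts exactly in a
closed system.

## Numerical and reproducibility choices

* Deterministic mode uses real-valued counts (no drift); stochastic mode uses
  integer counts with binomial/multinomial/Poisson sampling for every
  redistribution step.
* Per-node RNG streams are derived from `(seed, generation, node index)` via
  `numpy` seed sequences, so stage-1 results are independent of node
  processing order even with stochastic sampling; stage-2 and event draws use
  separate streams.
* Allele extinction threshold: exact zero in stochastic mode; 1e-9 frequency
  in deterministic mode (deterministic dynamics never reach exact zero).  A
  node where the population itself is extinct holds no diversity.
* Degenerate inputs: empty pools allocate nothing; zero-count cohorts are
  dropped; fitness of an empty cohort is a NaN sentinel; an extinct species in
  the P_max/P_min ratio yields an infinite-ratio sentinel.

## Benchmark communities

Both shipped communities are synthetic: their parameter sets
(`DEFAULT_POISONER_PREY_PARAMS`, `DEFAULT_TWO_CYCLES_PARAMS`) are free knobs
chosen once so the simulations reproduce the qualitative spatial-evolution
structure of interest, and are explicitly non-canonical — they are not fitted
to any organism, and absolute counts and generation numbers carry no units
beyond the model's own.

**Poisoner–prey** (10-node flow-through tube, flow rate 0.02): the prey lives
on the inflow substrate N1 and secretes S1; the poisoner consumes N1 and S1
under the compensatory law, secretes the toxin S2 that inhibits the prey, and
is activated by S1.  The prey is polymorphic in S2 sensitivity, the poisoner
in S1-utilization efficiency.  With these defaults the stochastic benchmark
(five replicates, 900 generations) shows: prey persisting only in the nodes
near the inflow while the poisoner occupies the whole tube; prey diversity
loss earliest at the outflow end (toxin accumulates downstream and the local
populations starve); poisoner diversity loss earliest at the inflow end
(downstream nodes keep receiving polymorphic migrants).  The 900-generation
horizon is the smallest at which the distal poisoner losses complete.

**Two trophic cycles** (rings P1–P2–P3 and P4–P5–P6; each species utilizes
its specific substrate plus inflow N and feeds the next ring member; all six
either non-compensatory or compensatory): the schedule transfers the
S6-utilization gene from P6 into P1 cells at generation 100 (founding P7,
which joins the rings and feeds P2), cuts the N inflow 100-fold at generation
2000 and restores it at 3000.  The perpendicular-flow benchmark enables cell
diffusion (d = 0.1) so P7 can spread without flow or chemotaxis, and runs
deterministically for 3100 generations.  Differentiation is measured as the
P_max/P_min ratio across the six founding species at the starvation plateau;
P7's survival is asserted separately.  The restriction to the founding ring is
a deliberate scope choice: under our minimal growth laws a generalist is
strictly superior per share, so P7's absolute size sits on a competitive-
exclusion knife edge and an all-species ratio would measure P7's survival
rather than starvation differentiation.  The specific-substrate cost
`c_s = 6` was chosen because the generalist's edge scales as
`2(1 + c_s)/(1 + 2 c_s)`, which approaches 1 for large `c_s` and keeps all
seven species coexisting through the experiment.

## What the synthetic benchmarks do and do not show

Passing tests show that the implemented primitives interact as designed —
conservation, closed-form flow solutions, logistic saturation, the exact
Fisher relation `Δw̄ = Var(w)/(1 + w̄)` for constant selection, and the
qualitative source–sink evolution patterns above.  They do not show anything
about real microbial communities: yields are not mass-balanced, growth laws
lack uptake saturation and temperature/pH dependence, genomes are numeric
parameters rather than sequences, and all parameter values are calibration
artifacts.

## Known limitations

* No per-substrate uptake saturation: generalists are strictly superior per
  allocated share, so stable specialist/generalist coexistence exists only
  where parameters make the exclusion slow.
* Maintenance energy is modeled only as an optional resource-independent
  death rate; there is no explicit intracellular metabolite budget.
* Chemotaxis is deterministic best-neighbor movement; no run-and-tumble
  stochasticity.
* Parallel execution of the order-independent stage 1 is deliberately out of
  scope (the contract that enables it is tested).
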