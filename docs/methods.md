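# Methods

## The model

`foragesim` simulates a population of `N` foragers whose social state is a
directed binary network of *foraging ties*: a tie `i -> j` means `i` is
willing to forage with `j`. Only reciprocated ties produce co-foraging.
*Groups* are the connected components (with at least two members) of the
mutual-tie graph — the chain rule: if A reciprocates with B and B with C,
all three form one group whether or not A and C are tied.

The environment holds a single resource patch of size `R` units, fully
replenished every time step and inaccessible to lone individuals. Each step:

1. **Group detection** on the current mutual-tie graph.
2. **Allocation.** Under the default *group-competition* rule, group `k` of
   size `n_k` takes `s_k = R * n_k^2 / Σ_j n_j^2` (competitiveness scales
   with the squared group size, the number of possible within-group
   relationships), shared evenly: `r_i = s_k / n_k`. The *equal-allocation*
   variant ignores group size: `r_i = R / Σ_j n_j` for every group member.
   Lone individuals always receive `r_i = 0`.
3. **Tie update.** Every forager reacts only to its own payoff: `r_i < 1`
   (negative outcome) removes one uniformly random outgoing tie; `r_i > 1`
   (missed opportunity) adds an outgoing tie to a uniformly random
   individual it is not already tied to; `r_i = 1` changes nothing. There is
   no strategy, memory, or partner choice.
4. **Injection.** With probability 0.01% per step, one random directed tie
   is added from a random current group member to a random other individual,
   modeling occasional attempts to form new groups.

A sole group of exactly `R` members with `r_i = 1` is a fixed point of the
dynamics (absent injection); `R` is therefore the optimal group size.

The **reproductive** variant adds demography after the tie update. Each
individual of age `a` (steps alive) reproduces with probability
`Pr(a) = 1e-3 / (1 + exp(-0.1 a + 5))` — a logistic ramp, ~6.7e-6 at age 0,
5e-4 at the midpoint age 50, ceiling 1e-3 — and dies with the identical
probability, keeping the population stationary in expectation while sizes
fluctuate. The population is single-sex (females; males are uncounted and
disperse), so each offspring has one recorded parent. An offspring inherits
every incoming and outgoing tie of its parent plus one unreciprocated
offspring-to-parent tie: it is born into its parent's group but founds no
new group, and from that moment it is subject to the ordinary payoff
dynamics like everyone else (a birth into an optimal group pushes every
member to `r_i < 1` the next step). A death removes all ties incident to
the deceased. The pedigree (parent -> offspring graph over everyone ever
born) is append-only; dead individuals keep carrying kinship paths.

## Metrics

- Per step: number of groups, mean group size (groups only), mean payoff
  over individuals with `r_i > 0`. Missing values are encoded as missing,
  never as 0.
- **Social stability** `s_ij(t)` = fraction of the `t` elapsed steps in
  which `i` and `j` held a mutual tie. Each step contributes the network the
  step foraged on (the state entering the step). The denominator is total
  elapsed time, so dyads accrue weight only while co-alive but are diluted
  by the full run length.
- **Exclusivity** `E`: rank individuals by weighted degree in the stability
  network (ties broken by ascending id); `E` is the stability weight on
  dyads with *both* endpoints among the top `R` individuals, divided by the
  total weight. `E ~ 1` means one optimally sized group monopolized the
  patch for most of the run. The alternative numerator (all edges incident
  to the top-`R` set) is systematically higher; this package uses the
  induced-subgraph definition throughout.
- **Relatedness** `l_ij = 1 / 2^d` with `d` the shortest undirected path in
  the pedigree (0 if disconnected): 0.5 for parent-offspring, 0.25 for
  grandparent-grandoffspring. Because the model tracks a single sex, the
  formula gives same-mother sibs `d = 2`, i.e. 0.25 — they are effectively
  half-sibs (the uncounted fathers are independent), even though diploid
  full sibs would conventionally be 0.5. The formula is applied literally.
- **Within-group relatedness** `l_m`: mean pairwise relatedness within each
  group, then the unweighted mean across groups. The **permutation null**
  `l_r` refills groups of the observed number and sizes by sampling living
  individuals without replacement (100 draws by default) and averages the
  same statistic. `L_t = ln(l_m / l_r)`; `l_r = 0` is flagged undefined and
  `l_m = 0` flagged as negative infinity, both distinct from ordinary
  values.
- **Pedigree diameter**: longest shortest path in the largest component of
  the full undirected pedigree (dead included) — a generations-elapsed
  statistic.

## Numerical and design choices

- **Exact payoff branch.** Whether `r_i` is below, at, or above 1 decides
  the tie update, and `r_i = 1` is exactly attainable; the comparison is
  done in integer arithmetic (`R * n_k` vs `Σ n_j^2`; `R` vs `Σ n_j` for
  equal allocation), so the fixed point is never lost to float noise.
- **Synchronous updates.** All tie decisions in a step are evaluated
  against the pre-update network and applied atomically; outcomes are
  independent of any within-step ordering of individuals. The random-stream
  protocol (draw order, sorted candidate lists) is documented in
  `baseline.py` and pinned by an oracle test against a literal dict-of-sets
  reimplementation.
- **Within-step order (reproductive):** detect -> allocate -> update ->
  inject -> births -> deaths -> age increments. Births precede deaths, so a
  newborn can lose its parent in its birth step; newborns are exempt from
  birth/death draws in their birth step and age to 1 at its end. Ids are
  never reused.
- **Injection scope.** One Bernoulli(1e-4) event per step for the whole
  population (not per individual or per dyad, which would scale with `N`).
  It requires a group member as source; a population with no groups
  receives no injections. Consequently a state with no mutual ties at all
  is absorbing — and reachable: when several size-2 groups coexist above
  the optimal total, simultaneous shedding can extinguish every mutual tie
  in one step. At `N = 40, R = 5, T_prob = 0.2` about 8% of replicates
  freeze this way, which makes final exclusivity bimodal (frozen replicates
  retain only transient weight, `E ~ 0.1`; group-bearing replicates reach
  `E ~ 0.98` by step 1000). Mean `E` over many replicates is therefore
  close to 0.90 rather than 1, and estimates of it converge slowly.
- **RNG.** One `numpy` PCG64 generator per replicate, seeded from the
  replicate seed. The reproductive model splits two child streams off the
  seed (dynamics; permutation null), so trajectories are invariant to the
  relatedness cadence. Grid replicate seeds hash `(master seed, N, R,
  round(1000*T_prob), replicate)` through `SeedSequence`: any subset of a
  sweep, in any execution order, reproduces the full sweep's values.
- **Relatedness cadence.** `l_m`, `l_r`, `L_t` are computed every
  `relatedness_every` steps (default 10) and always at the final step; the
  permutation null is the one expensive metric and this keeps long runs
  tractable without touching the dynamics.
- **Extinction** truncates a reproductive run cleanly and flags the result;
  it is never restarted silently.
- **Degenerate inputs.** `R > N` is allowed (with a CLI warning): no group
  can reach optimal size. Adding a tie with a saturated out-neighborhood is
  a no-op. Empty populations and empty pedigrees raise errors rather than
  returning conventional values; undefined metrics return missing.

## Reference experiment scales

The sensitivity sweep spans `N ∈ {2, 7, ..., 197}`, `R ∈ {5, 7, ..., 51}`,
`T_prob ∈ {0.2, 0.5, 0.8}`, with 500 replicates per baseline cell (run for
`N*5` steps) and 100 replicates per reproductive cell (1000 steps). The
package's own test suite exercises desk-scale versions chosen to keep the
full suite in minutes on one CPU: a 4x4 `N x R` subsample at 3 replicates
for the exclusivity trend, 15 replicates per cell for the equal-allocation
check, 100-300 replicates for the single-cell quantitative anchors, and 100
reproductive replicates for the pedigree-depth statistic. The acceptance
script (below, and `README.md`) uses the same scales.

## What the simulations do and do not show

All inputs are synthetic by construction — the model is the object of
study, there is no empirical data path. The generator's defaults are the
reference conditions above. Passing tests show that the implemented rules
reproduce the model's published equilibria and patterns (single optimal
group, patch monopolization, kin-structured groups, their parameter
trends); they say nothing about real foraging populations, which the model
idealizes heavily (no space, no energetics, no memory, no mate choice, one
resource patch, one sex). Known limitations worth restating: the
relatedness formula undercounts conventional full-sib relatedness (see
above); exclusivity depends on run length through its time-normalized
denominator; and the no-group absorbing state means a minority of baseline
replicates never recovers a group, which any aggregate over replicates must
include.
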