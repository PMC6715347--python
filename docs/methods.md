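# Methods

## Model overview and assumptions

`gamsig` couples a deterministic signaling layer to a stochastic
individual-based evolutionary loop.

The signaling layer treats ligand and receptor as membrane-bound molecules
whose interactions are strictly local: there is no diffusible pheromone field
and no population-scale signaling. Within a cell, each ligand–receptor pair
obeys mass-action production, reversible binding and first-order degradation.
Because production and turnover are assumed much faster than cell encounters,
a cell's concentrations are at their kinetic steady state whenever it meets a
partner. The two pairs (L, R) and (l, r) are mutually incompatible — no
cross-binding terms exist anywhere in the model — so each pair's steady state
is solved independently.

The steady state is obtained in closed form: eliminating the complex via
`[LR] = k+ [L][R] / (k− + γ_LR)` reduces the equilibrium system to one
quadratic in `[L]` whose unique nonnegative root is taken (the other root is
negative whenever production is positive). We solve this quadratic directly
rather than transcribing published closed-form expressions, and verify the
solver against long-time stiff ODE integration (100 random parameter draws,
relative agreement < 1e−6) and against the flux-balance identities
`nu_L = γ_L [L]* + γ_LR [LR]*`, `nu_R = γ_R [R]* + γ_LR [LR]*`, which hold to
1e−9 relative. With a common degradation rate the difference identity
`[L]* − [R]* = (nu_L − nu_R)/γ` is exact. The quadratic is evaluated in the
cancellation-free form `2 nu_L γ_R / (b + √disc)` when `b > 0`, which matters
when the binding channel is weak (`k+ → 0`).

The between-cell signal received by cell 1 from cell 2 is, per pair,
`kb [L2]* [R1]* (1 − [LR1]*/([LR1]* + kb [L2]* [R1]*))^n`, summed over the two
pairs. The bracket is the fraction of the receiver's receptor activation
attributable to the partner rather than to self-binding; `n` tunes how
severely self-activation corrupts the readout (n = 0 leaves only the
depletion cost). When both the receiver's complex and the cross term are zero
the pair's contribution is defined as 0, the continuous limit. Mating
probability is `P = W12 W21/(K + W12 W21)`.

**Saturation constant K.** K is calibrated once per kinetic configuration to
the maximum of `W12·W21` over the feasible genotype space, making P ≤ 1/2 and
nearly linear in the interaction strength, so only relative signaling quality
matters. The calibration runs a coarse grid search (default step 0.25 per
rate, respecting the per-locus budgets) with Nelder–Mead refinement, and
always checks the fully asymmetric complementary pair (α,0,0,α)↔(0,α,α,0)
explicitly. That pair in fact attains the analytic upper bound: flux balance
gives `[L]* ≤ nu_L/γ_L` with equality only when the cell binds none of that
pair's partner molecule, the readout bracket is ≤ 1, and the per-locus budget
caps `x·y + (α−x)(α−y)` at α², so `W12 ≤ kb α²/(γ_L γ_R)` with equality at
the fully asymmetric pair. Hence `K = kb² α⁴/(γ_L γ_R)²` exactly (e.g. K =
400 for kb = 5, γ = 0.5, α = 1), and the grid resolution does not affect the
result.

## Evolutionary loop

A generation applies, in order: (1) mutation of all four production genes in
every cell and of the recombination-modifier allele; (2) refresh of the
per-cell steady states; (3) the mating lottery until M cells have mated;
(4) recombination within each mated pair; (5) regulation back to N cells by
resampling the M offspring with replacement. Mutation precedes mating and
offspring are not re-mutated within a generation; the ordering is fixed and
documented here because the cycle's verbal description does not pin it down.

**Mutation.** Each gene independently receives a Normal(0, σ) increment with
probability μ. A proposal outside [0, α] is discarded (the gene keeps its
value). If the two genes at a locus then sum above the budget α they are
rescaled proportionally so the sum equals α, preserving their ratio. The
modifier mutates with probability μ_ρ by Normal(0, σ_ρ) and is clamped to
[0, 0.5]; clamping (rather than rejection) is used because ρ is a probability
with hard physical bounds, whereas the production-rate rule is stated as
rejection.

**Mating lottery.** Pairs of distinct cells are drawn uniformly at random
from the unmated pool and accepted with probability P; rejected cells return
to the pool; sampling repeats until M cells (M/2 pairs) have mated. The
implementation exploits that a failed draw leaves the state unchanged: the
next accepted pair is distributed over current-pool pairs with weight P, so
we draw pairs uniformly and accept with `P/Pmax`, where `Pmax` comes from the
analytic bound on `W12·W21` above evaluated at the population's current
maxima of free ligand and receptor. This thinning is exactly equivalent to
one-at-a-time rejection sampling but skips the millions of certain-to-fail
draws that occur when typical P is ~1e−4 (the low-γ regimes). A population in
which no pair can signal (bound = 0, e.g. all cells fully asymmetric of one
type) raises a deadlock error immediately — such a population is not viable —
and a cap on (equivalent) pair draws, default 1e8 per generation, guards the
nearly-incompatible case. The cap is sized to clear healthy invasion runs at
N = 1000, which need ~1e7 draw-equivalents per generation while a
weakly-compatible resident still dominates.

**Recombination.** The two ligand genes are tightly linked at one locus, the
two receptor genes at another; the modifier sits between them at equal
distances, and only recombination between the loci is modeled. For parents
R1–M1–L1 and R2–M2–L2 with joint rate `ρ12 = (ρ1 + ρ2)/2`, the two offspring
are one of four complementary configurations: parental with probability
(1−ρ12)², modifier exchanged with probability ρ12² (two crossovers), and the
two single-crossover arrangements with probability ρ12(1−ρ12) each. The two
offspring are exactly the two products of one meiosis — gene content per pair
is conserved, recombination shuffles haplotypes and never creates rates.
Note the marginal ligand–receptor recombination fraction is 2ρ(1−ρ).

**Convergence.** A run is at mutation–selection balance when |s(t) −
s(t−100)| < ε (default 1e−5; 1e−7 for the no-mutation invasion experiments),
checked every 100 generations; linkage runs additionally require the same
condition on mean ρ. Noisy parameter sets simply run to the generation cap —
under recurrent mutation the pointwise criterion rarely fires, by design.
Reported steady-state values (s*, ρ*) average the trailing 1000 generations.

## Experiments and defaults

Defaults follow the reference parameterization: N = 1000, M = N/2, μ = 0.01
per gene per generation, σ = 0.1, k− = 1, kb = k+/k− (equal within- and
between-cell affinity), n = 1, α = 1. `kb` is treated as a dimensionless
coupling: the model's formulas are followed literally even though an affinity
and a rate carry different units. Equilibrium experiments start monomorphic
at (1,1,0,0) (with a fixed ρ where relevant); invasion experiments introduce
mutants at frequency p with μ = μ_ρ = 0; the invasibility grid exposes p
because reported values for it disagree between 0.01 and 0.001.
Linkage coevolution starts at ρ = 0.5 with 1000 generations of modifier-only
drift before signaling mutation begins. Sweeps recalibrate K at every kinetic
grid point, log one spawned seed per replicate so any heatmap cell is
independently reproducible, and the E1→E2 threshold along a k+ grid is
reported as the midpoint between the last point with mean s* > 0.9 and the
first with mean s* < 0.1 (no standard rule exists; this one is symmetric and
resolution-limited). Genotype composition is summarized by nearest-archetype
binning (radius 0.25 around the eight reference genotypes, else "other") to
make statements like "the population consists of (1,0,0,1) and (0,1,1,0)"
operational.

Desk scale: at N = 1000 the engine runs ~2–10 ms per generation, so the
bundled 10⁴–2×10⁴-generation scenarios take one to a few minutes each; the
test suite uses N = 100–200 and hundreds of generations for everything except
the end-to-end reproductions.

## What the simulations do and do not show

The generator *is* the model: runs emulate a well-mixed haploid population
with synchronous sexual rounds, two signaling channels, and a single
recombination modifier. They do not emulate spatial structure, diffusible
long-range pheromones, more than two ligand–receptor pairs, diploid selection
(the zygote exists only to recombine), unequal within/between affinities
beyond the scalar kb, or asexual rounds between sexual episodes. Passing
tests therefore support the internal logic of the signaling-selection
mechanism, not its quantitative transfer to any real organism.

## Known limitations and open points

- **Low-degradation symmetric equilibrium.** At γ = 0.1, k+ = 1, kb = 1,
  n = 1 the symmetric state (1,1,0,0) is *not* an attractor of this
  implementation for any tested mutation s.d. (σ from 0.02 to 0.1): free
  concentrations scale as ν/γ, so a complementary pair of one-σ asymmetric
  mutants already gains more from a clean second channel (+23% joint
  interaction strength at σ = 0.1) than each loses alone (−7%), and the
  population slides to the asymmetric equilibrium. The same parameter set at
  γ = 0.5 holds the symmetric equilibrium for >10⁴ generations, and all
  γ = 0.5 regimes reproduce the reference outcomes with σ = 0.1. The
  acceptance script reports the measured low-γ value as-is; see the
  repository's decision log for the full analysis. The alternative
  "reject mutations that break the locus budget" reading of the cap rule
  stabilizes the symmetric state everywhere but then the asymmetric
  equilibrium never evolves at all, so it was discarded.
- The modifier's mutation s.d. σ_ρ is not separately documented in the
  reference parameter lists; it defaults to σ = 0.1.
- With α ≠ 1 the per-gene rejection bound is [0, α] (the natural
  generalization of the unit bound); results with synergy/competition caps
  should state this.
- The mating lottery's selection intensity is set by the process itself:
  because sampling continues until M cells mate, a genotype's realized
  fitness deficit is smaller than its deficit in interaction strength
  (late in each round even weak cells mate). This is a property of the
  described life cycle, not an implementation artifact.
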